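"""Synthetic fixture generator with planted ground truth.

Emits an internally consistent set of all pipeline inputs — replicate
abundance table, orthologue map, FASTA, per-receptor interactor lists,
iLIR-style list, domain and DDI tables, curated process-effect table,
transcript DE table and marker list — together with the bookkeeping needed
to verify every stage against the planted truth.  Default parameters state
the published experimental world: 3 replicates per condition, 70% of
differential proteins more abundant, 41% targeted, 19% of targets
multi-receptor, per-process contribution tallies whose first two reproduce
the printed 19/25 and 5/7 fractions, a 90% turnover fraction among
DE-transcribed genes, and an 83-gene marker list with 56 members planted
in the DE pool.

All randomness flows through one ``numpy`` generator seeded from the
scenario, so equal specs produce byte-identical fixture sets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    FilterConfig,
    OrthologPair,
    PipelineConfig,
    ProcessEffect,
    RECEPTORS,
    ScenarioSpecError,
    TranscriptRecord,
    write_fasta,
    write_transcript_table,
    _write_tsv,
)
from .targets import AMINO_ACIDS, MotifDefinition, XLIR_PATTERN, scan_motif

__all__ = ["ScenarioSpec", "GroundTruth", "FixtureBundle",
           "generate_scenario", "write_fixture_set"]

P62_PATTERN_DEFAULT = "[DE][DE][WFY]xx[LIV]"  # configurable working default
# Fixed planted instances, chosen so neither instance matches the other
# motif's pattern (cross-matches would corrupt the planted evidence truth).
_XLIR_INSTANCE = "PGWTAL"
_P62_INSTANCE = "DDWAAL"

_PROCESS_LABELS = (
    "apoptotic process", "DNA repair", "exocytosis", "endocytosis",
    "immune response", "mitochondrion organization", "cell adhesion",
    "protein transport", "oxidative stress response", "cytoskeleton organization",
)


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic world.

    Fractions mirror the published profile: 70% of differential proteins
    up, 41% of the human-mapped set targeted, 19% of targets hit by more
    than one receptor.  ``process_sizes`` / ``process_stim_fractions`` give
    each process's contribution count and stimulatory share (defaults put
    a 19/25-inhibitory and a 5/7-stimulatory process first).
    ``turnover_delta`` separates protein and transcript log2FC for the
    planted turnover subset and must exceed the 0.7 attribution cutoff.
    """

    n_proteins: int = 400
    frac_differential: float = 0.5
    frac_up_among_differential: float = 0.70
    frac_targeted: float = 0.41
    frac_multi_targeted: float = 0.19
    frac_peptide_fail: float = 0.05
    n_processes: int = 6
    process_sizes: tuple[int, ...] = (25, 7, 10, 15, 8, 12)
    process_stim_fractions: tuple[float, ...] = (
        6 / 25, 5 / 7, 0.5, 0.8, 0.375, 1.0)
    frac_no_transcript: float = 0.1
    turnover_fraction: float = 0.9
    turnover_delta: float = 1.5
    noise_sd: float = 0.25
    n_replicates: int = 3
    n_background_genes: int = 500
    n_background_de: int = 120
    n_markers: int = 83
    n_marker_de: int = 56
    sequence_length: int = 200
    min_abs_log2fc: float = 1.2
    max_abs_log2fc: float = 3.5
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("frac_differential", "frac_up_among_differential",
                     "frac_targeted", "frac_multi_targeted",
                     "frac_peptide_fail", "frac_no_transcript",
                     "turnover_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ScenarioSpecError(f"{name} must lie in [0, 1]")
        if self.frac_multi_targeted > self.frac_targeted:
            raise ScenarioSpecError(
                "frac_multi_targeted cannot exceed frac_targeted")
        if self.turnover_delta <= FilterConfig().delta_log2fc:
            raise ScenarioSpecError(
                "turnover_delta must exceed the 0.7 attribution cutoff")
        if len(self.process_sizes) != self.n_processes or \
                len(self.process_stim_fractions) != self.n_processes:
            raise ScenarioSpecError(
                "process_sizes/process_stim_fractions must have n_processes "
                "entries")
        if self.n_marker_de > min(self.n_markers, self.n_background_de):
            raise ScenarioSpecError(
                "n_marker_de cannot exceed n_markers or n_background_de")
        if self.n_proteins > 0:
            n_diff = round(self.frac_differential * self.n_proteins)
            n_targ = round(self.frac_targeted * (n_diff + 1))
            if sum(self.process_sizes) > max(n_targ, 0):
                raise ScenarioSpecError(
                    f"process contributions ({sum(self.process_sizes)}) "
                    f"exceed the planted targeted set ({n_targ})")
        if self.min_abs_log2fc < 1.0:
            raise ScenarioSpecError(
                "min_abs_log2fc below 1 cannot guarantee |FC| >= 2")


@dataclass
class GroundTruth:
    """Planted truth, consistent with the emitted tables by construction."""

    differential: dict[str, str] = field(default_factory=dict)  # mouse -> dir
    planted_log2fc: dict[str, float] = field(default_factory=dict)  # mouse
    peptide_fail: list[str] = field(default_factory=list)
    ortholog: dict[str, list[str]] = field(default_factory=dict)
    expanded_mouse_id: str | None = None
    human_differential: dict[str, dict] = field(default_factory=dict)
    targeted: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    motif_positions: dict[str, list] = field(default_factory=dict)
    process_truth: dict[str, dict] = field(default_factory=dict)
    attribution: dict[str, str] = field(default_factory=dict)
    marker_overlap_k: int = 0
    de_genes: list[str] = field(default_factory=list)

    @property
    def n_differential(self) -> int:
        return len(self.differential)

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.differential.values() if d == "up")


@dataclass
class FixtureBundle:
    """All generated input tables plus the ground truth."""

    spec: ScenarioSpec
    abundance: pd.DataFrame
    orthologs: list[OrthologPair]
    fasta: dict[str, str]
    interactors: dict[str, list[str]]
    lir_list: list[str]
    domains: list[tuple[str, str]]
    ddi: list[tuple[str, str]]
    effects: list[ProcessEffect]
    transcripts: list[TranscriptRecord]
    markers: list[str]
    truth: GroundTruth


def _classify(n_stim: int, n_total: int, threshold: float = 0.70) -> str:
    frac = n_stim / n_total
    if frac > threshold:
        return "upregulated"
    if (1.0 - frac) > threshold:
        return "downregulated"
    return "dual"


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _motif_free_sequence(rng: np.random.Generator, length: int,
                         motifs: list[MotifDefinition]) -> str:
    for _ in range(500):
        seq = _random_sequence(rng, length)
        if all(not scan_motif(seq, m) for m in motifs):
            return seq
    raise ScenarioSpecError(
        f"could not draw a motif-free sequence of length {length}")


def _sequence_with_motifs(rng: np.random.Generator, length: int,
                          plant: list[tuple[MotifDefinition, str]],
                          all_motifs: list[MotifDefinition],
                          ) -> tuple[str, list[tuple[str, int]]]:
    """Sequence containing exactly the planted motif instances.

    Returns (sequence, [(motif name, 1-based position), ...]); retries until
    scanning each motif recovers exactly its planted occurrence(s).
    """
    for _ in range(500):
        seq = list(_motif_free_sequence(rng, length, all_motifs))
        positions: list[tuple[str, int]] = []
        cursor = 0
        ok = True
        for motif, instance in plant:
            lo = cursor
            hi = length - len(instance)
            if lo > hi:
                ok = False
                break
            start = int(rng.integers(lo, hi + 1))
            seq[start:start + len(instance)] = list(instance)
            positions.append((motif.name, start + 1))
            cursor = start + len(instance)
        if not ok:
            continue
        text = "".join(seq)
        wanted: dict[str, set[int]] = {}
        for name, pos in positions:
            wanted.setdefault(name, set()).add(pos)
        if all({p for p, _ in scan_motif(text, m)} == wanted.get(m.name, set())
               for m in all_motifs):
            return text, positions
    raise ScenarioSpecError("motif planting failed repeatedly")


def generate_scenario(spec: ScenarioSpec = ScenarioSpec()) -> FixtureBundle:
    """Generate the full fixture bundle for one scenario."""
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    n = spec.n_proteins
    mouse_ids = [f"MUP{i:05d}" for i in range(n)]
    human_of = {m: f"HUP{i:05d}" for i, m in enumerate(mouse_ids)}

    # --- plant differential / peptide-fail sets and directions -----------
    n_diff = round(spec.frac_differential * n)
    order = rng.permutation(n)
    diff_idx = sorted(order[:n_diff])
    n_pf = round(spec.frac_peptide_fail * n_diff)
    pf_idx = sorted(order[n_diff:n_diff + n_pf])
    n_up = round(spec.frac_up_among_differential * n_diff)
    up_set = set(rng.choice(diff_idx, size=n_up, replace=False).tolist()
                 ) if n_diff else set()

    plant = np.zeros(n)
    for i in diff_idx + pf_idx:
        mag = rng.uniform(spec.min_abs_log2fc, spec.max_abs_log2fc)
        if i in diff_idx:
            sign = 1.0 if i in up_set else -1.0
        else:
            sign = 1.0 if rng.random() < spec.frac_up_among_differential else -1.0
        plant[i] = sign * mag
    for i in diff_idx:
        truth.differential[mouse_ids[i]] = "up" if i in up_set else "down"
        truth.planted_log2fc[mouse_ids[i]] = float(plant[i])
    truth.peptide_fail = [mouse_ids[i] for i in pf_idx]

    # --- abundance table (log2-normal replicate noise) -------------------
    mu = rng.uniform(20.0, 28.0, size=n)
    rep = spec.n_replicates
    wt = mu[:, None] + rng.normal(0.0, spec.noise_sd, size=(n, rep))
    ko = (mu + plant)[:, None] + rng.normal(0.0, spec.noise_sd, size=(n, rep))
    peptides = rng.integers(2, 31, size=n)
    for i in pf_idx:
        peptides[i] = 1
    cols: dict[str, list] = {"protein_id": mouse_ids,
                             "unique_peptides": peptides.tolist()}
    for j in range(rep):
        cols[f"wt_{j + 1}"] = (2.0 ** wt[:, j]).tolist()
    for j in range(rep):
        cols[f"ko_{j + 1}"] = (2.0 ** ko[:, j]).tolist()
    abundance = pd.DataFrame(cols)

    # --- orthologue map: 1:1 everywhere plus exactly one 1:2 expansion ---
    orthologs = [OrthologPair(m, human_of[m], 1.0) for m in mouse_ids]
    if diff_idx:
        exp_i = diff_idx[0]
        exp_mouse = mouse_ids[exp_i]
        second = f"HUP{exp_i:05d}B"
        orthologs.append(OrthologPair(exp_mouse, second, 1.0))
        truth.expanded_mouse_id = exp_mouse
    for m in mouse_ids[: min(5, n)]:  # low-confidence decoys
        orthologs.append(OrthologPair(m, f"HLX{m[3:]}", 0.5))
    for m in mouse_ids:
        truth.ortholog[m] = [p.human_id for p in orthologs
                             if p.mouse_id == m and p.confidence >= 1.0]

    human_diff: list[str] = []
    for i in diff_idx:
        m = mouse_ids[i]
        for h in truth.ortholog[m]:
            human_diff.append(h)
            truth.human_differential[h] = {
                "direction": truth.differential[m],
                "log2fc": truth.planted_log2fc[m],
                "mouse_id": m,
            }

    # --- targeting plan ---------------------------------------------------
    n_h = len(human_diff)
    n_targ = round(spec.frac_targeted * n_h)
    targeted = sorted(rng.choice(human_diff, size=n_targ,
                                 replace=False).tolist()) if n_targ else []
    n_multi = round(spec.frac_multi_targeted * n_targ)
    multi = set(rng.choice(targeted, size=n_multi,
                           replace=False).tolist()) if n_multi else set()
    channel_options = {
        "p62": ("experimental", "p62_motif"),
        "LC3": ("experimental", "database_list", "lir_motif"),
        "ATG16L1": ("experimental", "ddi"),
    }
    for h in targeted:
        k = 2 if h in multi else 1
        receptors = rng.choice(list(RECEPTORS), size=k, replace=False)
        truth.targeted[h] = {}
        for r in receptors:
            ch = str(rng.choice(channel_options[str(r)]))
            truth.targeted[h][str(r)] = [ch]

    # --- FASTA with planted / excluded motifs -----------------------------
    xlir = MotifDefinition.from_string("xLIR", XLIR_PATTERN, source="iLIR")
    p62m = MotifDefinition.from_string("p62", P62_PATTERN_DEFAULT,
                                       source="synthetic default")
    fasta: dict[str, str] = {}
    for h in human_diff:
        to_plant: list[tuple[MotifDefinition, str]] = []
        for r, chans in truth.targeted.get(h, {}).items():
            if "lir_motif" in chans:
                to_plant.append((xlir, _XLIR_INSTANCE))
            if "p62_motif" in chans:
                to_plant.append((p62m, _P62_INSTANCE))
        if to_plant:
            seq, positions = _sequence_with_motifs(
                rng, spec.sequence_length, to_plant, [xlir, p62m])
            fasta[h] = seq
            truth.motif_positions[h] = positions
        else:
            fasta[h] = _motif_free_sequence(rng, spec.sequence_length,
                                            [xlir, p62m])

    # --- interactor / iLIR lists -----------------------------------------
    non_diff_humans = [human_of[m] for i, m in enumerate(mouse_ids)
                       if i not in set(diff_idx)]
    interactors: dict[str, list[str]] = {}
    for r in RECEPTORS:
        members = [h for h, recs in truth.targeted.items()
                   if "experimental" in recs.get(r, [])]
        n_decoy = min(10, len(non_diff_humans))
        decoys = rng.choice(non_diff_humans, size=n_decoy,
                            replace=False).tolist() if n_decoy else []
        interactors[r] = sorted(members + decoys)
    lir_members = [h for h, recs in truth.targeted.items()
                   if "database_list" in recs.get("LC3", [])]
    n_decoy = min(10, len(non_diff_humans))
    lir_decoys = rng.choice(non_diff_humans, size=n_decoy,
                            replace=False).tolist() if n_decoy else []
    lir_list = sorted(lir_members + lir_decoys)

    # --- domain annotations and DDI pairs --------------------------------
    domains: list[tuple[str, str]] = [("ATG16L1", "PF00400")]
    ddi: list[tuple[str, str]] = []
    for idx, h in enumerate(sorted(truth.targeted)):
        if "ddi" in truth.targeted[h].get("ATG16L1", []):
            dom = f"PF{10000 + idx:05d}"
            domains.append((h, dom))
            ddi.append(("PF00400", dom))
    for idx, h in enumerate(human_diff):
        if "ddi" not in truth.targeted.get(h, {}).get("ATG16L1", []):
            if rng.random() < 0.5:  # decoy domains, never partnered to WD40
                domains.append((h, f"PF9{idx:04d}"))
    ddi.append(("PF90000", "PF90001"))  # decoy pair among decoy domains

    # --- curated process effects ------------------------------------------
    effects: list[ProcessEffect] = []
    for j in range(spec.n_processes):
        size = spec.process_sizes[j]
        if size == 0 or not targeted:
            continue
        pid = f"GO:{7000000 + j}"
        label = _PROCESS_LABELS[j % len(_PROCESS_LABELS)]
        chosen = rng.choice(targeted, size=size, replace=False).tolist()
        n_stim = round(spec.process_stim_fractions[j] * size)
        for pos, h in enumerate(chosen):
            stim = pos < n_stim
            direction = truth.human_differential[h]["direction"]
            effect = ("activation" if (direction == "up") == stim
                      else "inhibition")
            effects.append(ProcessEffect(h, pid, label, effect, True))
        truth.process_truth[pid] = {
            "label": label, "n_stimulatory": n_stim,
            "n_inhibitory": size - n_stim,
            "classification": _classify(n_stim, size),
        }
    if targeted:  # out-of-context decoy rows, discarded by the curation flag
        for h in targeted[: min(5, len(targeted))]:
            effects.append(ProcessEffect(h, "GO:0001508", "action potential",
                                         "activation", False))

    # --- transcripts, turnover plan, background and markers ---------------
    transcripts: list[TranscriptRecord] = []
    n_t = len(targeted)
    n_no_t = round(spec.frac_no_transcript * n_t)
    no_transcript = set(rng.choice(targeted, size=n_no_t,
                                   replace=False).tolist()) if n_no_t else set()
    with_t = [h for h in targeted if h not in no_transcript]
    n_turn = round(spec.turnover_fraction * len(with_t))
    turnover = set(rng.choice(with_t, size=n_turn,
                              replace=False).tolist()) if n_turn else set()
    for h in targeted:
        p = truth.human_differential[h]["log2fc"]
        if h in no_transcript:
            truth.attribution[h] = "no_transcript"
            continue
        if h in turnover:
            t = p - float(np.sign(p)) * spec.turnover_delta
            truth.attribution[h] = "turnover"
        else:
            t = p + rng.uniform(-0.2, 0.2)
            truth.attribution[h] = "transcriptional"
        transcripts.append(TranscriptRecord(h, float(t), 0.01))
    for h in human_diff:  # non-targeted differential genes track the protein
        if h not in targeted:
            p = truth.human_differential[h]["log2fc"]
            transcripts.append(TranscriptRecord(
                h, float(p + rng.uniform(-0.2, 0.2)), 0.01))

    bg_ids = [f"GENE{j:05d}" for j in range(spec.n_background_genes)]
    bg_de = bg_ids[: spec.n_background_de]
    for j, g in enumerate(bg_ids):
        if g in set(bg_de):
            fc = rng.uniform(1.5, 3.0) * (1.0 if rng.random() < 0.5 else -1.0)
            transcripts.append(TranscriptRecord(g, float(fc), 0.01))
        else:
            transcripts.append(TranscriptRecord(
                g, float(rng.uniform(-0.5, 0.5)),
                float(rng.uniform(0.06, 0.9))))
    markers = sorted(
        rng.choice(bg_de, size=spec.n_marker_de, replace=False).tolist()
        + rng.choice(bg_ids[spec.n_background_de:],
                     size=spec.n_markers - spec.n_marker_de,
                     replace=False).tolist())
    truth.marker_overlap_k = spec.n_marker_de

    cfg = FilterConfig()
    truth.de_genes = sorted(
        t.gene_id for t in transcripts
        if abs(t.log2fc) >= cfg.transcript_abs_log2fc_min
        and t.q_value <= cfg.transcript_q_max)

    return FixtureBundle(
        spec=spec, abundance=abundance, orthologs=orthologs, fasta=fasta,
        interactors=interactors, lir_list=lir_list, domains=domains,
        ddi=ddi, effects=effects, transcripts=transcripts, markers=markers,
        truth=truth)


def write_fixture_set(bundle: FixtureBundle,
                      outdir: str | Path) -> PipelineConfig:
    """Write every fixture file in the dialects the readers consume.

    Returns a PipelineConfig pointing at the written files (also saved as
    ``config.yaml``); the ground truth is saved alongside as JSON for
    inspection but is never read by the pipeline.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.abundance, out / "abundance.tsv")
    _write_tsv(pd.DataFrame(
        [{"mouse_id": p.mouse_id, "human_id": p.human_id,
          "confidence": repr(p.confidence)} for p in bundle.orthologs],
        columns=["mouse_id", "human_id", "confidence"]),
        out / "orthologs.tsv")
    write_fasta(bundle.fasta, out / "sequences.fasta")
    interactor_paths = {}
    for receptor, members in bundle.interactors.items():
        path = out / f"interactors_{receptor}.tsv"
        _write_tsv(pd.DataFrame({"id": members}, columns=["id"]), path)
        interactor_paths[receptor] = str(path)
    _write_tsv(pd.DataFrame({"id": bundle.lir_list}, columns=["id"]),
               out / "ilir.tsv")
    _write_tsv(pd.DataFrame(bundle.domains,
                            columns=["protein_id", "domain_accession"]),
               out / "domains.tsv")
    _write_tsv(pd.DataFrame(bundle.ddi, columns=["domain_a", "domain_b"]),
               out / "ddi.tsv")
    _write_tsv(pd.DataFrame(
        [{"protein_id": e.protein_id, "process_id": e.process_id,
          "process_label": e.process_label, "effect": e.effect,
          "in_context": int(e.in_context)} for e in bundle.effects],
        columns=["protein_id", "process_id", "process_label", "effect",
                 "in_context"]),
        out / "effects.tsv")
    write_transcript_table(bundle.transcripts, out / "transcripts.tsv")
    _write_tsv(pd.DataFrame({"id": bundle.markers}, columns=["id"]),
               out / "markers.tsv")

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(dataclasses.asdict(bundle.truth), fh, indent=1,
                  sort_keys=True)

    config = PipelineConfig(
        abundance=str(out / "abundance.tsv"),
        orthologs=str(out / "orthologs.tsv"),
        fasta=str(out / "sequences.fasta"),
        interactors=interactor_paths,
        lir_list=str(out / "ilir.tsv"),
        domains=str(out / "domains.tsv"),
        ddi=str(out / "ddi.tsv"),
        effects=str(out / "effects.tsv"),
        transcripts=str(out / "transcripts.tsv"),
        markers=str(out / "markers.tsv"),
        outdir=str(out / "results"),
        seed=bundle.spec.seed,
        p62_motif=P62_PATTERN_DEFAULT,
    )
    config.to_yaml(out / "config.yaml")
    return config
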