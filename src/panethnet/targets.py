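"""Selective-autophagy target prediction for differential proteins.

Each human-mapped differential protein is tested for potential targeting by
the receptor/adaptor trio p62, LC3 and ATG16L1 through three evidence
channels: membership in experimentally curated interactor lists (Autophagy
Regulatory Network style), short-linear-motif scanning (LIR motifs for LC3,
a recognition motif for p62), and domain-domain-interaction (DDI) inference
for ATG16L1 (a candidate is predicted when one of its Pfam domains is a
known interaction partner of an ATG16L1 domain).  Evidence rows are
deduplicated and summarized as a three-set Venn partition.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import (
    RECEPTORS,
    Receptor,
    SequenceAlphabetError,
    TargetEvidence,
    logger,
)
from .differential import DifferentialProtein

__all__ = [
    "AMINO_ACIDS", "MotifDefinition", "LIR_CORE_PATTERN", "XLIR_PATTERN",
    "scan_motif", "predict_ddi_targets", "collect_evidence",
    "VennCounts", "overlap_partition",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Canonical LIR core and the extended xLIR definition used by the iLIR
# resource, written as position-restricted alphabets ('x' = any residue).
LIR_CORE_PATTERN = "[WFY]xx[LIV]"
XLIR_PATTERN = "[ADEFGLPRSK][DEGMSTV][WFY][DEILQTV][ADEFHIKLMPSTV][ILV]"


@dataclass(frozen=True)
class MotifDefinition:
    """A short linear motif as a list of per-position allowed alphabets.

    An empty string at a position is the wildcard 'x' (any residue,
    including the ambiguity code X); restricted positions never match X.
    """

    name: str
    positions: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError(f"motif {self.name}: pattern length must be >= 3")
        for i, alphabet in enumerate(self.positions):
            if any(ch not in AMINO_ACIDS for ch in alphabet):
                raise ValueError(
                    f"motif {self.name}: position {i + 1} alphabet "
                    f"{alphabet!r} outside the amino-acid alphabet")

    @classmethod
    def from_string(cls, name: str, pattern: str,
                    source: str = "") -> "MotifDefinition":
        """Parse a compact pattern like ``[WFY]xx[LIV]``."""
        positions: list[str] = []
        for token in re.findall(r"\[([A-Z]+)\]|([A-Zx])", pattern):
            bracket, single = token
            if bracket:
                positions.append(bracket)
            elif single == "x":
                positions.append("")
            else:
                positions.append(single)
        return cls(name=name, positions=tuple(positions), source=source)

    def __len__(self) -> int:
        return len(self.positions)


def scan_motif(sequence: str,
               motif: MotifDefinition) -> list[tuple[int, str]]:
    """All (1-based start, matched substring) motif occurrences, ascending.

    Overlapping matches are all reported.  X is tolerated in the sequence
    but never satisfies a restricted position.
    """
    for i, ch in enumerate(sequence):
        if ch not in AMINO_ACIDS and ch != "X":
            raise SequenceAlphabetError(
                f"illegal character {ch!r} at position {i + 1}")
    m = len(motif)
    hits: list[tuple[int, str]] = []
    for start in range(len(sequence) - m + 1):
        window = sequence[start:start + m]
        ok = True
        for ch, alphabet in zip(window, motif.positions):
            if alphabet and ch not in alphabet:
                ok = False
                break
        if ok:
            hits.append((start + 1, window))
    return hits


def predict_ddi_targets(
    query_domains: Iterable[str],
    candidates: Iterable[tuple[str, str]],
    ddi: set[frozenset[str]],
) -> set[str]:
    """Proteins carrying a domain known to interact with a query domain.

    ``candidates`` are (protein_id, domain_accession) annotation pairs;
    proteins with no annotation are simply never predicted.
    """
    query = set(query_domains)
    hits: set[str] = set()
    for protein_id, domain in candidates:
        for q in query:
            if frozenset((q, domain)) in ddi:
                hits.add(protein_id)
                break
    return hits


def ddi_partner_pairs(
    query_domains: Iterable[str],
    domains_of: Mapping[str, set[str]],
    ddi: set[frozenset[str]],
) -> dict[str, list[tuple[str, str]]]:
    """Per-protein list of (query domain, candidate domain) supporting pairs."""
    out: dict[str, list[tuple[str, str]]] = {}
    for protein_id, doms in domains_of.items():
        pairs = [(q, d) for q in sorted(set(query_domains))
                 for d in sorted(doms) if frozenset((q, d)) in ddi]
        if pairs:
            out[protein_id] = pairs
    return out


def collect_evidence(
    proteins: Sequence[tuple[str, DifferentialProtein]],
    sequences: Mapping[str, str],
    interactor_lists: Mapping[str, Iterable[str]],
    lir_list: Iterable[str],
    p62_motif: MotifDefinition,
    lir_motif: MotifDefinition,
    domains: Sequence[tuple[str, str]],
    ddi: set[frozenset[str]],
    atg16l1_id: str = "ATG16L1",
) -> list[TargetEvidence]:
    """Union of all targeting evidence for the human-mapped differential set.

    Channels: curated interactor lists per receptor (experimental); iLIR
    list membership (database_list -> LC3); LIR motif scan (lir_motif ->
    LC3); p62 recognition-motif scan (p62_motif -> p62); DDI inference
    against ATG16L1's own domains (ddi -> ATG16L1).  Proteins missing from
    the FASTA are logged and skip the motif channels only.
    """
    human_ids = [hid for hid, _ in proteins]
    id_set = set(human_ids)
    evidence: set[TargetEvidence] = set()

    for receptor, members in interactor_lists.items():
        if receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {receptor!r} in interactor lists")
        for hid in members:
            if hid in id_set:
                evidence.add(TargetEvidence(hid, receptor, "experimental", "ARN"))

    for hid in lir_list:
        if hid in id_set:
            evidence.add(TargetEvidence(hid, "LC3", "database_list", "iLIR"))

    missing_fasta = []
    for hid in human_ids:
        seq = sequences.get(hid)
        if seq is None:
            missing_fasta.append(hid)
            continue
        for pos, match in scan_motif(seq, p62_motif):
            evidence.add(TargetEvidence(hid, "p62", "p62_motif",
                                        f"{pos}:{match}"))
        for pos, match in scan_motif(seq, lir_motif):
            evidence.add(TargetEvidence(hid, "LC3", "lir_motif",
                                        f"{pos}:{match}"))
    if missing_fasta:
        logger.warning("targets: %d differential proteins absent from FASTA; "
                       "motif channels skipped for them: %s",
                       len(missing_fasta), ", ".join(sorted(missing_fasta)))

    domains_of: dict[str, set[str]] = {}
    for pid, dom in domains:
        domains_of.setdefault(pid, set()).add(dom)
    query_domains = sorted(domains_of.get(atg16l1_id, set()))
    if not query_domains:
        logger.warning("targets: no domain annotation for ATG16L1 accession "
                       "%r; DDI channel inactive", atg16l1_id)
    candidate_domains = {hid: domains_of.get(hid, set()) for hid in id_set}
    for hid, pairs in ddi_partner_pairs(query_domains, candidate_domains,
                                        ddi).items():
        for q, d in pairs:
            evidence.add(TargetEvidence(hid, "ATG16L1", "ddi", f"{q}~{d}"))

    out = sorted(evidence, key=lambda e: (e.human_id, e.receptor,
                                          e.evidence_type, e.detail))
    logger.info("targets: %d evidence rows over %d distinct proteins",
                len(out), len({e.human_id for e in out}))
    return out


@dataclass
class VennCounts:
    """Disjoint 7-cell overlap partition of the targeted protein set."""

    cells: dict[tuple[Receptor, ...], int] = field(default_factory=dict)
    n_targeted: int = 0
    n_multi: int = 0
    fraction_multi: float = 0.0
    empty: bool = False

    def cell(self, *receptors: Receptor) -> int:
        return self.cells.get(tuple(sorted(receptors)), 0)


def overlap_partition(evidence: Sequence[TargetEvidence]) -> VennCounts:
    """Partition targeted proteins into the 7 receptor-combination cells.

    Cells are disjoint and sum to the number of distinct targeted proteins;
    ``fraction_multi`` is the share targeted by two or more receptors (0,
    with ``empty`` flagged, when nothing is targeted).
    """
    by_protein: dict[str, set[Receptor]] = {}
    for ev in evidence:
        by_protein.setdefault(ev.human_id, set()).add(ev.receptor)
    cells: dict[tuple[Receptor, ...], int] = {
        tuple(sorted(combo)): 0
        for r in range(1, 4)
        for combo in itertools.combinations(RECEPTORS, r)}
    for receptors in by_protein.values():
        cells[tuple(sorted(receptors))] += 1
    n_targeted = len(by_protein)
    n_multi = sum(1 for rs in by_protein.values() if len(rs) >= 2)
    return VennCounts(
        cells=cells,
        n_targeted=n_targeted,
        n_multi=n_multi,
        fraction_multi=(n_multi / n_targeted) if n_targeted else 0.0,
        empty=(n_targeted == 0),
    )
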