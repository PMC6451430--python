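"""Shared domain types, table readers/writers, configuration and logging.

Every tabular format the pipeline touches is plain TSV with a header row;
sequences are FASTA.  Readers reject malformed input with errors that name
the offending column or row, and every reader/writer pair round-trips
losslessly on valid data so that stage outputs can be diffed bit-exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("panethnet")

Receptor = Literal["p62", "LC3", "ATG16L1"]
RECEPTORS: tuple[Receptor, ...] = ("p62", "LC3", "ATG16L1")

EVIDENCE_TYPES = ("experimental", "lir_motif", "p62_motif", "ddi", "database_list")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PanethNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PanethNetError):
    """Invalid configuration: missing column, empty mapping table, bad paths."""


class TableParseError(PanethNetError):
    """Malformed cell in a delimited input table; message cites the row."""


class InsufficientReplicatesError(PanethNetError):
    """A statistical test received a group with fewer than two values."""


class DegenerateInputError(PanethNetError):
    """Numerically degenerate input (e.g. non-positive mean after flooring)."""


class SequenceAlphabetError(PanethNetError):
    """Illegal character in an amino-acid sequence; message cites position."""


class NoEvidenceError(PanethNetError):
    """Trend aggregation called with an empty contribution list."""


class AmbiguityError(PanethNetError):
    """Duplicated keys where a unique mapping is required."""


class ConsistencyError(PanethNetError):
    """Cross-table reference to an identifier that does not exist."""


class ScenarioSpecError(PanethNetError):
    """Infeasible synthetic-scenario specification."""


class PipelineStageError(PanethNetError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AbundanceRecord:
    """One protein's per-replicate normalized intensities and test statistics.

    ``rel_fc`` is the signed relative fold-change: a value ``>= 1`` is the
    KO/WT ratio, a value ``<= -1`` is ``-(WT/KO)``; its magnitude is >= 1 by
    construction.  ``log2fc`` carries the same sign on the log2 scale.
    """

    protein_id: str
    intensities_wt: list[float]
    intensities_ko: list[float]
    unique_peptides: int
    anova_p: float | None = None
    rel_fc: float | None = None
    log2fc: float | None = None

    def __post_init__(self) -> None:
        if not self.intensities_wt or not self.intensities_ko:
            raise ValueError(f"{self.protein_id}: empty replicate list")
        if self.rel_fc is not None and abs(self.rel_fc) < 1:
            raise ValueError(f"{self.protein_id}: |rel_fc| must be >= 1")


@dataclass(frozen=True)
class TranscriptRecord:
    """One gene's differential-expression result (log2 fold-change, q-value)."""

    gene_id: str
    log2fc: float
    q_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.q_value <= 1:
            raise ValueError(f"{self.gene_id}: q_value outside [0, 1]")


@dataclass(frozen=True)
class OrthologPair:
    """A mouse-to-human orthologue assignment with a confidence score."""

    mouse_id: str
    human_id: str
    confidence: float = 1.0


@dataclass(frozen=True)
class TargetEvidence:
    """One (protein, receptor, evidence-type) autophagy-targeting assertion."""

    human_id: str
    receptor: Receptor
    evidence_type: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.evidence_type not in EVIDENCE_TYPES:
            raise ValueError(f"unknown evidence type {self.evidence_type!r}")


@dataclass(frozen=True)
class ProcessEffect:
    """Curated (protein, biological process, activation|inhibition) link.

    ``in_context`` marks effects retained by the intestinal-context curation;
    out-of-context rows are kept in the table but never enter trend calls.
    """

    protein_id: str
    process_id: str
    process_label: str
    effect: str  # "activation" | "inhibition"
    in_context: bool = True

    def __post_init__(self) -> None:
        if self.in_context and self.effect not in ("activation", "inhibition"):
            raise ValueError(
                f"{self.protein_id}/{self.process_id}: effect must be "
                f"'activation' or 'inhibition', got {self.effect!r}"
            )


@dataclass
class FilterConfig:
    """Every numeric cutoff used across the pipeline.

    Defaults are the published analysis thresholds: differential protein
    abundance at P < 0.05, |relative FC| >= 2 and >= 2 unique peptides;
    differentially expressed transcripts at |log2FC| >= 1 and q <= 0.05;
    turnover attribution when protein and transcript log2FC differ by more
    than 0.7; and the strict >70% majority for process trend calls.
    """

    p_max: float = 0.05
    abs_fc_min: float = 2.0
    min_peptides: int = 2
    transcript_abs_log2fc_min: float = 1.0
    transcript_q_max: float = 0.05
    delta_log2fc: float = 0.7
    trend_threshold: float = 0.70

    def __post_init__(self) -> None:
        for name in ("p_max", "abs_fc_min", "min_peptides",
                     "transcript_abs_log2fc_min", "transcript_q_max",
                     "delta_log2fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.5 < self.trend_threshold < 1:
            raise ValueError("trend_threshold must lie in (0.5, 1)")


@dataclass
class PipelineConfig:
    """File locations and run parameters for the full pipeline."""

    abundance: str
    orthologs: str
    fasta: str
    interactors: dict[str, str]  # receptor -> TSV path
    lir_list: str
    domains: str
    ddi: str
    effects: str
    transcripts: str
    markers: str
    outdir: str = "panethnet_out"
    seed: int = 0
    receptors: tuple[str, ...] = RECEPTORS
    atg16l1_id: str = "ATG16L1"
    lir_motif: str = "[ADEFGLPRSK][DEGMSTV][WFY][DEILQTV][ADEFHIKLMPSTV][ILV]"
    p62_motif: str = "[DE][DE][WFY]xx[LIV]"
    min_confidence: float = 1.0
    filters: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filt = FilterConfig(**raw.pop("filters", {}))
        raw["interactors"] = dict(raw.get("interactors", {}))
        if "receptors" in raw:
            raw["receptors"] = tuple(raw["receptors"])
        return cls(filters=filt, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["receptors"] = list(self.receptors)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass(frozen=True)
class AbundanceDialect:
    """Column-name mapping for abundance tables.

    Supplementary tables and Progenesis exports disagree on column names, so
    the mapping is explicit configuration, never sniffed.  ``wt_columns`` /
    ``ko_columns`` default to every column starting with ``wt_`` / ``ko_``.
    ``missing``: 'strict' rejects empty/NA intensity cells with the row
    number; 'impute' replaces them with half the smallest intensity observed
    in the table (a standard label-free detection-floor surrogate).
    """

    protein_id: str = "protein_id"
    unique_peptides: str = "unique_peptides"
    wt_columns: tuple[str, ...] | None = None
    ko_columns: tuple[str, ...] | None = None
    anova_p: str | None = None
    rel_fc: str | None = None
    missing: str = "strict"


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for col in cols:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing mandatory column '{col}'")


def load_abundance_table(
    path: str | Path, dialect: AbundanceDialect = AbundanceDialect()
) -> list[AbundanceRecord]:
    """Read a quantified label-free abundance table into records, file order."""
    df = _read_tsv(path)
    wt_cols = dialect.wt_columns or tuple(
        c for c in df.columns if c.startswith("wt_"))
    ko_cols = dialect.ko_columns or tuple(
        c for c in df.columns if c.startswith("ko_"))
    if not wt_cols or not ko_cols:
        raise ConfigurationError(
            f"{path}: no WT/KO intensity columns found (looked for prefix "
            "'wt_'/'ko_' or an explicit dialect mapping)")
    _require_columns(df, [dialect.protein_id, dialect.unique_peptides,
                          *wt_cols, *ko_cols], path)

    def parse_block(cols: Sequence[str]) -> list[list[float | None]]:
        out = []
        for row_no in range(1, len(df) + 1):
            vals: list[float | None] = []
            for col in cols:
                cell = df.iloc[row_no - 1][col]
                if cell == "" or cell.upper() in ("NA", "NAN"):
                    if dialect.missing == "strict":
                        raise TableParseError(
                            f"{path}: missing intensity in column '{col}', "
                            f"row {row_no}")
                    vals.append(None)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise TableParseError(
                        f"{path}: non-numeric intensity {cell!r} in column "
                        f"'{col}', row {row_no}") from None
            out.append(vals)
        return out

    wt_block = parse_block(wt_cols)
    ko_block = parse_block(ko_cols)

    if dialect.missing == "impute":
        observed = [v for row in wt_block + ko_block for v in row
                    if v is not None and v > 0]
        fill = 0.5 * min(observed) if observed else 1.0
        wt_block = [[fill if v is None else v for v in row] for row in wt_block]
        ko_block = [[fill if v is None else v for v in row] for row in ko_block]

    records: list[AbundanceRecord] = []
    for i in range(len(df)):
        row = df.iloc[i]
        try:
            peptides = int(float(row[dialect.unique_peptides]))
        except ValueError:
            raise TableParseError(
                f"{path}: non-integer unique_peptides "
                f"{row[dialect.unique_peptides]!r}, row {i + 1}") from None
        anova_p = rel_fc = None
        if dialect.anova_p and row[dialect.anova_p] != "":
            anova_p = float(row[dialect.anova_p])
        if dialect.rel_fc and row[dialect.rel_fc] != "":
            rel_fc = float(row[dialect.rel_fc])
        log2fc = None
        if rel_fc is not None:
            log2fc = math.copysign(math.log2(abs(rel_fc)), rel_fc)
        records.append(AbundanceRecord(
            protein_id=row[dialect.protein_id],
            intensities_wt=[float(v) for v in wt_block[i]],
            intensities_ko=[float(v) for v in ko_block[i]],
            unique_peptides=peptides,
            anova_p=anova_p,
            rel_fc=rel_fc,
            log2fc=log2fc,
        ))
    lengths = {(len(r.intensities_wt), len(r.intensities_ko)) for r in records}
    if len(lengths) > 1:
        raise TableParseError(f"{path}: unequal replicate counts across rows")
    return records


def load_transcript_table(path: str | Path) -> list[TranscriptRecord]:
    df = _read_tsv(path)
    _require_columns(df, ["gene_id", "log2fc", "q_value"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(TranscriptRecord(row.gene_id, float(row.log2fc),
                                        float(row.q_value)))
        except ValueError as exc:
            raise TableParseError(f"{path}: row {i}: {exc}") from None
    return out


def load_ortholog_table(path: str | Path) -> list[OrthologPair]:
    df = _read_tsv(path)
    _require_columns(df, ["mouse_id", "human_id"], path)
    pairs = []
    seen = set()
    for row in df.itertuples(index=False):
        conf = float(row.confidence) if "confidence" in df.columns else 1.0
        key = (row.mouse_id, row.human_id)
        if key in seen:
            continue  # duplicates collapse silently; pairs are a set
        seen.add(key)
        pairs.append(OrthologPair(row.mouse_id, row.human_id, conf))
    return pairs


def load_id_list(path: str | Path, column: str = "id") -> list[str]:
    """One-column TSV of identifiers (interactor lists, markers, iLIR hits)."""
    df = _read_tsv(path)
    if column not in df.columns:
        column = df.columns[0]
    return [v for v in df[column].tolist() if v != ""]


def load_domain_table(path: str | Path) -> list[tuple[str, str]]:
    """(protein_id, domain_accession) pairs, deduplicated, file order."""
    df = _read_tsv(path)
    _require_columns(df, ["protein_id", "domain_accession"], path)
    seen, out = set(), []
    for row in df.itertuples(index=False):
        key = (row.protein_id, row.domain_accession)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def load_ddi_table(path: str | Path) -> set[frozenset[str]]:
    """Unordered interacting-domain pairs, canonicalized to frozensets."""
    df = _read_tsv(path)
    _require_columns(df, ["domain_a", "domain_b"], path)
    return {frozenset((a, b)) for a, b in zip(df.domain_a, df.domain_b)}


def load_effects_table(path: str | Path) -> list[ProcessEffect]:
    df = _read_tsv(path)
    _require_columns(df, ["protein_id", "process_id", "process_label",
                          "effect", "in_context"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        flag = str(row.in_context).strip().lower() in ("1", "true", "yes")
        try:
            out.append(ProcessEffect(row.protein_id, row.process_id,
                                     row.process_label, row.effect, flag))
        except ValueError as exc:
            raise TableParseError(f"{path}: row {i}: {exc}") from None
    return out


def load_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Writers (fixed column order; deterministic row sort where stated)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_evidence_table(records: Sequence[TargetEvidence],
                         path: str | Path) -> None:
    """Write targeting evidence sorted by (human_id, receptor, evidence_type)."""
    rows = sorted(
        ({"human_id": r.human_id, "receptor": r.receptor,
          "evidence_type": r.evidence_type, "detail": r.detail}
         for r in records),
        key=lambda d: (d["human_id"], d["receptor"], d["evidence_type"],
                       d["detail"]))
    df = pd.DataFrame(rows, columns=["human_id", "receptor", "evidence_type",
                                     "detail"])
    _write_tsv(df, path)


def read_evidence_table(path: str | Path) -> list[TargetEvidence]:
    df = _read_tsv(path)
    _require_columns(df, ["human_id", "receptor", "evidence_type", "detail"],
                     path)
    return [TargetEvidence(r.human_id, r.receptor, r.evidence_type, r.detail)
            for r in df.itertuples(index=False)]


def write_transcript_table(records: Sequence[TranscriptRecord],
                           path: str | Path) -> None:
    df = pd.DataFrame(
        [{"gene_id": r.gene_id, "log2fc": repr(r.log2fc),
          "q_value": repr(r.q_value)} for r in records],
        columns=["gene_id", "log2fc", "q_value"])
    _write_tsv(df, path)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile, mode="w"))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)
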