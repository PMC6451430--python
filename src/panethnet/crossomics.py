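"""Proteome-transcriptome concordance and turnover attribution.

For each targeted differential protein the transcript log2 fold-change of
its coding gene is looked up; when protein and transcript log2FC differ by
strictly more than 0.7 the abundance change is attributed to impaired
autophagy-mediated turnover rather than transcription.  Transcripts are
additionally flagged as differentially expressed at |log2FC| >= 1 and
q <= 0.05 (both inclusive); a transcript failing those thresholds still
enters the delta computation, only its DE flag differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import AmbiguityError, FilterConfig, TranscriptRecord, logger

__all__ = ["ConcordanceRecord", "classify_de_transcript", "attribute_change",
           "concordance_table"]


@dataclass(frozen=True)
class ConcordanceRecord:
    """Paired protein/transcript fold-changes with turnover attribution."""

    id: str
    protein_log2fc: float
    transcript_log2fc: float | None
    transcript_q: float | None
    transcript_de: bool
    delta: float | None
    attribution: str  # "turnover" | "transcriptional" | "no_transcript"


def classify_de_transcript(rec: TranscriptRecord,
                           cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff |log2FC| and q pass the DE thresholds (inclusive)."""
    return (abs(rec.log2fc) >= cfg.transcript_abs_log2fc_min
            and rec.q_value <= cfg.transcript_q_max)


def attribute_change(protein_log2fc: float,
                     transcript_log2fc: float | None,
                     cfg: FilterConfig = FilterConfig()) -> str:
    """Attribute a protein change to turnover vs transcription.

    no_transcript when the gene was not measured; turnover iff the absolute
    difference of the signed log2FCs is strictly greater than the cutoff
    (default 0.7); transcriptional otherwise.
    """
    if transcript_log2fc is None:
        return "no_transcript"
    delta = abs(protein_log2fc - transcript_log2fc)
    return "turnover" if delta > cfg.delta_log2fc else "transcriptional"


def concordance_table(
    proteins: Iterable[tuple[str, float]],
    transcripts: Sequence[TranscriptRecord],
    id_map: Mapping[str, str] | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[ConcordanceRecord], dict[str, int]]:
    """One concordance record per (protein id, protein log2FC) input.

    ``id_map`` translates protein ids into transcript gene ids (identity
    when None).  Duplicate transcript gene ids raise an ambiguity error.
    Returns the records plus summary counts: n_input, n_with_transcript,
    n_de_transcript (DE among those with a transcript), n_turnover,
    n_transcriptional, n_no_transcript, and n_de_and_turnover (turnover
    calls among the DE-transcribed subset, the published 40-of-44 style
    count).
    """
    by_gene: dict[str, TranscriptRecord] = {}
    dupes = []
    for t in transcripts:
        if t.gene_id in by_gene:
            dupes.append(t.gene_id)
        by_gene[t.gene_id] = t
    if dupes:
        raise AmbiguityError(
            "duplicated transcript gene ids: " + ", ".join(sorted(set(dupes))))

    records: list[ConcordanceRecord] = []
    for pid, p_log2fc in proteins:
        gene = id_map.get(pid, pid) if id_map is not None else pid
        t = by_gene.get(gene)
        if t is None:
            records.append(ConcordanceRecord(pid, p_log2fc, None, None,
                                             False, None, "no_transcript"))
            continue
        de = classify_de_transcript(t, cfg)
        records.append(ConcordanceRecord(
            id=pid,
            protein_log2fc=p_log2fc,
            transcript_log2fc=t.log2fc,
            transcript_q=t.q_value,
            transcript_de=de,
            delta=abs(p_log2fc - t.log2fc),
            attribution=attribute_change(p_log2fc, t.log2fc, cfg)))

    summary = {
        "n_input": len(records),
        "n_with_transcript": sum(1 for r in records
                                 if r.attribution != "no_transcript"),
        "n_de_transcript": sum(1 for r in records if r.transcript_de),
        "n_turnover": sum(1 for r in records if r.attribution == "turnover"),
        "n_transcriptional": sum(1 for r in records
                                 if r.attribution == "transcriptional"),
        "n_no_transcript": sum(1 for r in records
                               if r.attribution == "no_transcript"),
        "n_de_and_turnover": sum(1 for r in records if r.transcript_de
                                 and r.attribution == "turnover"),
    }
    logger.info("cross-omics: %(n_input)d proteins, %(n_with_transcript)d "
                "with transcript, %(n_de_transcript)d DE, %(n_turnover)d "
                "attributed to turnover", summary)
    return records, summary
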