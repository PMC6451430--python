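"""Full pipeline orchestration: filter -> orthology -> targets -> trends ->
cross-omics -> enrichment -> export.

Every stage writes its output table to the configured directory with fixed
column order, so a rerun on identical inputs and configuration is
byte-identical.  A stage failure aborts the run with the stage name and
cause, and leaves an ``INCOMPLETE`` marker naming the failed stage so
partial outputs are never mistaken for a finished run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd

from . import crossomics as xo
from . import differential as da
from . import enrichment as en
from . import orthology as om
from . import targets as tg
from . import trends as tr
from .core_io import (
    PipelineConfig,
    PipelineStageError,
    TargetEvidence,
    load_abundance_table,
    load_ddi_table,
    load_domain_table,
    load_effects_table,
    load_fasta,
    load_id_list,
    load_ortholog_table,
    load_transcript_table,
    logger,
    write_evidence_table,
    _write_tsv,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run plus the summary counts."""

    differential: list = field(default_factory=list)
    human_rows: list = field(default_factory=list)
    mapping_report: Any = None
    evidence: list[TargetEvidence] = field(default_factory=list)
    venn: Any = None
    trends: list = field(default_factory=list)
    unannotated: list[str] = field(default_factory=list)
    network: nx.DiGraph | None = None
    concordance: list = field(default_factory=list)
    concordance_summary: dict = field(default_factory=dict)
    enrichment: Any = None
    summary: dict = field(default_factory=dict)


def _require_path(path: str, what: str) -> str:
    if not Path(path).exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write all outputs.

    Returns the in-memory result bundle; all tables, network exports and
    ``summary.json`` land in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    result = PipelineResult()
    stage = "init"
    try:
        # ------------------------------------------------ filter ----------
        stage = "filter"
        marker.write_text(stage + "\n")
        records = load_abundance_table(_require_path(config.abundance,
                                                     "abundance"))
        result.differential = da.filter_differential(records, config.filters)
        _write_tsv(pd.DataFrame(
            [{"protein_id": p.protein_id, "log2fc": repr(p.log2fc),
              "direction": p.direction, "anova_p": repr(p.anova_p),
              "unique_peptides": p.unique_peptides}
             for p in result.differential],
            columns=["protein_id", "log2fc", "direction", "anova_p",
                     "unique_peptides"]),
            outdir / "differential.tsv")

        # ------------------------------------------------ orthology -------
        stage = "orthology"
        marker.write_text(stage + "\n")
        if result.differential:
            pairs = load_ortholog_table(_require_path(config.orthologs,
                                                      "orthologue"))
            result.human_rows, result.mapping_report = om.map_to_human(
                result.differential, pairs, config.min_confidence)
        else:
            result.human_rows, result.mapping_report = [], om.MappingReport()
        _write_tsv(pd.DataFrame(
            [{"human_id": hid, "mouse_id": p.protein_id,
              "log2fc": repr(p.log2fc), "direction": p.direction}
             for hid, p in result.human_rows],
            columns=["human_id", "mouse_id", "log2fc", "direction"]),
            outdir / "differential_human.tsv")
        _write_tsv(pd.DataFrame(
            {"mouse_id": result.mapping_report.unmapped},
            columns=["mouse_id"]), outdir / "unmapped.tsv")

        # ------------------------------------------------ targets ---------
        stage = "targets"
        marker.write_text(stage + "\n")
        sequences = load_fasta(_require_path(config.fasta, "FASTA"))
        interactor_lists = {
            receptor: load_id_list(_require_path(path, f"{receptor} interactor"))
            for receptor, path in config.interactors.items()}
        lir_list = load_id_list(_require_path(config.lir_list, "iLIR"))
        domains = load_domain_table(_require_path(config.domains, "domain"))
        ddi = load_ddi_table(_require_path(config.ddi, "DDI"))
        p62_motif = tg.MotifDefinition.from_string("p62", config.p62_motif)
        lir_motif = tg.MotifDefinition.from_string("xLIR", config.lir_motif)
        result.evidence = tg.collect_evidence(
            result.human_rows, sequences, interactor_lists, lir_list,
            p62_motif, lir_motif, domains, ddi, config.atg16l1_id)
        write_evidence_table(result.evidence, outdir / "evidence.tsv")
        result.venn = tg.overlap_partition(result.evidence)
        _write_tsv(pd.DataFrame(
            [{"receptors": "+".join(combo), "count": count}
             for combo, count in sorted(result.venn.cells.items())]
            + [{"receptors": "fraction_multi",
                "count": repr(result.venn.fraction_multi)}],
            columns=["receptors", "count"]), outdir / "venn.tsv")

        # ------------------------------------------------ trends ----------
        stage = "trends"
        marker.write_text(stage + "\n")
        effects = load_effects_table(_require_path(config.effects, "effects"))
        targeted_ids = {e.human_id for e in result.evidence}
        directions = {hid: p.direction for hid, p in result.human_rows
                      if hid in targeted_ids}
        result.trends, result.unannotated = tr.classify_all_processes(
            directions, effects, config.filters)
        _write_tsv(pd.DataFrame(
            [{"process_id": t.process_id, "process_label": t.process_label,
              "n_stimulatory": t.n_stimulatory,
              "n_inhibitory": t.n_inhibitory,
              "fraction_stimulatory": repr(t.fraction_stimulatory),
              "classification": t.classification} for t in result.trends],
            columns=["process_id", "process_label", "n_stimulatory",
                     "n_inhibitory", "fraction_stimulatory",
                     "classification"]), outdir / "trends.tsv")
        context_effects = [e for e in effects
                           if e.in_context and e.protein_id in directions]
        result.network = tr.build_network(result.evidence, context_effects,
                                          directions, result.trends)
        tr.write_sif(result.network, outdir / "network.sif")
        nx.write_graphml(result.network, outdir / "network.graphml")
        tr.write_node_attributes(result.network,
                                 outdir / "node_attributes.tsv")

        # ------------------------------------------------ cross-omics -----
        stage = "crossomics"
        marker.write_text(stage + "\n")
        transcripts = load_transcript_table(_require_path(config.transcripts,
                                                          "transcript"))
        targeted_fc = [(hid, p.log2fc) for hid, p in result.human_rows
                       if hid in targeted_ids]
        result.concordance, result.concordance_summary = xo.concordance_table(
            targeted_fc, transcripts, None, config.filters)
        _write_tsv(pd.DataFrame(
            [{"id": r.id, "protein_log2fc": repr(r.protein_log2fc),
              "transcript_log2fc": "" if r.transcript_log2fc is None
              else repr(r.transcript_log2fc),
              "transcript_q": "" if r.transcript_q is None
              else repr(r.transcript_q),
              "transcript_de": int(r.transcript_de),
              "delta": "" if r.delta is None else repr(r.delta),
              "attribution": r.attribution} for r in result.concordance],
            columns=["id", "protein_log2fc", "transcript_log2fc",
                     "transcript_q", "transcript_de", "delta",
                     "attribution"]), outdir / "concordance.tsv")

        # ------------------------------------------------ enrichment ------
        stage = "enrichment"
        marker.write_text(stage + "\n")
        markers = load_id_list(_require_path(config.markers, "marker"))
        universe = [t.gene_id for t in transcripts]
        de_genes = [t.gene_id for t in transcripts
                    if xo.classify_de_transcript(t, config.filters)]
        result.enrichment = en.marker_enrichment(markers, de_genes, universe)
        _write_tsv(pd.DataFrame([{
            "overlap_k": result.enrichment.overlap_k,
            "markers_K": result.enrichment.markers_K,
            "list_n": result.enrichment.list_n,
            "universe_N": result.enrichment.universe_N,
            "p_value": repr(result.enrichment.p_value),
            "log10_p": repr(result.enrichment.log10_p)}]),
            outdir / "enrichment.tsv")

        # ------------------------------------------------ export/summary --
        stage = "export"
        marker.write_text(stage + "\n")
        n_up = sum(1 for p in result.differential if p.direction == "up")
        result.summary = {
            "n_differential": len(result.differential),
            "n_up": n_up,
            "n_down": len(result.differential) - n_up,
            "n_human": len(result.human_rows),
            "n_unmapped": len(result.mapping_report.unmapped),
            "n_targeted": result.venn.n_targeted,
            "fraction_multi": result.venn.fraction_multi,
            "venn": {"+".join(combo): count
                     for combo, count in sorted(result.venn.cells.items())},
            "trends": {t.process_id: t.classification for t in result.trends},
            "concordance": result.concordance_summary,
            "enrichment": {
                "k": result.enrichment.overlap_k,
                "K": result.enrichment.markers_K,
                "n": result.enrichment.list_n,
                "N": result.enrichment.universe_N,
                "p_value": result.enrichment.p_value,
            },
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=1, sort_keys=True)
        marker.unlink()
        logger.info("pipeline complete: %d differential (%d up), %d targeted",
                    len(result.differential), n_up, result.venn.n_targeted)
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc
    return result
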