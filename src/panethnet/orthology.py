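"""Mouse-to-human orthologue mapping of differential proteins.

Consumes an InParanoid-style pair table.  One-to-many mouse->human
assignments expand rows (the published profile maps 283 mouse proteins onto
284 human orthologues); many-to-one collapses keep the representative with
the extreme |log2fc| so the "altered" call survives, and are logged in the
report rather than silently applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core_io import ConfigurationError, OrthologPair, logger
from .differential import DifferentialProtein

__all__ = ["MappingReport", "map_to_human"]


@dataclass
class MappingReport:
    """Bookkeeping for an orthology-mapping run."""

    n_input: int = 0
    n_output: int = 0
    unmapped: list[str] = field(default_factory=list)
    expanded: dict[str, list[str]] = field(default_factory=dict)
    collapsed: list[tuple[str, str]] = field(default_factory=list)  # (human, dropped mouse)


def map_to_human(
    proteins: Sequence[DifferentialProtein],
    pairs: Sequence[OrthologPair],
    min_confidence: float = 1.0,
) -> tuple[list[tuple[str, DifferentialProtein]], MappingReport]:
    """Expand each mouse protein to all its human orthologues.

    Direction and log2fc are copied unchanged onto every human row.
    Proteins without an orthologue at ``min_confidence`` are reported, not
    dropped silently.  Returns (human rows, report).
    """
    if not pairs:
        raise ConfigurationError("empty orthologue mapping table")
    by_mouse: dict[str, list[str]] = {}
    for pair in pairs:
        if pair.confidence >= min_confidence:
            by_mouse.setdefault(pair.mouse_id, []).append(pair.human_id)

    report = MappingReport(n_input=len(proteins))
    rows: list[tuple[str, DifferentialProtein]] = []
    seen_human: dict[str, int] = {}
    for prot in proteins:
        humans = by_mouse.get(prot.protein_id, [])
        if not humans:
            report.unmapped.append(prot.protein_id)
            continue
        if len(humans) > 1:
            report.expanded[prot.protein_id] = list(humans)
        for hid in humans:
            if hid in seen_human:
                # many-to-one: keep the extreme |log2fc| representative
                idx = seen_human[hid]
                incumbent = rows[idx][1]
                if abs(prot.log2fc) > abs(incumbent.log2fc):
                    report.collapsed.append((hid, incumbent.protein_id))
                    rows[idx] = (hid, prot)
                else:
                    report.collapsed.append((hid, prot.protein_id))
                logger.warning("orthology: human id %s reached from several "
                               "mouse proteins; kept extreme |log2FC|", hid)
                continue
            seen_human[hid] = len(rows)
            rows.append((hid, prot))
    report.n_output = len(rows)
    logger.info("orthology: %d mouse -> %d human rows (%d unmapped)",
                report.n_input, report.n_output, len(report.unmapped))
    return rows, report
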