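"""Differential protein abundance from replicate label-free intensities.

A protein is called differentially abundant when its one-factor ANOVA
P-value is below 0.05, its absolute relative fold-change is at least 2 and
it was quantified from at least 2 unique peptides.  The ANOVA runs on
log2-transformed intensities by default (standard for label-free data);
the fold-change is the ratio of arithmetic means of the untransformed
normalized intensities, stored signed with magnitude >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import (
    AbundanceRecord,
    DegenerateInputError,
    FilterConfig,
    InsufficientReplicatesError,
    logger,
)

__all__ = ["DifferentialProtein", "one_factor_anova", "relative_fold_change",
           "filter_differential"]


@dataclass(frozen=True)
class DifferentialProtein:
    """A protein retained by the differential-abundance filter."""

    protein_id: str
    log2fc: float
    direction: str  # "up" | "down"
    anova_p: float
    unique_peptides: int

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down'")
        if (self.direction == "up") != (self.log2fc > 0):
            raise ValueError(
                f"{self.protein_id}: direction inconsistent with log2fc sign")


def one_factor_anova(groups: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA P-value across the given replicate groups.

    For two groups this equals the equal-variance two-sample t-test
    (F = t^2).  Degenerate variance cases follow an explicit convention:
    zero within-group variance with equal group means gives P = 1, with
    differing means gives P = 0 (infinite separation).
    """
    if len(groups) < 2:
        raise InsufficientReplicatesError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for arr in arrays:
        if arr.size < 2:
            raise InsufficientReplicatesError(
                f"group of size {arr.size}; at least 2 replicates required")
    means = [a.mean() for a in arrays]
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        return 1.0 if len(set(means)) == 1 else 0.0
    with np.errstate(invalid="ignore"):
        _, p = stats.f_oneway(*arrays)
    return float(min(max(p, 0.0), 1.0))


def relative_fold_change(mean_wt: float, mean_ko: float) -> float:
    """Signed relative fold-change: KO/WT if KO >= WT, else -(WT/KO)."""
    if mean_wt <= 0 or mean_ko <= 0:
        raise DegenerateInputError(
            f"non-positive group mean (wt={mean_wt}, ko={mean_ko})")
    if mean_ko >= mean_wt:
        return mean_ko / mean_wt
    return -(mean_wt / mean_ko)


def _signed_log2(rel_fc: float) -> float:
    return math.copysign(math.log2(abs(rel_fc)), rel_fc)


def compute_statistics(
    records: Sequence[AbundanceRecord],
    *,
    log_transform: bool = True,
    intensity_floor: float | None = None,
) -> None:
    """Fill anova_p / rel_fc / log2fc in place where absent.

    ``intensity_floor`` defaults to half the smallest nonzero intensity in
    the table; intensities are clipped to the floor before the log transform
    so that zeros do not blow up the test.
    """
    if intensity_floor is None:
        nonzero = [v for r in records
                   for v in (*r.intensities_wt, *r.intensities_ko) if v > 0]
        intensity_floor = 0.5 * min(nonzero) if nonzero else 1.0
    for rec in records:
        wt = np.maximum(np.asarray(rec.intensities_wt, float), intensity_floor)
        ko = np.maximum(np.asarray(rec.intensities_ko, float), intensity_floor)
        if rec.rel_fc is None:
            rec.rel_fc = relative_fold_change(float(wt.mean()), float(ko.mean()))
            rec.log2fc = _signed_log2(rec.rel_fc)
        if rec.log2fc is None:
            rec.log2fc = _signed_log2(rec.rel_fc)
        if rec.anova_p is None:
            if log_transform:
                rec.anova_p = one_factor_anova([np.log2(wt), np.log2(ko)])
            else:
                rec.anova_p = one_factor_anova([wt, ko])


def filter_differential(
    records: Sequence[AbundanceRecord],
    cfg: FilterConfig = FilterConfig(),
    *,
    log_transform: bool = True,
    intensity_floor: float | None = None,
) -> list[DifferentialProtein]:
    """Apply the differential filter, preserving input order.

    Retains exactly the records with ``anova_p < p_max`` (strict, as
    printed), ``|rel_fc| >= abs_fc_min`` and ``unique_peptides >=
    min_peptides`` (both inclusive).  Statistics missing on input are
    computed first.
    """
    compute_statistics(records, log_transform=log_transform,
                       intensity_floor=intensity_floor)
    out: list[DifferentialProtein] = []
    for rec in records:
        assert rec.anova_p is not None and rec.rel_fc is not None
        if (rec.anova_p < cfg.p_max
                and abs(rec.rel_fc) >= cfg.abs_fc_min
                and rec.unique_peptides >= cfg.min_peptides):
            out.append(DifferentialProtein(
                protein_id=rec.protein_id,
                log2fc=rec.log2fc,
                direction="up" if rec.log2fc > 0 else "down",
                anova_p=rec.anova_p,
                unique_peptides=rec.unique_peptides))
    n_up = sum(1 for p in out if p.direction == "up")
    logger.info("differential filter: %d/%d retained (%d up, %d down)",
                len(out), len(records), n_up, len(out) - n_up)
    return out
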