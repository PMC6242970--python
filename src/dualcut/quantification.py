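"""Lesion rates, background subtraction, and specificity summaries.

Per-class molecule counts are converted to percentages of all molecules; a
triplicate negative-control group defines the background that is subtracted
(per class, and per indel position/length) from treated samples, floored at
zero.  The precise-deletion fraction — the headline statistic for a dual
nuclease — is the precise-deletion percentage divided by the summed
percentage of all six lesion classes.  Helpers for the logit transform and
Benjamini-Hochberg adjustment are provided so rate tables can be handed to
any downstream ANOVA; the ANOVA itself is ordinary statistics and not
re-implemented here.

GUIDE-seq specificity summaries consume a site/count table (peak calling is
done upstream): the specificity ratio is the unique on-target read count
divided by the summed unique reads over all identified off-target sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UNEDITED",
    "UNCLASSIFIED",
    "LESION_CLASSES",
    "CLASS_SCHEMA",
    "LesionCountTable",
    "RateTable",
    "SpecificitySummary",
    "compute_rates",
    "subtract_background",
    "subtract_background_catalog",
    "precise_deletion_fraction",
    "logit_transform",
    "bh_adjust",
    "specificity_ratio",
    "fold_improvement",
    "summarize_specificity",
]

UNEDITED = "UNEDITED"
UNCLASSIFIED = "UNCLASSIFIED"

#: the six lesion classes a pair of nearby double-strand breaks can leave
LESION_CLASSES: Tuple[str, ...] = (
    "SP_INDEL",
    "PARTNER_INDEL",
    "BOTH_INDEL",
    "PRECISE_DELETION",
    "IMPRECISE_DELETION",
    "INVERSION",
)

CLASS_SCHEMA: Tuple[str, ...] = (UNEDITED,) + LESION_CLASSES


@dataclass(frozen=True)
class LesionCountTable:
    """Per-class molecule counts for one sample.

    ``counts`` covers the seven repair classes; molecules that failed every
    identity floor are tallied under ``unclassified`` and included in the
    total so percentages stay on a whole-sample denominator.
    """

    sample_id: str
    counts: Mapping[str, int]
    unclassified: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CLASS_SCHEMA)
        if unknown:
            raise ValueError(f"unknown lesion classes {sorted(unknown)}")
        if self.unclassified < 0 or any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    def count(self, cls: str) -> int:
        return int(self.counts.get(cls, 0))

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unclassified


@dataclass(frozen=True)
class RateTable:
    """Per-class percentages of total molecules for one sample."""

    sample_id: str
    rates: Mapping[str, float]
    unclassified_rate: float = 0.0
    corrected: bool = False
    replicate_set: Optional[str] = None
    total_molecules: Optional[int] = None

    def rate(self, cls: str) -> float:
        return float(self.rates.get(cls, 0.0))

    @property
    def total_lesion_rate(self) -> float:
        return sum(self.rate(c) for c in LESION_CLASSES)


def compute_rates(table: LesionCountTable) -> RateTable:
    """Percentage per class = 100 * count / total molecules."""
    total = table.total
    if total <= 0:
        raise ValueError(f"{table.sample_id}: cannot compute rates for an empty sample")
    rates = {cls: 100.0 * table.count(cls) / total for cls in CLASS_SCHEMA}
    return RateTable(table.sample_id, rates,
                     unclassified_rate=100.0 * table.unclassified / total,
                     corrected=False, total_molecules=total)


def subtract_background(treated: RateTable, controls: Sequence[RateTable]) -> RateTable:
    """Subtract the mean of the negative-control replicates from the treated
    rates, class by class, flooring at zero (negative lesion rates are
    meaningless)."""
    if not controls:
        raise ValueError("at least one control replicate is required")
    schema = set(CLASS_SCHEMA)
    for ctrl in controls:
        if set(ctrl.rates) - schema:
            raise ValueError(f"control {ctrl.sample_id} has an incompatible class schema")
    corrected = {}
    for cls in CLASS_SCHEMA:
        mean_bg = sum(c.rate(cls) for c in controls) / len(controls)
        corrected[cls] = max(0.0, treated.rate(cls) - mean_bg)
    mean_uncls = sum(c.unclassified_rate for c in controls) / len(controls)
    return RateTable(treated.sample_id, corrected,
                     unclassified_rate=max(0.0, treated.unclassified_rate - mean_uncls),
                     corrected=True, replicate_set=treated.replicate_set,
                     total_molecules=treated.total_molecules)


_CATALOG_KEY = ["frame", "kind", "position", "length"]


def subtract_background_catalog(
    treated: pd.DataFrame,
    controls: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Positional background subtraction on a per-indel catalog.

    Catalogs have columns frame/kind/position/length/frequency; lesions are
    matched exactly on (frame, kind, position, length) and the mean control
    frequency is subtracted, floored at zero.  Rows whose corrected frequency
    is zero are dropped.
    """
    if not controls:
        raise ValueError("at least one control catalog is required")
    for df in (treated, *controls):
        missing = set(_CATALOG_KEY + ["frequency"]) - set(df.columns)
        if missing:
            raise ValueError(f"catalog is missing columns {sorted(missing)}")
    bg = (
        pd.concat([c[_CATALOG_KEY + ["frequency"]] for c in controls])
        .groupby(_CATALOG_KEY, as_index=False)["frequency"].sum()
    )
    bg["frequency"] /= len(controls)
    merged = treated.merge(bg, on=_CATALOG_KEY, how="left",
                           suffixes=("", "_background"))
    merged["frequency_background"] = merged["frequency_background"].fillna(0.0)
    merged["frequency_corrected"] = (
        merged["frequency"] - merged["frequency_background"]).clip(lower=0.0)
    return merged[merged["frequency_corrected"] > 0].reset_index(drop=True)


def precise_deletion_fraction(rates: RateTable) -> float:
    """Precise-deletion percentage over the summed percentage of all six
    lesion classes; NaN (undefined) when the sample has no lesions."""
    total_lesions = rates.total_lesion_rate
    if total_lesions <= 0:
        return math.nan
    return rates.rate("PRECISE_DELETION") / total_lesions


def logit_transform(p: float, n_total: Optional[int] = None,
                    eps: Optional[float] = None) -> float:
    """ln(p / (1-p)) with the boundary clamp p <- clamp(p, eps, 1-eps).

    ``eps`` defaults to 1/(2*n_total) when a molecule total is given — half a
    molecule on the proportion scale — so 0% and 100% map to large finite
    values instead of infinities.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion {p} outside [0, 1]")
    if eps is None and n_total:
        eps = 1.0 / (2.0 * n_total)
    if eps:
        p = min(max(p, eps), 1.0 - eps)
    if p == 0.0:
        return -math.inf
    if p == 1.0:
        return math.inf
    return math.log(p / (1.0 - p))


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvals = list(pvalues)
    if not pvals:
        return []
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def specificity_ratio(on_count: int, off_counts: Sequence[int]) -> float:
    """On-target unique reads over summed off-target unique reads.

    Returns +inf (infinite specificity) when there are on-target reads but no
    off-target reads, and NaN (undefined) when both are zero.
    """
    if on_count < 0 or any(c < 0 for c in off_counts):
        raise ValueError("counts must be non-negative")
    off_sum = sum(off_counts)
    if off_sum == 0:
        return math.inf if on_count > 0 else math.nan
    return on_count / off_sum


def fold_improvement(ratio_variant: float, ratio_reference: float) -> float:
    """Specificity ratio of a variant relative to a reference nuclease.
    An infinite-specificity variant propagates as +inf."""
    if math.isnan(ratio_reference) or ratio_reference <= 0:
        raise ValueError("reference specificity ratio must be positive")
    if math.isinf(ratio_variant):
        return math.inf
    return ratio_variant / ratio_reference


@dataclass(frozen=True)
class SpecificitySummary:
    """GUIDE-seq specificity summary for one nuclease."""

    nuclease_id: str
    on_target_count: int
    off_target_counts: Tuple[Tuple[str, int], ...]
    specificity_ratio: float
    fold_improvement: float = math.nan


def summarize_specificity(
    table: pd.DataFrame,
    reference_nuclease: Optional[str] = None,
) -> List[SpecificitySummary]:
    """Summarize a GUIDE-seq site/count table.

    ``table`` needs columns site_id, is_on_target, unique_reads and, when it
    covers several nucleases, a nuclease column.  When ``reference_nuclease``
    is given, fold improvements are computed against its specificity ratio.
    """
    required = {"site_id", "is_on_target", "unique_reads"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"specificity table is missing columns {sorted(missing)}")
    if "nuclease" not in table.columns:
        table = table.assign(nuclease="nuclease")

    summaries: Dict[str, SpecificitySummary] = {}
    for nuclease, sub in table.groupby("nuclease", sort=True):
        on = int(sub.loc[sub["is_on_target"].astype(bool), "unique_reads"].sum())
        off = sub.loc[~sub["is_on_target"].astype(bool)]
        off_counts = tuple(zip(off["site_id"].astype(str), off["unique_reads"].astype(int)))
        ratio = specificity_ratio(on, [c for _, c in off_counts])
        summaries[str(nuclease)] = SpecificitySummary(str(nuclease), on, off_counts, ratio)

    if reference_nuclease is not None:
        if reference_nuclease not in summaries:
            raise ValueError(f"reference nuclease {reference_nuclease!r} not in table")
        ref_ratio = summaries[reference_nuclease].specificity_ratio
        for name, s in list(summaries.items()):
            summaries[name] = SpecificitySummary(
                s.nuclease_id, s.on_target_count, s.off_target_counts,
                s.specificity_ratio, fold_improvement(s.specificity_ratio, ref_ratio))
    return [summaries[k] for k in sorted(summaries)]
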