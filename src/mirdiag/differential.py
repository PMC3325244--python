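"""Per-miRNA pairwise differential-abundance testing.

For each miRNA the two classes are compared with an unpaired two-tailed
Wilcoxon-Mann-Whitney (WMW) test; p-values are adjusted across the miRNA
universe with the Benjamini-Hochberg step-up procedure, and per-group
Shapiro-Wilk normality statistics are recorded for reference (they do not
gate the rank test).  Marker sets from several comparisons are combined
into exclusive/shared Venn regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SampleAnnotation

__all__ = [
    "ComparisonResult",
    "VennPartition",
    "shapiro_wilk",
    "wmw_test",
    "bh_adjust",
    "run_comparison",
    "build_venn",
]

#: Largest smaller-group size for which the exact WMW null is enumerated.
EXACT_WMW_LIMIT = 8


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for approximate normality.

    Recorded descriptively per miRNA per group; inference always uses the
    rank test regardless of this outcome.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def wmw_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Returns ``(U_a, p)`` where ``U_a`` counts pairs won by group ``a``
    (ties half).  The exact null distribution is enumerated when the
    smaller group has at most 8 observations and the pooled data are free
    of ties; otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_WMW_LIMIT
                         and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Differential-abundance results for one ordered class pair.

    ``table`` has one row per miRNA: the WMW U statistic (for group A),
    raw and BH-adjusted p-values, per-group Shapiro-Wilk p-values
    (NaN where undefined), the difference of group medians A - B on the
    matrix scale, and the significance call at ``alpha`` on adjusted p.
    """

    comparison: tuple[str, str]
    table: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant_set(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def run_comparison(matrix: ExpressionMatrix, annotation: SampleAnnotation,
                   class_a: str, class_b: str,
                   alpha: float = 0.05,
                   adjusted: bool = True) -> ComparisonResult:
    """Test every miRNA in the matrix for a class A vs class B shift.

    ``adjusted=False`` calls significance on raw instead of BH-adjusted
    p-values (exposed because published marker counts do not always state
    which scale they used).
    """
    samples_a = [s for s in annotation.samples_of(class_a)
                 if s in matrix.data.index]
    samples_b = [s for s in annotation.samples_of(class_b)
                 if s in matrix.data.index]
    if not samples_a or not samples_b:
        missing = class_a if not samples_a else class_b
        raise ValueError(f"class {missing!r} absent from matrix/annotation")

    xa = matrix.data.loc[samples_a].to_numpy()
    xb = matrix.data.loc[samples_b].to_numpy()
    records = []
    for j, mirna in enumerate(matrix.data.columns):
        u, p = wmw_test(xa[:, j], xb[:, j])
        rec = {"mirna_id": mirna, "U": u, "raw_p": p,
               "median_diff": float(np.median(xa[:, j]) - np.median(xb[:, j]))}
        for tag, grp in (("shapiro_p_a", xa[:, j]), ("shapiro_p_b", xb[:, j])):
            try:
                rec[tag] = shapiro_wilk(grp)[1]
            except ValueError:
                rec[tag] = np.nan
        records.append(rec)
    table = pd.DataFrame.from_records(records, index="mirna_id")
    table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
    basis = "adjusted_p" if adjusted else "raw_p"
    table["significant"] = table[basis] < alpha
    order = ["U", "raw_p", "adjusted_p", "shapiro_p_a", "shapiro_p_b",
             "median_diff", "significant"]
    return ComparisonResult((class_a, class_b), table[order], alpha=alpha)


@dataclass
class VennPartition:
    """Exclusive/shared regions of 2 or 3 named marker sets.

    Region keys join the contributing set names with ``"&"``; regions are
    pairwise disjoint and cover the union of the inputs.
    """

    set_names: list[str]
    regions: dict[str, set[str]] = field(default_factory=dict)

    @property
    def region_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}


def build_venn(named_sets: dict[str, set[str]]) -> VennPartition:
    """Partition 2 or 3 marker sets into exclusive and shared Venn regions."""
    names = list(named_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("build_venn supports exactly 2 or 3 sets")
    sets = {n: set(named_sets[n]) for n in names}
    regions: dict[str, set[str]] = {}
    # every non-empty subset of set names defines one exclusive region
    from itertools import combinations
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(sets[n] for n in inside))
            for n in outside:
                region -= sets[n]
            regions["&".join(inside)] = region
    return VennPartition(names, regions)
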