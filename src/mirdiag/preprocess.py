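"""Probe-level preprocessing: background correction, replicate summary,
variance-stabilizing normalization, annotation intersection.

The chain mirrors standard miRNA microarray processing: per-array
background subtraction, then the median of the replicate features of each
miRNA, then calibration + generalized-log transform so that measurement
variance is approximately independent of intensity.

The normalization here fits a per-array affine calibration ``(a_s, b_s)``
by robust regression of each array's intensity quantiles onto a reference
array's quantiles and then applies the glog transform

    h_s(x) = asinh((x - a_s) / b_s),

which is strictly monotone per array (rank-preserving), so downstream
rank tests are invariant to each array's calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datatypes import ExpressionMatrix, ProbeLevelData

__all__ = [
    "VsnFit",
    "correct_background",
    "summarize_replicates",
    "vsn_normalize",
    "intersect_annotation",
    "technical_reproducibility",
]

#: Floor applied after background subtraction so glog input stays positive.
INTENSITY_FLOOR = 1e-6


@dataclass
class VsnFit:
    """Per-array affine calibration of the glog transform.

    ``offsets[s]`` is ``a_s`` and ``scales[s]`` is ``b_s`` in
    ``h_s(x) = asinh((x - a_s)/b_s)``; scales are strictly positive.
    """

    offsets: pd.Series
    scales: pd.Series
    reference: str

    def __post_init__(self) -> None:
        if (self.scales <= 0).any():
            raise ValueError("calibration scales must be strictly positive")


def correct_background(data: ProbeLevelData,
                       quantile: float = 0.05) -> ProbeLevelData:
    """Subtract each array's `quantile` intensity from all its values.

    The per-array low quantile estimates the additive background (blank
    features are not modelled); results are floored at a small positive
    constant so the downstream glog transform is defined.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    if data.intensities.size == 0:
        raise ValueError("empty probe data")
    flat = data.intensities.reshape(len(data.array_ids), -1)
    bg = np.quantile(flat, quantile, axis=1)
    corrected = data.intensities - bg[:, None, None]
    np.maximum(corrected, INTENSITY_FLOOR, out=corrected)
    return ProbeLevelData(list(data.array_ids), list(data.mirna_ids), corrected)


def summarize_replicates(data: ProbeLevelData) -> ExpressionMatrix:
    """Median over the replicate features of each (sample, miRNA).

    With seven replicates per miRNA the median tolerates up to three
    outlying features.  Even replicate counts use the midpoint convention.
    """
    if data.intensities.shape[2] < 1:
        raise ValueError("no replicate features present")
    if np.isnan(data.intensities).any():
        bad = np.argwhere(np.isnan(data.intensities).any(axis=2))[0]
        raise ValueError(
            f"missing replicate block for "
            f"({data.array_ids[bad[0]]}, {data.mirna_ids[bad[1]]})")
    med = np.median(data.intensities, axis=2)
    frame = pd.DataFrame(med, index=pd.Index(data.array_ids, name="sample_id"),
                         columns=data.mirna_ids)
    return ExpressionMatrix(frame, stage="raw-summarized")


def _reference_array(matrix: ExpressionMatrix) -> str:
    """Array whose total intensity is the cohort median (deterministic;
    ties broken by sample id, even counts take the lower middle)."""
    totals = matrix.data.sum(axis=1).sort_values(kind="mergesort")
    return str(totals.index[(len(totals) - 1) // 2])


def vsn_normalize(matrix: ExpressionMatrix,
                  reference: str | None = None,
                  n_quantiles: int = 101) -> tuple[ExpressionMatrix, VsnFit]:
    """Calibrate each array onto a reference and apply the glog transform.

    Per array, the quantiles of its intensity distribution are regressed
    onto the reference array's quantiles with a Theil-Sen fit, giving a
    robust affine calibration ``x ~ a_s + b_s * x_ref``; the normalized
    value is ``asinh((x - a_s)/b_s)``.  The transform is strictly monotone
    within each array.
    """
    if matrix.stage != "raw-summarized":
        raise ValueError("vsn_normalize expects a raw-summarized matrix "
                         f"(got stage {matrix.stage!r}); normalization is "
                         "applied exactly once")
    if reference is None:
        reference = _reference_array(matrix)
    elif reference not in matrix.data.index:
        raise KeyError(f"reference array {reference!r} not in matrix")

    probs = np.linspace(0.02, 0.98, n_quantiles)  # trimmed: tails are noisy
    mid = (probs >= 0.25) & (probs <= 0.95)  # slope: scale-dominated region
    low = probs <= 0.25                      # offset: background-dominated
    ref_q = np.quantile(matrix.data.loc[reference].to_numpy(), probs)

    offsets: dict[str, float] = {}
    scales: dict[str, float] = {}
    values = np.empty_like(matrix.data.to_numpy())
    for i, sid in enumerate(matrix.data.index):
        row = matrix.data.iloc[i].to_numpy()
        if np.ptp(row) == 0:
            raise ValueError(f"array {sid!r} has zero spread; "
                             "cannot calibrate")
        q = np.quantile(row, probs)
        # median log-ratio over mid/high quantiles: a scale estimate that
        # heavy-tailed top intensities cannot destabilize
        with np.errstate(divide="ignore"):
            log_ratio = (np.log(np.maximum(q[mid], INTENSITY_FLOOR))
                         - np.log(np.maximum(ref_q[mid], INTENSITY_FLOOR)))
        slope = float(np.exp(np.median(log_ratio)))
        if not np.isfinite(slope) or slope <= 0:
            raise ValueError(f"non-positive calibration slope for {sid!r}")
        # residual additive offset from the background-dominated low end
        intercept = float(np.median(q[low] - slope * ref_q[low]))
        offsets[sid] = intercept
        scales[sid] = slope
        values[i] = np.arcsinh((row - intercept) / slope)

    frame = pd.DataFrame(values, index=matrix.data.index.copy(),
                         columns=matrix.data.columns.copy())
    fit = VsnFit(pd.Series(offsets), pd.Series(scales), reference)
    return ExpressionMatrix(frame, stage="normalized"), fit


def intersect_annotation(matrix: ExpressionMatrix,
                         annotation_versions: list[set[str]]) -> ExpressionMatrix:
    """Restrict the matrix to miRNAs present in every annotation version.

    Mirrors the practice of keeping only transcripts consistently annotated
    across successive miRBase releases; column order is preserved.
    """
    if not annotation_versions or any(len(s) == 0 for s in annotation_versions):
        raise ValueError("annotation versions must be non-empty sets")
    common = set.intersection(*map(set, annotation_versions))
    keep = [m for m in matrix.data.columns if m in common]
    if not keep:
        raise ValueError("no miRNA survives the annotation intersection")
    return ExpressionMatrix(matrix.data[keep].copy(), stage=matrix.stage)


def technical_reproducibility(matrix: ExpressionMatrix,
                              replicate_pairs: list[tuple[str, str]]) -> float:
    """Mean Pearson correlation over pairs of technical-replicate arrays."""
    if not replicate_pairs:
        raise ValueError("no replicate pairs given")
    cors = []
    for a, b in replicate_pairs:
        for sid in (a, b):
            if sid not in matrix.data.index:
                raise KeyError(f"sample {sid!r} not in matrix")
        x = matrix.data.loc[a].to_numpy()
        y = matrix.data.loc[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("correlation undefined for a constant profile")
        cors.append(float(pearsonr(x, y).statistic))
    return float(np.mean(cors))
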