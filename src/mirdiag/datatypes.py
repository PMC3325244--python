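"""Core in-memory containers shared across the pipeline.

The analysis moves through three representations:

``ProbeLevelData``
    Raw per-array fluorescence intensities with replicate features per
    miRNA — what the scanner software exports and what the simulator emits.
``ExpressionMatrix``
    A samples x miRNAs matrix, either median-summarized raw intensities
    (``stage="raw-summarized"``) or calibrated glog-scale abundances after
    normalization (``stage="normalized"``).
``SampleAnnotation``
    Sample metadata: which cohort (blood or tissue) and which diagnostic
    class (PDAC, CP, healthy/normal) each sample belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProbeLevelData", "ExpressionMatrix", "SampleAnnotation", "CLASS_LABELS"]

#: Class vocabulary used by annotations. "healthy" is the blood control
#: label, "normal" the tissue control label.
CLASS_LABELS = ("PDAC", "CP", "healthy", "normal")

#: Labels treated as the unaffected/control class when orienting effects
#: and sensitivity/specificity.
CONTROL_LABELS = frozenset({"healthy", "normal", "control"})


@dataclass
class ProbeLevelData:
    """Raw intensities, one block of replicate features per (array, miRNA).

    Parameters
    ----------
    array_ids : list of str
        Ordered, unique sample/array identifiers.
    mirna_ids : list of str
        Ordered, unique miRNA identifiers.
    intensities : ndarray, shape (n_arrays, n_mirnas, n_replicates)
        Non-negative fluorescence values in arbitrary units.
    """

    array_ids: list[str]
    mirna_ids: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be 3-dimensional "
                             "(arrays x miRNAs x replicates)")
        n_a, n_m, _ = self.intensities.shape
        if len(self.array_ids) != n_a or len(self.mirna_ids) != n_m:
            raise ValueError("id lists inconsistent with intensity dimensions")
        if len(set(self.array_ids)) != n_a:
            raise ValueError("duplicate array ids")
        if len(set(self.mirna_ids)) != n_m:
            raise ValueError("duplicate miRNA ids")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeLevelData):
            return NotImplemented
        return (self.array_ids == other.array_ids
                and self.mirna_ids == other.mirna_ids
                and np.array_equal(self.intensities, other.intensities))


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs abundance matrix with a processing-stage tag.

    ``stage`` is either ``"raw-summarized"`` (replicate medians, raw
    intensity scale) or ``"normalized"`` (glog scale after calibration).
    The stage tag lets downstream steps refuse un-normalized input and
    guards against normalizing twice.
    """

    data: pd.DataFrame  # index = sample ids, columns = miRNA ids
    stage: str = "raw-summarized"

    _STAGES = ("raw-summarized", "normalized")

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; "
                             f"expected one of {self._STAGES}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate sample or miRNA ids")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.stage == other.stage and self.data.equals(other.data)


@dataclass
class SampleAnnotation:
    """Maps each sample id to its cohort ("blood"/"tissue") and class label."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"cohort", "class"}
        if not required.issubset(self.table.columns):
            raise ValueError("annotation needs 'cohort' and 'class' columns")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotation")

    @classmethod
    def from_labels(cls, sample_ids: list[str], classes: list[str],
                    cohort: str = "blood") -> "SampleAnnotation":
        tbl = pd.DataFrame({"cohort": cohort, "class": list(classes)},
                           index=pd.Index(sample_ids, name="sample_id"))
        return cls(tbl)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def classes_for(self, sample_ids: list[str]) -> pd.Series:
        """Class labels for the given samples, raising if any is unannotated."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples missing from annotation: {missing[:5]}")
        return self.table.loc[sample_ids, "class"]

    def samples_of(self, cls_label: str) -> list[str]:
        return list(self.table.index[self.table["class"] == cls_label])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleAnnotation):
            return NotImplemented
        return self.table.equals(other.table)
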