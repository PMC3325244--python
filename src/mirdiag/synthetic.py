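"""Synthetic probe-level microarray cohorts with known ground truth.

The generator emulates the data model of a bead/biochip miRNA microarray
study of pancreatic disease: each array probes ``n_mirnas`` transcripts
with ``n_replicates`` identical features, and samples fall into diagnostic
classes (PDAC tumor, chronic pancreatitis, healthy/normal controls).

The error model is the additive-multiplicative one that variance-stabilizing
normalization assumes.  Each sample ``s`` has a latent glog-scale abundance
per miRNA ``m``::

    x[s, m] = mu[m] + delta[m, class(s)] + Normal(0, sigma_bio**2)

and every replicate feature measures::

    y = o_a + b_a * sinh(x) * exp(eta) + Normal(0, sigma_add**2),   y >= 0

with per-array calibration offset ``o_a`` and scale ``b_a``, multiplicative
noise ``eta ~ Normal(0, sigma_mult**2)``, and additive background noise.
Class effects ``delta`` are additive on the glog scale with a random sign
per miRNA — the rank-shift signal a Wilcoxon-Mann-Whitney test detects.

Marker sets for different disease classes share a configurable fraction of
miRNAs (with identical shifts), so the Venn-region structure of pairwise
comparisons is reproducible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import child_rng
from .datatypes import CONTROL_LABELS, ProbeLevelData, SampleAnnotation

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "simulate_cohort",
    "write_fixture",
    "BLOOD_CLASS_SIZES",
    "TISSUE_CLASS_SIZES",
]

#: Study cohort sizes: 116 blood samples (45 tumor, 38 pancreatitis,
#: 33 healthy) and 129 tissue samples (94 tumor, 19 pancreatitis, 16 normal).
BLOOD_CLASS_SIZES = {"PDAC": 45, "CP": 38, "healthy": 33}
TISSUE_CLASS_SIZES = {"PDAC": 94, "CP": 19, "normal": 16}


@dataclass
class CohortConfig:
    """Parameters of one simulated cohort.

    Attributes
    ----------
    n_mirnas : int
        Size of the probed miRNA universe (study value 863).
    n_replicates : int
        Replicate features per miRNA per array (study value 7).
    class_sizes : dict
        Class label -> number of samples.
    n_differential : int
        Truly differential miRNAs per disease class (vs control).
    effect_size : float
        Magnitude of the class shift on the glog scale.
    sigma_bio : float
        Biological (between-sample) SD on the glog scale.
    sigma_mult : float
        SD of the multiplicative (log-scale) replicate noise.
    sigma_add : float
        SD of the additive background noise on the raw intensity scale.
    array_scale_range, array_offset_range : tuple
        Uniform ranges for per-array calibration factor and offset.
    marker_overlap : float
        Fraction of each disease class's marker set shared (with identical
        shifts) across disease classes.
    cohort : str
        Cohort tag written into the annotation ("blood", "tissue", ...).
    seed : int
        Seed governing all randomness of the simulation.
    """

    n_mirnas: int = 863
    n_replicates: int = 7
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(BLOOD_CLASS_SIZES))
    n_differential: int = 50
    effect_size: float = 1.0
    sigma_bio: float = 0.5
    sigma_mult: float = 0.1
    sigma_add: float = 1.0
    array_scale_range: tuple[float, float] = (0.7, 1.3)
    array_offset_range: tuple[float, float] = (0.0, 10.0)
    marker_overlap: float = 0.3
    cohort: str = "blood"
    seed: int = 0

    @classmethod
    def blood_preset(cls, **kwargs) -> "CohortConfig":
        kwargs.setdefault("class_sizes", dict(BLOOD_CLASS_SIZES))
        kwargs.setdefault("cohort", "blood")
        return cls(**kwargs)

    @classmethod
    def tissue_preset(cls, **kwargs) -> "CohortConfig":
        kwargs.setdefault("class_sizes", dict(TISSUE_CLASS_SIZES))
        kwargs.setdefault("cohort", "tissue")
        return cls(**kwargs)

    def validate(self) -> None:
        if self.n_mirnas <= 0 or self.n_replicates <= 0:
            raise ValueError("n_mirnas and n_replicates must be positive")
        if not self.class_sizes:
            raise ValueError("class_sizes must be non-empty")
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ValueError("all class sizes must be positive")
        if self.n_differential < 0 or self.n_differential > self.n_mirnas:
            raise ValueError("n_differential must lie in [0, n_mirnas]")
        if self.sigma_bio <= 0:
            raise ValueError("sigma_bio must be > 0")
        if self.sigma_mult < 0 or self.sigma_add < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.marker_overlap <= 1.0:
            raise ValueError("marker_overlap must lie in [0, 1]")
        for name, (lo, hi) in (("array_scale_range", self.array_scale_range),
                               ("array_offset_range", self.array_offset_range)):
            if lo > hi:
                raise ValueError(f"{name} must be an interval (lo <= hi)")
        if self.array_scale_range[0] <= 0:
            raise ValueError("array scale factors must be positive")


@dataclass
class GroundTruth:
    """Simulation truth for parameter-recovery tests.

    ``differential_sets`` maps a comparison label ``"A_vs_B"`` to the set of
    miRNA ids whose latent means genuinely differ between classes A and B.
    ``true_effects`` maps ``(mirna_id, class)`` to the planted glog shift.
    """

    differential_sets: dict[str, set[str]]
    true_effects: dict[tuple[str, str], float]


def _control_class(class_labels: list[str]) -> str:
    """The unaffected class; falls back to the first label."""
    for lab in class_labels:
        if lab.lower() in CONTROL_LABELS:
            return lab
    return class_labels[0]


def simulate_cohort(
    config: CohortConfig,
) -> tuple[ProbeLevelData, SampleAnnotation, GroundTruth]:
    """Simulate one probe-level cohort.

    Returns the raw probe data, the sample annotation, and the ground truth
    (which miRNAs genuinely differ per pairwise comparison).  Fully
    reproducible: the same config (including seed) yields bit-identical
    output.
    """
    config.validate()
    rng = child_rng(config.seed, "simulate_cohort")

    classes = list(config.class_sizes)
    control = _control_class(classes)
    disease = [c for c in classes if c != control]

    mirna_ids = [f"sim-miR-{i + 1:04d}" for i in range(config.n_mirnas)]
    sample_ids: list[str] = []
    sample_classes: list[str] = []
    for lab in classes:
        for i in range(config.class_sizes[lab]):
            sample_ids.append(f"{lab}_{i + 1:03d}")
            sample_classes.append(lab)
    n_samples = len(sample_ids)

    # --- planted class effects -------------------------------------------
    # Disease classes share a core of markers (identical shifts) and carry
    # class-private markers on top; shifts have random sign per miRNA.
    effects = np.zeros((config.n_mirnas, len(classes)))  # glog shift per class
    n_shared = int(round(config.marker_overlap * config.n_differential))
    n_private = config.n_differential - n_shared
    if disease and config.n_differential > 0:
        need = n_shared + n_private * len(disease)
        if need > config.n_mirnas:
            raise ValueError("marker sets exceed the miRNA universe; "
                             "reduce n_differential or raise marker_overlap")
        pool = rng.permutation(config.n_mirnas)
        shared_idx = pool[:n_shared]
        shared_sign = rng.choice([-1.0, 1.0], size=n_shared)
        offset = n_shared
        for j, lab in enumerate(classes):
            if lab == control:
                continue
            col = classes.index(lab)
            effects[shared_idx, col] = shared_sign * config.effect_size
            priv = pool[offset:offset + n_private]
            offset += n_private
            sign = rng.choice([-1.0, 1.0], size=n_private)
            effects[priv, col] = sign * config.effect_size

    true_effects = {
        (mirna_ids[m], classes[c]): float(effects[m, c])
        for m in range(config.n_mirnas)
        for c in range(len(classes))
        if effects[m, c] != 0.0
    }
    differential_sets: dict[str, set[str]] = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            ca, cb = classes.index(a), classes.index(b)
            diff = np.nonzero(effects[:, ca] != effects[:, cb])[0]
            differential_sets[f"{a}_vs_{b}"] = {mirna_ids[m] for m in diff}

    # --- latent glog abundances ------------------------------------------
    # baseline spans the detection limit (glog 0: no signal, background
    # only) up to ~4 decades of raw intensity, as on a real array
    mu = rng.uniform(0.0, 10.0, size=config.n_mirnas)
    class_idx = np.array([classes.index(c) for c in sample_classes])
    latent = (mu[None, :]
              + effects[:, class_idx].T
              + rng.normal(0.0, config.sigma_bio, size=(n_samples,
                                                        config.n_mirnas)))

    # --- raw replicate intensities ---------------------------------------
    offsets = rng.uniform(*config.array_offset_range, size=n_samples)
    scales = rng.uniform(*config.array_scale_range, size=n_samples)
    signal = np.sinh(latent)  # true raw-scale signal, reference calibration
    eta = rng.normal(0.0, config.sigma_mult,
                     size=(n_samples, config.n_mirnas, config.n_replicates))
    background = rng.normal(0.0, config.sigma_add, size=eta.shape)
    raw = (offsets[:, None, None]
           + scales[:, None, None] * signal[:, :, None] * np.exp(eta)
           + background)
    np.maximum(raw, 0.0, out=raw)  # fluorescence is non-negative

    data = ProbeLevelData(sample_ids, mirna_ids, raw)
    annotation = SampleAnnotation.from_labels(sample_ids, sample_classes,
                                              cohort=config.cohort)
    return data, annotation, GroundTruth(differential_sets, true_effects)


def write_fixture(data: ProbeLevelData, annotation: SampleAnnotation,
                  directory: str | Path,
                  truth: GroundTruth | None = None) -> dict[str, Path]:
    """Write a simulated cohort as plain-text fixture files.

    Emits ``probes.tsv`` (long format), ``annotation.tsv`` and, if ground
    truth is given, ``ground_truth.json``.  Round-trips losslessly through
    :mod:`mirdiag.io`.
    """
    from . import io as mio  # local import: io depends on datatypes only

    if str(directory) == "":
        raise ValueError("empty directory path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": directory / "probes.tsv",
        "annotation": directory / "annotation.tsv",
    }
    mio.write_probe_tsv(data, paths["probes"])
    mio.write_annotation_tsv(annotation, paths["annotation"])
    if truth is not None:
        paths["ground_truth"] = directory / "ground_truth.json"
        mio.write_ground_truth_json(truth, paths["ground_truth"])
    return paths
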