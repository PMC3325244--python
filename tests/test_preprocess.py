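"""Preprocessing: background correction, replicate medians, glog
normalization, annotation intersection, technical reproducibility."""

import numpy as np
import pytest

from mirdiag import (CohortConfig, ExpressionMatrix, ProbeLevelData,
                     correct_background, intersect_annotation,
                     simulate_cohort, summarize_replicates,
                     technical_reproducibility, vsn_normalize)
from mirdiag.preprocess import INTENSITY_FLOOR


def _probe(values):
    """One array, shape (n_mirnas, n_replicates)."""
    arr = np.asarray(values, dtype=float)[None, :, :]
    ids = [f"m{i}" for i in range(arr.shape[1])]
    return ProbeLevelData(["a1"], ids, arr)


class TestCorrectBackground:
    def test_subtracts_low_quantile_with_floor(self):
        data = _probe([[10.0], [20.0], [30.0], [40.0], [50.0]])
        out = correct_background(data, quantile=0.0)  # min = 10
        expected = np.array([INTENSITY_FLOOR, 10.0, 20.0, 30.0, 40.0])
        assert out.intensities[0, :, 0] == pytest.approx(expected)

    def test_all_zero_array_floors_everything(self):
        data = _probe([[0.0], [0.0], [0.0]])
        out = correct_background(data)
        assert np.all(out.intensities == INTENSITY_FLOOR)

    def test_recovers_known_simulated_offset(self):
        """The per-array 5th percentile estimates the simulator's additive
        offset o_a to within a small bias when the weakest probes are
        background-dominated."""
        config = CohortConfig(n_mirnas=800,
                              class_sizes={"PDAC": 6, "healthy": 6},
                              n_differential=0,
                              array_offset_range=(5.0, 15.0), seed=21)
        data, _, _ = simulate_cohort(config)
        flat = data.intensities.reshape(len(data.array_ids), -1)
        bg = np.quantile(flat, 0.05, axis=1)
        # the simulator draws offsets before scales with the same stream;
        # recover truth by re-deriving the background from corrected data
        corrected = correct_background(data, 0.05)
        resid = np.quantile(
            corrected.intensities.reshape(len(data.array_ids), -1),
            0.05, axis=1)
        assert np.all(bg >= 4.0)  # dominated by the offset, not signal
        assert np.all(resid <= 1.0)  # background removed after correction

    def test_rejects_bad_quantile_and_empty(self):
        data = _probe([[1.0]])
        with pytest.raises(ValueError):
            correct_background(data, quantile=1.0)
        with pytest.raises(ValueError):
            correct_background(
                ProbeLevelData([], [], np.empty((0, 0, 1))), 0.05)


class TestSummarizeReplicates:
    @pytest.mark.parametrize("reps, expected", [
        ([10, 12, 11, 13, 9, 14, 12], 12.0),
        ([5, 5, 5, 5, 5, 5, 5], 5.0),
        ([1, 2, 3, 4, 5, 6, 100], 4.0),  # robust to one outlier
        ([1, 2, 3, 4], 2.5),             # even count: midpoint
    ])
    def test_median_of_replicates(self, reps, expected):
        data = _probe([[float(r) for r in reps]])
        matrix = summarize_replicates(data)
        assert matrix.values[0, 0] == expected
        assert matrix.stage == "raw-summarized"

    def test_invariant_under_replicate_permutation(self, rng):
        cube = rng.uniform(1, 100, size=(3, 5, 7))
        ids = [f"m{i}" for i in range(5)]
        base = summarize_replicates(ProbeLevelData(["a", "b", "c"], ids, cube))
        shuffled = cube[:, :, rng.permutation(7)]
        again = summarize_replicates(
            ProbeLevelData(["a", "b", "c"], ids, shuffled))
        assert np.allclose(base.values, again.values)


class TestVsnNormalize:
    def test_monotone_and_rank_preserving_per_array(self, small_normalized):
        matrix, _, _, _ = small_normalized
        # normalization must preserve within-array ranks; compare with the
        # raw-summarized matrix of the same cohort
        assert matrix.stage == "normalized"
        assert np.all(np.isfinite(matrix.values))

    def test_rank_preservation_against_raw(self, small_cohort):
        data, _, _ = small_cohort
        raw = summarize_replicates(correct_background(data))
        norm, _ = vsn_normalize(raw)
        for i in range(len(raw.sample_ids)):
            raw_order = np.argsort(raw.values[i], kind="mergesort")
            norm_order = np.argsort(norm.values[i], kind="mergesort")
            assert np.array_equal(raw_order, norm_order)

    def test_stabilizes_variance_across_intensity_strata(self):
        """Measurement noise is multiplicative at high and additive at low
        intensity; after calibration + glog the per-miRNA SD must be nearly
        flat across intensity quintiles (ratio <= 1.5) whereas the raw
        scale spans orders of magnitude (ratio >= 3)."""
        config = CohortConfig(n_mirnas=863,
                              class_sizes={"PDAC": 20, "healthy": 20},
                              n_differential=0, seed=42)
        data, _, _ = simulate_cohort(config)
        raw = summarize_replicates(correct_background(data))
        norm, _ = vsn_normalize(raw)

        def stratum_ratio(values):
            sd = values.std(axis=0, ddof=1)
            mean = values.mean(axis=0)
            edges = np.quantile(mean, [0.2, 0.4, 0.6, 0.8])
            strata = np.digitize(mean, edges)
            med = [np.median(sd[strata == i]) for i in range(5)]
            return max(med) / min(med)

        assert stratum_ratio(raw.values) >= 3.0
        assert stratum_ratio(norm.values) <= 1.5

    def test_refuses_double_normalization(self, small_normalized):
        matrix, _, _, _ = small_normalized
        with pytest.raises(ValueError, match="exactly once"):
            vsn_normalize(matrix)

    def test_degenerate_array_rejected(self):
        import pandas as pd
        frame = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                             index=["flat", "ok"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="zero spread"):
            vsn_normalize(ExpressionMatrix(frame, stage="raw-summarized"))

    def test_calibration_scales_positive(self, small_normalized):
        _, _, _, fit = small_normalized
        assert (fit.scales > 0).all()


class TestIntersectAnnotation:
    def _matrix(self, ids):
        import pandas as pd
        frame = pd.DataFrame(np.ones((2, len(ids))), index=["s1", "s2"],
                             columns=ids)
        return ExpressionMatrix(frame, stage="normalized")

    def test_simple_intersection_preserves_order(self):
        matrix = self._matrix(["A", "B", "C", "D"])
        out = intersect_annotation(matrix, [{"A", "B", "C"},
                                            {"B", "C", "D"}, {"B", "C"}])
        assert out.mirna_ids == ["B", "C"]

    def test_identity_when_version_matches(self):
        matrix = self._matrix(["A", "B"])
        out = intersect_annotation(matrix, [{"A", "B"}])
        assert out.mirna_ids == ["A", "B"]

    def test_common_core_of_three_versions(self, rng):
        """Three annotation releases of sizes 900/880/870 sharing an
        863-member core: exactly the core survives."""
        core = [f"c{i}" for i in range(863)]
        v1 = set(core) | {f"x{i}" for i in range(37)}
        v2 = set(core) | {f"y{i}" for i in range(17)}
        v3 = set(core) | {f"z{i}" for i in range(7)}
        matrix = self._matrix(core + ["x0", "y0", "z0"])
        out = intersect_annotation(matrix, [v1, v2, v3])
        assert out.mirna_ids == core

    def test_empty_intersection_rejected(self):
        matrix = self._matrix(["A"])
        with pytest.raises(ValueError):
            intersect_annotation(matrix, [{"A"}, {"B"}])


class TestTechnicalReproducibility:
    def _matrix(self, rows, ids):
        import pandas as pd
        frame = pd.DataFrame(np.asarray(rows, dtype=float), index=ids)
        return ExpressionMatrix(frame, stage="normalized")

    def test_identical_profiles_correlate_perfectly(self):
        matrix = self._matrix([[1, 2, 3], [1, 2, 3]], ["r1", "r2"])
        assert technical_reproducibility(matrix, [("r1", "r2")]) == \
            pytest.approx(1.0)

    def test_negated_profile_anticorrelates(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        matrix = self._matrix([x, 2 * x.mean() - x], ["r1", "r2"])
        assert technical_reproducibility(matrix, [("r1", "r2")]) == \
            pytest.approx(-1.0)

    def test_simulated_technical_replicates_above_095(self, rng):
        """Two measurements of the same latent profile with 5%
        multiplicative noise correlate above 0.95 after normalization."""
        mu = rng.uniform(0.0, 10.0, 300)
        latent = mu + rng.normal(0, 0.5, 300)
        reps = np.stack([
            np.sinh(latent)[:, None] * np.exp(rng.normal(0, 0.05, (300, 7)))
            + rng.normal(0, 1.0, (300, 7))
            for _ in range(2)
        ])
        reps = np.maximum(reps, 0.0)
        data = ProbeLevelData(["r1", "r2"], [f"m{i}" for i in range(300)],
                              reps)
        matrix, _ = vsn_normalize(summarize_replicates(data))
        assert technical_reproducibility(matrix, [("r1", "r2")]) > 0.95

    def test_constant_profile_rejected(self):
        matrix = self._matrix([[1, 1, 1], [1, 2, 3]], ["r1", "r2"])
        with pytest.raises(ValueError, match="constant"):
            technical_reproducibility(matrix, [("r1", "r2")])
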