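"""Retinotopic distance distributions, null normalization and displacement tests."""

import numpy as np
import pandas as pd
import pytest

from alloptical.topography import (
    average_profiles,
    centroid_displacement_test,
    retinotopic_distances,
    strength_matched_resample,
    weighted_distance_distribution,
)


class TestDistances:
    def test_colocated_responder_distance_zero(self):
        d = retinotopic_distances([[1.0, 2.0]], [[1.0, 2.0]])
        assert d[0, 0] == 0.0

    def test_euclidean_arithmetic(self):
        d = retinotopic_distances([[3.0, 4.0]], [[0.0, 0.0], [0.0, 2.0]])
        assert d[0] == pytest.approx([5.0, 3.6056], abs=1e-3)

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            retinotopic_distances([[0.0, 0.0]], np.empty((0, 2)))


class TestWeightedDistribution:
    def test_probabilities_sum_to_one(self, rng):
        resp = rng.uniform(0, 20, size=(30, 2))
        avail = rng.uniform(0, 20, size=(100, 2))
        src = rng.uniform(0, 5, size=(5, 2))
        d = weighted_distance_distribution(resp, avail, src, n_null=2000, rng=rng)
        assert d.responder_prob.sum() == pytest.approx(1.0)
        assert d.null_prob.sum() == pytest.approx(1.0)

    def test_whole_population_gives_uniform_weighting(self, rng):
        avail = rng.uniform(0, 25, size=(200, 2))
        src = rng.uniform(10, 15, size=(4, 2))
        d = weighted_distance_distribution(avail, avail, src, n_null=20000, rng=rng)
        occupied = np.isfinite(d.weighted) & (d.responder_prob > 0.01)
        assert np.allclose(d.weighted[occupied], 1.0, atol=0.05)

    def test_single_responder_uniform_null_ratio(self, rng):
        # 10 available neurons at bin centres 0..9 deg (bin width 1.2 -> their
        # own bins); the single responder sits in bin 2
        src = np.array([[0.0, 0.0]])
        avail = np.column_stack([np.arange(10) * 1.2 + 0.6, np.zeros(10)])
        resp = avail[[2]]
        d = weighted_distance_distribution(
            resp, avail, src, n_null=200_000, n_bins=10, rng=rng
        )
        assert d.weighted[2] == pytest.approx(10.0, rel=0.03)
        others = np.delete(np.arange(10), 2)
        assert np.all((d.weighted[others] == 0) | ~np.isfinite(d.weighted[others]))

    def test_exhaustive_null_matches_hand_ratio(self, rng):
        """Large-draw null converges to the per-neuron average histogram."""
        src = np.array([[0.0, 0.0]])
        avail = np.array([[0.5, 0.0], [1.5, 0.0], [2.5, 0.0]])
        resp = avail[[0]]
        d = weighted_distance_distribution(
            resp, avail, src, n_null=300_000, bin_deg=1.0, n_bins=5, rng=rng
        )
        # null mass 1/3 per occupied bin; responder mass 1 in bin 0
        assert d.weighted[0] == pytest.approx(3.0, rel=0.02)

    def test_density_invariance_under_duplication(self, rng):
        avail = rng.uniform(0, 20, size=(50, 2))
        src = rng.uniform(0, 5, size=(3, 2))
        resp = avail[:10]
        d1 = weighted_distance_distribution(resp, avail, src, n_null=100_000, rng=rng)
        d2 = weighted_distance_distribution(
            resp, np.vstack([avail, avail]), src, n_null=100_000, rng=rng
        )
        ok = np.isfinite(d1.weighted) & np.isfinite(d2.weighted)
        assert np.allclose(d1.weighted[ok], d2.weighted[ok], atol=0.15)


class TestAverageProfiles:
    def _dist(self, weighted, rng):
        from alloptical.topography import DistanceDistribution

        n = len(weighted)
        return DistanceDistribution(
            bin_edges_deg=1.2 * np.arange(n + 1),
            responder_prob=np.full(n, 1 / n),
            null_prob=np.full(n, 1 / n),
            weighted=np.asarray(weighted, float),
            smoothed=np.asarray(weighted, float),
        )

    def test_identical_profiles_have_zero_sem(self, rng):
        d = self._dist([1.0, 2.0, 3.0, 2.0, 1.0], rng)
        out = average_profiles([d, d, d])
        assert np.allclose(out["sem"], 0.0)
        assert bool(out["sem_defined"].iloc[0])

    def test_impulse_moving_average(self, rng):
        d = self._dist([0.0, 0.0, 1.0, 0.0, 0.0], rng)
        out = average_profiles([d], smooth_bins=5)
        assert out["mean"].iloc[2] == pytest.approx(0.2)
        assert out["mean"].iloc[0] == pytest.approx(1 / 3)

    def test_single_group_sem_flagged(self, rng):
        d = self._dist([1.0, 1.0, 1.0], rng)
        out = average_profiles([d])
        assert not bool(out["sem_defined"].iloc[0])
        assert np.allclose(out["sem"], 0.0)

    def test_negation_for_display(self, rng):
        d = self._dist([1.0, 2.0, 1.0], rng)
        out = average_profiles([d], negate=True)
        assert out["mean"].iloc[1] < 0


class TestDisplacement:
    def test_identical_centroids_p_one(self):
        t = centroid_displacement_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t.p_value == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        t = centroid_displacement_test([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert t.p_value == pytest.approx(0.1)  # 2/20 arrangements, exact

    def test_centroid_is_mean_distance(self):
        assert np.mean([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_empty_sign_rejected(self):
        with pytest.raises(ValueError):
            centroid_displacement_test([], [1.0])


class TestStrengthMatchedResample:
    @staticmethod
    def _table(strengths_a, strengths_b, fac_a, sup_a, fac_b, sup_b):
        rows = []
        for s, f, u in zip(strengths_a, fac_a, sup_a):
            rows.append(("feedforward", s, f, u))
        for s, f, u in zip(strengths_b, fac_b, sup_b):
            rows.append(("feedback", s, f, u))
        return pd.DataFrame(rows, columns=["direction", "strength",
                                           "fac_centroid", "sup_centroid"])

    def test_symmetric_null_proportion_half_on_average(self, rng):
        # within one dataset the resamples concentrate near that dataset's
        # empirical displacement, so the null expectation of 0.5 emerges
        # across independently drawn datasets
        n = 40
        props = []
        for _ in range(12):
            tab = self._table(
                np.full(n, 5.0), np.full(n, 5.0),
                rng.normal(10, 1, n), rng.normal(10, 1, n),
                rng.normal(10, 1, n), rng.normal(10, 1, n),
            )
            res = strength_matched_resample(tab, n_resamples=200, rng=rng)
            props.extend(res.proportion_negative.values())
        assert np.mean(props) == pytest.approx(0.5, abs=0.15)

    def test_constructed_displacements_detected(self, rng):
        n = 20
        tab = self._table(
            np.full(n, 5.0), np.full(n, 5.0),
            rng.normal(12, 0.5, n), rng.normal(5, 0.5, n),  # feedforward fac > sup
            rng.normal(5, 0.5, n), rng.normal(12, 0.5, n),  # feedback fac < sup
        )
        res = strength_matched_resample(tab, n_resamples=300, rng=rng)
        assert res.proportion_negative["feedback"] > 0.99
        assert res.proportion_negative["feedforward"] < 0.01

    def test_half_of_smaller_direction_sampled_per_bin(self, rng):
        # 10 groups one direction, 6 the other -> 3 sampled from each; with
        # feedback fac-sup values in {0,3}, 3-subset means lie on a 1-step grid
        tab = self._table(
            np.full(10, 5.0), np.full(6, 5.0),
            np.zeros(10), np.zeros(10),
            np.array([0.0, 0, 0, 3, 3, 3]), np.zeros(6),
        )
        res = strength_matched_resample(tab, n_resamples=200, rng=rng)
        vals = np.unique(np.round(res.displacements["feedback"], 6))
        assert set(vals).issubset({0.0, 1.0, 2.0, 3.0})
        assert len(vals) > 1  # varies across resamples -> truly subsampled

    def test_no_overlapping_bins_rejected(self, rng):
        tab = self._table([5.0], [50.0], [1.0], [1.0], [1.0], [1.0])
        with pytest.raises(ValueError):
            strength_matched_resample(tab, n_resamples=10, rng=rng)
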