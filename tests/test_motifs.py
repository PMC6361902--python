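import numpy as np
import pytest
from sklearn.base import clone

from brainsongs import (MotifExtractor, bin_timeseries, count_significant,
                        detect_events, extract_motifs, motif_activity,
                        motif_probabilities, mp_bounds, threshold_crossings,
                        zscore_events)


class TestBinning:
    def test_window_means(self):
        x = np.arange(1000, dtype=float)[None, :]
        binned = bin_timeseries(x, 200.0, dt=1.0)
        assert binned.shape == (1, 5)
        np.testing.assert_allclose(binned[0],
                                   [99.5, 299.5, 499.5, 699.5, 899.5])

    def test_bin_equal_to_dt_is_identity(self):
        x = np.random.default_rng(0).normal(size=(3, 50))
        np.testing.assert_array_equal(bin_timeseries(x, 1.0, 1.0), x)

    def test_constant_signal_and_trailing_window(self):
        x = np.full((1, 1050), 4.2)
        binned = bin_timeseries(x, 500.0, 1.0)
        assert binned.shape == (1, 2)  # partial trailing window dropped
        np.testing.assert_allclose(binned, 4.2)

    def test_non_multiple_bin_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            bin_timeseries(np.zeros((1, 100)), 1.5, 1.0)
        with pytest.raises(ValueError, match="multiple"):
            bin_timeseries(np.zeros((1, 100)), 0.5, 1.0)


class TestEventDetection:
    def test_upward_crossing_hand_trace(self):
        z = np.array([[-1.0, 0.0, 2.0, 2.0, 0.0, 3.0]])
        events = threshold_crossings(z, 1.0)
        np.testing.assert_array_equal(events, [[0, 0, 1, 0, 0, 1]])
        assert events.sum() == 2

    def test_single_crossing_for_monotone_series(self):
        z = np.linspace(-2, 2, 20)[None, :]
        assert threshold_crossings(z, 1.0).sum() == 1

    def test_no_events_below_threshold(self):
        z = np.zeros((2, 10))
        assert threshold_crossings(z, 1.0).sum() == 0

    def test_first_bin_counts_as_crossing(self):
        z = np.array([[2.0, 0.0, 0.0]])
        np.testing.assert_array_equal(threshold_crossings(z, 1.0),
                                      [[1, 0, 0]])

    def test_constant_regions_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        binned = rng.normal(size=(3, 100))
        binned[1] = 3.3
        with pytest.warns(UserWarning, match=r"\[1\]"):
            em = detect_events(binned, theta=1.0)
        assert em.excluded_regions == [1]
        assert em.binary[1].sum() == 0

    def test_all_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            detect_events(np.ones((3, 50)), 1.0)

    def test_plain_threshold_rule(self):
        rng = np.random.default_rng(1)
        binned = rng.normal(size=(2, 300))
        em_c = detect_events(binned, 1.0, rule="crossing")
        em_t = detect_events(binned, 1.0, rule="threshold")
        # every crossing is also a super-threshold bin
        assert np.all(em_t.binary >= em_c.binary)


class TestZscore:
    def test_alternating_row_hand_computation(self):
        em = detect_events(np.array([[0., 5., 0., 5.], [5., 0., 5., 0.]]),
                           theta=0.5)
        # crossing rule: row0 events at bins 2,4; row1 event at bin 1, 3
        z = zscore_events(em)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(z[0], [-1, 1, -1, 1])

    def test_postcondition_on_random_rasters(self):
        rng = np.random.default_rng(2)
        em = detect_events(rng.normal(size=(10, 400)), 1.0)
        z = zscore_events(em)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_eventless_rows_dropped(self):
        rng = np.random.default_rng(3)
        binned = rng.normal(size=(4, 200))
        binned[2] = np.linspace(0, 1, 200)  # monotone: one event only
        em = detect_events(binned, theta=8.0)  # nothing crosses 8 SD...
        with pytest.raises(ValueError, match="fewer than 2"):
            zscore_events(em)


class TestMarchenkoPastur:
    @pytest.mark.parametrize("q, rho2, expected", [
        (1.0, 1.0, (0.0, 4.0)),
        (4.0, 1.0, (0.25, 2.25)),
        (4.0, 2.0, (0.5, 4.5)),
    ])
    def test_closed_form_bounds(self, q, rho2, expected):
        lo, hi = mp_bounds(q, rho2)
        assert lo == pytest.approx(expected[0], abs=1e-12)
        assert hi == pytest.approx(expected[1], abs=1e-12)

    def test_q_below_one_rejected(self):
        with pytest.raises(ValueError, match="more time bins"):
            mp_bounds(0.5)


def _bin_level_raster(rng, n=30, n_bins=600, p=0.25, assemblies=()):
    """Binary event raster with optional planted co-active assemblies."""
    raster = (rng.random((n, n_bins)) < p).astype(float)
    for members in assemblies:
        on = rng.random(n_bins) < 0.3
        raster[np.ix_(members, np.flatnonzero(on))] = 1.0
    return raster


def _zscore_rows(r):
    return (r - r.mean(axis=1, keepdims=True)) / r.std(axis=1, keepdims=True)


class TestSignificance:
    def test_independent_rows_yield_no_components(self):
        hits = 0
        for seed in range(20):
            e = _zscore_rows(_bin_level_raster(np.random.default_rng(seed)))
            K, ev, (lo, hi) = count_significant(e)
            hits += K == 0
            assert ev[0] >= ev[-1]
        assert hits >= 18

    def test_single_planted_assembly_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            e = _zscore_rows(_bin_level_raster(rng,
                                               assemblies=[range(6)]))
            K, _, _ = count_significant(e)
            hits += K == 1
        assert hits >= 19

    def test_two_disjoint_assemblies_counted(self):
        rng = np.random.default_rng(42)
        e = _zscore_rows(_bin_level_raster(
            rng, assemblies=[range(6), range(6, 12)]))
        K, _, _ = count_significant(e)
        assert K == 2


class TestExtraction:
    def _planted(self, seed, two=False):
        rng = np.random.default_rng(seed)
        asm = [range(6), range(6, 12)] if two else [range(6)]
        return _zscore_rows(_bin_level_raster(rng, assemblies=asm))

    def test_single_assembly_membership_recovered(self):
        e = self._planted(7)
        w = extract_motifs(e, 1, seed=0)
        truth = np.zeros(30)
        truth[:6] = 1
        truth /= np.linalg.norm(truth)
        assert abs(w[:, 0] @ truth) > 0.9

    def test_two_assemblies_recovered_by_best_match(self):
        e = self._planted(8, two=True)
        w = extract_motifs(e, 2, seed=0)
        t = np.zeros((30, 2))
        t[:6, 0] = 1
        t[6:12, 1] = 1
        t /= np.linalg.norm(t, axis=0)
        cos = np.abs(w.T @ t)
        best = max(min(cos[0, 0], cos[1, 1]), min(cos[0, 1], cos[1, 0]))
        assert best > 0.9

    def test_extraction_stable_across_seeds(self):
        e = self._planted(9, two=True)
        w1 = extract_motifs(e, 2, seed=1)
        w2 = extract_motifs(e, 2, seed=2)
        cos = np.abs(w1.T @ w2)
        # match columns greedily; both pairings should be near-identical
        assert max(min(cos[0, 0], cos[1, 1]),
                   min(cos[0, 1], cos[1, 0])) > 0.99

    def test_unit_norm_and_sign_convention(self):
        e = self._planted(10, two=True)
        w = extract_motifs(e, 2, seed=0)
        np.testing.assert_allclose(np.linalg.norm(w, axis=0), 1.0,
                                   atol=1e-9)
        idx = np.argmax(np.abs(w), axis=0)
        assert np.all(w[idx, np.arange(2)] > 0)


class TestActivity:
    def test_quadratic_projection_closed_forms(self):
        w = np.zeros((4, 1))
        w[0] = 1.0
        e = np.column_stack([w[:, 0], [0, 1, 0, 0], 2 * w[:, 0]])
        A = motif_activity(e, w)
        np.testing.assert_allclose(A, [[1.0, 0.0, 4.0]])

    def test_requires_unit_norm_weights(self):
        with pytest.raises(ValueError, match="unit-norm"):
            motif_activity(np.eye(3), 2 * np.eye(3)[:, :1])

    @pytest.mark.parametrize("rows, expected", [
        (np.ones((1, 4)), [1.0]),
        (np.ones((3, 4)), [1 / 3] * 3),
        (np.array([[3., 0.], [1., 0.]]), [0.75, 0.25]),
    ])
    def test_probabilities(self, rows, expected):
        np.testing.assert_allclose(motif_probabilities(rows), expected)

    def test_all_zero_activity_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            motif_probabilities(np.zeros((2, 5)))


class TestMotifExtractorEstimator:
    def _activity(self, seed=0):
        import brainsongs as bs

        specs = [bs.AssemblySpec(list(range(k * 4, (k + 1) * 4)),
                                 duration_ms=200.0) for k in range(3)]
        act, _ = bs.make_planted_raster(20, 60_000.0, specs, seed=seed)
        return act.T  # sklearn orientation: (n_samples, n_regions)

    def test_fit_exposes_motif_attributes(self):
        ext = MotifExtractor(bin_ms=200.0, random_state=0).fit(
            self._activity())
        assert ext.n_motifs_ >= 1
        assert ext.weights_.shape[1] == ext.n_motifs_
        assert ext.activities_.shape[0] == ext.n_motifs_
        assert ext.probabilities_.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(ext.activities_ >= 0)
        K_count = np.sum(ext.eigenvalues_ > ext.mp_bounds_[1])
        assert ext.n_motifs_ == K_count

    def test_transform_projects_onto_fitted_motifs(self):
        X = self._activity()
        ext = MotifExtractor(bin_ms=200.0, random_state=0).fit(X)
        act = ext.transform(X)
        assert act.shape == (ext.activities_.shape[1], ext.n_motifs_)
        np.testing.assert_allclose(act, ext.activities_.T, atol=1e-9)

    def test_clone_and_params_roundtrip(self):
        ext = MotifExtractor(bin_ms=100.0, theta=1.5, random_state=3)
        cl = clone(ext)
        assert cl.get_params() == ext.get_params()
        cl.set_params(theta=0.5)
        assert cl.theta == 0.5 and ext.theta == 1.5

    def test_deterministic_given_random_state(self):
        X = self._activity(1)
        a = MotifExtractor(bin_ms=200.0, random_state=5).fit(X)
        b = MotifExtractor(bin_ms=200.0, random_state=5).fit(X)
        np.testing.assert_array_equal(a.weights_, b.weights_)
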