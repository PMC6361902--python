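import numpy as np
import pytest

import brainsongs as bs
from brainsongs import (AssemblySpec, damage_connectome, make_connectome,
                        make_planted_raster)
from brainsongs.motifs import bin_timeseries, count_significant, detect_events, zscore_events


class TestConnectomeGenerator:
    @pytest.mark.parametrize("family", ["community", "distance", "ring"])
    def test_invariants_hold(self, family):
        sc = make_connectome(20, family=family, seed=1)
        w = sc.weights
        np.testing.assert_allclose(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert np.all(w >= 0)
        assert w.sum() > 0

    def test_reproducible_from_seed(self):
        a = make_connectome(12, seed=7)
        b = make_connectome(12, seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)
        c = make_connectome(12, seed=8)
        assert not np.array_equal(a.weights, c.weights)

    def test_density_validation(self):
        with pytest.raises(ValueError, match="density"):
            make_connectome(10, density=0.0)
        with pytest.raises(ValueError, match="density"):
            make_connectome(10, density=1.5)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            make_connectome(10, family="smallworld")


class TestDamage:
    def test_zero_damage_is_identity(self):
        sc = make_connectome(15, seed=2)
        out = damage_connectome(sc, 0.0)
        np.testing.assert_array_equal(out.weights, sc.weights)

    def test_removes_exactly_the_largest_edges(self):
        sc = make_connectome(15, seed=3)
        iu = np.triu_indices(15, k=1)
        vals = sc.weights[iu]
        n_edges = int(np.sum(vals > 0))
        percent = 20.0
        out = damage_connectome(sc, percent)
        removed = (vals > 0) & (out.weights[iu] == 0)
        n_cut = int(np.ceil(percent / 100 * n_edges))
        assert removed.sum() == n_cut
        # sort oracle: the removed ones are the largest
        thresh = np.sort(vals[vals > 0])[-n_cut]
        assert np.all(vals[removed] >= thresh)

    def test_full_damage_empties_graph(self):
        sc = make_connectome(10, seed=4)
        assert damage_connectome(sc, 100.0).weights.sum() == 0


class TestPlantedRaster:
    def _specs(self, n=4, size=4, D=200.0):
        return [AssemblySpec(list(range(k * size, (k + 1) * size)),
                             duration_ms=D) for k in range(n)]

    def test_realised_activation_fraction_matches_spec(self):
        specs = self._specs()
        _, truth = make_planted_raster(24, 240_000.0, specs, seed=0)
        # ~180 activation cycles; allow a generous multiple of the SE
        for frac in truth["active_fraction"]:
            assert abs(frac - 0.15) < 0.05

    def test_members_coactivate_during_assembly_epochs(self):
        """Member event rates concentrate in assembly-active bins;
        background regions show no such modulation."""
        specs = self._specs()
        act, truth = make_planted_raster(24, 120_000.0, specs, seed=1)
        em = detect_events(bin_timeseries(act, 200.0), theta=1.0)
        active_bins = bin_timeseries(
            truth["active"].astype(float), 200.0) > 0.5
        member = truth["membership"].sum(axis=0) > 0
        # event rate of members inside vs outside their assembly's epochs
        in_rate = np.concatenate([
            em.binary[np.ix_(np.flatnonzero(truth["membership"][k] > 0),
                             np.flatnonzero(active_bins[k]))].ravel()
            for k in range(len(specs))]).mean()
        out_rate = np.concatenate([
            em.binary[np.ix_(np.flatnonzero(truth["membership"][k] > 0),
                             np.flatnonzero(~active_bins[k]))].ravel()
            for k in range(len(specs))]).mean()
        assert in_rate > 2.0 * out_rate
        assert em.binary[member].mean() > em.binary[~member].mean()

    def test_pure_noise_raster_yields_no_motifs(self):
        hits = 0
        for seed in range(10):
            act, _ = make_planted_raster(20, 60_000.0, [],
                                         global_amplitude=0.0, seed=seed)
            e = zscore_events(detect_events(bin_timeseries(act, 200.0), 1.0))
            K, _, _ = count_significant(e)
            hits += K == 0
        assert hits >= 9

    def test_duration_guard_and_member_range(self):
        with pytest.raises(ValueError, match="duration"):
            make_planted_raster(10, 1_000.0, self._specs(1, D=200.0))
        with pytest.raises(ValueError, match="region range"):
            make_planted_raster(4, 60_000.0,
                                [AssemblySpec([3, 9], duration_ms=100.0)])

    def test_shared_members_warn(self):
        specs = [AssemblySpec([0, 1, 2], duration_ms=100.0),
                 AssemblySpec([2, 3, 4], duration_ms=100.0)]
        with pytest.warns(UserWarning, match="share members"):
            make_planted_raster(8, 30_000.0, specs, seed=0)

    def test_reproducibility_and_truth_sidecar(self, tmp_path):
        specs = self._specs(2)
        a, truth = make_planted_raster(10, 30_000.0, specs, seed=3)
        b, _ = make_planted_raster(10, 30_000.0, specs, seed=3)
        np.testing.assert_array_equal(a, b)
        from brainsongs.synthetic import save_truth

        save_truth(truth, tmp_path / "truth.json")
        import json

        back = json.loads((tmp_path / "truth.json").read_text())
        assert back["seed"] == 3
        assert len(back["membership"]) == 2


class TestSurrogateBold:
    def test_forward_model_output_and_determinism(self, dmf_params):
        sc = make_connectome(5, seed=6)
        bold, truth = bs.make_surrogate_bold(
            sc, dmf_params, G=0.5, tr=2.0, duration_ms=70_000.0, seed=2)
        assert truth["G"] == 0.5
        assert bold.n_regions == 5
        assert np.all(np.isfinite(bold.values))
        assert bold.sampling_interval == 2.0
        again, _ = bs.make_surrogate_bold(
            sc, dmf_params, G=0.5, tr=2.0, duration_ms=70_000.0, seed=2)
        np.testing.assert_array_equal(bold.values, again.values)
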