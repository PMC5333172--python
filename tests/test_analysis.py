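"""Figure-level statistics: bins, CVs, correlations, KS bootstrap."""

import numpy as np
import pytest
from scipy import stats

from regevo.analysis import (
    BinProfile,
    affinity_set_correlation,
    bin_energy,
    energy_dynamics,
    generation_correlation,
    ks_bootstrap,
    ks_statistic,
    low_high_ratio,
    rms_energy_correlation,
)
from regevo.annotation import TFBS
from regevo.tracking import Trajectory

from oracles import bin_energy_oracle, cv_oracle, ks_oracle, pearson_oracle


def site(start, E, locus="hb", tf="X", length=8):
    return TFBS(tf, locus, start, length, "+", E)


class TestBinEnergy:
    LEN = {"hb": 900}

    def test_empty_bins_are_zero(self):
        prof = bin_energy([], self.LEN, 180)
        assert prof.n_bins == 5
        assert np.all(prof.E_bin == 0.0)

    def test_single_site_normalised_by_bin_length(self):
        prof = bin_energy([site(10, 9.0)], self.LEN, 180)
        assert prof.E_bin[0] == pytest.approx(9.0 / 180)

    def test_straddling_site_assigned_to_start_bin(self):
        prof = bin_energy([site(178, 6.0)], self.LEN, 180)
        assert prof.E_bin[0] == pytest.approx(6.0 / 180)
        assert prof.E_bin[1] == 0.0

    def test_trailing_partial_bin_uses_own_length(self):
        prof = bin_energy([site(905, 5.0)], {"hb": 900 + 30}, 180)
        # last bin of a 930 bp locus is 930 - 5*180 = 30 bp wide
        assert prof.E_bin[-1] == pytest.approx(5.0 / 30)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(200, 1200))
        width = int(rng.choice([60, 180, 250]))
        sites = [
            site(int(rng.integers(0, length - 8)), float(rng.uniform(0, 10)))
            for _ in range(rng.integers(0, 25))
        ]
        prof = bin_energy(sites, {"hb": length}, width)
        expected = bin_energy_oracle(
            [(s.start, s.E) for s in sites], length, width
        )
        np.testing.assert_allclose(prof.E_bin, expected, atol=1e-10)

    def test_invariant_under_site_reordering(self):
        rng = np.random.default_rng(1)
        sites = [site(int(rng.integers(0, 800)), float(rng.uniform(1, 9))) for _ in range(15)]
        a = bin_energy(sites, self.LEN, 180).E_bin
        b = bin_energy(sites[::-1], self.LEN, 180).E_bin
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_dE_is_difference_to_generation_zero(self):
        E = np.array([[1.0, 2.0], [0.5, 3.0]])
        prof = BinProfile({"hb": 360}, 180, E, [("hb", 0), ("hb", 180)])
        np.testing.assert_allclose(prof.dE(), [[0, 0], [-0.5, 1.0]])


class FakeRec:
    def __init__(self, generation, elite_sites, F=None):
        self.generation = generation
        self.elite_sites = elite_sites
        self.F_all = np.asarray(F if F is not None else [0.0])


class TestEnergyDynamics:
    def test_identical_energies_give_zero_cv(self):
        recs = [FakeRec(0, [[site(0, 5.0), site(20, 5.0)]])]
        df = energy_dynamics(recs, "all")
        assert df.loc[0, "cv"] == 0.0

    def test_mean_and_cv_match_oracle(self):
        es = [2.0, 4.0]
        recs = [FakeRec(0, [[site(0, 2.0), site(20, 4.0)]])]
        df = energy_dynamics(recs, "all")
        assert df.loc[0, "mean_E"] == pytest.approx(3.0)
        assert df.loc[0, "cv"] == pytest.approx(cv_oracle(es), abs=1e-12)

    def test_new_sites_identified_by_founder_coordinates(self):
        founder = [site(0, 5.0)]
        later = [site(0, 5.0), site(100, 7.0)]
        recs = [FakeRec(0, [founder]), FakeRec(1, [later])]
        df = energy_dynamics(recs, "new")
        assert df.loc[0, "n"] == 0
        assert df.loc[1, "n"] == 1
        assert df.loc[1, "mean_E"] == pytest.approx(7.0)

    def test_constant_run_has_constant_mean(self):
        sites = [site(0, 5.0), site(30, 2.0)]
        recs = [FakeRec(g, [list(sites)]) for g in range(5)]
        df = energy_dynamics(recs, "all")
        assert df["mean_E"].nunique() == 1


class TestLowHighRatio:
    def test_all_below_threshold_is_missing(self):
        out = low_high_ratio([[1.0, 2.0, 3.0]], threshold=4.0)
        assert np.isnan(out[0])

    def test_simple_ratio(self):
        out = low_high_ratio([[1, 2, 3, 5, 6, 7, 8, 9, 10]], threshold=4.0)
        assert out[0] == pytest.approx(3 / 6)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        es = rng.uniform(0, 10, size=50)
        ratios = []
        for thr in np.linspace(0.5, 9.5, 15):
            r = low_high_ratio([es], threshold=thr)[0]
            ratios.append(np.inf if np.isnan(r) else r)
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))


def make_traj(E_series, origin_gen=0, tf="X", locus="hb", start=0):
    return Trajectory(
        tf=tf,
        locus=locus,
        length=8,
        origin="initial" if origin_gen == 0 else "born",
        origin_generation=origin_gen,
        starts=[start] * len(E_series),
        strands=["+"] * len(E_series),
        energies=list(E_series),
    )


class TestAffinitySets:
    def test_single_set_is_trivially_one(self):
        trajs = [make_traj([1, 2, 3]), make_traj([2, 3, 4])]
        cm = affinity_set_correlation(trajs, 2, n_sets=1)
        assert cm.matrix.shape == (1, 1)
        assert cm.matrix[0, 0] == pytest.approx(1.0)

    def test_identical_series_fully_correlated(self):
        trajs = [make_traj([1, 2, 3]), make_traj([5, 6, 7])]
        cm = affinity_set_correlation(trajs, 2, n_sets=2)
        assert cm.matrix[0, 1] == pytest.approx(1.0)

    def test_too_few_trajectories_rejected(self):
        with pytest.raises(ValueError, match="n_sets"):
            affinity_set_correlation([make_traj([1, 2])], 1, n_sets=5)

    def test_planted_common_trend_recovered(self):
        """Series sharing a trend correlate strongly within blocks."""
        rng = np.random.default_rng(3)
        G = 60
        trend = np.linspace(0, 3, G + 1)
        trajs = []
        for k in range(40):
            base = rng.uniform(1, 9)
            trajs.append(make_traj(base + trend + rng.normal(0, 0.2, G + 1)))
        cm = affinity_set_correlation(trajs, G, n_sets=8)
        off = cm.matrix[~np.eye(8, dtype=bool)]
        assert np.nanmean(off) > 0.5

    def test_remainder_spread_over_leading_sets(self):
        trajs = [make_traj([float(i), float(i)]) for i in range(7)]
        cm = affinity_set_correlation(trajs, 1, n_sets=3)
        # 7 = 3 + 2 + 2: sample sizes recorded on the diagonal blocks
        assert cm.n[0, 0] == 2  # both generations jointly defined
        assert cm.matrix.shape == (3, 3)


class TestGenerationCorrelation:
    def test_constant_profiles_fully_correlated(self):
        E = np.tile(np.array([1.0, 2.0, 3.0, 1.0]), (5, 1))
        cm = generation_correlation(BinProfile({"hb": 720}, 180, E, [("hb", i * 180) for i in range(4)]))
        np.testing.assert_allclose(cm.matrix, 1.0)

    def test_diagonal_is_one_where_defined(self):
        rng = np.random.default_rng(0)
        E = rng.uniform(0, 1, size=(6, 10))
        cm = generation_correlation(BinProfile({"hb": 1800}, 180, E, [("hb", i) for i in range(10)]))
        np.testing.assert_allclose(np.diag(cm.matrix), 1.0)
        np.testing.assert_allclose(cm.matrix, cm.matrix.T)

    def test_flat_generation_row_undefined(self):
        E = np.vstack([np.zeros(6), np.arange(6.0)])
        cm = generation_correlation(BinProfile({"hb": 1080}, 180, E, [("hb", i) for i in range(6)]))
        assert np.isnan(cm.matrix[0, 1])
        assert cm.matrix[1, 1] == pytest.approx(1.0)


class TestKsBootstrap:
    def test_statistic_matches_oracle_and_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 40))
            b = rng.normal(0.5, 1.3, size=rng.integers(5, 40))
            s = ks_statistic(a, b)
            assert s == pytest.approx(ks_oracle(a, b), abs=1e-12)
            assert s == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)

    def test_identical_samples_statistic_zero_p_one(self):
        a = np.arange(30.0)
        res = ks_bootstrap(a, a.copy(), n_boot=99, rng=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports_reject(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 50)
        b = rng.uniform(5, 6, 50)
        res = ks_bootstrap(a, b, n_boot=999, rng=2)
        assert res.statistic == 1.0
        assert res.p_value <= 0.01

    def test_p_value_in_unit_interval(self):
        rng = np.random.default_rng(5)
        res = ks_bootstrap(rng.normal(size=20), rng.normal(size=25), n_boot=99, rng=6)
        assert 0.0 < res.p_value <= 1.0


class TestRmsEnergyCorrelation:
    def make_records(self, F_series, E_series):
        recs = []
        for g, (f, e) in enumerate(zip(F_series, E_series)):
            recs.append(FakeRec(g, [[site(0, float(e))]], F=[f]))
        return recs

    def test_constant_fitness_series_undefined(self):
        recs = self.make_records([1.0] * 9, np.arange(9.0))
        df = rms_energy_correlation(recs, "all", epoch_bounds=[0, 9])
        assert not df.loc[0, "defined"]

    def test_anticorrelated_pair_negative(self):
        f = np.linspace(0, 1, 12)
        recs = self.make_records(f, 5 - 4 * f)
        df = rms_energy_correlation(recs, "all", epoch_bounds=[0, 12])
        assert df.loc[0, "pearson_r"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0, 1, 15)
        e = rng.uniform(2, 8, 15)
        recs = self.make_records(f, e)
        df = rms_energy_correlation(recs, "all", epoch_bounds=[0, 15])
        assert df.loc[0, "pearson_r"] == pytest.approx(
            pearson_oracle(f, e), abs=1e-12
        )

    def test_default_epochs_are_thirds(self):
        recs = self.make_records(np.arange(9.0), np.arange(9.0))
        df = rms_energy_correlation(recs, "all")
        assert list(df["start"]) == [0, 3, 6]
        assert list(df["stop"]) == [3, 6, 9]
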