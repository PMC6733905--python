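"""Ground-truth generators: trees, traits, gene trees, climate, physiology."""

import numpy as np
import pytest

from climevol.bioclim import HOURS_PER_YEAR
from climevol.physiology import build_trait_table
from climevol.synthdata import (
    PaleoCurve,
    SimConfig,
    sim_bd_tree,
    sim_gene_trees,
    sim_microclim_grid,
    sim_occurrences,
    sim_paleo_curve,
    sim_physio_raw,
    sim_trait,
)
from climevol.treekit import root_to_tip_paths, write_newick


class TestBirthDeathTree:
    def test_minimal_two_tip_yule(self):
        t = sim_bd_tree(1.0, 0.0, 2, seed=0)
        assert len(t.tip_labels) == 2
        assert t.is_ultrametric()
        assert t.depth > 0

    def test_conditioned_tip_count_with_extinction(self):
        t = sim_bd_tree(0.3, 0.1, 25, seed=4)
        assert len(t.tip_labels) == 25
        assert t.is_ultrametric()
        assert all(n.length >= 0 for n in t.preorder())

    def test_same_seed_identical_newick(self):
        a = write_newick(sim_bd_tree(1.0, 0.2, 8, seed=5))
        b = write_newick(sim_bd_tree(1.0, 0.2, 8, seed=5))
        assert a == b

    def test_yule_mean_crown_age_matches_expectation(self):
        # closed form of the sampling scheme: from 2 lineages, the wait from k
        # to k+1 lineages is Exp(k*lam); the present extends a uniform
        # fraction of one further waiting time at n lineages
        n, lam, reps = 10, 1.0, 400
        ages = np.array([sim_bd_tree(lam, 0.0, n, seed=s).depth for s in range(reps)])
        expect = sum(1.0 / (k * lam) for k in range(2, n)) + 1.0 / (2 * n * lam)
        se = ages.std(ddof=1) / np.sqrt(reps)
        assert abs(ages.mean() - expect) < 3 * se

    def test_invalid_rates_raise(self):
        with pytest.raises(ValueError):
            sim_bd_tree(0.1, 0.2, 5, seed=0)
        with pytest.raises(ValueError):
            sim_bd_tree(1.0, 0.0, 1, seed=0)


class TestTraitSimulation:
    def test_near_zero_rate_collapses_to_root_state(self):
        t = sim_bd_tree(1.0, 0.0, 10, seed=1)
        st = sim_trait(t, sigma2=1e-14, seed=0)
        vals = [st[l] for l in t.tip_labels]
        assert np.ptp(vals) < 1e-5

    def test_bm_tip_variance_matches_closed_form(self):
        t = sim_bd_tree(1.0, 0.0, 10, seed=1)
        tip = t.tip_labels[0]
        reps = 2000
        draws = np.array([sim_trait(t, sigma2=2.0, seed=s)[tip] for s in range(reps)])
        expect = 2.0 * t.depth
        # variance of a sample variance: ~ sqrt(2/(n-1)) * var
        se = expect * np.sqrt(2.0 / (reps - 1))
        assert abs(draws.var(ddof=1) - expect) < 3 * se

    def test_ou_large_alpha_reaches_stationary_distribution(self):
        t = sim_bd_tree(1.0, 0.0, 10, seed=1)
        vals = []
        for s in range(500):
            st = sim_trait(t, model="ou", sigma2=2.0, alpha=8.0, theta=5.0, root_state=0.0, seed=s)
            vals.extend(st[l] for l in t.tip_labels)
        vals = np.array(vals)
        assert abs(vals.mean() - 5.0) < 0.05
        assert abs(vals.var() - 2.0 / (2 * 8.0)) < 0.02

    def test_invalid_params_raise(self):
        t = sim_bd_tree(1.0, 0.0, 4, seed=0)
        with pytest.raises(ValueError):
            sim_trait(t, sigma2=0.0)
        with pytest.raises(ValueError):
            sim_trait(t, model="ou", alpha=-1.0)


class TestGeneTrees:
    def test_no_coupling_no_noise_gives_clock(self):
        t = sim_bd_tree(1.0, 0.0, 8, seed=2)
        env = {l: float(i) for i, l in enumerate(t.tip_labels)}
        genes = sim_gene_trees(t, env, a=-2.0, b=0.0, noise_sd=0.0, n_genes=3, seed=0)
        for g in genes.values():
            assert g.is_ultrametric()
            paths = root_to_tip_paths(g)
            assert np.allclose(list(paths.values()), t.depth * np.exp(-2.0))

    def test_positive_coupling_orders_paths_on_symmetric_tree(self):
        # symmetric topology and symmetric env: the hotter cherry is strictly
        # faster in every noise-free gene
        from climevol.treekit import parse_newick

        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        env = {"A": -2.0, "B": -2.0, "C": 2.0, "D": 2.0}
        genes = sim_gene_trees(t, env, a=0.0, b=0.5, noise_sd=0.0, n_genes=2, seed=0)
        for g in genes.values():
            p = root_to_tip_paths(g)
            assert p["C"] > p["A"]
            assert p["D"] > p["B"]

    def test_clock_ratio_constant_iff_no_coupling(self):
        t = sim_bd_tree(1.0, 0.0, 8, seed=2)
        env = {l: float(i) for i, l in enumerate(t.tip_labels)}
        g0 = sim_gene_trees(t, env, a=-1.0, b=0.0, noise_sd=0.0, n_genes=2, seed=0)
        p1, p2 = (root_to_tip_paths(g) for g in g0.values())
        ratios = np.array([p1[l] / p2[l] for l in t.tip_labels])
        assert np.ptp(ratios) < 1e-12
        gb = sim_gene_trees(t, env, a=-1.0, b=0.3, noise_sd=0.0, n_genes=1, seed=0)
        pb = root_to_tip_paths(next(iter(gb.values())))
        ratios_b = np.array([pb[l] / p1[l] for l in t.tip_labels])
        assert np.ptp(ratios_b) > 1e-6

    def test_missing_env_lists_species(self):
        t = sim_bd_tree(1.0, 0.0, 4, seed=0)
        env = {l: 0.0 for l in t.tip_labels[:-1]}
        with pytest.raises(ValueError, match=t.tip_labels[-1]):
            sim_gene_trees(t, env, 0.0, 0.0, 0.0, 1, 0)


class TestMicroclimate:
    def test_degenerate_constant_grid(self):
        g = sim_microclim_grid((2, 3), annual_mean=25.0, mean_gradient=0.0,
                               seasonal_amp=0.0, diurnal_amp=0.0, rad_peak=400.0,
                               noise_sd=0.0, seed=0)
        assert np.all(g.temps == 25.0)
        assert np.all(g.tmax == 25.0) and np.all(g.tmin == 25.0)

    def test_radiation_zero_at_night_peaks_at_noon(self):
        g = sim_microclim_grid((3, 3), seed=1)
        assert np.all(g.rad[..., 0] == 0.0)
        assert np.all(g.rad[..., 23] == 0.0)
        assert np.all(g.rad[..., 12] == g.rad.max())

    def test_climatology_ordering_and_roundtrip(self, tmp_path):
        g = sim_microclim_grid((3, 2), seed=2)
        assert np.all(g.tmax >= g.tmin)
        g.to_tsv(tmp_path / "g.tsv")
        from climevol.bioclim import MicroclimGrid

        g2 = MicroclimGrid.from_tsv(tmp_path / "g.tsv")
        np.testing.assert_allclose(g2.temps, g.temps)
        np.testing.assert_allclose(g2.rad, g.rad)


class TestOccurrences:
    def test_zero_radius_all_points_at_center(self):
        g = sim_microclim_grid((5, 5), seed=0)
        occ = sim_occurrences(g, {"sp1": (2.5, 2.5)}, {"sp1": 0.0}, {"sp1": 20}, seed=0)
        assert (occ.records["x"] == 2.5).all() and (occ.records["y"] == 2.5).all()

    def test_points_within_radius_and_deterministic(self):
        g = sim_microclim_grid((6, 6), seed=0)
        occ1 = sim_occurrences(g, {"sp1": (3.0, 3.0)}, {"sp1": 1.2}, {"sp1": 50}, seed=9)
        occ2 = sim_occurrences(g, {"sp1": (3.0, 3.0)}, {"sp1": 1.2}, {"sp1": 50}, seed=9)
        assert occ1.records.equals(occ2.records)
        d = np.hypot(occ1.records["x"] - 3.0, occ1.records["y"] - 3.0)
        assert (d <= 1.2 + 1e-12).all()


class TestPhysioRaw:
    def test_noise_free_recovery_is_exact(self):
        raw = sim_physio_raw({"spA": 4}, true_hourly_loss=0.015, true_tpref=31.5,
                             weight_noise_sd=0.0, temp_noise_sd=0.0, seed=0)
        table = build_trait_table(raw)
        assert table.loc["spA", "tpref"] == pytest.approx(31.5, abs=1e-12)
        assert table.loc["spA", "iwl"] == pytest.approx(0.015, abs=1e-12)

    def test_noisy_recovery_within_monte_carlo_error(self):
        raw = sim_physio_raw({"spA": 50}, true_tpref=33.0, temp_noise_sd=0.8,
                             weight_noise_sd=0.002, seed=1)
        temps = raw[(raw["stream"] == "temp") & (raw["t"] > 15)]
        per_ind = temps.groupby("individual")["value"].mean()
        se = per_ind.std(ddof=1) / np.sqrt(len(per_ind))
        assert abs(per_ind.mean() - 33.0) < 3 * se


class TestPaleoCurve:
    def test_zero_wiggle_linear_ramp(self):
        c = sim_paleo_curve(span=65.0, start_temp=26.0, end_temp=14.0, wiggle=0.0)
        assert c(32.5) == pytest.approx(20.0)
        assert c(0.0) == pytest.approx(14.0)

    def test_clamped_beyond_oldest_knot(self):
        c = sim_paleo_curve(span=65.0, start_temp=26.0, end_temp=14.0, wiggle=0.0)
        assert c(100.0) == pytest.approx(26.0)

    def test_wiggles_bounded_and_deterministic(self):
        c1 = sim_paleo_curve(wiggle=2.0, seed=3)
        c2 = sim_paleo_curve(wiggle=2.0, seed=3)
        np.testing.assert_array_equal(c1.temps, c2.temps)
        ramp = sim_paleo_curve(wiggle=0.0)
        assert np.max(np.abs(c1.temps - ramp.temps)) <= 2.0

    def test_roundtrip_tsv(self, tmp_path):
        c = sim_paleo_curve(seed=0)
        c.to_tsv(tmp_path / "p.tsv")
        c2 = PaleoCurve.from_tsv(tmp_path / "p.tsv")
        np.testing.assert_allclose(c2.temps, c.temps)

    def test_invalid_knots_raise(self):
        with pytest.raises(ValueError):
            PaleoCurve(ages=np.array([0.0]), temps=np.array([1.0]))
        with pytest.raises(ValueError):
            PaleoCurve(ages=np.array([5.0, 1.0]), temps=np.array([1.0, 2.0]))


def test_sim_config_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        SimConfig(lambda0=0.1, mu0=0.2)
    (tmp_path / "c.yaml").write_text("seed: 7\nn_species: 9\ngrid_shape: [4, 5]\n")
    conf = SimConfig.from_yaml(tmp_path / "c.yaml")
    assert conf.seed == 7 and conf.n_species == 9 and conf.grid_shape == (4, 5)


def test_layer_values_bounded_by_year(rng):
    from climevol.bioclim import yearly_hours_layer

    g = sim_microclim_grid((4, 4), seed=3)
    layer = yearly_hours_layer(g, -100.0)  # always met
    assert np.all(layer == HOURS_PER_YEAR)
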