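import numpy as np
import pytest

from xhwtest import (
    BootstrapConfig,
    Scenario,
    Stratification,
    run_experiment,
    run_experiment_grid,
    sample_size_search,
    simulate_counts,
    simulate_stratified,
)
from xhwtest.simulate import (
    _simulate_counts_arrays,
    _simulate_stratified_arrays,
    load_experiment_config,
)


class TestScenario:
    @pytest.mark.parametrize(
        "N, ratio, Nm, Nf",
        [(800, (2, 1), 533, 267), (800, (1, 1), 400, 400),
         (1200, (1, 2), 400, 800), (2500, (0, 1), 0, 2500)],
    )
    def test_ratio_split(self, N, ratio, Nm, Nf):
        sc = Scenario(N=N, ratio=ratio, p_m=0.3)
        assert (sc.Nm, sc.Nf) == (Nm, Nf)

    def test_pf_from_epsilon(self):
        assert Scenario(p_m=0.3, epsilon=0.05).p_f == pytest.approx(0.35)
        with pytest.raises(ValueError):
            Scenario(p_m=0.99, epsilon=0.05)


class TestGenerators:
    def test_degenerate_frequency_one(self, rng):
        sc = Scenario(p_m=1.0, epsilon=0.0, rho=0.0, N=100, ratio=(1, 1))
        c = simulate_counts(sc, rng)
        assert c.as_tuple() == (50, 0, 50, 0, 0)

    def test_female_genotype_means(self, rng):
        sc = Scenario(p_m=0.3, epsilon=0.0, rho=0.1, N=200, ratio=(1, 1))
        _, _, n2f, n1f, n0f = _simulate_counts_arrays(sc, rng, 10000)
        Nf = sc.Nf
        for cell, p in zip((n2f, n1f, n0f), (0.111, 0.378, 0.511)):
            se = np.sqrt(p * (1 - p) / Nf / 10000)
            assert abs(cell.mean() / Nf - p) < 4 * se

    def test_female_genotype_multinomial_moments(self, rng):
        sc = Scenario(p_m=0.3, epsilon=0.0, rho=0.1, N=400, ratio=(1, 1))
        _, _, n2f, n1f, n0f = _simulate_counts_arrays(sc, rng, 20000)
        Nf = sc.Nf
        p = np.array([0.111, 0.378, 0.511])
        # variances Nf p(1-p), covariance -Nf p_i p_j
        assert np.var(n2f) == pytest.approx(Nf * p[0] * (1 - p[0]), rel=0.1)
        assert np.var(n1f) == pytest.approx(Nf * p[1] * (1 - p[1]), rel=0.1)
        cov = np.mean((n2f - n2f.mean()) * (n1f - n1f.mean()))
        assert cov == pytest.approx(-Nf * p[0] * p[1], rel=0.15)

    def test_stratified_reduces_to_simple_mixture(self, rng):
        strat = Stratification(p_m=(0.3, 0.3), epsilon=(0.0, 0.0))
        sc = Scenario(rho=0.0, N=400, stratification=strat)
        n1m, n0m, n2f, n1f, n0f = _simulate_stratified_arrays(sc, rng, 8000)
        Nm = n1m + n0m
        assert (n1m / Nm).mean() == pytest.approx(0.3, abs=0.01)
        Nf = n2f + n1f + n0f
        assert (n2f / Nf).mean() == pytest.approx(0.09, abs=0.01)

    def test_stratified_marginal_male_frequency(self, rng):
        strat = Stratification(p_m=(0.3, 0.5), epsilon=(0.0, 0.0))
        sc = Scenario(N=1800, stratification=strat)
        n1m, n0m, *_ = _simulate_stratified_arrays(sc, rng, 4000)
        assert (n1m.sum() / (n1m + n0m).sum()) == pytest.approx(0.4, abs=0.01)

    def test_stratified_fixed_split(self, rng):
        strat = Stratification(fixed_sex_split=True)
        sc = Scenario(N=1800, stratification=strat)
        c = simulate_stratified(sc, rng)
        assert c.Nm == 900 and c.Nf == 900

    def test_simulate_stratified_requires_block(self, rng):
        with pytest.raises(ValueError):
            simulate_stratified(Scenario(), rng)


class TestRunExperiment:
    def test_alpha_one_rejects_everything(self):
        sc = Scenario(p_m=0.3, N=200, ratio=(1, 1), n_reps=50, alpha=1.0)
        res = run_experiment(sc, ["Z1", "LRT0", "LRT2b"],
                             bootstrap=BootstrapConfig(B=20), seed=1)
        for t in res.tests.values():
            assert t.rate == 1.0

    def test_deterministic_under_seed(self):
        sc = Scenario(p_m=0.3, N=400, ratio=(1, 1), n_reps=200)
        a = run_experiment(sc, ["Z1", "LRT2b"], bootstrap=BootstrapConfig(B=50), seed=9)
        b = run_experiment(sc, ["Z1", "LRT2b"], bootstrap=BootstrapConfig(B=50), seed=9)
        for k in a.tests:
            assert a.tests[k].rate == b.tests[k].rate
        assert a.estimators["rho1"].mean == b.estimators["rho1"].mean

    def test_monomorphic_replicates_excluded_not_dropped(self):
        # tiny sample at extreme frequency: monomorphic draws happen often
        sc = Scenario(p_m=0.05, N=20, ratio=(1, 1), n_reps=300)
        res = run_experiment(sc, ["Z2"], seed=2)
        t = res.tests["Z2"]
        assert t.n_excluded > 0
        assert t.n_used + t.n_excluded == 300

    def test_rmse_decomposition(self):
        sc = Scenario(p_m=0.3, epsilon=0.0, rho=0.05, N=400, ratio=(1, 1),
                      n_reps=500)
        res = run_experiment(sc, ["LRT2"], seed=3)
        e = res.estimators["rho1"]
        assert e.rmse**2 == pytest.approx(e.bias**2 + e.sd**2, rel=1e-9)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            run_experiment(Scenario(n_reps=10), ["LRT9"])
        with pytest.raises(ValueError):
            run_experiment(Scenario(n_reps=10), [])

    def test_to_frame_layout(self):
        sc = Scenario(p_m=0.3, N=100, ratio=(1, 1), n_reps=20)
        frame = run_experiment(sc, ["Z1", "Z2"], seed=4).to_frame()
        assert list(frame["test"]) == ["Z1", "Z2"]
        assert {"rejection_rate", "mc_se", "n_used", "n_excluded"} <= set(frame.columns)


class TestSampleSizeSearch:
    def test_target_zero_returns_grid_minimum(self):
        sc = Scenario(p_m=0.35, epsilon=0.0, rho=0.05, N=100, ratio=(0, 1))
        nf = sample_size_search(0.0, sc, "Z2", nf_min=100, n_reps=50, seed=5)
        assert nf == 100

    def test_finds_moderate_power_point(self):
        sc = Scenario(p_m=0.35, epsilon=0.0, rho=0.10, N=100, ratio=(0, 1))
        nf = sample_size_search(0.5, sc, "Z2", grid_step=50, nf_min=50,
                                n_reps=400, seed=6)
        # power 50% for Z2 at rho=0.1 needs a few hundred females
        assert 100 <= nf <= 800

    def test_unreachable_target_signals(self):
        sc = Scenario(p_m=0.3, epsilon=0.0, rho=0.0, N=100, ratio=(0, 1))
        with pytest.raises(ValueError):
            sample_size_search(0.99, sc, "Z2", nf_min=100, nf_max=400,
                               n_reps=100, seed=7)


class TestConfigGrid:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "grid.yaml"
        cfg.write_text(
            "tests: [Z1, Z2]\n"
            "seed: 3\n"
            "defaults: {n_reps: 30, alpha: 0.05}\n"
            "scenarios:\n"
            "  - {p_m: 0.3, N: 100, ratio: [1, 1]}\n"
            "  - {p_m: 0.3, N: 1800, stratification: {p_m: [0.3, 0.5], epsilon: [-0.05, -0.05]}}\n"
        )
        scenarios, tests, boot, seed = load_experiment_config(cfg)
        assert len(scenarios) == 2
        assert scenarios[1].stratification.epsilon == (-0.05, -0.05)
        assert tests == ("Z1", "Z2")
        assert boot is None and seed == 3
        frame = run_experiment_grid(scenarios, tests, seed=seed)
        assert len(frame) == 4
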