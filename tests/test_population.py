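import dataclasses

import numpy as np
import pytest

from emtres.population import (
    Cell,
    PopulationConfig,
    birth,
    estimate_extinction,
    init_population,
    proliferation_probability,
    run,
    step,
    survival_probability,
    sweep_plane,
)


class TestSurvivalSigmoid:
    def test_midpoint_value(self):
        assert survival_probability(0.0, c=0.6) == pytest.approx(0.625)

    def test_limits(self):
        assert survival_probability(30.0) == pytest.approx(1.0)
        assert survival_probability(-30.0) == pytest.approx(0.0, abs=1e-10)

    def test_monotone_increasing(self):
        x = np.linspace(-6, 6, 100)
        assert np.all(np.diff(survival_probability(x)) > 0)

    def test_invalid_c(self):
        with pytest.raises(ValueError):
            survival_probability(0.0, c=0.0)


class TestProliferation:
    CFG = PopulationConfig()

    def test_at_capacity_is_zero(self):
        assert proliferation_probability(100_000, self.CFG) == 0.0

    def test_empty_population_gets_full_rate(self):
        assert proliferation_probability(0, self.CFG) == pytest.approx(0.91)

    def test_half_capacity(self):
        assert proliferation_probability(50_000, self.CFG) == pytest.approx(0.455)

    def test_never_negative_above_capacity(self):
        assert proliferation_probability(200_000, self.CFG) == 0.0


class TestBirth:
    def test_zero_heterogeneity_gives_exact_means(self):
        cfg = PopulationConfig(heterogeneity_sd=0.0)
        d = birth(Cell(-2.0, 2.0, "S"), cfg, np.random.default_rng(0))
        assert d.sensitive_score == pytest.approx(-2.0)
        assert d.resistant_score == pytest.approx(2.0)

    def test_daughter_inherits_state(self):
        cfg = PopulationConfig(heterogeneity_sd=0.5)
        rng = np.random.default_rng(1)
        assert birth(Cell(-2.0, 2.0, "R"), cfg, rng).state == "R"
        assert birth(Cell(-2.0, 2.0, "S"), cfg, rng).state == "S"

    def test_daughter_score_moments(self):
        cfg = PopulationConfig(heterogeneity_sd=0.5)
        rng = np.random.default_rng(2)
        scores = [birth(Cell(-2, 2, "S"), cfg, rng).sensitive_score for _ in range(10_000)]
        assert np.mean(scores) == pytest.approx(-2.0, abs=0.02)
        assert np.std(scores) == pytest.approx(0.5, abs=0.02)

    def test_scores_clamped(self):
        cfg = PopulationConfig(heterogeneity_sd=5.0)
        rng = np.random.default_rng(3)
        for _ in range(200):
            d = birth(Cell(0.0, 0.0, "S"), cfg, rng)
            assert -6 <= d.sensitive_score <= 6
            assert -6 <= d.resistant_score <= 6


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("p_sr", 1.5),
            ("basal_death", -0.1),
            ("carrying_capacity", 0),
            ("heterogeneity_sd", -1.0),
            ("sigmoid_c", 0.0),
        ],
    )
    def test_bad_values_rejected(self, field, value):
        with pytest.raises(ValueError, match=field):
            PopulationConfig(**{field: value})


class TestStep:
    def test_no_drug_no_death_only_births(self):
        cfg = PopulationConfig(
            basal_death=0.0, drug_on=False, heterogeneity_sd=0.0, initial_size=50
        )
        rng = np.random.default_rng(0)
        state = init_population(cfg, rng)
        new = step(state, cfg, rng)
        assert new.size >= 50  # nobody dies; some divide
        assert new.n_resistant == 0  # no switching configured

    def test_all_sensitive_no_plasticity_declines_to_zero(self):
        """Without switching or heterogeneity the drug clears the
        population monotonically."""
        cfg = PopulationConfig(heterogeneity_sd=0.0)
        traj = run(cfg, horizon=60, rng=np.random.default_rng(1))
        assert traj.extinct
        nonzero = traj.total[traj.total > 0]
        assert np.all(np.diff(nonzero.astype(float)) <= 5)  # near-monotone decline

    def test_full_sr_switching_rescues_population(self):
        """P_SR = 1 converts every survivor to the resistant state; the
        population establishes a growing colony."""
        cfg = PopulationConfig(p_sr=1.0, heterogeneity_sd=0.0)
        traj = run(cfg, horizon=60, rng=np.random.default_rng(2))
        assert not traj.extinct
        assert traj.final_size > 10 * cfg.initial_size


class TestRun:
    def test_logistic_growth_without_drug(self):
        """No drug, no switching: saturation near the carrying capacity."""
        cfg = PopulationConfig(
            drug_on=False, heterogeneity_sd=0.0, carrying_capacity=2000, initial_size=50
        )
        traj = run(cfg, horizon=80, rng=np.random.default_rng(3))
        # deterministic balance: growth stalls at K (1 - (1/(1-d) - 1)/r)
        eq = 2000 * (1 - (1 / 0.9 - 1) / 0.91)
        assert traj.final_size == pytest.approx(eq, rel=0.15)

    def test_extinction_zero_pads(self):
        cfg = PopulationConfig(heterogeneity_sd=0.0, initial_size=20)
        traj = run(cfg, horizon=80, rng=np.random.default_rng(4))
        assert traj.extinct
        first_zero = np.argmax(traj.total == 0)
        assert np.all(traj.total[first_zero:] == 0)

    def test_same_seed_identical(self):
        cfg = PopulationConfig(p_sr=0.3, p_rs=0.3, heterogeneity_sd=0.5)
        a = run(cfg, horizon=40, rng=np.random.default_rng(5))
        b = run(cfg, horizon=40, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.total, b.total)

    def test_population_capped_at_capacity(self):
        cfg = PopulationConfig(
            drug_on=False, basal_death=0.0, heterogeneity_sd=0.0,
            carrying_capacity=500, initial_size=500,
        )
        traj = run(cfg, horizon=20, rng=np.random.default_rng(6))
        assert np.max(traj.total) <= 500

    def test_counts_are_consistent(self):
        cfg = PopulationConfig(p_sr=0.4, p_rs=0.2, heterogeneity_sd=0.6)
        traj = run(cfg, horizon=40, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(traj.total, traj.n_sensitive + traj.n_resistant)


class TestMeanField:
    def test_logistic_recursion_agreement(self):
        """Drug off, SD = 0: replicate mean tracks the deterministic
        logistic recursion N' = N(1-d)(1 + r(1 - N(1-d)/K))."""
        cfg = PopulationConfig(
            drug_on=False, heterogeneity_sd=0.0, carrying_capacity=2000, initial_size=50
        )
        horizon, n_rep = 50, 50
        rng = np.random.default_rng(8)
        runs = np.array([run(cfg, horizon, rng).total for _ in range(n_rep)], dtype=float)
        mean = runs.mean(axis=0)
        sd = runs.std(axis=0, ddof=1) / np.sqrt(n_rep)
        n = 50.0
        for t in range(1, horizon + 1):
            survivors = n * 0.9
            n = survivors * (1 + 0.91 * (1 - survivors / 2000))
            assert abs(mean[t] - n) <= max(3 * sd[t], 0.02 * n + 1)


class TestExtinction:
    def test_certain_extinction_without_plasticity(self):
        cfg = PopulationConfig(heterogeneity_sd=0.0)
        est = estimate_extinction(cfg, horizon=100, n_replicates=20, rng=np.random.default_rng(9))
        assert est.probability == 1.0
        assert est.standard_error == 0.0
        assert len(est.surviving_sizes) == 0

    def test_binomial_se_consistent(self):
        cfg = PopulationConfig(p_sr=1.0, heterogeneity_sd=0.0)
        est = estimate_extinction(cfg, horizon=30, n_replicates=20, rng=np.random.default_rng(10))
        p = est.probability
        assert est.standard_error == pytest.approx(np.sqrt(p * (1 - p) / 20))

    def test_replicate_floor(self):
        with pytest.raises(ValueError):
            estimate_extinction(PopulationConfig(), n_replicates=5)

    def test_extinction_monotone_in_switching(self):
        """More S->R switching never hurts; more R->S never helps."""
        rng = np.random.default_rng(11)
        base = PopulationConfig(heterogeneity_sd=0.3)
        probs_psr = [
            estimate_extinction(
                dataclasses.replace(base, p_sr=p, p_rs=0.5),
                horizon=60, n_replicates=30, rng=np.random.default_rng(11),
            ).probability
            for p in (0.0, 0.5, 1.0)
        ]
        assert probs_psr[0] >= probs_psr[1] - 0.15 >= probs_psr[2] - 0.3

    def test_met_induction_never_grows_population(self):
        """Fixed (P_SR, P_RS): forcing resistant cells back to sensitivity
        cannot increase the final population size."""
        for psr, prs in ((0.5, 0.0), (1.0, 0.2)):
            base = PopulationConfig(p_sr=psr, p_rs=prs, heterogeneity_sd=0.0)
            with_met = dataclasses.replace(base, met_induced_prs=1.0)
            a = run(base, horizon=60, rng=np.random.default_rng(12)).final_size
            b = run(with_met, horizon=60, rng=np.random.default_rng(12)).final_size
            assert b <= a


class TestSweep:
    def test_single_cell_grid_matches_run_scale(self):
        cfg = PopulationConfig(heterogeneity_sd=0.0)
        out = sweep_plane(
            cfg, [1.0], [0.0], horizon=50, n_replicates=3, rng=np.random.default_rng(13)
        )
        assert out.shape == (1, 1)
        assert out[0, 0] > 10 * cfg.initial_size  # survival corner

    def test_survival_and_extinction_corners(self):
        cfg = PopulationConfig(heterogeneity_sd=0.0)
        out = sweep_plane(
            cfg, [0.0, 1.0], [0.0, 1.0], horizon=60, n_replicates=3,
            rng=np.random.default_rng(14),
        )
        assert out[0, 0] == 0.0  # P_SR = 0: drug clears the population
        assert out[0, 1] == 0.0
        assert out[1, 0] > 1000  # P_SR >> P_RS: near-capacity colony

    def test_grid_bounds_validated(self):
        with pytest.raises(ValueError):
            sweep_plane(PopulationConfig(), [1.5], [0.0])
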