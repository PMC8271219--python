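import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

import emtres as em
from emtres.fixtures import MixtureSpec, synth_score_ensemble
from emtres.scoring import (
    PHENOTYPES,
    ScoreThresholds,
    classify,
    compute_scores,
    correlate_em_resistance,
    fit_thresholds,
    label_frequencies,
    perturbation_report,
    randomization_control,
    znormalize,
)


def analytic_cutpoints(spec: MixtureSpec) -> list[float]:
    """Closed-form oracle: equal weighted-density points between adjacent
    components of a known mixture."""
    cuts = []
    for i in range(len(spec.means) - 1):
        w1, m1, s1 = spec.weights[i], spec.means[i], spec.sds[i]
        w2, m2, s2 = spec.weights[i + 1], spec.means[i + 1], spec.sds[i + 1]
        f = lambda x: w1 * sps.norm.pdf(x, m1, s1) - w2 * sps.norm.pdf(x, m2, s2)
        cuts.append(optimize.brentq(f, m1, m2))
    return cuts


class TestZNormalize:
    def _frame(self, levels, nodes=("A", "B")):
        df = pd.DataFrame(levels, columns=nodes)
        df.insert(0, "set_id", range(len(df)))
        return df

    def test_pooled_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        frame = self._frame(rng.lognormal(2, 1, size=(500, 2)))
        z, stats = znormalize(frame, ("A", "B"))
        assert z["A"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["A"].std(ddof=0) == pytest.approx(1.0, rel=1e-12)
        assert np.all(stats.std > 0)

    def test_symmetric_pair_centers_exactly(self):
        frame = self._frame([[2.0, 8.0], [8.0, 2.0]])
        z, _ = znormalize(frame, ("A", "B"))
        assert sorted(z["A"]) == pytest.approx([-1.0, 1.0])

    def test_stored_stats_reproduce_bit_exact(self):
        rng = np.random.default_rng(1)
        frame = self._frame(rng.lognormal(1, 0.5, size=(50, 2)))
        z, stats = znormalize(frame, ("A", "B"))
        held_out = rng.lognormal(1, 0.5, size=(1, 2))
        once = stats.apply(held_out)
        twice = stats.apply(held_out)
        np.testing.assert_array_equal(once, twice)

    def test_zero_concentration_floored_with_warning(self):
        frame = self._frame([[0.0, 1.0], [2.0, 3.0], [5.0, 4.0]])
        with pytest.warns(UserWarning, match="floored"):
            z, _ = znormalize(frame, ("A", "B"))
        assert np.isfinite(z[["A", "B"]].to_numpy()).all()

    def test_too_few_states_rejected(self):
        with pytest.raises(ValueError):
            znormalize(self._frame([[1.0, 2.0]]), ("A", "B"))


class TestScores:
    def _zframe(self, zeb1, mir200, er36, er66):
        return pd.DataFrame(
            {"ZEB1": [zeb1], "miR200": [mir200], "ERa36": [er36], "ERa66": [er66]}
        )

    def test_equal_z_gives_zero_em(self):
        out = compute_scores(self._zframe(0.7, 0.7, 0.0, 0.0))
        assert out["em_score"].iloc[0] == pytest.approx(0.0)

    def test_resistance_arithmetic(self):
        out = compute_scores(self._zframe(0, 0, 1.0, -1.0))
        assert out["resistance_score"].iloc[0] == pytest.approx(2.0)

    def test_missing_node_raises(self):
        with pytest.raises(KeyError):
            compute_scores(pd.DataFrame({"ZEB1": [1.0]}))


class TestThresholds:
    @pytest.mark.parametrize("n", [1000, 10_000])
    def test_trimodal_recovery_converges(self, n):
        """Cutpoints from the EM fit approach the analytic equal-posterior
        points of the generating mixture as n grows."""
        spec = MixtureSpec((1 / 3, 1 / 3, 1 / 3), (-2.0, 0.0, 2.0), (0.3, 0.3, 0.3))
        rng = np.random.default_rng(42)
        frame, em_spec, _ = synth_score_ensemble(n, rng, em_spec=spec)
        thr = fit_thresholds(frame, seed=0)
        expected = analytic_cutpoints(spec)
        assert thr.em_cuts[0] == pytest.approx(expected[0], abs=0.15)
        assert thr.em_cuts[1] == pytest.approx(expected[1], abs=0.15)
        assert not thr.degenerate_em

    def test_symmetric_bimodal_resistance_cut_near_zero(self):
        spec = MixtureSpec((0.5, 0.5), (-2.0, 2.0), (0.5, 0.5))
        rng = np.random.default_rng(3)
        frame, _, _ = synth_score_ensemble(5000, rng, resistance_spec=spec)
        thr = fit_thresholds(frame, seed=0)
        assert thr.resistance_cut == pytest.approx(0.0, abs=0.15)

    def test_degenerate_single_cluster_falls_back(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1e-6, size=500)
        frame = pd.DataFrame({"em_score": vals, "resistance_score": vals})
        with pytest.warns(UserWarning, match="degenerate"):
            thr = fit_thresholds(frame, seed=0)
        assert thr.em_cuts[0] < thr.em_cuts[1]

    def test_needs_enough_scores(self):
        frame = pd.DataFrame({"em_score": np.arange(10.0), "resistance_score": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_thresholds(frame)


class TestClassify:
    THR = ScoreThresholds(em_cuts=(-1.0, 1.0), resistance_cut=0.0)

    @pytest.mark.parametrize(
        "em, res, label",
        [
            (-3.0, -2.0, "ES"),
            (3.0, 2.0, "MR"),
            (0.0, 2.0, "HR"),
            (-1.0, 0.0, "ES"),  # exact ties go to the lower class
            (1.0, -0.5, "HS"),
        ],
    )
    def test_labels(self, em, res, label):
        assert classify(np.array([[em, res]]), self.THR)[0] == label

    def test_partition_property(self, medium_scored):
        """Every scored state gets exactly one of six labels; frequencies
        sum to one."""
        scores, _, _ = medium_scored
        freqs = label_frequencies(scores["label"].to_numpy())
        assert set(freqs.index) == set(PHENOTYPES)
        assert freqs.sum() == pytest.approx(1.0)
        assert scores["label"].isin(PHENOTYPES).all()


class TestCorrelation:
    def test_perfect_monotone(self):
        frame = pd.DataFrame(
            {"em_score": np.arange(20.0), "resistance_score": np.arange(20.0) ** 3}
        )
        rho, _ = correlate_em_resistance(frame)
        assert rho == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {"em_score": rng.normal(size=10_000), "resistance_score": rng.normal(size=10_000)}
        )
        rho, _ = correlate_em_resistance(frame)
        assert abs(rho) < 0.05

    def test_constant_vector_rejected(self):
        frame = pd.DataFrame({"em_score": [1.0, 1.0, 1.0], "resistance_score": [1, 2, 3.0]})
        with pytest.raises(ValueError):
            correlate_em_resistance(frame)


class TestEnsembleBiology:
    """Ensemble-level structure of the EMT / ER crosstalk network."""

    def test_em_resistance_strongly_correlated(self, medium_scored):
        scores, _, _ = medium_scored
        rho, pval = correlate_em_resistance(scores)
        assert rho > 0.6
        assert pval < 1e-10

    def test_dominant_and_rare_phenotypes(self, medium_scored):
        scores, _, _ = medium_scored
        freqs = label_frequencies(scores["label"].to_numpy())
        assert set(freqs.sort_values(ascending=False).index[:2]) == {"ES", "MR"}
        assert freqs.idxmin() == "MS"

    def test_zeb1_monotone_across_phenotypes(self, medium_scored):
        scores, _, _ = medium_scored
        means = scores.groupby("label")["ZEB1"].mean()
        order = [p for p in ("ES", "ER", "HS", "HR", "MS", "MR") if p in means.index]
        vals = [means[p] for p in order]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_slug_higher_in_hybrid_resistant(self, medium_scored):
        scores, _, _ = medium_scored
        hr = scores[scores["label"] == "HR"]["SLUG"].mean()
        hs = scores[scores["label"] == "HS"]["SLUG"].mean()
        assert hr > hs


class TestRandomizationControl:
    def test_zero_randomizations_returns_wild_type_only(self, default_topology):
        rng = np.random.default_rng(0)
        out = randomization_control(default_topology, 0, n_sets=60, n_init=20, rng=rng)
        assert len(out["random_rhos"]) == 0
        assert out["wild_type_rho"] > 0.4


class TestPerturbationReport:
    def test_zeb1_oe_shifts_toward_mesenchymal_resistant(self, default_topology):
        rng = np.random.default_rng(8)
        report = perturbation_report(
            default_topology,
            em.Perturbation("ZEB1", "over_expression", fold=10),
            em.SamplingRanges(),
            n_sets=150,
            n_init=50,
            rng=rng,
            n_replicates=3,
        )
        assert report.loc["MR", "delta"] > 0
        assert report.loc["ES", "delta"] < 0

    def test_null_perturbation_leaves_frequencies_alone(self, default_topology):
        rng = np.random.default_rng(9)
        report = perturbation_report(
            default_topology,
            em.Perturbation("ZEB1", "over_expression", fold=1.0),
            em.SamplingRanges(),
            n_sets=100,
            n_init=40,
            rng=rng,
            n_replicates=3,
        )
        # identical parameter sets -> identical classifications
        assert np.allclose(report["delta"].to_numpy(), 0.0, atol=1e-12)
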