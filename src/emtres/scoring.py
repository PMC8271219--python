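"""Phenotype scoring and classification of steady-state ensembles.

Steady states are log2-transformed and z-normalized per node across the
pooled ensemble. Two axes summarize each state:

* EM score        = z(ZEB1) - z(miR200)   (epithelial .. mesenchymal)
* resistance score = z(ERa36) - z(ERa66)  (tamoxifen sensitive .. resistant)

The EM score distribution is trimodal (epithelial / hybrid / mesenchymal)
and the resistance score bimodal (sensitive / resistant); Gaussian-mixture
fits provide the cutpoints, and their Cartesian product defines the six
phenotypes ES, ER, HS, HR, MS, MR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .grn import (
    ParameterEnsemble,
    Perturbation,
    SamplingRanges,
    apply_perturbation,
    sample_parameter_sets,
)
from .steady_states import enumerate_ensemble, solutions_to_frame
from .topology import NetworkTopology

PHENOTYPES = ("ES", "ER", "HS", "HR", "MS", "MR")

#: default node-name mapping for the score definitions
SCORE_NODES = {"zeb1": "ZEB1", "mir200": "miR200", "er36": "ERa36", "er66": "ERa66"}

_LOG2_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class NormalizationStats:
    """Per-node mean/SD of log2 steady-state levels over a pooled ensemble."""

    node_names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.std <= 0):
            raise ValueError("normalization SDs must be positive")

    def apply(self, levels: np.ndarray | pd.DataFrame) -> np.ndarray:
        """z-scores of linear-scale levels using the stored statistics."""
        if isinstance(levels, pd.DataFrame):
            levels = levels[list(self.node_names)].to_numpy()
        levels = np.maximum(np.asarray(levels, dtype=float), _LOG2_FLOOR)
        return (np.log2(levels) - self.mean) / self.std


def znormalize(
    frame: pd.DataFrame, node_names: tuple[str, ...]
) -> tuple[pd.DataFrame, NormalizationStats]:
    """Log2-transform and z-normalize pooled steady states per node.

    Every steady state is weighted equally, regardless of how many states
    its parameter set has. Zero concentrations are floored at the smallest
    positive float; a warning reports how many were floored.
    """
    if len(frame) < 2:
        raise ValueError("need at least 2 steady states to normalize")
    levels = frame[list(node_names)].to_numpy(dtype=float)
    n_floored = int(np.sum(levels < _LOG2_FLOOR))
    if n_floored:
        warnings.warn(f"floored {n_floored} non-positive concentrations before log2")
    logs = np.log2(np.maximum(levels, _LOG2_FLOOR))
    stats_ = NormalizationStats(
        node_names=tuple(node_names),
        mean=logs.mean(axis=0),
        std=logs.std(axis=0, ddof=0),
    )
    out = frame.copy()
    out[list(node_names)] = (logs - stats_.mean) / stats_.std
    return out, stats_


def compute_scores(
    zframe: pd.DataFrame, nodes: dict[str, str] = SCORE_NODES
) -> pd.DataFrame:
    """EM and resistance scores from a z-normalized state table."""
    for key in ("zeb1", "mir200", "er36", "er66"):
        if nodes[key] not in zframe.columns:
            raise KeyError(f"node {nodes[key]!r} missing from state table")
    out = zframe.copy()
    out["em_score"] = zframe[nodes["zeb1"]] - zframe[nodes["mir200"]]
    out["resistance_score"] = zframe[nodes["er36"]] - zframe[nodes["er66"]]
    return out


@dataclass(frozen=True)
class PhenotypeScores:
    """One state's coordinates on the EM and resistance axes (z-units)."""

    em_score: float
    resistance_score: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.em_score) and np.isfinite(self.resistance_score)):
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class ScoreThresholds:
    """Cutpoints separating E|H and H|M on the EM axis and S|R on the
    resistance axis."""

    em_cuts: tuple[float, float]
    resistance_cut: float
    degenerate_em: bool = False
    degenerate_resistance: bool = False

    def __post_init__(self) -> None:
        if not self.em_cuts[0] < self.em_cuts[1]:
            raise ValueError("EM cutpoints must be strictly ordered")

    def to_dict(self) -> dict:
        return {
            "em_cuts": list(self.em_cuts),
            "resistance_cut": self.resistance_cut,
            "degenerate_em": self.degenerate_em,
            "degenerate_resistance": self.degenerate_resistance,
        }


def _equal_posterior_cut(w1, m1, s1, w2, m2, s2) -> float:
    """Point between two component means where the weighted densities match."""

    def diff(x):
        return np.log(w1) + stats.norm.logpdf(x, m1, s1) - np.log(w2) - stats.norm.logpdf(x, m2, s2)

    lo, hi = m1, m2
    if diff(lo) * diff(hi) > 0:  # no sign change: fall back to midpoint
        return 0.5 * (m1 + m2)
    return float(optimize.brentq(diff, lo, hi, xtol=1e-10))


def _fit_axis_cuts(
    values: np.ndarray, n_components: int, seed: int
) -> tuple[list[float], bool]:
    """Mixture-model cutpoints for one score axis.

    Components are ordered by mean; adjacent pairs are separated at their
    equal-posterior boundary. A degenerate fit — a vanishing component
    weight (< 1e-3), adjacent components that are not actually separated
    (mean gap below half their pooled SD), or disordered boundaries — falls
    back to quantile cutpoints with a warning.
    """
    values = np.asarray(values, dtype=float)
    gm = GaussianMixture(
        n_components=n_components, n_init=20, random_state=seed, covariance_type="full"
    ).fit(values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_[order]
    m = gm.means_.ravel()[order]
    s = np.sqrt(gm.covariances_.ravel()[order])
    degenerate = bool(np.any(w < 1e-3)) or any(
        m[i + 1] - m[i] < 0.5 * np.sqrt(s[i] * s[i + 1]) for i in range(n_components - 1)
    )
    cuts: list[float] = []
    if not degenerate:
        for i in range(n_components - 1):
            cuts.append(_equal_posterior_cut(w[i], m[i], s[i], w[i + 1], m[i + 1], s[i + 1]))
        if not all(np.isfinite(cuts)) or any(
            cuts[i] >= cuts[i + 1] for i in range(len(cuts) - 1)
        ):
            degenerate = True
    if degenerate:
        warnings.warn(
            f"degenerate {n_components}-component fit; falling back to quantile cutpoints"
        )
        qs = [(i + 1) / n_components for i in range(n_components - 1)]
        cuts = list(np.quantile(values, qs))
        if len(cuts) > 1 and cuts[0] >= cuts[1]:  # tight cluster: force an ordering
            eps = 1e-9 + 1e-9 * abs(cuts[0])
            cuts[1] = cuts[0] + eps
    return cuts, degenerate


def fit_thresholds(scores: pd.DataFrame, seed: int = 0) -> ScoreThresholds:
    """Fit a 3-component mixture to EM scores and a 2-component mixture to
    resistance scores; cutpoints at equal-posterior boundaries."""
    if len(scores) < 100:
        raise ValueError("need at least 100 scores to fit thresholds")
    em_cuts, degen_em = _fit_axis_cuts(scores["em_score"].to_numpy(), 3, seed)
    res_cuts, degen_res = _fit_axis_cuts(scores["resistance_score"].to_numpy(), 2, seed)
    return ScoreThresholds(
        em_cuts=(em_cuts[0], em_cuts[1]),
        resistance_cut=res_cuts[0],
        degenerate_em=degen_em,
        degenerate_resistance=degen_res,
    )


def classify(
    scores: pd.DataFrame | np.ndarray, thresholds: ScoreThresholds
) -> np.ndarray:
    """Assign each (EM, resistance) score pair one of the six phenotypes.

    Scores exactly at a cutpoint go to the lower (less mesenchymal / more
    sensitive) class.
    """
    if isinstance(scores, pd.DataFrame):
        em = scores["em_score"].to_numpy()
        res = scores["resistance_score"].to_numpy()
    else:
        arr = np.asarray(scores, dtype=float)
        em, res = arr[:, 0], arr[:, 1]
    e_hm = np.where(em > thresholds.em_cuts[1], "M", np.where(em > thresholds.em_cuts[0], "H", "E"))
    s_r = np.where(res > thresholds.resistance_cut, "R", "S")
    return np.char.add(e_hm, s_r)


def label_frequencies(labels: np.ndarray) -> pd.Series:
    """Frequency of each of the six phenotypes (all present, summing to 1)."""
    ser = pd.Series(labels).value_counts(normalize=True)
    return ser.reindex(PHENOTYPES, fill_value=0.0)


def correlate_em_resistance(scores: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation between EM and resistance scores."""
    em = scores["em_score"].to_numpy()
    res = scores["resistance_score"].to_numpy()
    if len(em) < 3:
        raise ValueError("need at least 3 score pairs")
    if np.ptp(em) == 0 or np.ptp(res) == 0:
        raise ValueError("correlation undefined for constant scores")
    rho, p = stats.spearmanr(em, res)
    return float(rho), float(p)


def score_ensemble(
    topology: NetworkTopology,
    ranges: SamplingRanges,
    n_sets: int,
    n_init: int,
    rng: np.random.Generator,
    ensemble: ParameterEnsemble | None = None,
) -> tuple[pd.DataFrame, NormalizationStats, ScoreThresholds]:
    """Sample (or take) an ensemble, enumerate states, normalize, score and
    label them. Returns (scored frame with 'label', stats, thresholds)."""
    if ensemble is None:
        ensemble = sample_parameter_sets(topology, ranges, n_sets, rng)
    sols = enumerate_ensemble(ensemble, n_init=n_init, rng=rng)
    frame = solutions_to_frame(sols, topology.nodes)
    zframe, stats_ = znormalize(frame, topology.nodes)
    scores = compute_scores(zframe)
    thresholds = fit_thresholds(scores, seed=int(rng.integers(2**31)))
    scores["label"] = classify(scores, thresholds)
    return scores, stats_, thresholds


def randomization_control(
    topology: NetworkTopology,
    n_random: int,
    n_sets: int,
    n_init: int,
    rng: np.random.Generator,
    ranges: SamplingRanges | None = None,
) -> dict:
    """EM-resistance correlation of the wild-type network against an
    ensemble of degree- and sign-preserving randomized networks.

    Each randomized network is simulated, normalized and scored on its own;
    returns the wild-type rho, the randomized rho distribution and the
    wild-type percentile within it.
    """
    from .fixtures import RandomizationError, randomize_topology

    ranges = ranges or SamplingRanges()
    wt_scores, _, _ = score_ensemble(topology, ranges, n_sets, n_init, rng)
    wt_rho, _ = correlate_em_resistance(wt_scores)
    rhos: list[float] = []
    n_failed = 0
    for _ in range(n_random):
        try:
            rnd = randomize_topology(topology, rng=rng)
        except RandomizationError:
            n_failed += 1
            continue
        try:
            scores, _, _ = score_ensemble(rnd, ranges, n_sets, n_init, rng)
            rho, _ = correlate_em_resistance(scores)
        except ValueError:
            n_failed += 1
            continue
        rhos.append(rho)
    rhos_arr = np.array(rhos)
    pct = float(np.mean(wt_rho >= rhos_arr)) if len(rhos_arr) else 1.0
    return {
        "wild_type_rho": wt_rho,
        "random_rhos": rhos_arr,
        "wild_type_percentile": pct,
        "n_failed": n_failed,
    }


def perturbation_report(
    topology: NetworkTopology,
    perturbation: Perturbation,
    ranges: SamplingRanges,
    n_sets: int,
    n_init: int,
    rng: np.random.Generator,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Phenotype-frequency shift under a node perturbation.

    Per replicate: a control ensemble fixes the normalization statistics and
    mixture thresholds; the perturbation is applied to the same parameter
    sets and the perturbed states are scored with the CONTROL statistics and
    thresholds, so frequency deltas are comparable. Returns a table of mean
    and SD frequencies per phenotype and condition across replicates.
    """
    recs = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        rep_rng = np.random.default_rng(rep_seed)
        ensemble = sample_parameter_sets(topology, ranges, n_sets, rep_rng)
        sols = enumerate_ensemble(ensemble, n_init=n_init, rng=np.random.default_rng(rep_seed + 1))
        frame = solutions_to_frame(sols, topology.nodes)
        zframe, stats_ = znormalize(frame, topology.nodes)
        scores = compute_scores(zframe)
        thresholds = fit_thresholds(scores, seed=rep)
        ctrl_freq = label_frequencies(classify(scores, thresholds))

        # same IC stream as the control run: fold = 1 is an exact no-op
        pert_ens = apply_perturbation(ensemble, perturbation)
        pert_sols = enumerate_ensemble(
            pert_ens, n_init=n_init, rng=np.random.default_rng(rep_seed + 1)
        )
        pert_frame = solutions_to_frame(pert_sols, topology.nodes)
        pert_z = pert_frame.copy()
        pert_z[list(topology.nodes)] = stats_.apply(pert_frame[list(topology.nodes)])
        pert_scores = compute_scores(pert_z)
        pert_freq = label_frequencies(classify(pert_scores, thresholds))
        for ph in PHENOTYPES:
            recs.append((rep, ph, ctrl_freq[ph], pert_freq[ph]))
    df = pd.DataFrame(recs, columns=["replicate", "phenotype", "control", "perturbed"])
    out = df.groupby("phenotype", sort=False).agg(
        control_mean=("control", "mean"),
        control_sd=("control", "std"),
        perturbed_mean=("perturbed", "mean"),
        perturbed_sd=("perturbed", "std"),
    )
    out["delta"] = out["perturbed_mean"] - out["control_mean"]
    return out.reindex(PHENOTYPES)
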