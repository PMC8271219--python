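"""Stochastic dynamics and pseudo-potential landscapes.

Multistable parameter sets are simulated with the Euler-Maruyama scheme:

    X(t + dt) = X(t) + f(X) dt + eta * sqrt(dt) * N(0, 1)

per node, with f the deterministic shifted-Hill right-hand side and
concentrations clipped at zero. Long noisy trajectories visit the basins of
the co-existing phenotypes; binning their (EM score, resistance score)
occupancy gives a probability density P and the pseudo-potential -log(P),
whose valleys mark the attractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .grn import KineticParameterSet
from .scoring import NormalizationStats, ScoreThresholds, classify
from .steady_states import _params_arrays

DEFAULT_DT = 0.01
DEFAULT_NOISE = 0.05  # fraction of each node's g/k scale
DEFAULT_DWELL_MIN = 50  # steps a new label must persist to commit a transition


class SimulationBlowupError(RuntimeError):
    """Euler-Maruyama state exceeded the divergence guard (|X| > 1e9)."""


@dataclass
class SDETrajectory:
    """Uniformly sampled noisy trajectory of one parameter set."""

    times: np.ndarray
    levels: np.ndarray  # (n_samples, n_nodes), linear scale
    node_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.levels):
            raise ValueError("times and levels must have equal length")

    def scores(
        self, stats: NormalizationStats, nodes: dict[str, str] | None = None
    ) -> pd.DataFrame:
        """EM / resistance score series under fixed normalization stats.

        ``nodes`` maps the score roles (zeb1, mir200, er36, er66) to node
        names; defaults to the canonical EMT/ER names.
        """
        from .scoring import SCORE_NODES

        nodes = nodes or SCORE_NODES
        z = stats.apply(self.levels)
        iz = {name: i for i, name in enumerate(stats.node_names)}
        em = z[:, iz[nodes["zeb1"]]] - z[:, iz[nodes["mir200"]]]
        res = z[:, iz[nodes["er36"]]] - z[:, iz[nodes["er66"]]]
        return pd.DataFrame({"time": self.times, "em_score": em, "resistance_score": res})


def noise_amplitudes(params: KineticParameterSet, noise: float) -> np.ndarray:
    """Per-node additive noise amplitude: ``noise`` times the g/k scale."""
    return noise * params.production / params.degradation


def euler_maruyama(
    params: KineticParameterSet,
    x0: np.ndarray,
    dt: float = DEFAULT_DT,
    t_end: float = 100.0,
    noise: float = DEFAULT_NOISE,
    seed: int = 0,
    record_every: int = 10,
) -> SDETrajectory:
    """Simulate one noisy trajectory; seeded and reproducible.

    ``noise`` is the dimensionless amplitude relative to each node's
    unregulated scale g/k (0 recovers the deterministic integrator up to
    discretization error). Raises on numerical blow-up.
    """
    if dt <= 0 or t_end < dt:
        raise ValueError("require dt > 0 and t_end >= dt")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial condition must be non-negative")
    g, k, src, tgt, lam, nh, x0e = _params_arrays(params)
    eta = noise_amplitudes(params, noise)
    n_steps = int(round(t_end / dt))
    records, n_rec, ok = _kernels.euler_maruyama_kernel(
        x0, g, k, src, tgt, lam, nh, x0e, dt, n_steps, eta, seed, record_every
    )
    if not ok:
        raise SimulationBlowupError(
            f"trajectory diverged (|X| > 1e9) after ~{n_rec * record_every} steps"
        )
    times = np.arange(n_rec) * dt * record_every
    return SDETrajectory(times, records[:n_rec], params.topology.nodes)


@dataclass
class Landscape:
    """Binned occupancy probability and pseudo-potential over the score plane."""

    em_edges: np.ndarray
    resistance_edges: np.ndarray
    probability: np.ndarray  # (n_em_bins, n_res_bins), sums to 1
    potential: np.ndarray  # -log(P); +inf on empty bins

    def to_frame(self) -> pd.DataFrame:
        emc = 0.5 * (self.em_edges[:-1] + self.em_edges[1:])
        rsc = 0.5 * (self.resistance_edges[:-1] + self.resistance_edges[1:])
        em_grid, rs_grid = np.meshgrid(emc, rsc, indexing="ij")
        return pd.DataFrame(
            {
                "em_score": em_grid.ravel(),
                "resistance_score": rs_grid.ravel(),
                "probability": self.probability.ravel(),
                "potential": self.potential.ravel(),
            }
        )

    def n_minima(self, min_occupancy: float = 0.0) -> int:
        """Local minima of the potential over occupied bins (8-neighborhood).

        ``min_occupancy`` ignores bins whose probability is below that
        fraction of the best-occupied bin, which suppresses spurious minima
        in barely-visited fringe bins.
        """
        pot = self.potential
        occ = np.isfinite(pot) & (self.probability >= min_occupancy * self.probability.max())
        count = 0
        ni, nj = pot.shape
        for i in range(ni):
            for j in range(nj):
                if not occ[i, j]:
                    continue
                v = pot[i, j]
                is_min = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        a, b = i + di, j + dj
                        if 0 <= a < ni and 0 <= b < nj and occ[a, b] and pot[a, b] < v:
                            is_min = False
                            break
                    if not is_min:
                        break
                if is_min:
                    count += 1
        return count


def build_landscape(
    trajectories: list[SDETrajectory] | SDETrajectory,
    stats: NormalizationStats,
    bins: int = 60,
    smooth_sigma: float = 0.0,
    nodes: dict[str, str] | None = None,
) -> Landscape:
    """Occupancy histogram of score pairs, normalized, with -log(P).

    Optional Gaussian smoothing of the probability (in bins) before taking
    the log; by default empty bins stay empty (potential = +inf).
    """
    if isinstance(trajectories, SDETrajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("need at least one trajectory")
    frames = [t.scores(stats, nodes) for t in trajectories]
    em = np.concatenate([f["em_score"].to_numpy() for f in frames])
    rs = np.concatenate([f["resistance_score"].to_numpy() for f in frames])
    hist, em_edges, rs_edges = np.histogram2d(em, rs, bins=bins)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        hist = gaussian_filter(hist, smooth_sigma)
    prob = hist / hist.sum()
    with np.errstate(divide="ignore"):
        pot = -np.log(prob)
    return Landscape(em_edges, rs_edges, prob, pot)


def marginal_distribution(
    trajectory: SDETrajectory,
    stats: NormalizationStats,
    axis: str = "em",
    bins: int = 60,
    nodes: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized 1-D density of the EM or resistance score over time.

    Returns (bin centers, density); the density integrates to 1.
    """
    col = {"em": "em_score", "resistance": "resistance_score"}[axis]
    values = trajectory.scores(stats, nodes)[col].to_numpy()
    density, edges = np.histogram(values, bins=bins, density=True)
    return 0.5 * (edges[:-1] + edges[1:]), density


@dataclass(frozen=True)
class TransitionEvent:
    """One committed phenotype switch along a trajectory."""

    source: str
    target: str
    time: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target phenotypes must differ")


def detect_transitions(
    scores: pd.DataFrame,
    thresholds: ScoreThresholds,
    dwell_min: int = DEFAULT_DWELL_MIN,
) -> list[TransitionEvent]:
    """Debounced phenotype transitions from a scored trajectory.

    The score series is labeled via :func:`classify`; a transition commits
    when the new label persists for at least ``dwell_min`` consecutive
    samples, at the time the new label first appeared.
    """
    if dwell_min < 1:
        raise ValueError("dwell_min must be >= 1")
    labels = classify(scores, thresholds)
    times = scores["time"].to_numpy() if "time" in scores else np.arange(len(labels))
    events: list[TransitionEvent] = []
    if len(labels) == 0:
        return events
    current = labels[0]
    i = 1
    while i < len(labels):
        if labels[i] != current:
            j = i
            while j < len(labels) and labels[j] == labels[i] and j - i < dwell_min:
                j += 1
            if j - i >= dwell_min:
                events.append(TransitionEvent(str(current), str(labels[i]), float(times[i])))
                current = labels[i]
                i = j
            else:
                i = j if j > i else i + 1
        else:
            i += 1
    return events
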