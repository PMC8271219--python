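"""Shifted-Hill ODE models on a signed topology and kinetic-parameter sampling.

Each node follows

    dX_i/dt = g_i * prod_j H^s(X_j; X0_ji, n_ji, lambda_ji) - k_i * X_i

where the product runs over regulators j of node i and

    H^s(X) = lambda + (1 - lambda) / (1 + (X/X0)^n)

is the shifted Hill function: 1 with no regulator input (X = 0) and
approaching the fold-change lambda at saturation. Activation has lambda > 1,
inhibition 0 < lambda < 1.

Parameter ensembles are drawn uniformly from biologically plausible ranges
(production 1-100, degradation 0.1-1, integer Hill coefficient 1-6,
activation fold 1-100 with inhibition folds as reciprocals) with thresholds
set by the half-functional rule, so that each regulator has roughly even
odds of sitting above or below its threshold across the ensemble.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .topology import ACTIVATION, NetworkTopology

OVER_EXPRESSION = "over_expression"
DOWN_EXPRESSION = "down_expression"


def shifted_hill(
    x: float | np.ndarray,
    x0: float | np.ndarray,
    n: int | np.ndarray,
    lam: float | np.ndarray,
) -> float | np.ndarray:
    """Shifted Hill regulation multiplier ``lambda + (1-lambda)/(1+(x/x0)^n)``.

    Bounded between ``min(1, lambda)`` and ``max(1, lambda)``; equals 1 at
    ``x = 0`` and tends to ``lambda`` as ``x -> inf``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.asarray(x0) <= 0):
        raise ValueError("threshold x0 must be positive")
    if np.any(np.asarray(n) < 1):
        raise ValueError("Hill coefficient n must be >= 1")
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("fold change lambda must be positive")
    if np.any(x < 0):
        raise ValueError("concentration x must be non-negative")
    u = (x / x0) ** np.asarray(n)
    out = lam + (1.0 - lam) / (1.0 + u)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SamplingRanges:
    """Uniform sampling ranges for the kinetic-parameter ensemble."""

    g_range: tuple[float, float] = (1.0, 100.0)
    k_range: tuple[float, float] = (0.1, 1.0)
    n_range: tuple[int, int] = (1, 6)
    lam_range: tuple[float, float] = (1.0, 100.0)
    threshold_rule: str = "half_functional"

    def __post_init__(self) -> None:
        for name in ("g_range", "k_range", "lam_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lower < upper, got ({lo}, {hi})")
        lo, hi = self.n_range
        if not (1 <= lo <= hi) or (lo != int(lo) or hi != int(hi)):
            raise ValueError(f"n_range must be positive integer bounds, got ({lo}, {hi})")
        if self.threshold_rule not in ("half_functional", "half_functional_unregulated"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")

    def median_unregulated_level(self, n_samples: int = 200_000) -> float:
        """Median of g/k over the ranges (Monte Carlo, fixed internal seed).

        The baseline level scale of a node with no regulators; also the
        anchor of the simple (regulation-blind) threshold rule.
        """
        rng = np.random.default_rng(1234567)  # fixed: M is a property of the ranges
        g = rng.uniform(*self.g_range, size=n_samples)
        k = rng.uniform(*self.k_range, size=n_samples)
        return float(np.median(g / k))

    def median_levels(self, topology: NetworkTopology, n_samples: int = 100_000) -> np.ndarray:
        """Per-node median levels M_j used by the half-functional rule.

        Edge thresholds are drawn from U[0.02*M_j, 1.98*M_j] so that each
        regulator has roughly even odds of sitting above its threshold. A
        node's realized level is shaped by its own regulation — a strongly
        inhibited node lives far below g/k — so M_j is estimated by one
        Monte-Carlo pass: draw g/k, then multiply in a shifted-Hill factor
        for each incoming edge with the regulator at a random unregulated
        level and a threshold from the unregulated rule. The simple
        'half_functional_unregulated' variant skips the correction and uses
        the bare g/k median for every node.
        """
        m0 = self.median_unregulated_level(n_samples)
        if self.threshold_rule == "half_functional_unregulated":
            return np.full(topology.n_nodes, m0)
        rng = np.random.default_rng(7654321)  # fixed: M is a property of the rule
        out = np.empty(topology.n_nodes)
        for j, node in enumerate(topology.nodes):
            level = rng.uniform(*self.g_range, n_samples) / rng.uniform(
                *self.k_range, n_samples
            )
            for edge in topology.incoming(node):
                lam = rng.uniform(*self.lam_range, n_samples)
                if edge.sign != ACTIVATION:
                    lam = 1.0 / lam
                n = rng.integers(self.n_range[0], self.n_range[1] + 1, n_samples)
                x0 = rng.uniform(0.02 * m0, 1.98 * m0, n_samples)
                x_reg = rng.uniform(*self.g_range, n_samples) / rng.uniform(
                    *self.k_range, n_samples
                )
                level *= lam + (1.0 - lam) / (1.0 + (x_reg / x0) ** n)
            out[j] = np.median(level)
        return out


@dataclass(frozen=True)
class KineticParameterSet:
    """One sampled realization of all rates for a given topology.

    Arrays are aligned with ``topology.nodes`` (g, k) and ``topology.edges``
    (fold_change, hill_coefficient, threshold).
    """

    topology: NetworkTopology
    production: np.ndarray  # g, per node
    degradation: np.ndarray  # k, per node
    fold_change: np.ndarray  # lambda, per edge
    hill_coefficient: np.ndarray  # n, per edge (integer valued)
    threshold: np.ndarray  # X0, per edge

    def __post_init__(self) -> None:
        nn, ne = self.topology.n_nodes, self.topology.n_edges
        if self.production.shape != (nn,) or self.degradation.shape != (nn,):
            raise ValueError("g/k must have one entry per node")
        for arr in (self.fold_change, self.hill_coefficient, self.threshold):
            if arr.shape != (ne,):
                raise ValueError("per-edge parameter arrays must have one entry per edge")
        if np.any(self.production <= 0) or np.any(self.degradation <= 0):
            raise ValueError("g and k must be positive")
        if np.any(self.threshold <= 0):
            raise ValueError("thresholds must be positive")
        if np.any(self.hill_coefficient < 1):
            raise ValueError("Hill coefficients must be >= 1")
        _, _, sign = self.topology.edge_arrays()
        lam = self.fold_change
        if np.any(lam[sign == 1] < 1.0) or np.any((lam[sign == 2] >= 1.0) | (lam[sign == 2] <= 0)):
            raise ValueError("lambda must be > 1 on activation edges and in (0, 1) on inhibition edges")

    # -- derived quantities ---------------------------------------------------

    def level_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node (min, max) achievable steady levels.

        The shifted Hill multiplier of each incoming edge lies in
        [min(1, lambda), max(1, lambda)], so node levels are bracketed by
        (g/k) times the product of those extremes.
        """
        src, tgt, _ = self.topology.edge_arrays()
        lo = np.ones(self.topology.n_nodes)
        hi = np.ones(self.topology.n_nodes)
        for e in range(len(src)):
            lo[tgt[e]] *= min(1.0, self.fold_change[e])
            hi[tgt[e]] *= max(1.0, self.fold_change[e])
        base = self.production / self.degradation
        return base * lo, base * hi


@dataclass(frozen=True)
class Perturbation:
    """In-silico over- or down-expression of one node's production rate."""

    node: str
    mode: Literal["over_expression", "down_expression"]
    fold: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in (OVER_EXPRESSION, DOWN_EXPRESSION):
            raise ValueError(f"mode must be {OVER_EXPRESSION!r} or {DOWN_EXPRESSION!r}")
        if self.fold < 1:  # fold = 1 is the null perturbation (control)
            raise ValueError("fold must be >= 1")


class ParameterEnsemble:
    """Columnar collection of sampled parameter sets for one topology."""

    def __init__(
        self,
        topology: NetworkTopology,
        production: np.ndarray,
        degradation: np.ndarray,
        fold_change: np.ndarray,
        hill_coefficient: np.ndarray,
        threshold: np.ndarray,
    ) -> None:
        self.topology = topology
        self.production = np.atleast_2d(production)
        self.degradation = np.atleast_2d(degradation)
        self.fold_change = np.atleast_2d(fold_change)
        self.hill_coefficient = np.atleast_2d(hill_coefficient)
        self.threshold = np.atleast_2d(threshold)
        n = len(self.production)
        if not all(
            len(a) == n
            for a in (self.degradation, self.fold_change, self.hill_coefficient, self.threshold)
        ):
            raise ValueError("all parameter arrays must have the same number of sets")

    def __len__(self) -> int:
        return len(self.production)

    def __getitem__(self, i: int) -> KineticParameterSet:
        return KineticParameterSet(
            self.topology,
            self.production[i].copy(),
            self.degradation[i].copy(),
            self.fold_change[i].copy(),
            self.hill_coefficient[i].copy(),
            self.threshold[i].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per set; columns g_<node>, k_<node>, lam/n/x0_<edge>."""
        cols: dict[str, np.ndarray] = {"set_id": np.arange(len(self))}
        for j, name in enumerate(self.topology.nodes):
            cols[f"g_{name}"] = self.production[:, j]
            cols[f"k_{name}"] = self.degradation[:, j]
        for e, edge in enumerate(self.topology.edges):
            tag = f"{edge.source}_{edge.target}"
            cols[f"lam_{tag}"] = self.fold_change[:, e]
            cols[f"n_{tag}"] = self.hill_coefficient[:, e]
            cols[f"x0_{tag}"] = self.threshold[:, e]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, topology: NetworkTopology, frame: pd.DataFrame) -> "ParameterEnsemble":
        g = np.column_stack([frame[f"g_{n}"].to_numpy() for n in topology.nodes])
        k = np.column_stack([frame[f"k_{n}"].to_numpy() for n in topology.nodes])
        tags = [f"{e.source}_{e.target}" for e in topology.edges]
        lam = np.column_stack([frame[f"lam_{t}"].to_numpy() for t in tags])
        n = np.column_stack([frame[f"n_{t}"].to_numpy() for t in tags])
        x0 = np.column_stack([frame[f"x0_{t}"].to_numpy() for t in tags])
        return cls(topology, g, k, lam, n, x0)


def sample_parameter_sets(
    topology: NetworkTopology,
    ranges: SamplingRanges,
    n_sets: int,
    rng: np.random.Generator,
) -> ParameterEnsemble:
    """Draw ``n_sets`` independent kinetic parameter sets.

    Inhibition fold changes are the reciprocal of an activation-range draw,
    so they cover (1/hi, 1/lo) with the matching heavy tail toward strong
    repression. Thresholds follow the half-functional rule.
    """
    nn, ne = topology.n_nodes, topology.n_edges
    g = rng.uniform(*ranges.g_range, size=(n_sets, nn))
    k = rng.uniform(*ranges.k_range, size=(n_sets, nn))
    n = rng.integers(ranges.n_range[0], ranges.n_range[1] + 1, size=(n_sets, ne)).astype(float)
    lam = rng.uniform(*ranges.lam_range, size=(n_sets, ne))
    src, _, sign = topology.edge_arrays()
    inh = sign == 2
    lam[:, inh] = 1.0 / lam[:, inh]
    m = ranges.median_levels(topology)[src]  # per-edge: regulator's median level
    x0 = rng.uniform(0.02 * m, 1.98 * m, size=(n_sets, ne))
    return ParameterEnsemble(topology, g, k, lam, n, x0)


def sample_parameter_set(
    topology: NetworkTopology, ranges: SamplingRanges, rng: np.random.Generator
) -> KineticParameterSet:
    """Draw a single kinetic parameter set."""
    return sample_parameter_sets(topology, ranges, 1, rng)[0]


def apply_perturbation(
    params: KineticParameterSet | ParameterEnsemble, perturbation: Perturbation
) -> KineticParameterSet | ParameterEnsemble:
    """Return a copy with one node's production rate scaled by the fold.

    Over-expression multiplies g, down-expression divides it; everything
    else is untouched.
    """
    idx = (
        params.topology.node_index(perturbation.node)
        if isinstance(params, (KineticParameterSet, ParameterEnsemble))
        else None
    )
    factor = perturbation.fold if perturbation.mode == OVER_EXPRESSION else 1.0 / perturbation.fold
    if isinstance(params, KineticParameterSet):
        g = params.production.copy()
        g[idx] *= factor
        return replace(params, production=g)
    out = copy.copy(params)
    out.production = params.production.copy()
    out.production[:, idx] *= factor
    return out


def ode_rhs(
    state: np.ndarray, params: KineticParameterSet, topology: NetworkTopology | None = None
) -> np.ndarray:
    """Time derivatives of all node concentrations.

    Node i: g_i times the product of shifted-Hill multipliers over incoming
    edges (empty product = 1) minus k_i X_i.
    """
    topology = topology or params.topology
    state = np.asarray(state, dtype=float)
    if state.shape != (topology.n_nodes,):
        raise ValueError(f"state must have shape ({topology.n_nodes},), got {state.shape}")
    if np.any(state < 0):
        raise ValueError("state must be non-negative")
    src, tgt, _ = topology.edge_arrays()
    prod = np.ones(topology.n_nodes)
    for e in range(len(src)):
        prod[tgt[e]] *= shifted_hill(
            state[src[e]], params.threshold[e], params.hill_coefficient[e], params.fold_change[e]
        )
    return params.production * prod - params.degradation * state
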