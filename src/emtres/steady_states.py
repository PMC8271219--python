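"""Steady-state enumeration across kinetic-parameter ensembles.

For every sampled parameter set, trajectories are launched from many
log-uniform initial conditions and relaxed to equilibrium; the distinct
stable states found (deduplicated in log2 concentration space) define the
set's multistability. Ensemble-level summaries tabulate how often mono-,
bi-, tri- and higher-order multistability occurs and which phenotype
combinations ("phases") co-exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .grn import KineticParameterSet, ParameterEnsemble, ode_rhs

DEDUP_TOL_LOG2 = 0.1  # Euclidean distance in log2 space below which states merge
T_COARSE = 200.0  # integration budget before the Newton polish takes over
T_MAX = 1000.0
STABILITY_EIG_TOL = 1e-6  # max real part of the Jacobian eigenvalues


@dataclass(frozen=True)
class SteadyState:
    """One converged stable state: per-node concentrations (linear scale)."""

    levels: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        if np.any(self.levels < 0):
            raise ValueError("steady-state concentrations must be non-negative")


@dataclass
class ModelSolution:
    """Distinct steady states found for one parameter set."""

    set_id: int
    states: list[SteadyState] = field(default_factory=list)
    n_nonconverged: int = 0
    n_unstable: int = 0

    @property
    def n_states(self) -> int:
        return len(self.states)


def _params_arrays(params: KineticParameterSet):
    src, tgt, _ = params.topology.edge_arrays()
    return (
        params.production.astype(float),
        params.degradation.astype(float),
        src,
        tgt,
        params.fold_change.astype(float),
        params.hill_coefficient.astype(float),
        params.threshold.astype(float),
    )


def sample_initial_conditions(
    params: KineticParameterSet, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-uniform initial conditions within each node's achievable range.

    The bounds are the per-node minimum and maximum steady levels implied by
    the fold changes of incoming edges (see
    :meth:`KineticParameterSet.level_bounds`); for unregulated nodes the
    range collapses to g/k.
    """
    lo, hi = params.level_bounds()
    loglo, loghi = np.log(lo), np.log(hi)
    u = rng.uniform(0.0, 1.0, size=(n, params.topology.n_nodes))
    return np.exp(loglo + u * (loghi - loglo))


def sample_initial_condition(
    params: KineticParameterSet, rng: np.random.Generator
) -> np.ndarray:
    return sample_initial_conditions(params, 1, rng)[0]


def is_stable(params: KineticParameterSet, state: np.ndarray) -> bool:
    """Linear stability via the analytic Jacobian: all eigenvalue real parts
    below ``STABILITY_EIG_TOL``."""
    g, k, src, tgt, lam, nh, x0e = _params_arrays(params)
    jac = _kernels.jacobian(np.asarray(state, dtype=float), g, k, src, tgt, lam, nh, x0e)
    return bool(np.max(np.linalg.eigvals(jac).real) < STABILITY_EIG_TOL)


def integrate_to_steady_state(
    params: KineticParameterSet,
    x0: np.ndarray,
    tol: float = 1e-6,
    t_max: float = T_MAX,
) -> SteadyState | None:
    """Relax one initial condition to equilibrium.

    Returns a :class:`SteadyState` whose relative residual
    ``max |dX/dt| / max(X, 1)`` is below ``tol`` (normally far below, after
    the Newton polish), or None when the trajectory fails to settle within
    the ``t_max`` budget (e.g. sustained oscillations).
    """
    x = np.array(x0, dtype=float)
    if np.any(x < 0):
        raise ValueError("initial condition must be non-negative")
    g, k, src, tgt, lam, nh, x0e = _params_arrays(params)
    ok, res = _kernels.find_steady_state(
        x, g, k, src, tgt, lam, nh, x0e, min(T_COARSE, t_max), t_max
    )
    if not ok or res >= tol:
        return None
    return SteadyState(levels=x, residual=float(res))


def enumerate_steady_states(
    params: KineticParameterSet,
    n_init: int = 100,
    rng: np.random.Generator | None = None,
    dedup_tol: float = DEDUP_TOL_LOG2,
    set_id: int = 0,
) -> ModelSolution:
    """Distinct stable steady states of one parameter set from ``n_init``
    log-uniform initial conditions, sorted by the first node's level."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    ens = ParameterEnsemble(
        params.topology,
        params.production[None, :],
        params.degradation[None, :],
        params.fold_change[None, :],
        params.hill_coefficient[None, :],
        params.threshold[None, :],
    )
    return enumerate_ensemble(ens, n_init=n_init, rng=rng, dedup_tol=dedup_tol)[0]


def enumerate_ensemble(
    ensemble: ParameterEnsemble,
    n_init: int = 100,
    rng: np.random.Generator | None = None,
    dedup_tol: float = DEDUP_TOL_LOG2,
    max_states: int = 16,
) -> list[ModelSolution]:
    """Run the steady-state search for every parameter set of an ensemble.

    Initial conditions are drawn log-uniformly per set; the heavy lifting is
    a compiled kernel (adaptive Runge-Kutta + Newton polish). States whose
    Jacobian eigenvalues indicate instability — a rare outcome of the polish
    landing on a saddle — are dropped and counted per solution.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    src, tgt, _ = ensemble.topology.edge_arrays()
    n_sets = len(ensemble)
    n_nodes = ensemble.topology.n_nodes
    ics = np.empty((n_sets, n_init, n_nodes))
    for s in range(n_sets):
        ics[s] = sample_initial_conditions(ensemble[s], n_init, rng)
    states, counts, resid, nonconv = _kernels.enumerate_ensemble_kernel(
        ensemble.production.astype(float),
        ensemble.degradation.astype(float),
        ensemble.fold_change.astype(float),
        ensemble.hill_coefficient.astype(float),
        ensemble.threshold.astype(float),
        src,
        tgt,
        ics,
        dedup_tol,
        T_COARSE,
        T_MAX,
        max_states,
    )
    solutions: list[ModelSolution] = []
    for s in range(n_sets):
        params = ensemble[s]
        kept: list[SteadyState] = []
        n_unstable = 0
        for q in range(counts[s]):
            lv = states[s, q]
            if is_stable(params, lv):
                kept.append(SteadyState(levels=lv.copy(), residual=float(resid[s, q])))
            else:
                n_unstable += 1
        kept.sort(key=lambda st: st.levels[0])
        solutions.append(
            ModelSolution(
                set_id=s, states=kept, n_nonconverged=int(nonconv[s]), n_unstable=n_unstable
            )
        )
    return solutions


def solutions_to_frame(
    solutions: list[ModelSolution], node_names: tuple[str, ...]
) -> pd.DataFrame:
    """One row per (parameter set, steady state): set_id, state_index,
    linear-scale levels per node, n_states."""
    rows = []
    for sol in solutions:
        for j, st in enumerate(sol.states):
            rows.append(
                (sol.set_id, j, sol.n_states, st.residual, *st.levels)
            )
    cols = ["set_id", "state_index", "n_states", "residual", *node_names]
    return pd.DataFrame(rows, columns=cols)


def tabulate_multistability(solutions: list[ModelSolution]) -> pd.Series:
    """Fractions of parameter sets by stable-state count: 1, 2, 3 and '4+'.

    Sets where every initial condition failed to converge are excluded from
    the denominator and reported under 'non_converged' (count, not fraction).
    """
    if not solutions:
        raise ValueError("empty ensemble")
    counts = {1: 0, 2: 0, 3: 0, "4+": 0}
    n_empty = 0
    for sol in solutions:
        if sol.n_states == 0:
            n_empty += 1
        elif sol.n_states >= 4:
            counts["4+"] += 1
        else:
            counts[sol.n_states] += 1
    denom = len(solutions) - n_empty
    table = pd.Series(
        {key: (c / denom if denom else np.nan) for key, c in counts.items()},
        name="fraction",
    )
    table["non_converged"] = n_empty
    return table


def tabulate_phases(frame: pd.DataFrame) -> pd.DataFrame:
    """Frequency of phenotype-label combinations per stability class.

    ``frame`` must carry 'set_id', 'n_states' and 'label' columns (one row
    per steady state, labels from the six phenotypes). The phase of a set is
    the sorted multiset of its co-existing labels; frequencies are reported
    within each multistability class and sum to 1 there.
    """
    if "label" not in frame.columns:
        raise ValueError("states are unlabeled: run phenotype scoring first")
    if frame["label"].isna().any():
        raise ValueError("every steady state must carry a phenotype label")
    phases = (
        frame.groupby("set_id")
        .agg(n_states=("n_states", "first"), phase=("label", lambda s: ",".join(sorted(s))))
        .reset_index()
    )
    out = []
    for n_states, grp in phases.groupby("n_states"):
        freq = grp["phase"].value_counts(normalize=True)
        for phase, f in freq.items():
            out.append((int(n_states), phase, float(f)))
    return pd.DataFrame(out, columns=["n_states", "phase", "frequency"])
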