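"""Synthetic inputs for testing every pipeline stage without external data:
degree- and sign-preserving randomized topologies, toy networks with
oracle-verified attractors, and score ensembles with known mixture structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .grn import KineticParameterSet, ode_rhs
from .topology import ACTIVATION, INHIBITION, NetworkTopology, RegulatoryEdge


class RandomizationError(RuntimeError):
    """No valid degree/sign-preserving randomization could be produced."""


@dataclass(frozen=True)
class RandomizationConstraints:
    """What topology randomization must preserve, and how hard to try."""

    preserve_degrees: bool = True
    preserve_sign_counts: bool = True
    max_attempts: int = 10_000


def randomize_topology(
    topology: NetworkTopology,
    constraints: RandomizationConstraints = RandomizationConstraints(),
    rng: np.random.Generator | None = None,
    n_swaps: int | None = None,
) -> NetworkTopology:
    """Randomize a signed network by directed double-edge swaps.

    A swap picks two edges (a->b), (c->d) and rewires them to (a->d),
    (c->b); each edge keeps its sign, so per-node in/out degrees and the
    global activation/inhibition counts are preserved exactly. Swaps that
    would create a duplicate edge or a new self-loop are rejected, and
    self-loops are never selected for swapping (they stay self-loops). The
    result must differ from the input in at least one edge.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if topology.n_edges < 2:
        raise RandomizationError("need at least 2 edges to randomize")
    edges = [(e.source, e.target, e.sign) for e in topology.edges]
    swappable = [i for i, (s, t, _) in enumerate(edges) if s != t]
    if len(swappable) < 2:
        raise RandomizationError("fewer than 2 non-self edges; no legal swap exists")
    target_swaps = n_swaps if n_swaps is not None else 10 * len(edges)
    done = 0
    changed = False
    present = {(s, t) for s, t, _ in edges}
    for _ in range(constraints.max_attempts):
        if done >= target_swaps:
            break
        i, j = rng.choice(len(swappable), size=2, replace=False)
        ia, ib = swappable[i], swappable[j]
        a, b, sign1 = edges[ia]
        c, d, sign2 = edges[ib]
        # rewire targets; reject duplicates and newly created self-loops
        if a == d or c == b:
            continue
        if (a, d) in present or (c, b) in present:
            continue
        present.discard((a, b))
        present.discard((c, d))
        present.add((a, d))
        present.add((c, b))
        edges[ia] = (a, d, sign1)
        edges[ib] = (c, b, sign2)
        done += 1
        changed = True
    if not changed:
        raise RandomizationError(
            f"no valid swap found in {constraints.max_attempts} attempts"
        )
    out = NetworkTopology(
        topology.nodes, tuple(RegulatoryEdge(s, t, g) for s, t, g in edges)
    )
    if constraints.preserve_degrees or constraints.preserve_sign_counts:
        assert out.degree_signature() == topology.degree_signature()
    return out


@dataclass
class ToyFixture:
    """A small network with a parameter set whose stable states are known
    from an independent dense root search."""

    topology: NetworkTopology
    params: KineticParameterSet
    stable_states: list[np.ndarray] = field(default_factory=list)


def _root_search_states(
    params: KineticParameterSet, grid: int = 12, tol: float = 1e-8
) -> list[np.ndarray]:
    """Oracle: dense grid-seeded root finding + Jacobian stability filter.

    Independent of the package's integrate-then-polish pipeline: roots come
    from scipy's hybrid Powell solver, stability from finite-difference
    Jacobian eigenvalues.
    """
    topo = params.topology
    lo, hi = params.level_bounds()
    seeds = np.meshgrid(
        *[np.geomspace(max(l, 1e-3), h, grid) for l, h in zip(lo, hi)], indexing="ij"
    )
    seeds = np.stack([s.ravel() for s in seeds], axis=1)
    roots: list[np.ndarray] = []
    for x0 in seeds:
        sol = optimize.fsolve(lambda x: ode_rhs(np.abs(x), params, topo), x0, full_output=True)
        x, _, ier, _ = sol
        x = np.abs(x)
        if ier != 1 or np.max(np.abs(ode_rhs(x, params, topo))) > tol:
            continue
        if any(np.linalg.norm(np.log2(x + 1e-12) - np.log2(r + 1e-12)) < 0.05 for r in roots):
            continue
        eps = 1e-6
        n = topo.n_nodes
        jac = np.empty((n, n))
        f0 = ode_rhs(x, params, topo)
        for jcol in range(n):
            dx = np.zeros(n)
            dx[jcol] = eps * max(x[jcol], 1.0)
            jac[:, jcol] = (ode_rhs(np.abs(x + dx), params, topo) - f0) / dx[jcol]
        if np.max(np.linalg.eigvals(jac).real) < -1e-9:
            roots.append(x)
    roots.sort(key=lambda r: r[0])
    return roots


def make_toggle_fixture() -> ToyFixture:
    """Symmetric two-node mutual-inhibition toggle switch with exactly two
    stable states (verified by dense root search)."""
    topo = NetworkTopology(
        ("A", "B"),
        (RegulatoryEdge("A", "B", INHIBITION), RegulatoryEdge("B", "A", INHIBITION)),
    )
    params = KineticParameterSet(
        topology=topo,
        production=np.array([10.0, 10.0]),
        degradation=np.array([1.0, 1.0]),
        fold_change=np.array([0.05, 0.05]),
        hill_coefficient=np.array([4.0, 4.0]),
        threshold=np.array([5.0, 5.0]),
    )
    states = _root_search_states(params, grid=25)
    assert len(states) == 2, f"toggle fixture expected 2 stable states, found {len(states)}"
    return ToyFixture(topo, params, states)


def make_autorepressor_fixture() -> ToyFixture:
    """Single self-inhibiting node: provably monostable (monotone decreasing
    production vs linear decay cross exactly once)."""
    topo = NetworkTopology(("A",), (RegulatoryEdge("A", "A", INHIBITION),))
    params = KineticParameterSet(
        topology=topo,
        production=np.array([20.0]),
        degradation=np.array([1.0]),
        fold_change=np.array([0.1]),
        hill_coefficient=np.array([3.0]),
        threshold=np.array([8.0]),
    )
    states = _root_search_states(params, grid=60)
    assert len(states) == 1
    return ToyFixture(topo, params, states)


def make_cascade_fixture() -> ToyFixture:
    """Feed-forward activation cascade A -> B -> C (no feedback): a unique
    fixed point computable sequentially in closed form."""
    topo = NetworkTopology(
        ("A", "B", "C"),
        (RegulatoryEdge("A", "B", ACTIVATION), RegulatoryEdge("B", "C", ACTIVATION)),
    )
    params = KineticParameterSet(
        topology=topo,
        production=np.array([10.0, 5.0, 2.0]),
        degradation=np.array([1.0, 0.5, 0.2]),
        fold_change=np.array([4.0, 3.0]),
        hill_coefficient=np.array([2.0, 2.0]),
        threshold=np.array([8.0, 12.0]),
    )
    from .grn import shifted_hill

    a = 10.0 / 1.0
    b = (5.0 / 0.5) * shifted_hill(a, 8.0, 2, 4.0)
    c = (2.0 / 0.2) * shifted_hill(b, 12.0, 2, 3.0)
    return ToyFixture(topo, params, [np.array([a, b, c])])


@dataclass(frozen=True)
class MixtureSpec:
    """Known Gaussian-mixture generating parameters for one score axis."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means and sds must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")
        if any(s <= 0 for s in self.sds):
            raise ValueError("component SDs must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        return rng.normal(np.asarray(self.means)[comp], np.asarray(self.sds)[comp])


#: trimodal EM axis / bimodal resistance axis, mimicking the shape of the
#: network ensemble's score distributions
DEFAULT_EM_SPEC = MixtureSpec((0.4, 0.2, 0.4), (-2.0, 0.0, 2.0), (0.5, 0.4, 0.5))
DEFAULT_RES_SPEC = MixtureSpec((0.5, 0.5), (-1.5, 1.5), (0.6, 0.6))


def synth_score_ensemble(
    n: int,
    rng: np.random.Generator,
    em_spec: MixtureSpec = DEFAULT_EM_SPEC,
    resistance_spec: MixtureSpec = DEFAULT_RES_SPEC,
) -> tuple[pd.DataFrame, MixtureSpec, MixtureSpec]:
    """Score pairs drawn from known mixtures, returned with their generating
    parameters for threshold-recovery tests."""
    frame = pd.DataFrame(
        {
            "em_score": em_spec.sample(n, rng),
            "resistance_score": resistance_spec.sample(n, rng),
        }
    )
    return frame, em_spec, resistance_spec
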