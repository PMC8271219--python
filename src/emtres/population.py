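"""Agent-based population model of drug-sensitive/resistant cancer cells.

Each cell carries two fixed scores sampled at birth — a sensitive-state
score ~ Normal(-2, SD^2) and a resistant-state score ~ Normal(+2, SD^2),
both clamped to [-6, 6] — plus a state index (S or R) telling which score is
currently active. The SD is the non-genetic heterogeneity of the population.

Per time step, in order:

1. death — a basal draw (p = basal_death) and, under drug, an independent
   drug draw: a cell escapes drug death with probability
   e^x / (e^x + c) of its active score x (survival sigmoid, c = 0.6);
2. drug-induced plasticity — surviving S cells flip to R with probability
   ``drug_induced_psr`` (drug on only);
3. stochastic switching — S->R with p_sr, R->S with p_rs, plus an
   independent MET-induced R->S draw with ``met_induced_prs``;
4. proliferation — logistic: each survivor divides with probability
   rate * (1 - N/K); daughters inherit the state and resample both scores.

Extinction probability is the fraction of replicate simulations that reach
zero cells by the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

SCORE_BOUND = 6.0


def survival_probability(x: np.ndarray | float, c: float = 0.6) -> np.ndarray | float:
    """Per-step probability of escaping drug-induced death at resistance
    score x: e^x / (e^x + c); monotone increasing, -> 1 as x -> +inf."""
    if c <= 0:
        raise ValueError("sigmoid constant c must be positive")
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + c * np.exp(-x))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PopulationConfig:
    """All rates and initial conditions of the agent model (per-step units)."""

    proliferation_rate: float = 0.91
    basal_death: float = 0.1
    carrying_capacity: int = 100_000
    sigmoid_c: float = 0.6
    mean_sensitive: float = -2.0
    mean_resistant: float = 2.0
    heterogeneity_sd: float = 0.0
    p_sr: float = 0.0
    p_rs: float = 0.0
    drug_induced_psr: float = 0.0
    met_induced_prs: float = 0.0
    initial_size: int = 100
    initial_resistant_fraction: float = 0.0
    drug_on: bool = True

    def __post_init__(self) -> None:
        for name in ("basal_death", "p_sr", "p_rs", "drug_induced_psr",
                     "met_induced_prs", "initial_resistant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        if self.sigmoid_c <= 0:
            raise ValueError("sigmoid_c must be positive")
        if self.initial_size < 0:
            raise ValueError("initial_size must be >= 0")
        if self.proliferation_rate < 0:
            raise ValueError("proliferation_rate must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def proliferation_probability(current_size: int, config: PopulationConfig) -> float:
    """Logistic division probability: max(0, rate * (1 - N/K)); state-blind."""
    if current_size < 0:
        raise ValueError("population size must be >= 0")
    return max(0.0, config.proliferation_rate * (1.0 - current_size / config.carrying_capacity))


@dataclass(frozen=True)
class Cell:
    """Single-cell view: the two fixed scores and the current state index."""

    sensitive_score: float
    resistant_score: float
    state: str  # "S" | "R"

    def __post_init__(self) -> None:
        if self.state not in ("S", "R"):
            raise ValueError("state must be 'S' or 'R'")
        for v in (self.sensitive_score, self.resistant_score):
            if not -SCORE_BOUND <= v <= SCORE_BOUND:
                raise ValueError(f"scores must lie in [-{SCORE_BOUND}, {SCORE_BOUND}]")


@dataclass
class PopulationState:
    """Vectorized cell population: per-cell scores and current state index."""

    sensitive_score: np.ndarray
    resistant_score: np.ndarray
    is_resistant: np.ndarray  # bool

    @property
    def size(self) -> int:
        return len(self.is_resistant)

    @property
    def n_resistant(self) -> int:
        return int(self.is_resistant.sum())

    @property
    def n_sensitive(self) -> int:
        return self.size - self.n_resistant

    def active_score(self) -> np.ndarray:
        return np.where(self.is_resistant, self.resistant_score, self.sensitive_score)


def _sample_scores(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=n), -SCORE_BOUND, SCORE_BOUND)


def _truncated_scores(
    mean: float, sd: float, n: int, rng: np.random.Generator, sign: int
) -> np.ndarray:
    """Rejection-sample Normal(mean, sd) until sign*score > 0, then clamp."""
    out = rng.normal(mean, sd, size=n)
    if sd > 0:
        for _ in range(1000):
            bad = sign * out <= 0
            if not bad.any():
                break
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, -SCORE_BOUND, SCORE_BOUND)


def init_population(config: PopulationConfig, rng: np.random.Generator) -> PopulationState:
    """Initial population: sensitive cells have sensitive score < 0,
    initially resistant cells have resistant score > 0 (rejection-sampled)."""
    n = config.initial_size
    n_res = int(round(config.initial_resistant_fraction * n))
    is_res = np.zeros(n, dtype=bool)
    is_res[:n_res] = True
    s = _sample_scores(config.mean_sensitive, config.heterogeneity_sd, n, rng)
    r = _sample_scores(config.mean_resistant, config.heterogeneity_sd, n, rng)
    s[~is_res] = _truncated_scores(
        config.mean_sensitive, config.heterogeneity_sd, n - n_res, rng, sign=-1
    )
    r[is_res] = _truncated_scores(
        config.mean_resistant, config.heterogeneity_sd, n_res, rng, sign=+1
    )
    return PopulationState(s, r, is_res)


def birth(parent: Cell, config: PopulationConfig, rng: np.random.Generator) -> Cell:
    """Daughter cell: inherits the parent's S/R state, resamples both scores."""
    s = float(_sample_scores(config.mean_sensitive, config.heterogeneity_sd, 1, rng)[0])
    r = float(_sample_scores(config.mean_resistant, config.heterogeneity_sd, 1, rng)[0])
    return Cell(s, r, parent.state)


def step(
    state: PopulationState, config: PopulationConfig, rng: np.random.Generator
) -> PopulationState:
    """Advance the population by one time step (death, plasticity,
    switching, proliferation — in that order)."""
    n = state.size
    if n == 0:
        return state

    # 1. death: basal and (under drug) drug-induced, independent draws
    alive = rng.random(n) >= config.basal_death
    if config.drug_on:
        surv_p = survival_probability(state.active_score(), config.sigmoid_c)
        alive &= rng.random(n) < surv_p
    s = state.sensitive_score[alive]
    r = state.resistant_score[alive]
    is_res = state.is_resistant[alive]
    m = len(is_res)
    if m == 0:
        return PopulationState(s, r, is_res)

    # 2. drug-induced plasticity: drug-surviving S cells may flip to R
    if config.drug_on and config.drug_induced_psr > 0:
        flip = (~is_res) & (rng.random(m) < config.drug_induced_psr)
        is_res = is_res | flip

    # 3. stochastic switching (simultaneous, based on the current state),
    #    with an independent MET-induced R->S draw
    u = rng.random(m)
    to_r = (~is_res) & (u < config.p_sr)
    to_s = is_res & (u < config.p_rs)
    if config.met_induced_prs > 0:
        to_s |= is_res & (rng.random(m) < config.met_induced_prs)
    is_res = (is_res | to_r) & ~to_s

    # 4. proliferation at the post-death population size
    p_div = proliferation_probability(m, config)
    divides = rng.random(m) < p_div
    n_new = int(divides.sum())
    if n_new:
        s_new = _sample_scores(config.mean_sensitive, config.heterogeneity_sd, n_new, rng)
        r_new = _sample_scores(config.mean_resistant, config.heterogeneity_sd, n_new, rng)
        s = np.concatenate([s, s_new])
        r = np.concatenate([r, r_new])
        is_res = np.concatenate([is_res, is_res[divides]])
    return PopulationState(s, r, is_res)


@dataclass
class PopulationTrajectory:
    """Per-step counts; zero-padded after extinction."""

    total: np.ndarray
    n_sensitive: np.ndarray
    n_resistant: np.ndarray

    @property
    def extinct(self) -> bool:
        return self.total[-1] == 0

    @property
    def final_size(self) -> int:
        return int(self.total[-1])


def run(
    config: PopulationConfig, horizon: int = 100, rng: np.random.Generator | None = None
) -> PopulationTrajectory:
    """Simulate one population for ``horizon`` steps (plus the initial state)."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    state = init_population(config, rng)
    total = np.zeros(horizon + 1, dtype=np.int64)
    n_sen = np.zeros(horizon + 1, dtype=np.int64)
    n_res = np.zeros(horizon + 1, dtype=np.int64)
    total[0], n_sen[0], n_res[0] = state.size, state.n_sensitive, state.n_resistant
    for t in range(1, horizon + 1):
        state = step(state, config, rng)
        total[t], n_sen[t], n_res[t] = state.size, state.n_sensitive, state.n_resistant
        if state.size == 0:
            break  # remaining entries stay zero
    return PopulationTrajectory(total, n_sen, n_res)


@dataclass(frozen=True)
class ExtinctionEstimate:
    """Extinction probability with binomial SE over replicate simulations."""

    probability: float
    standard_error: float
    n_replicates: int
    horizon: int
    surviving_sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def mean_surviving_size(self) -> float:
        return float(self.surviving_sizes.mean()) if len(self.surviving_sizes) else float("nan")


def estimate_extinction(
    config: PopulationConfig,
    horizon: int = 100,
    n_replicates: int = 100,
    rng: np.random.Generator | None = None,
) -> ExtinctionEstimate:
    """Fraction of replicates extinct at the horizon (binomial SE), plus the
    final sizes of the surviving replicates."""
    if n_replicates < 10:
        raise ValueError("need at least 10 replicates")
    rng = rng if rng is not None else np.random.default_rng(0)
    extinct = 0
    surviving: list[int] = []
    for _ in range(n_replicates):
        traj = run(config, horizon, rng)
        if traj.extinct:
            extinct += 1
        else:
            surviving.append(traj.final_size)
    p = extinct / n_replicates
    se = float(np.sqrt(p * (1 - p) / n_replicates))
    return ExtinctionEstimate(p, se, n_replicates, horizon, np.array(surviving, dtype=np.int64))


def sweep_plane(
    config: PopulationConfig,
    psr_grid: np.ndarray,
    prs_grid: np.ndarray,
    horizon: int = 100,
    n_replicates: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean final population size at the horizon over a (P_SR, P_RS) grid.

    Returns a matrix of shape (len(psr_grid), len(prs_grid))."""
    from dataclasses import replace

    rng = rng if rng is not None else np.random.default_rng(0)
    psr_grid = np.asarray(psr_grid, dtype=float)
    prs_grid = np.asarray(prs_grid, dtype=float)
    if np.any((psr_grid < 0) | (psr_grid > 1)) or np.any((prs_grid < 0) | (prs_grid > 1)):
        raise ValueError("switching-probability grids must lie within [0, 1]")
    out = np.zeros((len(psr_grid), len(prs_grid)))
    for i, psr in enumerate(psr_grid):
        for j, prs in enumerate(prs_grid):
            cfg = replace(config, p_sr=float(psr), p_rs=float(prs))
            sizes = [run(cfg, horizon, rng).final_size for _ in range(n_replicates)]
            out[i, j] = float(np.mean(sizes))
    return out
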