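"""End-to-end reproducible drivers: ensemble -> scoring -> phase tables,
stochastic landscapes, and population-dynamics panels, each from a single
config and master seed.

A master seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(master).spawn``, so each stage is independently
reproducible. Every run writes a manifest (config snapshot, seed, sha256 of
each output) that makes byte-identical replay checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grn import Perturbation, SamplingRanges, sample_parameter_sets
from .landscape import build_landscape, detect_transitions, euler_maruyama
from .population import PopulationConfig, estimate_extinction, run as run_population, sweep_plane
from .scoring import (
    compute_scores,
    correlate_em_resistance,
    fit_thresholds,
    classify,
    label_frequencies,
    perturbation_report,
    znormalize,
)
from .steady_states import (
    enumerate_ensemble,
    solutions_to_frame,
    tabulate_multistability,
    tabulate_phases,
)
from .topology import load_default_topology, read_topology


@dataclass
class RunConfig:
    """Everything a workflow run needs; loadable from YAML."""

    topology_path: str | None = None  # None -> bundled default network
    seed: int = 0
    n_sets: int = 2000
    n_init: int = 100
    ranges: SamplingRanges = field(default_factory=SamplingRanges)
    perturbation: Perturbation | None = None
    n_replicates: int = 3
    # SDE settings
    sde_dt: float = 0.01
    sde_t_end: float = 2000.0
    sde_noise: float = 0.05
    sde_n_trajectories: int = 5
    landscape_bins: int = 60
    dwell_min: int = 50
    # population settings
    population: PopulationConfig = field(default_factory=PopulationConfig)
    horizon: int = 100
    extinction_replicates: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "ranges" in kwargs:
            r = kwargs["ranges"]
            for key in ("g_range", "k_range", "n_range", "lam_range"):
                if key in r:
                    r[key] = tuple(r[key])
            kwargs["ranges"] = SamplingRanges(**r)
        if kwargs.get("perturbation"):
            kwargs["perturbation"] = Perturbation(**kwargs["perturbation"])
        if "population" in kwargs:
            kwargs["population"] = PopulationConfig(**kwargs["population"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def load_topology(self):
        if self.topology_path is None:
            return load_default_topology()
        return read_topology(self.topology_path)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, config: RunConfig, outputs: list[Path]) -> Path:
    from . import __version__ as version

    manifest = {
        "version": version,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def run_ensemble_workflow(config: RunConfig, out_dir: str | Path) -> dict:
    """Sample an ensemble, enumerate steady states, score and classify them;
    write parameters, states, scores, fraction/phase tables and a manifest.
    With a perturbation configured, also write the control-vs-perturbed
    phenotype frequency report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    topo = config.load_topology()
    rng_sample, rng_enum, rng_pert = _child_rngs(config.seed, 3)

    ensemble = sample_parameter_sets(topo, config.ranges, config.n_sets, rng_sample)
    sols = enumerate_ensemble(ensemble, n_init=config.n_init, rng=rng_enum)
    frame = solutions_to_frame(sols, topo.nodes)
    zframe, stats = znormalize(frame, topo.nodes)
    scores = compute_scores(zframe)
    thresholds = fit_thresholds(scores, seed=config.seed)
    scores["label"] = classify(scores, thresholds)
    rho, pval = correlate_em_resistance(scores)

    outputs = []
    for name, df in (
        ("parameters.tsv", ensemble.to_frame()),
        ("states.tsv", frame),
        ("scores.tsv", scores),
        ("multistability.tsv", tabulate_multistability(sols).rename_axis("n_states").reset_index()),
        ("phases.tsv", tabulate_phases(scores)),
        ("phenotype_frequencies.tsv", label_frequencies(scores["label"].to_numpy()).rename_axis("label").reset_index()),
    ):
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs.append(path)
    side = out_dir / "normalization.json"
    side.write_text(
        json.dumps(
            {
                "mean": stats.mean.tolist(),
                "std": stats.std.tolist(),
                "node_names": list(stats.node_names),
                "thresholds": thresholds.to_dict(),
                "spearman_rho": rho,
                "spearman_p": pval,
            },
            indent=2,
        )
        + "\n"
    )
    outputs.append(side)

    if config.perturbation is not None:
        report = perturbation_report(
            topo,
            config.perturbation,
            config.ranges,
            config.n_sets,
            config.n_init,
            rng_pert,
            n_replicates=config.n_replicates,
        )
        path = out_dir / "perturbation_report.tsv"
        report.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs.append(path)

    manifest = _write_manifest(out_dir, config, outputs)
    return {
        "scores": scores,
        "stats": stats,
        "thresholds": thresholds,
        "spearman_rho": rho,
        "outputs": outputs + [manifest],
    }


def run_landscape_workflow(
    config: RunConfig, set_id: int, ensemble_dir: str | Path, out_dir: str | Path
) -> dict:
    """Simulate one parameter set from a prior ensemble run under noise and
    write trajectory, landscape and transition-event files."""
    from .grn import ParameterEnsemble

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ensemble_dir = Path(ensemble_dir)
    topo = config.load_topology()
    params_frame = pd.read_csv(ensemble_dir / "parameters.tsv", sep="\t")
    if set_id not in set(params_frame["set_id"]):
        raise KeyError(f"set_id {set_id} not present in {ensemble_dir / 'parameters.tsv'}")
    ensemble = ParameterEnsemble.from_frame(topo, params_frame)
    params = ensemble[set_id]
    side = json.loads((ensemble_dir / "normalization.json").read_text())
    from .scoring import NormalizationStats, ScoreThresholds

    stats = NormalizationStats(
        tuple(side["node_names"]), np.array(side["mean"]), np.array(side["std"])
    )
    thresholds = ScoreThresholds(
        em_cuts=tuple(side["thresholds"]["em_cuts"]),
        resistance_cut=side["thresholds"]["resistance_cut"],
    )

    rngs = _child_rngs(config.seed, config.sde_n_trajectories)
    from .steady_states import sample_initial_conditions

    trajectories = []
    for i, rng in enumerate(rngs):
        x0 = sample_initial_conditions(params, 1, rng)[0]
        trajectories.append(
            euler_maruyama(
                params,
                x0,
                dt=config.sde_dt,
                t_end=config.sde_t_end,
                noise=config.sde_noise,
                seed=int(rng.integers(2**31)),
            )
        )
    outputs = []
    traj_frames = []
    for i, t in enumerate(trajectories):
        f = t.scores(stats)
        for j, name in enumerate(topo.nodes):
            f[name] = t.levels[:, j]
        f.insert(0, "trajectory", i)
        f["label"] = classify(f, thresholds)
        traj_frames.append(f)
    traj = pd.concat(traj_frames, ignore_index=True)
    path = out_dir / "trajectories.tsv"
    traj.to_csv(path, sep="\t", index=False, float_format="%.8g")
    outputs.append(path)

    scape = build_landscape(trajectories, stats, bins=config.landscape_bins)
    path = out_dir / "landscape.tsv"
    scape.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")
    outputs.append(path)

    events = []
    for i, t in enumerate(trajectories):
        for ev in detect_transitions(t.scores(stats), thresholds, config.dwell_min):
            events.append((i, ev.source, ev.target, ev.time))
    path = out_dir / "transitions.tsv"
    pd.DataFrame(events, columns=["trajectory", "source", "target", "time"]).to_csv(
        path, sep="\t", index=False
    )
    outputs.append(path)
    manifest = _write_manifest(out_dir, config, outputs)
    return {"landscape": scape, "trajectories": trajectories, "outputs": outputs + [manifest]}


def run_popdyn_workflow(
    config: RunConfig, out_dir: str | Path, preset: str | None = None
) -> dict:
    """Population-dynamics panels: growth trajectories, a (P_SR, P_RS)
    sweep, and extinction estimates, written as TSV/JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_traj, rng_sweep, rng_ext = _child_rngs(config.seed, 3)
    outputs = []
    results: dict = {}

    if preset in (None, "fig5d"):
        grid = np.round(np.arange(0.0, 1.01, 0.1), 2)
        mats = {}
        for sd in (0.0, 1.0):
            cfg = dataclasses.replace(config.population, heterogeneity_sd=sd)
            mats[sd] = sweep_plane(
                cfg, grid, grid, horizon=config.horizon, n_replicates=3, rng=rng_sweep
            )
            df = pd.DataFrame(mats[sd], index=grid, columns=grid)
            path = out_dir / f"sweep_sd{sd:g}.tsv"
            df.rename_axis("p_sr").to_csv(path, sep="\t", float_format="%.6g")
            outputs.append(path)
        results["sweeps"] = mats

    if preset in (None, "fig6a"):
        ests = {}
        for sd in (0.65, 0.70, 0.75):
            cfg = dataclasses.replace(
                config.population, heterogeneity_sd=sd, p_sr=0.5, p_rs=1.0
            )
            ests[sd] = estimate_extinction(
                cfg, horizon=config.horizon, n_replicates=config.extinction_replicates, rng=rng_ext
            )
        path = out_dir / "extinction.json"
        path.write_text(
            json.dumps(
                {
                    str(sd): {
                        "probability": e.probability,
                        "se": e.standard_error,
                        "n": e.n_replicates,
                        "horizon": e.horizon,
                        "mean_surviving_size": None
                        if np.isnan(e.mean_surviving_size)
                        else e.mean_surviving_size,
                    }
                    for sd, e in ests.items()
                },
                indent=2,
            )
            + "\n"
        )
        outputs.append(path)
        results["extinction"] = ests

    if preset in (None, "fig7"):
        recs = []
        for dpsr in (0.0, 1.0):
            for met in (0.0, 1.0):
                cfg = dataclasses.replace(
                    config.population,
                    p_sr=0.2,
                    p_rs=0.0,
                    drug_induced_psr=dpsr,
                    met_induced_prs=met,
                )
                traj = run_population(cfg, horizon=config.horizon, rng=rng_traj)
                for t in range(len(traj.total)):
                    recs.append(
                        (dpsr, met, t, traj.total[t], traj.n_sensitive[t], traj.n_resistant[t])
                    )
        path = out_dir / "met_inducer_trajectories.tsv"
        pd.DataFrame(
            recs,
            columns=["drug_induced_psr", "met_induced_prs", "time", "total", "sensitive", "resistant"],
        ).to_csv(path, sep="\t", index=False)
        outputs.append(path)

    manifest = _write_manifest(out_dir, config, outputs)
    results["outputs"] = outputs + [manifest]
    return results
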