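"""Experiment orchestration: ensembles -> NI tables -> model agreement.

An experiment is a network source (exhaustive enumeration, stratified
random sample, or files on disk), a list of models, and a preset deciding
grid resolution and integration windows.  ``run_experiment`` computes an NI
distribution per (network, model), caches each as JSON keyed by a content
hash of everything that determines it, and summarises cross-model agreement.

Presets
-------
``desk``
    24 x 24 grids with short reference windows — minutes-scale runs for
    development and testing.
``full``
    192 x 192 grids with long reference windows — the full-fidelity setting
    (hours per network; intended for batch execution).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import comparison as _comparison
from .dynamics import MODELS, SimulationConfig, default_params
from .ictogenicity import (
    IctalClassifierConfig,
    NIDistribution,
    ParameterGrid,
    compute_ni,
    default_grid,
    ni_to_csv,
)
from .networks import (
    Network,
    enumerate_digraphs,
    load_adjacency_csv,
    load_edge_list,
    network_id,
    sample_random_digraphs,
)

logger = logging.getLogger("ictonet")

__all__ = ["ExperimentConfig", "ExperimentResult", "PRESETS", "run_experiment",
           "preset_sim_config", "preset_resolution", "load_config", "save_config"]


# preset -> (grid resolution, per-model integration windows)
PRESETS: dict[str, dict] = {
    "desk": {
        "resolution": 24,
        "sim": {
            "physiological": {"dt": 1e-3, "t_ref": 8.0, "t_burn": 2.0},
            "theta": {"dt": 2e-3, "t_ref": 20.0, "t_burn": 2.0},
            "bistable": {"dt": 2e-3, "t_ref": 20.0, "t_burn": 0.0},
        },
    },
    "full": {
        "resolution": 192,
        "sim": {
            "physiological": {"dt": 1e-3, "t_ref": 20.0, "t_burn": 4.0},
            "theta": {"dt": 2e-3, "t_ref": 40.0, "t_burn": 4.0},
            "bistable": {"dt": 2e-3, "t_ref": 40.0, "t_burn": 0.0},
        },
    },
}


def preset_resolution(preset: str) -> int:
    return PRESETS[preset]["resolution"]


def preset_sim_config(model: str, preset: str = "desk", seed: int = 0,
                      overrides: dict | None = None) -> SimulationConfig:
    """The preset's integration window for one model."""
    spec = dict(PRESETS[preset]["sim"][model])
    if overrides:
        spec.update(overrides)
    return SimulationConfig(seed=seed, **spec)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    ``networks`` selects the source:
    ``{"kind": "enumerate", "n_nodes": 4}``,
    ``{"kind": "sample", "n_nodes": 19, "n_networks": 125,
    "edge_range": [18, 342], "seed": 0}`` or
    ``{"kind": "files", "paths": [...]}`` (edge-list TSV or adjacency CSV).
    """

    name: str
    networks: dict
    models: list[str] = field(default_factory=lambda: list(MODELS))
    preset: str = "desk"
    resolution: int | None = None          # overrides the preset grid
    sim_overrides: dict = field(default_factory=dict)   # model -> window fields
    classifier: dict = field(default_factory=dict)
    master_seed: int = 0
    out_dir: str = "results"
    n_workers: int = 1

    def validate(self) -> None:
        if not self.models:
            raise ValueError("experiment has an empty model list")
        unknown = [m for m in self.models if m not in MODELS]
        if unknown:
            raise ValueError(f"unknown models {unknown}; expected subset of {MODELS}")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        kind = self.networks.get("kind")
        if kind not in ("enumerate", "sample", "files"):
            raise ValueError(f"unknown network source kind {kind!r}")

    def grid_for(self, model: str) -> ParameterGrid:
        res = self.resolution or preset_resolution(self.preset)
        return default_grid(model, resolution=res)

    def sim_for(self, model: str) -> SimulationConfig:
        return preset_sim_config(model, self.preset,
                                 overrides=self.sim_overrides.get(model))

    def classifier_config(self) -> IctalClassifierConfig:
        return IctalClassifierConfig(**self.classifier)

    def build_networks(self) -> list[Network]:
        src = self.networks
        if src["kind"] == "enumerate":
            return enumerate_digraphs(src["n_nodes"])
        if src["kind"] == "sample":
            return sample_random_digraphs(
                src["n_nodes"], src["n_networks"], tuple(src["edge_range"]),
                seed=src.get("seed", self.master_seed),
            )
        nets = []
        for path in src["paths"]:
            path = Path(path)
            if path.suffix == ".csv":
                nets.append(load_adjacency_csv(path))
            else:
                nets.append(load_edge_list(path))
        return nets


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.__dict__, fh, sort_keys=False)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ExperimentConfig(**data)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    networks: list[Network]
    ni: dict[str, list[NIDistribution]]       # model -> per-network NI
    mean_tau: dict[tuple[str, str], float]
    heterogeneity: object | None              # DataFrame when computed
    comparison: _comparison.ComparisonResult | None
    failures: list[dict]
    manifest_path: Path | None


def _task_key(config: ExperimentConfig, net: Network, model: str) -> str:
    grid = config.grid_for(model)
    sim = config.sim_for(model)
    payload = json.dumps(
        {
            "adjacency": net.adjacency.tolist(),
            "labels": net.labels,
            "model": model,
            "grid": [grid.p_range, grid.alpha_range, grid.resolution],
            "sim": [sim.dt, sim.t_ref, sim.t_burn],
            "classifier": config.classifier,
            "master_seed": config.master_seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _ni_task(config: ExperimentConfig, net: Network, model: str,
             cache_dir: Path | None) -> NIDistribution:
    key = _task_key(config, net, model)
    cache_file = cache_dir / f"ni_{model}_{key}.json" if cache_dir else None
    if cache_file is not None and cache_file.exists():
        data = json.loads(cache_file.read_text())
        logger.debug("cache hit for %s / network %s", model, data["network_id"])
        return NIDistribution(
            model=model, network_id=data["network_id"],
            labels=tuple(data["labels"]), ni=np.asarray(data["ni"]),
            mean_bni_full=data["mean_bni_full"],
            mean_bni_removed=np.asarray(data["mean_bni_removed"]),
            master_seed=data["master_seed"],
        )
    dist = compute_ni(net, model, config.grid_for(model), config.sim_for(model),
                      config.classifier_config(), config.master_seed)
    if cache_file is not None:
        cache_file.write_text(json.dumps({
            "network_id": dist.network_id, "labels": list(dist.labels),
            "ni": dist.ni.tolist(), "mean_bni_full": dist.mean_bni_full,
            "mean_bni_removed": dist.mean_bni_removed.tolist(),
            "master_seed": dist.master_seed,
        }))
    return dist


def run_experiment(config: ExperimentConfig, dry_run: bool = False,
                   write_outputs: bool = True) -> ExperimentResult:
    """Compute NI for every (network, model) and summarise model agreement.

    Work units are cached under ``<out_dir>/cache`` keyed by a content hash
    of the network, model parameters, grid, windows and seed policy, so an
    interrupted run resumes without recomputation and node-removal results
    are never reused across incompatible settings.  Per-cell seeding makes
    results independent of the worker count.
    """
    config.validate()
    networks = config.build_networks()
    tasks = [(k, model) for k in range(len(networks)) for model in config.models]
    if dry_run:
        for k, model in tasks:
            logger.info("would compute NI: network %d (%d nodes, %d edges), %s",
                        k, networks[k].n_nodes, networks[k].n_edges, model)
        return ExperimentResult(config, networks, {}, {}, None, None, [], None)

    out_dir = Path(config.out_dir) / config.name
    cache_dir = None
    if write_outputs:
        cache_dir = out_dir / "cache"
        cache_dir.mkdir(parents=True, exist_ok=True)

    def run_one(k: int, model: str):
        try:
            return k, model, _ni_task(config, networks[k], model, cache_dir), None
        except Exception as exc:  # isolate per-task failures
            logger.error("NI failed for network %d / %s: %s", k, model, exc)
            return k, model, None, str(exc)

    if config.n_workers > 1:
        from joblib import Parallel, delayed

        # threads, not processes: the numba kernels release the GIL, and
        # per-cell seeding makes results identical for any worker count
        outcomes = Parallel(n_jobs=config.n_workers, prefer="threads")(
            delayed(run_one)(k, model) for k, model in tasks
        )
    else:
        outcomes = [run_one(k, model) for k, model in tasks]

    ni: dict[str, list] = {m: [None] * len(networks) for m in config.models}
    failures = []
    for k, model, dist, err in outcomes:
        if err is None:
            ni[model][k] = dist
        else:
            failures.append({"network": k, "model": model, "error": err})

    complete = [k for k in range(len(networks))
                if all(ni[m][k] is not None for m in config.models)]
    ni_complete = {m: [ni[m][k] for k in complete] for m in config.models}
    nets_complete = [networks[k] for k in complete]

    mean_tau: dict[tuple[str, str], float] = {}
    het = None
    comp = None
    if len(config.models) >= 2 and len(complete) >= 1:
        for i, a in enumerate(config.models):
            for b in config.models[i + 1:]:
                taus = _comparison.pairwise_tau(ni_complete[a], ni_complete[b],
                                                networks=nets_complete)
                defined = np.isfinite(taus)
                mean_tau[(a, b)] = (float(taus[defined].mean())
                                    if defined.any() else float("nan"))
        try:
            het, comp = _comparison.heterogeneity_analysis(ni_complete, nets_complete)
        except ValueError as exc:
            logger.info("heterogeneity binning skipped: %s", exc)

    manifest_path = None
    if write_outputs:
        for model in config.models:
            dists = [d for d in ni[model] if d is not None]
            ni_to_csv(dists, out_dir / f"ni_{model}.csv")
        if comp is not None:
            comp.binned.to_csv(out_dir / "tau_vs_dni_bins.csv", index=False)
            het.to_csv(out_dir / "heterogeneity.csv", index=False)
        summary = {
            "experiment": config.name,
            "mean_tau": {f"{a}|{b}": v for (a, b), v in mean_tau.items()},
            "spearman": ({m: comp.spearman[m] for m in config.models}
                         if comp is not None else None),
            "n_failures": len(failures),
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest = {
            "config": config.__dict__,
            "network_ids": [network_id(n) for n in networks],
            "task_keys": {f"{k}:{m}": _task_key(config, networks[k], m)
                          for k, m in tasks},
            "failures": failures,
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))

    return ExperimentResult(config, networks, ni, mean_tau, het, comp,
                            failures, manifest_path)
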