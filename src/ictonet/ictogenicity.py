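"""Brain network ictogenicity (BNI) and node ictogenicity (NI).

BNI measures the propensity of a network to sit in the seizure-like state:
for the recurrently switching models (physiological, theta) it is the mean
fraction of the reference window that nodes spend in the ictal state; for
the bistable model it is one minus the mean (censored) first-passage time
from the background fixed point to the oscillatory attractor, normalised by
the reference time.

Rather than fixing a single operating point, BNI is evaluated over a
regular excitability x coupling grid, and node ictogenicity is the
fractional reduction of the *map-averaged* BNI when one node is removed:

    NI_i = (<BNI>_0 - <BNI>_i) / <BNI>_0

where ``<.>`` averages over the whole grid, 0 is the intact network and
``i`` the network with node ``i`` deleted.  NI_i is negative when removal
makes the remaining network more ictogenic.  The spread
``dNI = max_i NI_i - min_i NI_i`` quantifies how heterogeneously
ictogenicity is distributed across nodes.

The classical single-operating-point variant (calibrate the global coupling
until BNI = 0.5, then measure removals there) is provided by
:func:`calibrate_coupling_for_bni`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import (
    MODELS,
    SimulationConfig,
    SimulationError,
    SimulationResult,
    default_dt,
    default_params,
    simulate,
    theta_steady_state,
)
from .networks import Network, network_id, remove_node

__all__ = [
    "ParameterGrid",
    "IctalClassifierConfig",
    "BNIMap",
    "NIDistribution",
    "default_grid",
    "derive_seed",
    "ictal_fraction",
    "escape_time_bni",
    "single_point_bni",
    "compute_bni_map",
    "compute_ni",
    "calibrate_coupling_for_bni",
    "resolve_classifier",
    "save_bni_map_h5",
    "load_bni_map_h5",
    "save_bni_map_csv",
    "ni_to_csv",
    "ni_summary_json",
]


# ---------------------------------------------------------------------------
# Grids and classifier configuration
# ---------------------------------------------------------------------------

_DEFAULT_RANGES = {
    # model: (excitability range, coupling range)
    "physiological": ((50.0, 110.0), (0.0, 1000.0)),
    "theta": ((-4.0, -0.1), (0.0, 10.0)),
    "bistable": ((-1.0, 0.0), (0.0, 10.0)),
}


@dataclass(frozen=True)
class ParameterGrid:
    """Regular excitability x coupling grid over which BNI is mapped."""

    p_range: tuple[float, float]
    alpha_range: tuple[float, float]
    resolution: int = 192

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("grid resolution must be >= 2")
        if self.p_range[0] >= self.p_range[1] or self.alpha_range[0] >= self.alpha_range[1]:
            raise ValueError("ranges must be increasing (min, max)")

    @property
    def p_values(self) -> np.ndarray:
        return np.linspace(self.p_range[0], self.p_range[1], self.resolution)

    @property
    def alpha_values(self) -> np.ndarray:
        return np.linspace(self.alpha_range[0], self.alpha_range[1], self.resolution)

    @property
    def n_cells(self) -> int:
        return self.resolution * self.resolution


def default_grid(model: str, resolution: int = 192) -> ParameterGrid:
    """The model's standard excitability/coupling window.

    Physiological: p in [50, 110], alpha in [0, 1000]; theta: p in
    [-4, -0.1], alpha in [0, 10]; bistable: p in [-1, 0], alpha in [0, 10].
    """
    if model not in _DEFAULT_RANGES:
        raise ValueError(f"unknown model {model!r}")
    p_range, a_range = _DEFAULT_RANGES[model]
    return ParameterGrid(p_range, a_range, resolution)


@dataclass(frozen=True)
class IctalClassifierConfig:
    """Model-specific rules deciding which samples count as ictal.

    theta
        A node is ictal while its phase is outside a band of half-width
        ``theta_band`` around the uncoupled steady state — i.e. for the full
        span of each spike excursion.
    physiological
        A node is ictal while its output deviates from its own per-trajectory
        median (a robust stand-in for the background fixed-point output) by
        more than ``phys_threshold`` mV.  When unset, the threshold is
        auto-calibrated as ``phys_threshold_factor`` times the robust
        standard deviation of a noise-driven subthreshold reference node, so
        large-amplitude epileptiform excursions are caught while background
        fluctuations are not.
    bistable
        A node has transited once ``|z|^2`` reaches
        ``bistable_escape_radius_sq`` (which dominates the unstable-cycle
        separatrix ``1 - sqrt(1 + p)`` over the whole standard grid).
    """

    theta_band: float = np.pi / 4.0
    phys_threshold: float | None = None
    phys_threshold_factor: float = 6.0
    bistable_escape_radius_sq: float = 1.0

    def __post_init__(self) -> None:
        if self.theta_band <= 0 or self.phys_threshold_factor <= 0:
            raise ValueError("classifier thresholds must be positive")
        if self.phys_threshold is not None and self.phys_threshold <= 0:
            raise ValueError("phys_threshold must be positive")
        if self.bistable_escape_radius_sq < 1.0:
            raise ValueError(
                "escape radius^2 must be >= 1 to dominate the unstable cycle "
                "over the standard excitability range"
            )


# ---------------------------------------------------------------------------
# Seed derivation
# ---------------------------------------------------------------------------

def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0xFFFFFFFFFFFFFFFF


def derive_seed(master_seed: int, net_id: int, stream: int, cell_index: int) -> int:
    """Deterministic 31-bit per-cell seed.

    A pure function of (master seed, network id, stream, cell index), so
    every map is reproducible in isolation and independent of evaluation
    order or worker count.  ``stream`` separates statistically independent
    uses of the same cell: each model gets its own stream, so cross-model
    rank agreement is never inflated by shared Monte-Carlo error, while
    within a model the intact and node-removal maps share the stream
    (common random numbers for the paired removal comparison).
    """
    h = _splitmix64(int(master_seed))
    h = _splitmix64(h ^ int(net_id))
    h = _splitmix64(h ^ (int(stream) + 2))
    h = _splitmix64(h ^ int(cell_index))
    return h % (1 << 31)


# ---------------------------------------------------------------------------
# Classification of trajectories
# ---------------------------------------------------------------------------

def _wrap_angle(d: np.ndarray) -> np.ndarray:
    return (d + np.pi) % (2.0 * np.pi) - np.pi


def ictal_fraction(series: np.ndarray, model: str,
                   classifier: IctalClassifierConfig,
                   theta_s: float | None = None) -> np.ndarray:
    """Per-node fraction of retained samples classified as ictal.

    ``series`` has shape (n_samples, n_nodes): phases for the theta model,
    output potentials for the physiological model.  The network-level BNI is
    the mean over nodes.
    """
    series = np.asarray(series)
    if series.ndim != 2 or series.shape[0] == 0:
        raise ValueError("series must be a non-empty (n_samples, n_nodes) array")
    if model == "theta":
        if theta_s is None:
            raise ValueError("theta classification needs the steady-state phase")
        dist = np.abs(_wrap_angle(series - theta_s))
        return (dist > classifier.theta_band).mean(axis=0)
    if model == "physiological":
        if classifier.phys_threshold is None:
            raise ValueError(
                "physiological threshold unset; resolve the classifier first"
            )
        baseline = np.median(series, axis=0)
        return (np.abs(series - baseline) > classifier.phys_threshold).mean(axis=0)
    raise ValueError(f"ictal_fraction applies to theta/physiological, not {model!r}")


def escape_time_bni(radius_sq: np.ndarray, classifier: IctalClassifierConfig,
                    t_ref: float, dt: float) -> tuple[float, np.ndarray]:
    """Escape-time BNI of a bistable trajectory started at ``z = 0``.

    Per node, the first time ``|z|^2`` reaches the escape radius; nodes that
    never escape are censored at ``t_ref``.  Returns
    ``(1 - mean(escape time)/t_ref, per-node escape times)``.
    """
    radius_sq = np.asarray(radius_sq)
    if radius_sq.ndim != 2 or radius_sq.shape[0] == 0:
        raise ValueError("radius_sq must be a non-empty (n_samples, n_nodes) array")
    n_samples = radius_sq.shape[0]
    if n_samples * dt < t_ref - 0.5 * dt:
        raise ValueError("trajectory shorter than the reference time")
    crossed = radius_sq >= classifier.bistable_escape_radius_sq
    any_cross = crossed.any(axis=0)
    first = np.argmax(crossed, axis=0)
    times = np.where(any_cross, (first + 1) * dt, t_ref)
    times = np.minimum(times, t_ref)
    return float(1.0 - times.mean() / t_ref), times


def resolve_classifier(classifier: IctalClassifierConfig, model: str, params,
                       config: SimulationConfig, grid_p_min: float,
                       calib_seed: int) -> IctalClassifierConfig:
    """Fill in the auto-calibrated physiological threshold if needed.

    The calibration run is a single uncoupled noise-driven node at the low
    end of the excitability window (subthreshold background activity); the
    threshold is ``phys_threshold_factor`` times the robust (MAD-based)
    standard deviation of its output.  Deterministic given ``calib_seed``,
    hence identical for the intact and all node-removal maps.
    """
    if model != "physiological" or classifier.phys_threshold is not None:
        return classifier
    single = Network(np.zeros((1, 1), dtype=np.int8))
    calib_cfg = SimulationConfig(dt=config.dt, t_ref=min(10.0, config.t_ref),
                                 t_burn=max(config.t_burn, 1.0), seed=calib_seed)
    res = simulate(single, "physiological",
                   replace(params, p=grid_p_min, alpha=0.0), calib_cfg)
    x = res.observables[:, 0]
    robust_sd = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    return replace(classifier, phys_threshold=classifier.phys_threshold_factor * robust_sd)


# ---------------------------------------------------------------------------
# BNI maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BNIMap:
    """BNI on a regular excitability x coupling grid for one network/model."""

    model: str
    p_values: np.ndarray
    alpha_values: np.ndarray
    bni: np.ndarray               # shape (len(p_values), len(alpha_values))
    network_id: int
    master_seed: int
    removed_node: int = -1        # -1: intact network

    @property
    def mean(self) -> float:
        return float(self.bni.mean())


def single_point_bni(net: Network, model: str, params,
                     config: SimulationConfig,
                     classifier: IctalClassifierConfig) -> float:
    """BNI of one simulation at a single (excitability, coupling) point."""
    if model == "bistable":
        cfg = replace(config, t_burn=0.0)  # escape time runs from t = 0
        res = simulate(net, model, params, cfg)
        bni, _ = escape_time_bni(res.radius_sq, classifier, cfg.t_ref, cfg.dt)
        return bni
    res = simulate(net, model, params, config)
    theta_s = theta_steady_state(min(params.p, 0.0)) if model == "theta" else None
    return float(ictal_fraction(res.observables, model, classifier, theta_s).mean())


def _cell_bni_fused(adj, net, model: str, params, config: SimulationConfig,
                    classifier: IctalClassifierConfig, theta_s, seed: int,
                    buf) -> float:
    from . import dynamics as _dyn

    seeds = _dyn.node_stream_seeds(seed, net.labels)
    if model == "theta":
        n = adj.shape[0]
        theta0 = np.full(n, theta_s)
        return float(_dyn._theta_bni(
            adj, params.p, params.alpha, theta_s, theta0,
            params.sigma_diffusion, config.dt, config.n_burn, config.n_ret,
            seeds, classifier.theta_band))
    if model == "physiological":
        return float(_dyn._phys_bni(
            adj, params.p, params.alpha, params.A, params.B, params.G,
            params.A_d, params.a, params.b, params.g, params.a_d,
            params.C1, params.C2, params.C3, params.C4, params.C5,
            params.C6, params.C7, params.nu0, params.e0, params.r,
            params.sigma_noise, config.dt, config.n_burn, config.n_ret,
            seeds, buf, classifier.phys_threshold))
    return float(_dyn._bistable_bni(
        adj, params.p, params.alpha, params.omega, params.sigma_noise,
        params.beta, config.dt, config.n_ret, seeds,
        classifier.bistable_escape_radius_sq))


def _cell_bni_stored(net, model: str, params, config: SimulationConfig,
                     classifier: IctalClassifierConfig, theta_s) -> float:
    if model == "bistable":
        res = simulate(net, model, params, config)
        value, _ = escape_time_bni(res.radius_sq, classifier,
                                   config.t_ref, config.dt)
        return value
    res = simulate(net, model, params, config)
    return float(ictal_fraction(res.observables, model, classifier, theta_s).mean())


def compute_bni_map(net: Network, model: str, grid: ParameterGrid,
                    config: SimulationConfig,
                    classifier: IctalClassifierConfig | None = None,
                    master_seed: int = 0,
                    params=None,
                    parent_id: int | None = None,
                    removed_node: int = -1,
                    engine: str = "fused") -> BNIMap:
    """One stochastic simulation per grid cell; BNI per cell.

    Each cell's seed derives from (master seed, network id, cell index);
    ``parent_id`` lets post-removal maps keep seeding against the intact
    network's id, and surviving node labels keep their per-label noise
    streams, so removal maps are paired with the intact map (common random
    numbers) while remaining independently reproducible.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if params is None:
        params = default_params(model)
    if classifier is None:
        classifier = IctalClassifierConfig()
    net_id = network_id(net) if parent_id is None else int(parent_id)
    calib_seed = derive_seed(master_seed, 0, -1, 1 << 24)
    classifier = resolve_classifier(classifier, model, params, config,
                                    grid.p_range[0], calib_seed)
    if engine not in ("fused", "stored"):
        raise ValueError(f"unknown engine {engine!r}")
    p_vals = grid.p_values
    a_vals = grid.alpha_values
    bni = np.empty((len(p_vals), len(a_vals)))
    adj = np.ascontiguousarray(net.adjacency, dtype=np.int8)
    buf = np.empty((config.n_ret, net.n_nodes)) if model == "physiological" else None
    for ip, p in enumerate(p_vals):
        theta_s = theta_steady_state(min(p, 0.0)) if model == "theta" else None
        for ia, alpha in enumerate(a_vals):
            cell = ip * len(a_vals) + ia
            # the cell seed (and through it each node label's noise stream)
            # is shared between the intact map and all node-removal maps of
            # one model (paired comparisons), but differs across models
            seed = derive_seed(master_seed, net_id, MODELS.index(model), cell)
            cfg = config.with_seed(seed)
            if model == "bistable":
                cfg = replace(cfg, t_burn=0.0)  # escape time runs from t = 0
            cell_params = replace(params, p=float(p), alpha=float(alpha))
            try:
                if engine == "fused":
                    value = _cell_bni_fused(adj, net, model, cell_params, cfg,
                                            classifier, theta_s, seed, buf)
                else:
                    value = _cell_bni_stored(net, model, cell_params, cfg,
                                             classifier, theta_s)
                if not np.isfinite(value):
                    raise SimulationError("non-finite BNI (diverged trajectory)")
            except Exception as exc:
                raise RuntimeError(
                    f"BNI simulation failed at cell (p={p}, alpha={alpha}) "
                    f"of the {model} map for network {net_id}"
                ) from exc
            bni[ip, ia] = value
    return BNIMap(model, p_vals, a_vals, bni, net_id, master_seed, removed_node)


# ---------------------------------------------------------------------------
# Node ictogenicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NIDistribution:
    """Per-node NI of one (network, model), with the heterogeneity spread."""

    model: str
    network_id: int
    labels: tuple[int, ...]
    ni: np.ndarray                      # aligned with labels
    mean_bni_full: float
    mean_bni_removed: np.ndarray        # aligned with labels
    master_seed: int = 0

    @property
    def delta_ni(self) -> float:
        return float(self.ni.max() - self.ni.min())

    def as_dict(self) -> dict[int, float]:
        return {l: float(v) for l, v in zip(self.labels, self.ni)}


def compute_ni(net: Network, model: str, grid: ParameterGrid,
               config: SimulationConfig,
               classifier: IctalClassifierConfig | None = None,
               master_seed: int = 0,
               params=None) -> NIDistribution:
    """Node ictogenicity from map-averaged BNI before/after each removal.

    The removal maps use the *same* grid ranges as the intact network, so
    the comparison is over identical parameter windows.  Fails with an
    explicit error when the intact network's mean BNI is zero (NI undefined).
    """
    if params is None:
        params = default_params(model)
    if classifier is None:
        classifier = IctalClassifierConfig()
    calib_seed = derive_seed(master_seed, 0, -1, 1 << 24)
    classifier = resolve_classifier(classifier, model, params, config,
                                    grid.p_range[0], calib_seed)
    net_id = network_id(net)
    full = compute_bni_map(net, model, grid, config, classifier, master_seed,
                           params, parent_id=net_id)
    if full.mean <= 0.0:
        raise ValueError(
            f"mean BNI of network {net_id} is zero under {model}; NI undefined"
        )
    removed_means = np.empty(net.n_nodes)
    for k, label in enumerate(net.labels):
        sub = remove_node(net, label)
        m = compute_bni_map(sub, model, grid, config, classifier, master_seed,
                            params, parent_id=net_id, removed_node=label)
        removed_means[k] = m.mean
    ni = (full.mean - removed_means) / full.mean
    return NIDistribution(model, net_id, net.labels, ni, full.mean,
                          removed_means, master_seed)


def calibrate_coupling_for_bni(net: Network, model: str, p: float,
                               config: SimulationConfig,
                               classifier: IctalClassifierConfig | None = None,
                               target_bni: float = 0.5,
                               alpha_bracket: tuple[float, float] | None = None,
                               tol: float = 0.05,
                               n_reps: int = 3,
                               max_iter: int = 25,
                               master_seed: int = 0,
                               params=None) -> float:
    """Bisection on the global coupling until BNI reaches ``target_bni``.

    Supports the single-operating-point NI variant: fix the excitability,
    raise the coupling from zero until the intact network spends the target
    fraction of time in the ictal state.  Each BNI evaluation averages
    ``n_reps`` fresh stochastic realisations.  Raises when the bracket does
    not straddle the target.
    """
    if params is None:
        params = default_params(model)
    if classifier is None:
        classifier = IctalClassifierConfig()
    if alpha_bracket is None:
        alpha_bracket = _DEFAULT_RANGES[model][1]
    calib_seed = derive_seed(master_seed, 0, -1, 1 << 24)
    classifier = resolve_classifier(classifier, model, params, config, p, calib_seed)
    net_id = network_id(net)
    counter = [0]

    def bni_at(alpha: float) -> float:
        vals = []
        for _ in range(n_reps):
            counter[0] += 1
            seed = derive_seed(master_seed, net_id, -1, counter[0])
            cfg = config.with_seed(seed)
            vals.append(single_point_bni(net, model,
                                         replace(params, p=float(p), alpha=float(alpha)),
                                         cfg, classifier))
        return float(np.mean(vals))

    lo, hi = alpha_bracket
    b_lo, b_hi = bni_at(lo), bni_at(hi)
    if not (b_lo < target_bni < b_hi):
        raise ValueError(
            f"coupling bracket {alpha_bracket} does not straddle "
            f"BNI={target_bni} (BNI({lo})={b_lo:.3f}, BNI({hi})={b_hi:.3f})"
        )
    alpha = 0.5 * (lo + hi)
    for _ in range(max_iter):
        alpha = 0.5 * (lo + hi)
        b = bni_at(alpha)
        if abs(b - target_bni) <= tol:
            return alpha
        if b < target_bni:
            lo = alpha
        else:
            hi = alpha
    return alpha


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_bni_map_h5(bmap: BNIMap, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("p_values", data=bmap.p_values)
        fh.create_dataset("alpha_values", data=bmap.alpha_values)
        fh.create_dataset("bni", data=bmap.bni)
        fh.attrs["model"] = bmap.model
        fh.attrs["network_id"] = bmap.network_id
        fh.attrs["master_seed"] = bmap.master_seed
        fh.attrs["removed_node"] = bmap.removed_node


def load_bni_map_h5(path) -> BNIMap:
    import h5py

    with h5py.File(path, "r") as fh:
        return BNIMap(
            model=str(fh.attrs["model"]),
            p_values=fh["p_values"][:],
            alpha_values=fh["alpha_values"][:],
            bni=fh["bni"][:],
            network_id=int(fh.attrs["network_id"]),
            master_seed=int(fh.attrs["master_seed"]),
            removed_node=int(fh.attrs["removed_node"]),
        )


def save_bni_map_csv(bmap: BNIMap, path) -> None:
    """Tidy CSV: one row per grid cell (p, alpha, bni)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["p", "alpha", "bni"])
        for ip, p in enumerate(bmap.p_values):
            for ia, a in enumerate(bmap.alpha_values):
                writer.writerow([repr(float(p)), repr(float(a)),
                                 repr(float(bmap.bni[ip, ia]))])


def ni_to_csv(dists: list[NIDistribution], path) -> None:
    """Tidy CSV of NI values: (network_id, model, node, ni)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["network_id", "model", "node", "ni"])
        for d in dists:
            for label, value in zip(d.labels, d.ni):
                writer.writerow([d.network_id, d.model, label, repr(float(value))])


def ni_summary_json(dist: NIDistribution, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "network_id": dist.network_id,
                "model": dist.model,
                "mean_bni_full": dist.mean_bni_full,
                "delta_ni": dist.delta_ni,
                "ni": dist.as_dict(),
            },
            fh,
            indent=1,
        )
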