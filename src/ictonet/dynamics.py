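"""Node dynamics: three seizure-transition models on a directed network.

Each node of a network carries one of three stochastic dynamical systems
that can switch between a "background" and an "ictal" (seizure-like) state:

``physiological``
    A modified Jansen-Rit neural mass with four interacting populations
    (pyramidal cells, excitatory interneurons, slow and fast inhibitory
    interneurons) plus a slow efferent loop; 12 state variables per node.
    The parameter regime places each node near a SNIC (saddle-node on
    invariant circle) bifurcation so that noise triggers transitions from a
    fixed point to large-amplitude epileptiform oscillations.  The observable
    is the pyramidal membrane potential ``y3 - y5 - y7`` (mV).

``theta``
    The Ermentrout-Kopell canonical ("theta neuron") model — the normal
    form of the SNIC bifurcation, one phase variable per node.  For an
    uncoupled noise-free node the SNIC sits exactly at excitability
    ``p_T = 0``: below it the phase rests at a steady state, above it the
    node spikes periodically with period ``pi / sqrt(p_T)``.

``bistable``
    The normal form of the subcritical Hopf bifurcation (complex variable
    ``z`` per node) modified with a quintic term so that for
    ``-1 <= p_B <= 0`` a stable fixed point ``z = 0`` coexists with a
    stable limit cycle at ``|z|^2 = 1 + sqrt(1 + p_B)``.  Noise drives
    escapes from the fixed point to the cycle.

All three are integrated with a fixed-step Euler-Maruyama scheme; noise is
realised as independent Gaussian increments of standard deviation
``sigma * sqrt(dt)`` per step and channel, where ``sigma`` is the model's
continuous-time diffusion (for the theta model the nominal noise amplitude
is converted to a diffusion once — see :class:`ThetaParams`).  Coupling
always enters through the binary adjacency matrix ``M`` with the convention
that row ``i`` lists the inputs of node ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .networks import Network

__all__ = [
    "MODELS",
    "PhysiologicalParams",
    "ThetaParams",
    "BistableParams",
    "SimulationConfig",
    "SimulationResult",
    "SimulationError",
    "default_params",
    "default_dt",
    "sigmoid",
    "theta_steady_state",
    "bistable_cycle_amplitude",
    "simulate",
    "node_stream_seeds",
    "save_trajectory_h5",
    "locate_theta_spiking_onset",
    "theta_spike_period",
    "bistable_settled_amplitude",
    "bistable_coexistence_lower_bound",
]

MODELS = ("physiological", "theta", "bistable")


class SimulationError(RuntimeError):
    """Raised when an integration produces non-finite state."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysiologicalParams:
    """Modified Jansen-Rit parameters (gains in mV, rates in 1/s)."""

    A: float = 5.0        # average excitatory gain
    B: float = 44.0       # average slow inhibitory gain
    G: float = 20.0       # average fast inhibitory gain
    A_d: float = 3.25     # gain of delayed efferent activity
    a: float = 100.0      # inverse time constant, excitatory loop
    b: float = 50.0       # inverse time constant, slow inhibitory loop
    g: float = 500.0      # inverse time constant, fast inhibitory loop
    a_d: float = 100.0    # inverse time constant, delayed efferent activity
    C1: float = 135.0     # connectivity constants C1..C7
    C2: float = 0.8 * 135.0
    C3: float = 0.25 * 135.0
    C4: float = 0.25 * 135.0
    C5: float = 0.3 * 135.0
    C6: float = 0.1 * 135.0
    C7: float = 0.25 * 135.0
    nu0: float = 6.0      # sigmoid midpoint (mV)
    e0: float = 2.5       # half of max firing rate (1/s)
    r: float = 0.56       # sigmoid steepness (1/mV)
    sigma_noise: float = 1.85
    p: float = 80.0       # excitability p_P
    alpha: float = 0.0    # coupling alpha_P

    def __post_init__(self) -> None:
        for name in ("a", "b", "g", "a_d", "e0", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ThetaParams:
    """Theta-model parameters; excitability must allow a steady state
    (``p <= 0``) when trajectories are initialised at the resting phase.

    ``sigma_noise`` is the standard deviation of the Gaussian noise current
    entering the input ``I`` per integration step at the model's native step
    ``noise_step``.  Internally it is converted to the equivalent
    step-size-independent diffusion ``sigma_noise * sqrt(noise_step)``, so
    trajectory statistics converge as ``dt`` is refined.  (Interpreting
    sigma_noise directly as a continuous-time diffusion would make phase
    noise dominate the dynamics completely, erasing all coupling and most
    excitability dependence.)
    """

    p: float = -1.0       # excitability p_T
    alpha: float = 0.0    # coupling alpha_T
    sigma_noise: float = 8.0
    noise_step: float = 2e-3

    @property
    def sigma_diffusion(self) -> float:
        return self.sigma_noise * float(np.sqrt(self.noise_step))


@dataclass(frozen=True)
class BistableParams:
    """Subcritical-Hopf normal-form parameters."""

    p: float = -0.5       # excitability p_B
    alpha: float = 0.0    # coupling alpha_B
    omega: float = 20.0   # oscillation frequency
    beta: float = 0.01    # noise scale multiplying sigma_noise
    sigma_noise: float = 1.85


_PARAM_TYPES = {
    "physiological": PhysiologicalParams,
    "theta": ThetaParams,
    "bistable": BistableParams,
}

_DEFAULT_DT = {"physiological": 1e-3, "theta": 2e-3, "bistable": 2e-3}


def default_params(model: str, **overrides):
    """Default parameter set of one model, with optional field overrides."""
    if model not in _PARAM_TYPES:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return _PARAM_TYPES[model](**overrides)


def default_dt(model: str) -> float:
    return _DEFAULT_DT[model]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration window: step, retained duration, discarded transient.

    ``dt`` is the Euler-Maruyama step (model time units; seconds for the
    physiological model).  The first ``t_burn`` units are integrated but
    discarded as transient before any statistic is computed; ``t_ref`` units
    are retained as the reference window.
    """

    dt: float
    t_ref: float
    t_burn: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_ref <= 0 or self.t_burn < 0:
            raise ValueError("need dt > 0, t_ref > 0, t_burn >= 0")

    @property
    def n_burn(self) -> int:
        return int(round(self.t_burn / self.dt))

    @property
    def n_ret(self) -> int:
        return int(round(self.t_ref / self.dt))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class SimulationResult:
    """Per-node observable time series over the retained window."""

    model: str
    times: np.ndarray            # (n_ret,), measured from the end of the burn-in
    observables: np.ndarray      # (n_ret, n_nodes)
    radius_sq: np.ndarray | None = None   # bistable only: |z|^2 series
    theta_init_fallback: bool = False     # theta started at pi (no steady state)

    @property
    def n_nodes(self) -> int:
        return self.observables.shape[1]


# ---------------------------------------------------------------------------
# Closed-form helpers
# ---------------------------------------------------------------------------

def sigmoid(nu, params: PhysiologicalParams | None = None):
    """Potential-to-firing-rate sigmoid ``2 e0 / (1 + exp(r (nu0 - nu)))``."""
    if params is None:
        params = PhysiologicalParams()
    return 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.nu0 - np.asarray(nu, dtype=float))))


def theta_steady_state(p: float) -> float:
    """Resting phase ``-arccos((1 + p) / (1 - p))`` of an uncoupled node.

    Defined for ``p <= 0`` only; beyond the SNIC (``p > 0``) no steady state
    exists and the node spikes periodically.
    """
    if p > 0:
        raise ValueError("no steady state beyond the SNIC (need p <= 0)")
    return -float(np.arccos((1.0 + p) / (1.0 - p)))


def bistable_cycle_amplitude(p: float) -> tuple[float, float]:
    """Squared radii of the stable and unstable limit cycles.

    Returns ``(1 + sqrt(1 + p), 1 - sqrt(1 + p))``; the second value is the
    separatrix radius used by the escape detector, meaningful on
    ``-1 <= p <= 0``.
    """
    if p < -1:
        raise ValueError("limit cycles exist only for p >= -1")
    s = float(np.sqrt(1.0 + p))
    return 1.0 + s, 1.0 - s


# ---------------------------------------------------------------------------
# Euler-Maruyama kernels (numba)
#
# The Gaussian increments come from an inline xorshift64* / Marsaglia-polar
# generator rather than numba's np.random: the per-step draw is the hot path
# of every BNI map, and the inline generator is about three times faster.
# Streams are fully determined by the 31-bit seed.
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rng_init(seed):
    # splitmix64 of the seed; the state must never be zero
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True, inline="always")
def _rng_next(state):
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return x * np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _rng_uniform(state):
    # uniform in (0, 1) from the top 53 bits
    return (np.float64(_rng_next(state) >> np.uint64(11)) + 0.5) * (2.0 ** -53)


@njit(cache=True, inline="always")
def _rng_normal(state, spare):
    if spare[0] != 0.0:
        v = spare[1]
        spare[0] = 0.0
        return v
    while True:
        u = 2.0 * _rng_uniform(state) - 1.0
        v = 2.0 * _rng_uniform(state) - 1.0
        s = u * u + v * v
        if 0.0 < s < 1.0:
            f = np.sqrt(-2.0 * np.log(s) / s)
            spare[0] = 1.0
            spare[1] = v * f
            return u * f


@njit(cache=True, fastmath=True)
def _theta_kernel(adj, p, alpha, theta_s, theta0, sigma, dt, n_burn, n_ret, seeds, out):
    n = adj.shape[0]
    states = np.empty(n, dtype=np.uint64)
    for i in range(n):
        states[i] = _rng_init(seeds[i])
    spares = np.zeros((n, 2))
    theta = theta0.copy()
    sqdt = np.sqrt(dt)
    c = np.empty(n)
    for step in range(n_burn + n_ret):
        for j in range(n):
            c[j] = 1.0 - np.cos(theta[j] - theta_s)
        for i in range(n):
            coup = 0.0
            for j in range(n):
                if adj[i, j] != 0:
                    coup += c[j]
            cos_i = np.cos(theta[i])
            drift = 1.0 - cos_i + (1.0 + cos_i) * (p + alpha * coup)
            noise = 0.0
            if sigma > 0.0:
                noise = (1.0 + cos_i) * sigma * sqdt * _rng_normal(states[i:i + 1], spares[i])
            theta[i] = theta[i] + dt * drift + noise
        if step >= n_burn:
            t = step - n_burn
            for i in range(n):
                out[t, i] = theta[i]


@njit(cache=True, fastmath=True)
def _phys_kernel(adj, p, alpha, A, B, G, Ad, a, b, g, ad,
                 C1, C2, C3, C4, C5, C6, C7, nu0, e0, r,
                 sigma, dt, n_burn, n_ret, seeds, out):
    n = adj.shape[0]
    states = np.empty(n, dtype=np.uint64)
    for i in range(n):
        states[i] = _rng_init(seeds[i])
    spares = np.zeros((n, 2))
    y = np.zeros((12, n))
    sqdt = np.sqrt(dt)
    noise_amp = A * a * sigma * sqdt   # noise enters the y4 equation inside A*a*(...)
    R = np.empty(n)
    two_e0 = 2.0 * e0
    for step in range(n_burn + n_ret):
        for i in range(n):
            s = 0.0
            for j in range(n):
                if adj[i, j] != 0:
                    s += y[10, j]
            R[i] = alpha * s
        for i in range(n):
            obs = y[2, i] - y[4, i] - y[6, i]
            S_out = two_e0 / (1.0 + np.exp(r * (nu0 - obs)))
            S_c1 = two_e0 / (1.0 + np.exp(r * (nu0 - C1 * y[0, i])))
            S_c3 = two_e0 / (1.0 + np.exp(r * (nu0 - C3 * y[0, i])))
            S_c5 = two_e0 / (1.0 + np.exp(r * (nu0 - (C5 * y[0, i] - y[8, i]))))
            d1 = y[1, i]
            d2 = A * a * S_out - 2.0 * a * y[1, i] - a * a * y[0, i]
            d3 = y[3, i]
            d4 = A * a * (p + R[i] + C2 * S_c1) - 2.0 * a * y[3, i] - a * a * y[2, i]
            d5 = y[5, i]
            d6 = B * b * C4 * S_c3 - 2.0 * b * y[5, i] - b * b * y[4, i]
            d7 = y[7, i]
            d8 = G * g * C7 * S_c5 - 2.0 * g * y[7, i] - g * g * y[6, i]
            d9 = y[9, i]
            d10 = B * b * C6 * S_c3 - 2.0 * b * y[9, i] - b * b * y[8, i]
            d11 = y[11, i]
            d12 = Ad * ad * S_out - 2.0 * ad * y[11, i] - ad * ad * y[10, i]
            y[0, i] += dt * d1
            y[1, i] += dt * d2
            y[2, i] += dt * d3
            y[3, i] += dt * d4
            if sigma > 0.0:
                y[3, i] += noise_amp * _rng_normal(states[i:i + 1], spares[i])
            y[4, i] += dt * d5
            y[5, i] += dt * d6
            y[6, i] += dt * d7
            y[7, i] += dt * d8
            y[8, i] += dt * d9
            y[9, i] += dt * d10
            y[10, i] += dt * d11
            y[11, i] += dt * d12
        if step >= n_burn:
            t = step - n_burn
            for i in range(n):
                out[t, i] = y[2, i] - y[4, i] - y[6, i]


@njit(cache=True, fastmath=True)
def _bistable_kernel(adj, p, alpha, omega, sigma, beta, dt, n_burn, n_ret, seeds,
                     out_x, out_u):
    n = adj.shape[0]
    states = np.empty(n, dtype=np.uint64)
    for i in range(n):
        states[i] = _rng_init(seeds[i])
    spares = np.zeros((n, 2))
    x = np.zeros(n)
    yv = np.zeros(n)
    xp = np.empty(n)
    sqdt = np.sqrt(dt)
    noise_amp = beta * sigma * sqdt
    for step in range(n_burn + n_ret):
        for i in range(n):
            xp[i] = x[i]
        for i in range(n):
            coup = 0.0
            for j in range(n):
                if adj[i, j] != 0:
                    coup += xp[j]
            u = x[i] * x[i] + yv[i] * yv[i]
            f = p + 2.0 * u - u * u
            dx = -yv[i] * omega + x[i] * f + alpha * coup
            dy = x[i] * omega + yv[i] * f
            x[i] = x[i] + dt * dx
            yv[i] = yv[i] + dt * dy
            if sigma > 0.0:
                x[i] += noise_amp * _rng_normal(states[i:i + 1], spares[i])
                yv[i] += noise_amp * _rng_normal(states[i:i + 1], spares[i])
        if step >= n_burn:
            t = step - n_burn
            for i in range(n):
                out_x[t, i] = x[i]
                out_u[t, i] = x[i] * x[i] + yv[i] * yv[i]


# ---------------------------------------------------------------------------
# Fused BNI kernels
#
# Grid sweeps classify trajectories on the fly instead of materialising them:
# the stored-trajectory route (simulate + the classifiers in the ictogenicity
# module) is the reference implementation, and these kernels reproduce it
# bit-for-bit because they consume the same noise streams in the same order.
# ---------------------------------------------------------------------------

@njit(cache=True, nogil=True)
def _theta_bni(adj, p, alpha, theta_s, theta0, sigma, dt, n_burn, n_ret,
               seeds, band):
    n = adj.shape[0]
    states = np.empty(n, dtype=np.uint64)
    for i in range(n):
        states[i] = _rng_init(seeds[i])
    spares = np.zeros((n, 2))
    theta = theta0.copy()
    sqdt = np.sqrt(dt)
    c = np.empty(n)
    two_pi = 2.0 * np.pi
    ictal = 0
    for step in range(n_burn + n_ret):
        for j in range(n):
            c[j] = 1.0 - np.cos(theta[j] - theta_s)
        for i in range(n):
            coup = 0.0
            for j in range(n):
                if adj[i, j] != 0:
                    coup += c[j]
            cos_i = np.cos(theta[i])
            drift = 1.0 - cos_i + (1.0 + cos_i) * (p + alpha * coup)
            noise = 0.0
            if sigma > 0.0:
                noise = (1.0 + cos_i) * sigma * sqdt * _rng_normal(states[i:i + 1], spares[i])
            theta[i] = theta[i] + dt * drift + noise
        if step >= n_burn:
            for i in range(n):
                d = theta[i] - theta_s
                d = d - two_pi * np.floor(d / two_pi + 0.5)
                if np.abs(d) > band:
                    ictal += 1
    for i in range(n):
        if not np.isfinite(theta[i]):
            return np.nan
    return ictal / (n_ret * n)


@njit(cache=True, nogil=True)
def _phys_bni(adj, p, alpha, A, B, G, Ad, a, b, g, ad,
              C1, C2, C3, C4, C5, C6, C7, nu0, e0, r,
              sigma, dt, n_burn, n_ret, seeds, buf, threshold):
    n = adj.shape[0]
    states = np.empty(n, dtype=np.uint64)
    for i in range(n):
        states[i] = _rng_init(seeds[i])
    spares = np.zeros((n, 2))
    y = np.zeros((12, n))
    sqdt = np.sqrt(dt)
    noise_amp = A * a * sigma * sqdt
    R = np.empty(n)
    two_e0 = 2.0 * e0
    for step in range(n_burn + n_ret):
        for i in range(n):
            s = 0.0
            for j in range(n):
                if adj[i, j] != 0:
                    s += y[10, j]
            R[i] = alpha * s
        for i in range(n):
            obs = y[2, i] - y[4, i] - y[6, i]
            S_out = two_e0 / (1.0 + np.exp(r * (nu0 - obs)))
            S_c1 = two_e0 / (1.0 + np.exp(r * (nu0 - C1 * y[0, i])))
            S_c3 = two_e0 / (1.0 + np.exp(r * (nu0 - C3 * y[0, i])))
            S_c5 = two_e0 / (1.0 + np.exp(r * (nu0 - (C5 * y[0, i] - y[8, i]))))
            d1 = y[1, i]
            d2 = A * a * S_out - 2.0 * a * y[1, i] - a * a * y[0, i]
            d3 = y[3, i]
            d4 = A * a * (p + R[i] + C2 * S_c1) - 2.0 * a * y[3, i] - a * a * y[2, i]
            d5 = y[5, i]
            d6 = B * b * C4 * S_c3 - 2.0 * b * y[5, i] - b * b * y[4, i]
            d7 = y[7, i]
            d8 = G * g * C7 * S_c5 - 2.0 * g * y[7, i] - g * g * y[6, i]
            d9 = y[9, i]
            d10 = B * b * C6 * S_c3 - 2.0 * b * y[9, i] - b * b * y[8, i]
            d11 = y[11, i]
            d12 = Ad * ad * S_out - 2.0 * ad * y[11, i] - ad * ad * y[10, i]
            y[0, i] += dt * d1
            y[1, i] += dt * d2
            y[2, i] += dt * d3
            y[3, i] += dt * d4
            if sigma > 0.0:
                y[3, i] += noise_amp * _rng_normal(states[i:i + 1], spares[i])
            y[4, i] += dt * d5
            y[5, i] += dt * d6
            y[6, i] += dt * d7
            y[7, i] += dt * d8
            y[8, i] += dt * d9
            y[9, i] += dt * d10
            y[10, i] += dt * d11
            y[11, i] += dt * d12
        if step >= n_burn:
            t = step - n_burn
            for i in range(n):
                buf[t, i] = y[2, i] - y[4, i] - y[6, i]
    for i in range(n):
        if not np.isfinite(y[2, i] - y[4, i] - y[6, i]):
            return np.nan
    ictal = 0
    col = np.empty(n_ret)
    for i in range(n):
        for t in range(n_ret):
            col[t] = buf[t, i]
        med = np.median(col)
        for t in range(n_ret):
            if np.abs(col[t] - med) > threshold:
                ictal += 1
    return ictal / (n_ret * n)


@njit(cache=True, nogil=True)
def _bistable_bni(adj, p, alpha, omega, sigma, beta, dt, n_ret, seeds, esc_r2):
    # first-passage times from z = 0, censored at n_ret steps; integration
    # stops early once every node has escaped (later steps cannot change
    # any first-passage time)
    n = adj.shape[0]
    states = np.empty(n, dtype=np.uint64)
    for i in range(n):
        states[i] = _rng_init(seeds[i])
    spares = np.zeros((n, 2))
    x = np.zeros(n)
    yv = np.zeros(n)
    xp = np.empty(n)
    first = np.full(n, n_ret, dtype=np.int64)
    sqdt = np.sqrt(dt)
    noise_amp = beta * sigma * sqdt
    n_escaped = 0
    for step in range(n_ret):
        for i in range(n):
            xp[i] = x[i]
        for i in range(n):
            coup = 0.0
            for j in range(n):
                if adj[i, j] != 0:
                    coup += xp[j]
            u = x[i] * x[i] + yv[i] * yv[i]
            f = p + 2.0 * u - u * u
            dx = -yv[i] * omega + x[i] * f + alpha * coup
            dy = x[i] * omega + yv[i] * f
            x[i] = x[i] + dt * dx
            yv[i] = yv[i] + dt * dy
            if sigma > 0.0:
                x[i] += noise_amp * _rng_normal(states[i:i + 1], spares[i])
                yv[i] += noise_amp * _rng_normal(states[i:i + 1], spares[i])
            if first[i] == n_ret and x[i] * x[i] + yv[i] * yv[i] >= esc_r2:
                first[i] = step
                n_escaped += 1
        if n_escaped == n:
            break
    for i in range(n):
        if not np.isfinite(x[i]) or not np.isfinite(yv[i]):
            return np.nan
    total = 0.0
    for i in range(n):
        total += (first[i] + 1) * dt if first[i] < n_ret else n_ret * dt
    return 1.0 - total / (n * n_ret * dt)


# ---------------------------------------------------------------------------
# Public simulation interface
# ---------------------------------------------------------------------------

def node_stream_seeds(seed: int, labels: tuple[int, ...]) -> np.ndarray:
    """Per-node RNG stream seeds derived from a simulation seed.

    Each node *label* gets its own noise stream, so a node's noise
    realisation is unchanged when other nodes are removed from the network.
    Node-removal comparisons run under common random numbers, which removes
    most of the shared Monte-Carlo error from BNI differences.
    """
    out = np.empty(len(labels), dtype=np.int64)
    for k, label in enumerate(labels):
        z = (int(seed) & 0xFFFFFFFFFFFFFFFF) ^ ((int(label) + 1) * 0x9E3779B97F4A7C15)
        z &= 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        out[k] = (z ^ (z >> 31)) & 0x7FFFFFFFFFFFFFFF
    return out


def simulate(net: Network, model: str, params=None,
             config: SimulationConfig | None = None) -> SimulationResult:
    """Integrate one model on a network; return retained observables.

    Initial conditions follow each model's ictogenicity definition:
    physiological — all state variables zero (transient discarded);
    theta — every phase at the uncoupled steady state (falling back to
    ``pi`` with a flag if ``p > 0``); bistable — ``z = 0`` exactly, as
    required by the escape-time definition of ictogenicity.

    Noise streams are keyed by (config.seed, node label) — see
    :func:`node_stream_seeds`.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if params is None:
        params = default_params(model)
    if config is None:
        config = SimulationConfig(dt=default_dt(model), t_ref=40.0, t_burn=4.0)

    adj = np.ascontiguousarray(net.adjacency, dtype=np.int8)
    n = adj.shape[0]
    n_burn, n_ret = config.n_burn, config.n_ret
    seeds = node_stream_seeds(config.seed, net.labels)
    times = (np.arange(n_ret) + 1) * config.dt

    if model == "theta":
        fallback = params.p > 0
        theta_s = theta_steady_state(min(params.p, 0.0))
        theta0 = np.full(n, np.pi if fallback else theta_s)
        out = np.empty((n_ret, n))
        _theta_kernel(adj, params.p, params.alpha, theta_s, theta0,
                      params.sigma_diffusion, config.dt, n_burn, n_ret, seeds, out)
        result = SimulationResult("theta", times, out, theta_init_fallback=fallback)
    elif model == "physiological":
        out = np.empty((n_ret, n))
        _phys_kernel(adj, params.p, params.alpha, params.A, params.B, params.G,
                     params.A_d, params.a, params.b, params.g, params.a_d,
                     params.C1, params.C2, params.C3, params.C4, params.C5,
                     params.C6, params.C7, params.nu0, params.e0, params.r,
                     params.sigma_noise, config.dt, n_burn, n_ret, seeds, out)
        result = SimulationResult("physiological", times, out)
    else:
        out_x = np.empty((n_ret, n))
        out_u = np.empty((n_ret, n))
        _bistable_kernel(adj, params.p, params.alpha, params.omega,
                         params.sigma_noise, params.beta, config.dt,
                         n_burn, n_ret, seeds, out_x, out_u)
        result = SimulationResult("bistable", times, out_x, radius_sq=out_u)

    if not np.isfinite(result.observables[-1]).all():
        raise SimulationError(
            f"{model} integration diverged (p={params.p}, alpha={params.alpha}, "
            f"dt={config.dt}, seed={config.seed})"
        )
    return result


def save_trajectory_h5(result: SimulationResult, path, params=None,
                       config: SimulationConfig | None = None) -> None:
    """Debugging export: per-node observable arrays plus run metadata."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=result.times)
        fh.create_dataset("observables", data=result.observables)
        if result.radius_sq is not None:
            fh.create_dataset("radius_sq", data=result.radius_sq)
        fh.attrs["model"] = result.model
        if config is not None:
            fh.attrs["dt"] = config.dt
            fh.attrs["seed"] = config.seed
        if params is not None:
            fh.attrs["params"] = repr(params)


# ---------------------------------------------------------------------------
# Deterministic bifurcation diagnostics
# ---------------------------------------------------------------------------

def _theta_spikes(p: float, dt: float, t_max: float) -> bool:
    """Noise-free single node started below threshold: does the phase ever
    pass ``pi`` (complete a spike) within ``t_max``?"""
    adj = np.zeros((1, 1), dtype=np.int8)
    out = np.empty((int(round(t_max / dt)), 1))
    theta0 = np.full(1, -np.pi / 2.0)
    _theta_kernel(adj, p, 0.0, 0.0, theta0, 0.0, dt, 0, out.shape[0],
                  np.zeros(1, dtype=np.int64), out)
    return bool((out[:, 0] >= np.pi).any())


def locate_theta_spiking_onset(tol: float = 1e-3, dt: float = 1e-3,
                               t_max: float = 250.0,
                               bracket: tuple[float, float] = (-0.1, 0.1)) -> float:
    """Bisection estimate of the excitability at which an uncoupled,
    noise-free theta node starts spiking (the SNIC, at ``p = 0``).

    ``t_max`` bounds the detectable period (``pi / sqrt(p)``), so it must
    exceed the period at ``p = tol`` for the bracket to shrink reliably.
    """
    lo, hi = bracket
    if _theta_spikes(lo, dt, t_max) or not _theta_spikes(hi, dt, t_max):
        raise ValueError("bracket does not straddle the spiking onset")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _theta_spikes(mid, dt, t_max):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def theta_spike_period(p: float, dt: float = 1e-4, n_spikes: int = 12) -> float:
    """Inter-spike interval of the noise-free theta node at ``p > 0``,
    measured from successive upward crossings of ``pi`` of the unwrapped
    phase (closed form: ``pi / sqrt(p)``)."""
    if p <= 0:
        raise ValueError("periodic spiking requires p > 0")
    expected = np.pi / np.sqrt(p)
    t_max = expected * (n_spikes + 2)
    n_steps = int(round(t_max / dt))
    adj = np.zeros((1, 1), dtype=np.int8)
    out = np.empty((n_steps, 1))
    theta0 = np.full(1, -np.pi / 2.0)
    _theta_kernel(adj, p, 0.0, 0.0, theta0, 0.0, dt, 0, n_steps,
                  np.zeros(1, dtype=np.int64), out)
    phase = out[:, 0]
    # unwrapped phase increases monotonically; spike k completes at pi + 2*pi*k
    crossings = []
    level = np.pi
    for k in range(n_spikes):
        idx = np.searchsorted(phase, level)
        if idx >= n_steps:
            break
        # linear interpolation between the straddling steps
        if idx == 0:
            t_cross = dt
        else:
            frac = (level - phase[idx - 1]) / (phase[idx] - phase[idx - 1])
            t_cross = (idx - 1 + frac + 1) * dt
        crossings.append(t_cross)
        level += 2.0 * np.pi
    if len(crossings) < 2:
        raise SimulationError(f"too few spikes detected at p={p}")
    return float(np.mean(np.diff(crossings)))


def _bistable_radial_rhs(t, u, p):
    # |z|^2 dynamics; the rotation at omega decouples exactly from the modulus
    return 2.0 * u * (p + 2.0 * u - u * u)


def bistable_settled_amplitude(p: float, z0: complex = 2.0 + 0.0j,
                               t_max: float = 400.0) -> float:
    """Long-run ``|z|^2`` of the deterministic single node from ``z0``.

    In polar form ``z = sqrt(u) e^{i phi}`` the phase rotates rigidly at
    ``omega`` while ``du/dt = 2u (p + 2u - u^2)``, so the settled amplitude
    is found by integrating the one-dimensional radial equation at tight
    tolerance.  Converges to ``1 + sqrt(1 + p)`` when started outside the
    unstable cycle (for ``-1 <= p <= 0``), and to 0 otherwise.
    """
    u0 = z0.real * z0.real + z0.imag * z0.imag
    sol = solve_ivp(_bistable_radial_rhs, (0.0, t_max), [u0], args=(p,),
                    rtol=1e-10, atol=1e-12, method="RK45")
    if not sol.success:
        raise SimulationError(f"bistable continuation failed at p={p}")
    return float(sol.y[0, -1])


def bistable_coexistence_lower_bound(tol: float = 1e-3,
                                     bracket: tuple[float, float] = (-1.5, -0.5),
                                     t_max: float = 400.0) -> float:
    """Bisection on excitability for the disappearance of the nonzero
    attractor of the deterministic bistable node (exact value: ``p = -1``,
    the saddle-node of limit cycles).

    A trajectory started well outside the unstable cycle settles on the
    stable cycle when it exists and spirals into ``z = 0`` otherwise.
    """
    def has_cycle(p: float) -> bool:
        return bistable_settled_amplitude(p, t_max=t_max) > 0.5

    lo, hi = bracket
    if has_cycle(lo) or not has_cycle(hi):
        raise ValueError("bracket does not straddle the saddle-node of cycles")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_cycle(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
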