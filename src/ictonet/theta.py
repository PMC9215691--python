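"""Theta-model (Ermentrout-Kopell canonical type-I neuron) network simulation.

Each network node i carries a phase theta_i obeying

    dtheta_i/dt = (1 - cos theta_i) + (1 + cos theta_i) * I_i(t)
    I_i(t) = I0 + xi_i(t) + (K/N) * sum_{j != i} w_ji * [1 - cos(theta_j - theta_s)]

where w is the functional-network PLV matrix, K a global coupling scale, and
xi Gaussian noise of standard deviation sigma per unit sqrt(time) standing in
for input from regions outside the network.  For I_i < 0 the node rests,
fluctuating near the stable phase theta_s = -arccos((1+I0)/(1-I0)); for
I_i > 0 the phase rotates, the model's seizure-like state; the transition is
a saddle-node-on-invariant-circle bifurcation at I_i = 0.

Integration is Euler-Maruyama from theta_i(0) = theta_s.  A sample counts as
seizure-like when the phase sits on the escape arc past the unstable fixed
point theta_u = +arccos((1+I0)/(1-I0)), i.e. mod(theta - theta_s, 2*pi) >
theta_u - theta_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .networks import FunctionalNetwork

__all__ = [
    "ThetaModelParams",
    "SimulationResult",
    "stable_phase",
    "unstable_phase",
    "seizure_classification",
    "simulate",
]


@dataclass
class ThetaModelParams:
    """Simulator constants.

    ``n_steps`` is the total number of Euler-Maruyama steps (the canonical
    full-length run uses 4e6 steps of dt = 0.01 model-time units; tests and
    the cohort pipeline scale this down).  ``transient_steps=None`` resolves
    to 5% of ``n_steps``.  ``noise_per_step=True`` switches the noise term
    from the SDE scaling sigma*sqrt(dt) to a per-step standard deviation
    sigma (alternative bookkeeping kept switchable for comparison).
    ``n_norm`` overrides the N in the K/N coupling normalization (by default
    the current network size, which shrinks after node removal).
    """

    i0: float = -1.2
    noise_sd: float = 0.6
    k: float = 1.0
    dt: float = 0.01
    n_steps: int = 4_000_000
    transient_steps: int | None = None
    seed: int = 0
    noise_per_step: bool = False
    n_norm: int | None = None

    def resolved_transient(self) -> int:
        t = self.n_steps // 20 if self.transient_steps is None else self.transient_steps
        return int(t)

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        t = self.resolved_transient()
        if not (0 <= t < self.n_steps):
            raise ValueError("need n_steps > transient_steps >= 0")


@dataclass
class SimulationResult:
    """Per-node fraction of post-transient time spent in the seizure-like state."""

    seizure_fraction: np.ndarray
    params: ThetaModelParams
    channel_labels: tuple[str, ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.seizure_fraction.size

    @property
    def mean_fraction(self) -> float:
        return float(self.seizure_fraction.mean())


def stable_phase(i0: float) -> float:
    """Stable fixed point theta_s = -arccos((1+I0)/(1-I0)) of the resting node.

    Only defined for I0 < 0; at I0 = 0 the stable and unstable points merge
    (SNIC bifurcation) and for I0 > 0 none exists.
    """
    if i0 >= 0:
        raise ValueError("stable phase exists only for I0 < 0")
    return -math.acos((1.0 + i0) / (1.0 - i0))


def unstable_phase(i0: float) -> float:
    """Unstable fixed point, the mirror image +arccos((1+I0)/(1-I0))."""
    if i0 >= 0:
        raise ValueError("unstable phase exists only for I0 < 0")
    return math.acos((1.0 + i0) / (1.0 - i0))


def _fixed_points(i0: float) -> tuple[float, float]:
    # For I0 >= 0 use the bifurcation limit theta_s = theta_u = 0: the whole
    # circle is escape arc and any rotation counts as seizure-like.
    if i0 < 0:
        return stable_phase(i0), unstable_phase(i0)
    return 0.0, 0.0


def seizure_classification(
    theta: np.ndarray, theta_s: float, i0: float
) -> np.ndarray:
    """Boolean ictal mask over a phase trajectory (ordered in time).

    A sample is seizure-like while the phase, within its current rotation
    cycle, sits on the escape arc past the unstable fixed point (progress
    from theta_s exceeding theta_u - theta_s) -- i.e. from the escape
    through the antipode until the rotation completes back at rest.  Cycle
    bookkeeping distinguishes a rotating phase approaching theta_s from a
    resting fluctuation just below it; for the first sample the circle is
    cut at the midpoint of the escape arc (the antipode of theta_s counts
    as ictal).
    """
    _, theta_u = _fixed_points(i0)
    arc = theta_u - theta_s
    two_pi = 2.0 * math.pi
    u = np.unwrap(np.atleast_1d(np.asarray(theta, dtype=float))) - theta_s
    u0 = u[0] % two_pi
    if u0 > math.pi + arc / 2.0:
        u0 -= two_pi
    u = u - u[0] + u0
    out = np.empty(u.size, dtype=bool)
    base = 0.0
    for k in range(u.size):
        rel = u[k] - base
        if rel >= two_pi:
            base += two_pi * math.floor(rel / two_pi)
            rel = u[k] - base
        elif rel <= arc - two_pi:
            base -= two_pi
            rel += two_pi
        out[k] = rel > arc
    return out


@njit(cache=True, fastmath=True)
def _integrate(w, i0, sigma_step, k_over_n, dt, n_steps, transient,
               theta_s, arc, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n = w.shape[0]
    theta = np.full(n, theta_s)  # unwrapped phases
    base = np.zeros(n)  # completed-rotation offset per node
    count = np.zeros(n, dtype=np.int64)
    out = np.empty(n)
    two_pi = 2.0 * math.pi
    for step in range(n_steps):
        for j in range(n):
            out[j] = 1.0 - math.cos(theta[j] - theta_s)
        for i in range(n):
            coup = 0.0
            for j in range(n):
                coup += w[j, i] * out[j]
            c = math.cos(theta[i])
            drift = (1.0 - c) + (1.0 + c) * (i0 + k_over_n * coup)
            theta[i] = (
                theta[i]
                + dt * drift
                + (1.0 + c) * sigma_step * np.random.normal(0.0, 1.0)
            )
        if not math.isfinite(theta[0]):
            for i in range(n):
                if not math.isfinite(theta[i]):
                    return count, step, i
        for i in range(n):
            # rotation bookkeeping on the unwrapped phase: a node is
            # seizure-like while its progress within the current cycle
            # exceeds the arc to the unstable point, until the rotation
            # completes back at the stable phase
            u = theta[i] - theta_s - base[i]
            if u >= two_pi:
                base[i] += two_pi * math.floor(u / two_pi)
                u = theta[i] - theta_s - base[i]
            elif u <= arc - two_pi:
                base[i] -= two_pi
                u += two_pi
            if step >= transient and u > arc:
                count[i] += 1
    return count, -1, -1


def simulate(net: FunctionalNetwork, params: ThetaModelParams) -> SimulationResult:
    """Euler-Maruyama simulation of the theta model on a functional network.

    Deterministic given ``params.seed``.  Raises ``RuntimeError`` if the
    state becomes non-finite (reports the step and node).
    """
    params.validate()
    w = np.ascontiguousarray(net.weights, dtype=np.float64)
    n = net.n_nodes
    n_norm = n if params.n_norm is None else int(params.n_norm)
    theta_s, theta_u = _fixed_points(params.i0)
    if params.noise_per_step:
        # noise draw treated as a constant input current over the step,
        # integrated like the rest of I (amplitude sigma*dt per step)
        sigma_step = params.noise_sd * params.dt
    else:
        sigma_step = params.noise_sd * math.sqrt(params.dt)
    count, err_step, err_node = _integrate(
        w,
        float(params.i0),
        float(sigma_step),
        float(params.k) / float(n_norm),
        float(params.dt),
        int(params.n_steps),
        int(params.resolved_transient()),
        theta_s,
        theta_u - theta_s,
        int(params.seed) % (2**32),
    )
    if err_step >= 0:
        raise RuntimeError(
            f"non-finite state at step {err_step}, node {err_node}"
        )
    n_eff = params.n_steps - params.resolved_transient()
    return SimulationResult(
        seizure_fraction=count / n_eff,
        params=replace(params),
        channel_labels=net.channel_labels,
    )
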