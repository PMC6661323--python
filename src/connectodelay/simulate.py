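"""Euler–Maruyama integration of delay-coupled oscillator networks.

The network equations are integrated on a dimensionless time grid where each
oscillator's natural frequency is ``omega0`` (1 rad per unit by default);
link delays in seconds are rescaled by ``2*pi*frequency_hz`` so that a node
oscillates at the target wall-clock frequency.  The coupling on node i is the
linear difference ``(1/N) sum_j K_ij [x_j(t - tau'_ij) - x_i(t)]``, read from
a ring-buffer history with each delay rounded to the nearest grid multiple.
Additive Gaussian noise of intensity D (standard deviation sqrt(2*D*dt) per
step) enters the same state components as the coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .connectome import Connectome, CouplingMatrix, DelayMatrix, delays_from_lengths
from .models import ModelSpec, model_drift

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "Trajectory",
    "IntegrationError",
    "dimensionless_delays",
    "coupling_input",
    "integrate",
]

_CHUNK = 8192


class IntegrationError(RuntimeError):
    """Raised when the integration produces NaN/Inf or violates a precondition."""


@dataclass(frozen=True)
class SimConfig:
    """Run settings for one integration, in dimensionless time units.

    ``noise_intensity`` is the dimensionless D of the Langevin equations; the
    pipeline layer converts wall-clock rates (s^-1) by dividing by
    ``2*pi*frequency_hz`` before building this object.  ``dt=None`` selects
    the largest step satisfying the delay-resolution and period-resolution
    preconditions.  ``t_transient=None`` discards the first 20% of ``t_total``.
    """

    frequency_hz: float
    t_total: float
    noise_intensity: float = 0.0
    dt: Optional[float] = None
    t_transient: Optional[float] = None
    seed: int = 0
    velocity: float = 5.0
    store_stride: Optional[int] = None

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be > 0")
        if self.noise_intensity < 0:
            raise ValueError("noise_intensity must be >= 0")
        if self.t_total <= 0:
            raise ValueError("t_total must be > 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        tt = self.transient
        if not (0 <= tt < self.t_total):
            raise ValueError("t_transient must lie in [0, t_total)")

    @property
    def transient(self) -> float:
        return 0.2 * self.t_total if self.t_transient is None else self.t_transient


@dataclass
class Trajectory:
    """Per-node state time series on a uniform (decimated) grid.

    ``t`` is dimensionless time, ``t_seconds`` the wall-clock grid
    (``t / (2*pi*f)``).  ``steady_start`` indexes the first sample at or after
    the transient; slicing helpers expose the analysis window.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: Optional[np.ndarray]
    dt: float
    stride: int
    frequency_hz: float
    steady_start: int
    model: ModelSpec
    config: SimConfig
    provenance: dict = field(default_factory=dict)

    @property
    def t_seconds(self) -> np.ndarray:
        return self.t / (2.0 * np.pi * self.frequency_hz)

    @property
    def dt_sample(self) -> float:
        """Dimensionless spacing of the stored grid."""
        return self.dt * self.stride

    @property
    def n_nodes(self) -> int:
        return self.x.shape[1]

    def steady(self, arr: Optional[np.ndarray] = None) -> np.ndarray:
        """Post-transient slice of ``arr`` (default: x)."""
        a = self.x if arr is None else arr
        return a[self.steady_start:]

    @property
    def t_steady(self) -> np.ndarray:
        return self.t[self.steady_start:]


def dimensionless_delays(tau: DelayMatrix | np.ndarray, frequency_hz: float) -> np.ndarray:
    """Rescale delays from seconds to dimensionless time: tau' = tau * 2*pi*f."""
    if frequency_hz <= 0:
        raise ValueError("frequency_hz must be > 0")
    t = tau.tau if isinstance(tau, DelayMatrix) else np.asarray(tau, dtype=float)
    return t * (2.0 * np.pi * frequency_hz)


def coupling_input(
    history: np.ndarray,
    pos: int,
    lags: np.ndarray,
    K: CouplingMatrix | np.ndarray,
    x_now: np.ndarray,
) -> np.ndarray:
    """Linear-difference coupling c_i = (1/N) sum_j K_ij [x_j(t - tau'_ij) - x_i].

    ``history`` is the ring buffer (L, N) with ``history[pos] == x(t)``;
    ``lags`` the integer delay of each link in steps.  Raises if any lag
    exceeds the buffer capacity.
    """
    k = K.k if isinstance(K, CouplingMatrix) else np.asarray(K, dtype=float)
    L, n = history.shape
    lags = np.asarray(lags)
    if lags.max(initial=0) >= L:
        raise IntegrationError(
            f"history of length {L} too short for max lag {int(lags.max())}"
        )
    rows = (pos - lags) % L
    delayed = history[rows, np.arange(n)[None, :]]  # delayed[i, j] = x_j(t - tau_ij)
    return (k * delayed).sum(axis=1) / n - k.sum(axis=1) / n * x_now


def _settle_periods(kind: str) -> float:
    return {"ls": 10.0, "vdp": 40.0, "rossler": 80.0}[kind]


def _initial_states(spec: ModelSpec, phases: np.ndarray, dt: float) -> np.ndarray:
    """Each node on/near its uncoupled attractor at a random phase.

    Landau–Stuart starts exactly on the unit circle; van der Pol and Rössler
    start on a circle of plausible radius and are settled onto the attractor
    by integrating the uncoupled deterministic flow.
    """
    n = phases.shape[0]
    state = np.zeros((n, spec.state_dim))
    if spec.kind == "ls":
        state[:, 0] = np.cos(phases)
        state[:, 1] = np.sin(phases)
        return state
    if spec.kind == "vdp":
        amp = 2.0 / np.sqrt(max(spec.beta, 1e-12))
        state[:, 0] = amp * spec.omega0 * np.cos(phases)
        state[:, 1] = amp * np.sin(phases)
    else:  # rossler
        state[:, 0] = 5.0 * np.cos(phases)
        state[:, 1] = 5.0 * np.sin(phases)
        state[:, 2] = 0.02
    t_settle = _settle_periods(spec.kind) * 2.0 * np.pi / spec.omega0
    for _ in range(int(np.ceil(t_settle / dt))):
        state = state + dt * model_drift(spec, state, 0.0, 0.0)
    return state


def _auto_dt(spec: ModelSpec, tau_prime: np.ndarray, linked: np.ndarray) -> float:
    # The Rössler z-spikes are much faster than the cycle itself; a step that
    # resolves only the period collapses the chaotic attractor onto a
    # periodic orbit (checked via the largest Lyapunov exponent).
    steps_per_period = 1600.0 if spec.kind == "rossler" else 256.0
    dt = 2.0 * np.pi / (spec.omega0 * steps_per_period)
    nz = tau_prime[linked & (tau_prime > 0)]
    if nz.size:
        dt = min(dt, float(nz.min()) / 4.0)
    return dt


def _check_dt(dt: float, spec: ModelSpec, tau_prime: np.ndarray, linked: np.ndarray) -> None:
    if dt > 2.0 * np.pi / (spec.omega0 * 200.0) * (1 + 1e-12):
        raise IntegrationError(
            f"dt={dt:g} resolves fewer than 200 steps per natural period"
        )
    nz = tau_prime[linked & (tau_prime > 0)]
    if nz.size and dt > float(nz.min()) / 4.0 * (1 + 1e-12):
        raise IntegrationError(
            f"dt={dt:g} exceeds a quarter of the smallest link delay "
            f"({float(nz.min()):g})"
        )


def integrate(
    conn: Connectome,
    K: CouplingMatrix,
    spec: ModelSpec,
    cfg: SimConfig,
    tau_prime: Optional[np.ndarray] = None,
    use_numba: bool = True,
    initial_phases: Optional[np.ndarray] = None,
) -> Trajectory:
    """Integrate the delay-coupled network and return a (decimated) Trajectory.

    The state is recorded every ``store_stride`` steps (default: about 32
    samples per natural period).  The transient portion is retained in the
    returned arrays; ``Trajectory.steady_start`` marks the analysis window.
    ``initial_phases`` overrides the seeded uniform draw of the per-node
    attractor phases (useful for controlled experiments).
    """
    n = conn.n_nodes
    if K.k.shape != (n, n):
        raise ValueError("coupling matrix size does not match connectome")
    if tau_prime is None:
        tau = delays_from_lengths(conn, cfg.velocity)
        tau_prime = dimensionless_delays(tau, cfg.frequency_hz)
    linked = K.k > 0
    dt = cfg.dt if cfg.dt is not None else _auto_dt(spec, tau_prime, linked)
    _check_dt(dt, spec, tau_prime, linked)

    lags = np.zeros((n, n), dtype=np.int64)
    lags[linked] = np.rint(tau_prime[linked] / dt).astype(np.int64)
    L = int(lags.max()) + 1

    stride = cfg.store_stride or max(
        1, int(round(2.0 * np.pi / spec.omega0 / 32.0 / dt))
    )
    n_steps = int(round(cfg.t_total / dt))
    n_out = n_steps // stride + 1

    dst, src = np.nonzero(linked)
    kw = (K.k[dst, src] / n).astype(np.float64)
    lag_l = lags[dst, src]
    ksum = K.k.sum(axis=1) / n

    rng = np.random.default_rng(cfg.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if initial_phases is not None:
        phases = np.asarray(initial_phases, dtype=float)
        if phases.shape != (n,):
            raise ValueError(f"initial_phases must have shape ({n},)")
    state = _initial_states(spec, phases, dt)

    # Fill the delay history by running the uncoupled deterministic flow
    # forward for L-1 steps; H[L-1] is the state at t=0.
    is_ls = spec.kind == "ls"
    Hx = np.empty((L, n))
    Hy = np.empty((L, n)) if is_ls else np.empty((1, n))
    hist_states = np.empty((L, n, spec.state_dim))
    hist_states[0] = state
    for step in range(1, L):
        state = state + dt * model_drift(spec, state, 0.0, 0.0)
        hist_states[step] = state
    Hx[:, :] = hist_states[:, :, 0]
    if is_ls:
        Hy[:, :] = hist_states[:, :, 1]
    pos = L - 1

    x = np.ascontiguousarray(state[:, 0])
    y = np.ascontiguousarray(state[:, 1])
    z = np.ascontiguousarray(state[:, 2]) if spec.kind == "rossler" else None

    out_x = np.empty((n_out, n))
    out_y = np.empty((n_out, n))
    out_z = np.empty((n_out, n)) if z is not None else None
    out_x[0], out_y[0] = x, y
    if out_z is not None:
        out_z[0] = z

    sigma = np.sqrt(2.0 * cfg.noise_intensity * dt)
    ncomp = spec.n_noise_components
    fast = use_numba and _kernels.NUMBA_AVAILABLE

    g = 0
    while g < n_steps:
        chunk = min(_CHUNK, n_steps - g)
        shape = (chunk, n, 2) if ncomp == 2 else (chunk, n)
        noise = rng.standard_normal(shape)
        if fast:
            pos = _run_chunk_numba(
                spec, Hx, Hy, pos, x, y, z, src, dst, lag_l, kw, ksum,
                dt, sigma, noise, out_x, out_y, out_z, g, stride,
            )
        else:
            pos = _run_chunk_numpy(
                spec, Hx, Hy, pos, x, y, z, lags, K.k, dt, sigma, noise,
                out_x, out_y, out_z, g, stride,
            )
        g += chunk
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise IntegrationError(f"non-finite state at step {g} (t={g * dt:g})")

    t_grid = np.arange(n_out) * (dt * stride)
    steady_start = int(np.searchsorted(t_grid, cfg.transient))
    prov = {
        "connectome": conn.fingerprint(),
        "model": spec.kind,
        "dt": dt,
        "stride": stride,
        "seed": cfg.seed,
        "frequency_hz": cfg.frequency_hz,
        "noise_intensity": cfg.noise_intensity,
        "global_coupling": K.global_coupling,
        "kernel": "numba" if fast else "numpy",
    }
    return Trajectory(
        t=t_grid, x=out_x, y=out_y, z=out_z, dt=dt, stride=stride,
        frequency_hz=cfg.frequency_hz, steady_start=steady_start,
        model=spec, config=cfg, provenance=prov,
    )


def _run_chunk_numba(spec, Hx, Hy, pos, x, y, z, src, dst, lag_l, kw, ksum,
                     dt, sigma, noise, out_x, out_y, out_z, g0, stride):
    if spec.kind == "rossler":
        return _kernels.rossler_chunk(
            Hx, pos, x, y, z, src, dst, lag_l, kw, ksum,
            spec.a, spec.b, spec.c, spec.omega0, dt, sigma, noise,
            out_x, out_y, out_z, g0, stride,
        )
    if spec.kind == "vdp":
        return _kernels.vdp_chunk(
            Hx, pos, x, y, src, dst, lag_l, kw, ksum,
            spec.m, spec.beta, spec.omega0, spec.literal_vdp, dt, sigma, noise,
            out_x, out_y, g0, stride,
        )
    return _kernels.ls_chunk(
        Hx, Hy, pos, x, y, src, dst, lag_l, kw, ksum,
        spec.q, spec.omega0, dt, sigma, noise,
        out_x, out_y, g0, stride,
    )


def _run_chunk_numpy(spec, Hx, Hy, pos, x, y, z, lags, kmat, dt, sigma, noise,
                     out_x, out_y, out_z, g0, stride):
    """Reference chunk stepper; same stream and storage semantics as the
    compiled kernels, built on :func:`coupling_input` and
    :func:`~connectodelay.models.model_drift`."""
    n = x.shape[0]
    L = Hx.shape[0]
    is_ls = spec.kind == "ls"
    for s in range(noise.shape[0]):
        cx = coupling_input(Hx, pos, lags, kmat, x)
        cy = coupling_input(Hy, pos, lags, kmat, y) if is_ls else None
        if spec.kind == "rossler":
            state = np.stack([x, y, z], axis=1)
        else:
            state = np.stack([x, y], axis=1)
        d = model_drift(spec, state, cx, cy)
        if is_ls:
            x += dt * d[:, 0] + sigma * noise[s, :, 0]
            y += dt * d[:, 1] + sigma * noise[s, :, 1]
        else:
            x += dt * d[:, 0] + sigma * noise[s, :]
            y += dt * d[:, 1]
            if z is not None:
                z += dt * d[:, 2]
        pos = (pos + 1) % L
        Hx[pos] = x
        if is_ls:
            Hy[pos] = y
        g = g0 + s + 1
        if g % stride == 0:
            k = g // stride
            out_x[k] = x
            out_y[k] = y
            if out_z is not None:
                out_z[k] = z
    return pos
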