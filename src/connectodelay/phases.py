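"""Phase extraction and mean-field analysis.

The pipeline from raw trajectories to proper phases has two stages.  First a
*protophase* is read off each node's (x, y) plane as the quadrant-correct,
unwrapped angle about the orbit's time-mean centre.  A protophase winds once
per cycle but grows non-uniformly around a distorted limit cycle, which would
bias circular statistics; the second stage therefore applies the standard
protophase-to-phase transformation — average the inverse angular velocity in
bins of the protophase, integrate, and normalise — producing a phase that by
construction grows uniformly on average while preserving each node's mean
frequency.

On top of the phases: per-hemisphere Kuramoto order parameters (synchrony
level r and mean-field phase Psi), the entrainment frequency Omega (slope of
the unwrapped mean-field phase), rotating-frame relative phases, a
synchronized/drifting classification, RMS amplitudes and amplitude spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .simulate import Trajectory

__all__ = [
    "ProtophaseSeries",
    "PhaseSeries",
    "MeanField",
    "EmptyBinError",
    "protophase",
    "protophase_from_xy",
    "protophase_to_phase",
    "order_parameter",
    "mean_frequency",
    "rotating_frame",
    "classify_synchronized",
    "amplitude_metric",
    "power_spectrum",
    "peak_frequency",
    "circular_mean",
    "circular_var",
    "wrap_angle",
]


class EmptyBinError(ValueError):
    """A protophase bin received no samples (too little data for n_bins)."""


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)


def circular_mean(a: np.ndarray, axis=None) -> np.ndarray | float:
    return np.angle(np.exp(1j * np.asarray(a)).mean(axis=axis))


def circular_var(a: np.ndarray, axis=None) -> np.ndarray | float:
    """Circular variance 1 - R (resultant length), in [0, 1]."""
    return 1.0 - np.abs(np.exp(1j * np.asarray(a)).mean(axis=axis))


@dataclass
class ProtophaseSeries:
    """Unwrapped per-node protophases on the trajectory's steady grid."""

    phi: np.ndarray  # (T, N), rad, unwrapped
    t: np.ndarray  # (T,), dimensionless


@dataclass
class PhaseSeries:
    """Uniformly-growing per-node phases plus the protophase->phase tables.

    ``table_edges`` (n_bins+1,) and ``table_theta`` (N, n_bins+1) give each
    node's monotone map evaluated at the protophase bin edges on [0, 2*pi];
    the map extends periodically (theta(phi + 2*pi) = theta(phi) + 2*pi).
    """

    theta: np.ndarray  # (T, N), rad, unwrapped
    t: np.ndarray
    table_edges: np.ndarray
    table_theta: np.ndarray


@dataclass
class MeanField:
    """Hemispheric (and pooled) Kuramoto order parameters over time.

    ``r[g]`` is the synchrony level in [0, 1] and ``psi[g]`` the unwrapped
    mean-field phase for group ``g`` in {"L", "R", "global"}.
    """

    t: np.ndarray
    r: dict = field(default_factory=dict)
    psi: dict = field(default_factory=dict)

    def r_mean(self, group: str = "global") -> float:
        return float(self.r[group].mean())


def protophase_from_xy(
    x: np.ndarray, y: np.ndarray, center: bool = True
) -> np.ndarray:
    """Unwrapped quadrant-correct angle of (x, y), optionally about the
    time-mean centre (columns are nodes)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
        y = y[:, None]
    if center:
        x = x - x.mean(axis=0)
        y = y - y.mean(axis=0)
    radius = np.hypot(x, y)
    if np.any(radius.max(axis=0) < 1e-12):
        raise ValueError("trajectory collapsed to a point: angle undefined")
    return np.unwrap(np.arctan2(y, x), axis=0)


def protophase(traj: Trajectory, center: bool = True, min_cycles: float = 10.0) -> ProtophaseSeries:
    """Protophases of all nodes over the post-transient window."""
    x = traj.steady(traj.x)
    y = traj.steady(traj.y)
    phi = protophase_from_xy(x, y, center=center)
    cycles = (phi[-1] - phi[0]) / (2.0 * np.pi)
    if np.any(cycles < min_cycles):
        raise ValueError(
            f"need at least {min_cycles} cycles post-transient; "
            f"minimum over nodes is {cycles.min():.2f}"
        )
    return ProtophaseSeries(phi=phi, t=traj.t_steady.copy())


def protophase_to_phase(phi: ProtophaseSeries, n_bins: int = 64) -> PhaseSeries:
    """Transform protophases to uniformly-growing phases.

    Per node: estimate the angular velocity by finite differences, average
    its reciprocal in ``n_bins`` bins of phi mod 2*pi, integrate the binned
    profile into a monotone 2*pi-periodic-compatible map (linear between bin
    edges), and rescale the resulting series so its total growth equals the
    protophase's (mean-frequency preservation).
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    ph = np.atleast_2d(phi.phi.T).T  # (T, N)
    t = phi.t
    T, N = ph.shape
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    width = edges[1] - edges[0]
    theta = np.empty_like(ph)
    table = np.empty((N, n_bins + 1))
    phidot = np.gradient(ph, t, axis=0)
    for i in range(N):
        psi = np.mod(ph[:, i], 2.0 * np.pi)
        idx = np.minimum((psi / width).astype(int), n_bins - 1)
        inv = 1.0 / phidot[:, i]
        counts = np.bincount(idx, minlength=n_bins)
        if np.any(counts == 0):
            raise EmptyBinError(
                f"node {i}: {int((counts == 0).sum())} empty protophase bins "
                f"at n_bins={n_bins}; use more data or fewer bins"
            )
        w = np.bincount(idx, weights=inv, minlength=n_bins) / counts
        # retrograde samples would make the map non-monotone; floor the
        # binned weights at a small positive value
        floor = 1e-6 * np.median(np.abs(w))
        w = np.maximum(w, floor)
        F = np.concatenate([[0.0], np.cumsum(w) * width])
        F_tot = F[-1]
        table[i] = 2.0 * np.pi * F / F_tot
        k = np.floor(ph[:, i] / (2.0 * np.pi))
        frac = F[idx] + w[idx] * (psi - edges[idx])
        th = 2.0 * np.pi * (k + frac / F_tot)
        # exact mean-frequency preservation over the series
        growth = th[-1] - th[0]
        if growth != 0.0:
            th = th[0] + (th - th[0]) * ((ph[-1, i] - ph[0, i]) / growth)
        theta[:, i] = th
    return PhaseSeries(theta=theta, t=t.copy(), table_edges=edges, table_theta=table)


def order_parameter(
    theta: PhaseSeries | np.ndarray,
    labels: Optional[np.ndarray] = None,
    t: Optional[np.ndarray] = None,
) -> MeanField:
    """Complex order parameter r*exp(i*Psi) per hemisphere and pooled.

    ``r`` is the modulus of the mean unit phasor over the group's nodes,
    ``Psi`` its unwrapped argument.
    """
    if isinstance(theta, PhaseSeries):
        th, t = theta.theta, theta.t
    else:
        th = np.asarray(theta)
        if t is None:
            t = np.arange(th.shape[0], dtype=float)
    zc = np.exp(1j * th)
    groups: dict[str, np.ndarray] = {"global": np.ones(th.shape[1], dtype=bool)}
    if labels is not None:
        labels = np.asarray(labels)
        for g in ("L", "R"):
            m = labels == g
            if m.any():
                groups[g] = m
    mf = MeanField(t=np.asarray(t))
    for g, m in groups.items():
        if not m.any():
            raise ValueError(f"group {g!r} has no nodes")
        zm = zc[:, m].mean(axis=1)
        mf.r[g] = np.abs(zm)
        mf.psi[g] = np.unwrap(np.angle(zm))
    return mf


def mean_frequency(
    mf: MeanField,
    which: str = "hemispheres",
    min_cycles: float = 5.0,
) -> float:
    """Entrainment frequency Omega: least-squares slope of the unwrapped
    mean-field phase over the steady segment.

    ``which="hemispheres"`` (default) averages the two hemispheric slopes;
    a group name ("L", "R", "global") selects that slope alone.
    """
    def slope(g: str) -> float:
        psi = mf.psi[g]
        cycles = abs(psi[-1] - psi[0]) / (2.0 * np.pi)
        if cycles < min_cycles:
            raise ValueError(
                f"segment spans only {cycles:.2f} cycles of group {g!r}; "
                f"need >= {min_cycles}"
            )
        return float(np.polyfit(mf.t, psi, 1)[0])

    if which == "hemispheres":
        gs = [g for g in ("L", "R") if g in mf.psi] or ["global"]
        return float(np.mean([slope(g) for g in gs]))
    return slope(which)


def rotating_frame(theta: np.ndarray, t: np.ndarray, Omega: float) -> np.ndarray:
    """Relative phases theta_i - Omega*t (bounded for locked nodes)."""
    theta = np.asarray(theta)
    return theta - Omega * np.asarray(t)[:, None] if theta.ndim == 2 else theta - Omega * t


def classify_synchronized(
    theta: PhaseSeries,
    mf: MeanField,
    Omega: float,
    labels: np.ndarray,
    drift_max: float = 2.0 * np.pi,
    circ_var_max: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node synchronized flag and circular-mean relative phase.

    A node counts as synchronized when its net rotating-frame drift over the
    steady segment — |relative phase at the end minus at the start| — stays
    below ``drift_max`` (default one full turn) and the circular variance of
    theta_i - Psi (its own hemisphere's mean field) is below
    ``circ_var_max``.  The net drift rather than the total excursion is used
    because under the operating noise level a locked node occasionally slips
    by 2*pi and relocks; a single slip (or a steady frequency offset) still
    disqualifies a node, but transient balanced slips do not.  The mean
    relative phase is the circular mean of theta_i - Psi.
    """
    labels = np.asarray(labels)
    rel = rotating_frame(theta.theta, theta.t, Omega)
    drift = np.abs(rel[-1] - rel[0])
    n = theta.theta.shape[1]
    sync = np.zeros(n, dtype=bool)
    mean_rel = np.zeros(n)
    for i in range(n):
        g = labels[i] if labels[i] in mf.psi else "global"
        d = theta.theta[:, i] - mf.psi[g]
        # the (1 - 1e-9) margin makes a single exact 2*pi slip count as drift
        sync[i] = (drift[i] < drift_max * (1.0 - 1e-9)) and (
            circular_var(d) < circ_var_max
        )
        mean_rel[i] = circular_mean(d)
    return sync, mean_rel


def amplitude_metric(x: np.ndarray) -> np.ndarray:
    """Per-node RMS of x about its mean (columns are nodes)."""
    x = np.asarray(x, dtype=float)
    return np.sqrt(((x - x.mean(axis=0)) ** 2).mean(axis=0))


def power_spectrum(
    x: np.ndarray, dt_seconds: float, window: str = "hann"
) -> tuple[np.ndarray, np.ndarray]:
    """Tapered amplitude spectrum of each column of x; returns (freqs_hz, amp)."""
    x = np.asarray(x, dtype=float)
    freqs, pxx = signal.periodogram(
        x, fs=1.0 / dt_seconds, window=window, axis=0, scaling="spectrum",
        detrend="constant",
    )
    return freqs, np.sqrt(pxx)


def peak_frequency(freqs: np.ndarray, amp: np.ndarray) -> np.ndarray:
    """Frequency of the largest spectral amplitude, per column."""
    amp = np.atleast_2d(amp.T).T
    return freqs[np.argmax(amp, axis=0)]
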