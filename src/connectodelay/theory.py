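"""Analytic phase prediction and synchronization condition.

For a two-cluster (hemispheric) network of phase oscillators with a bimodal
delay structure — weighted mean intra-hemispheric delay tau_int and
inter-hemispheric delay tau_ext — the stationary phase of a synchronized node
relative to its hemisphere's mean field is

    <theta_i> = arcsin((omega0 - Omega) / (K_i r cos(Omega dtau))) - Omega ttau

with dtau = (tau_ext - tau_int)/2, ttau = (tau_ext + tau_int)/2, r the
hemispheric synchrony level, Omega the entrainment frequency and K_i the
node's effective coupling strength (here: its per-node mean coupling,
(1/N) sum_j K_ij, in the same rate units as omega0 and Omega).  A node can
lock only when

    |omega0 - Omega| <= K_i r cos(Omega dtau),

and the network settles into anti-phase locking between the hemispheres when
Omega tau_ext lies in the left complex half-plane (cos(Omega tau_ext) < 0).

All quantities are evaluated in wall-clock units: omega0 = 2*pi*f rad/s,
delays in seconds, K_i in rad/s; r and Omega are measured from simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .phases import circular_mean, wrap_angle

__all__ = [
    "TheoryInputs",
    "TheoryPrediction",
    "predicted_phase",
    "sync_condition",
    "antiphase_regime",
    "theory_vs_simulation",
]


@dataclass(frozen=True)
class TheoryInputs:
    """Inputs of the analytic prediction, in mutually consistent units.

    ``strengths`` and ``r`` are per-node (each node uses its own hemisphere's
    synchrony level); ``delta_tau`` and ``tau_tilde`` are the half-difference
    and midpoint of the weighted external/internal delay means.
    """

    omega0: float
    Omega: float
    r: np.ndarray
    strengths: np.ndarray
    delta_tau: float
    tau_tilde: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        s = np.asarray(self.strengths, dtype=float)
        if r.shape != s.shape:
            raise ValueError("r and strengths must have the same shape")
        if np.any((r < 0) | (r > 1)):
            raise ValueError("r must lie in [0, 1]")
        if not np.isfinite(self.Omega):
            raise ValueError("Omega must be finite")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "strengths", s)


@dataclass
class TheoryPrediction:
    """Predicted mean phases (NaN where undefined), lockability and regime."""

    mean_phase: np.ndarray
    synchronized: np.ndarray
    regime: str


def _arcsin_argument(inp: TheoryInputs) -> np.ndarray:
    denom = inp.strengths * inp.r * np.cos(inp.Omega * inp.delta_tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0.0, (inp.omega0 - inp.Omega) / denom, np.inf)


def predicted_phase(inp: TheoryInputs) -> np.ndarray:
    """Predicted mean relative phase per node; NaN where the arcsin argument
    leaves [-1, 1] (node not lockable at these parameters)."""
    if abs(np.cos(inp.Omega * inp.delta_tau)) < 1e-12:
        raise ZeroDivisionError("cos(Omega * delta_tau) = 0: prediction undefined")
    arg = _arcsin_argument(inp)
    out = np.full(arg.shape, np.nan)
    ok = np.abs(arg) <= 1.0
    out[ok] = np.arcsin(arg[ok]) - inp.Omega * inp.tau_tilde
    return out


def sync_condition(inp: TheoryInputs) -> np.ndarray:
    """Lockability per node: |omega0 - Omega| <= K_i r cos(Omega delta_tau)
    (boundary included)."""
    rhs = inp.strengths * inp.r * np.cos(inp.Omega * inp.delta_tau)
    return np.abs(inp.omega0 - inp.Omega) <= rhs


def antiphase_regime(Omega: float, tau_ext: float) -> str:
    """Locking regime between the hemispheres.

    ``"anti_phase"`` when Omega*tau_ext falls in the left complex half-plane
    (cos < 0, i.e. Omega*tau_ext mod 2*pi in (pi/2, 3*pi/2)); ``"in_phase"``
    otherwise.
    """
    if tau_ext < 0:
        raise ValueError("tau_ext must be >= 0")
    return "anti_phase" if np.cos(Omega * tau_ext) < 0.0 else "in_phase"


def theory_vs_simulation(
    sim_phases: np.ndarray,
    sim_sync: np.ndarray,
    prediction: TheoryPrediction | np.ndarray,
    min_nodes: int = 3,
) -> dict:
    """Circular RMSE (after optimal common rotation) and Spearman rank
    agreement between simulated and predicted mean relative phases.

    Only nodes that are synchronized in the simulation and have a defined
    prediction enter the comparison; the common rotation absorbs the
    arbitrary mean-field phase offset.
    """
    pred = prediction.mean_phase if isinstance(prediction, TheoryPrediction) else np.asarray(prediction)
    sim_phases = np.asarray(sim_phases)
    sel = np.asarray(sim_sync, dtype=bool) & np.isfinite(pred)
    if sel.sum() < min_nodes:
        raise ValueError(
            f"only {int(sel.sum())} synchronized nodes with defined "
            f"prediction; need >= {min_nodes}"
        )
    d = sim_phases[sel] - pred[sel]
    rot = circular_mean(d)
    resid = wrap_angle(d - rot)
    rmse = float(np.sqrt(np.mean(resid**2)))
    ws = wrap_angle(sim_phases[sel] - circular_mean(sim_phases[sel]))
    wp = wrap_angle(pred[sel] - circular_mean(pred[sel]))
    rho = spearmanr(ws, wp).statistic
    return {
        "circular_rmse": rmse,
        "spearman_rho": float(rho),
        "n_nodes": int(sel.sum()),
        "rotation": float(rot),
    }
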