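"""Local node models: Rössler, van der Pol and Landau–Stuart oscillators.

All three are self-sustained oscillators with a parameter ``omega0`` setting
the natural angular frequency in dimensionless time (1 rad per time unit by
default); wall-clock frequency is obtained downstream by rescaling time with
2*pi*f.  The coupling enters as a linear difference of delayed states — on
the first variable for Rössler and van der Pol, on both components (the
complex state) for Landau–Stuart — and additive Gaussian white noise enters
the same components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelSpec", "model_drift", "natural_frequency", "MODEL_KINDS"]

MODEL_KINDS = ("rossler", "vdp", "ls")


@dataclass(frozen=True)
class ModelSpec:
    """Oscillator kind and parameters.

    Parameters
    ----------
    kind : {"rossler", "vdp", "ls"}
    a, b, c : float
        Rössler parameters; defaults (0.2, 0.2, 5.7) put the uncoupled
        oscillator in the chaotic regime.
    m : float
        van der Pol nonlinearity (0 = harmonic oscillator, <<1 quasi-linear).
    beta : float
        van der Pol amplitude parameter (unit-amplitude convention).
    q : float
        Landau–Stuart non-isochronicity (0 = isochronous).
    omega0 : float
        Natural angular frequency, rad per dimensionless time unit.
    literal_vdp : bool
        If True, use the restoring term ``-omega0**2 * x`` exactly as some
        sources print it (which has no restoring force and cannot oscillate);
        the default uses the standard Liénard form ``-omega0**2 * y``.
    """

    kind: str = "ls"
    a: float = 0.2
    b: float = 0.2
    c: float = 5.7
    m: float = 0.75
    beta: float = 1.0
    q: float = 0.5
    omega0: float = 1.0
    literal_vdp: bool = False

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; use {MODEL_KINDS}")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be > 0")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        for name in ("a", "b", "c", "m", "beta", "q", "omega0"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} is not finite")

    @property
    def state_dim(self) -> int:
        return 3 if self.kind == "rossler" else 2

    @property
    def n_noise_components(self) -> int:
        """Number of state components receiving noise (and coupling)."""
        return 2 if self.kind == "ls" else 1


def model_drift(
    spec: ModelSpec,
    state: np.ndarray,
    cx: np.ndarray,
    cy: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic drift for per-node states.

    ``state`` has shape (n_nodes, state_dim); ``cx`` is the coupling input to
    the first variable and ``cy`` (Landau–Stuart only) to the second.
    Returns an array of the same shape as ``state``.
    """
    state = np.asarray(state, dtype=float)
    if state.ndim == 1:
        state = state[None, :]
        squeeze = True
    else:
        squeeze = False
    if state.shape[1] != spec.state_dim:
        raise ValueError(
            f"state dimension {state.shape[1]} != {spec.state_dim} for {spec.kind}"
        )
    cx = np.broadcast_to(np.asarray(cx, dtype=float), state.shape[0])
    out = np.empty_like(state)
    x, y = state[:, 0], state[:, 1]
    w0 = spec.omega0
    if spec.kind == "rossler":
        z = state[:, 2]
        out[:, 0] = -w0 * y - z + cx
        out[:, 1] = w0 * x + spec.a * y
        out[:, 2] = spec.b + z * (x - spec.c)
    elif spec.kind == "vdp":
        restore = x if spec.literal_vdp else y
        out[:, 0] = 2.0 * spec.m * (1.0 - spec.beta * y**2) * x - w0**2 * restore + cx
        out[:, 1] = x
    else:  # ls
        if cy is None:
            cy = np.zeros_like(cx)
        cy = np.broadcast_to(np.asarray(cy, dtype=float), state.shape[0])
        r2 = x**2 + y**2
        # complex form: dX/dt = X[(1 + i*w0) - (1 + i*q)|X|^2] + C
        out[:, 0] = x * (1.0 - r2) - y * (w0 - spec.q * r2) + cx
        out[:, 1] = y * (1.0 - r2) + x * (w0 - spec.q * r2) + cy
    return out[0] if squeeze else out


from functools import lru_cache


@lru_cache(maxsize=32)
def natural_frequency(spec: ModelSpec, n_periods: float = 200.0,
                      dt: float = 0.005) -> float:
    """Principal angular frequency (rad per dimensionless unit) of the
    uncoupled, noiseless oscillator.

    This is what the wall-clock time rescaling must map onto ``2*pi*f``: the
    limit-cycle rotation rate generally differs from ``omega0`` (for
    Landau–Stuart it is exactly ``omega0 - q`` on the unit-amplitude cycle;
    the nonlinear damping of van der Pol and the chaotic Rössler dynamics
    shift it as well).  Landau–Stuart is returned in closed form; the other
    two are measured as the mean winding rate of the centred (x, y) angle over
    ``n_periods`` natural periods after discarding a settling transient.
    """
    if spec.kind == "ls":
        return spec.omega0 - spec.q
    state = np.array([[2.0, 0.0]] if spec.kind == "vdp" else [[5.0, 0.0, 0.02]])
    t_settle = 50.0 * 2.0 * np.pi / spec.omega0
    for _ in range(int(t_settle / dt)):
        state = state + dt * model_drift(spec, state, 0.0)
    n = int(n_periods * 2.0 * np.pi / spec.omega0 / dt)
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        state = state + dt * model_drift(spec, state, 0.0)
        xs[i], ys[i] = state[0, 0], state[0, 1]
    ang = np.unwrap(np.arctan2(ys - ys.mean(), xs - xs.mean()))
    return float((ang[-1] - ang[0]) / ((n - 1) * dt))
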