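"""Structural connectome container and derived network quantities.

A connectome here is a weighted undirected graph over cortical regions:
``weights`` holds streamline counts between region pairs, ``tract_lengths``
the mean white-matter tract length in millimetres, and every region carries a
hemisphere label (``L`` or ``R``).  From these we derive the coupling matrix
(global coupling constant times the weights), per-link propagation delays
(length over conduction velocity), per-node strengths and the weighted
intra-/inter-hemispheric delay summary that parameterises the analytic phase
prediction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "CouplingMatrix",
    "DelayMatrix",
    "DelaySummary",
    "ConnectomeError",
    "DimensionMismatchError",
    "NegativeEntryError",
    "MissingLabelError",
    "ZeroWeightsError",
    "NoLinksError",
    "load_connectome",
    "write_connectome",
    "delays_from_lengths",
    "coupling_matrix",
    "node_strengths",
    "effective_strengths",
    "delay_summary",
    "hemisphere_mask",
]


class ConnectomeError(ValueError):
    """Base class for connectome validation failures."""


class DimensionMismatchError(ConnectomeError):
    """Matrices / label vector do not agree in size, or a matrix is not square."""


class NegativeEntryError(ConnectomeError):
    """A weight or tract length is negative."""


class MissingLabelError(ConnectomeError):
    """A hemisphere label is absent or not in {L, R}."""


class ZeroWeightsError(ConnectomeError):
    """The weight matrix has no non-zero entry (normalisation undefined)."""


class NoLinksError(ConnectomeError):
    """A required link class (intra- or inter-hemispheric) is empty."""


def _symmetrize(a: np.ndarray, name: str) -> np.ndarray:
    if not np.allclose(a, a.T, rtol=1e-12, atol=0.0):
        warnings.warn(
            f"{name} matrix is not symmetric; symmetrizing as (A + A.T)/2",
            stacklevel=3,
        )
        a = (a + a.T) / 2.0
    else:
        a = (a + a.T) / 2.0  # remove rounding asymmetry silently
    return a


@dataclass(frozen=True)
class Connectome:
    """Validated structural connectome.

    Attributes
    ----------
    weights : ndarray (n, n)
        Symmetric, non-negative streamline counts; zero diagonal.
    tract_lengths : ndarray (n, n)
        Symmetric, non-negative tract lengths in mm; positive wherever a
        weight is positive.
    hemisphere : ndarray (n,) of str
        Per-node label, ``"L"`` or ``"R"``.
    """

    weights: np.ndarray
    tract_lengths: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        lg = np.asarray(self.tract_lengths, dtype=float)
        labels = np.asarray(self.hemisphere)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionMismatchError(f"weights must be square, got {w.shape}")
        if lg.shape != w.shape:
            raise DimensionMismatchError(
                f"tract_lengths shape {lg.shape} != weights shape {w.shape}"
            )
        if labels.shape != (w.shape[0],):
            raise DimensionMismatchError(
                f"{labels.shape[0] if labels.ndim == 1 else labels.shape} labels "
                f"for {w.shape[0]} nodes"
            )
        for name, a in (("weights", w), ("tract_lengths", lg)):
            if np.any(a < 0):
                i, j = np.argwhere(a < 0)[0]
                raise NegativeEntryError(f"negative {name} entry at ({i}, {j})")
            if not np.allclose(a, a.T, rtol=1e-9, atol=1e-12):
                raise ConnectomeError(f"{name} matrix is not symmetric")
        bad = ~np.isin(labels, ("L", "R"))
        if bad.any():
            raise MissingLabelError(
                f"hemisphere label of node {int(np.argwhere(bad)[0][0])} "
                "is not 'L' or 'R'"
            )
        if np.any((w > 0) & (lg <= 0) & ~np.eye(w.shape[0], dtype=bool)):
            i, j = np.argwhere((w > 0) & (lg <= 0))[0]
            raise ConnectomeError(
                f"link ({i}, {j}) has positive weight but non-positive length"
            )
        w = w.copy()
        lg = lg.copy()
        np.fill_diagonal(w, 0.0)
        np.fill_diagonal(lg, 0.0)
        w.setflags(write=False)
        lg.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "tract_lengths", lg)
        object.__setattr__(self, "hemisphere", labels.astype("U1"))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def fingerprint(self) -> str:
        """Short content hash used in run provenance."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.weights).tobytes())
        h.update(np.ascontiguousarray(self.tract_lengths).tobytes())
        h.update("".join(self.hemisphere).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class CouplingMatrix:
    """Pairwise coupling strengths K_ij = global_coupling * normalised weights."""

    k: np.ndarray
    global_coupling: float
    normalization: str = "none"

    @property
    def n_nodes(self) -> int:
        return self.k.shape[0]


@dataclass(frozen=True)
class DelayMatrix:
    """Per-link propagation delays in seconds at a given velocity (m/s)."""

    tau: np.ndarray
    velocity: float


@dataclass(frozen=True)
class DelaySummary:
    """Weighted means of intra- (internal) and inter-hemispheric (external) delays.

    ``delta_tau = (tau_ext - tau_int)/2`` and ``tau_tilde = (tau_ext + tau_int)/2``
    are the half-difference and midpoint that enter the analytic phase
    prediction; all values in seconds.
    """

    tau_int: float
    tau_ext: float

    @property
    def delta_tau(self) -> float:
        return (self.tau_ext - self.tau_int) / 2.0

    @property
    def tau_tilde(self) -> float:
        return (self.tau_ext + self.tau_int) / 2.0

    def to_dict(self) -> dict:
        return {
            "tau_int": self.tau_int,
            "tau_ext": self.tau_ext,
            "delta_tau": self.delta_tau,
            "tau_tilde": self.tau_tilde,
        }


def _read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    a = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return a


def load_connectome(
    weights_path: str | Path,
    lengths_path: str | Path,
    labels_path: str | Path,
) -> Connectome:
    """Load a connectome from delimited text files.

    ``weights_path`` and ``lengths_path`` each hold one square numeric matrix
    (whitespace- or comma-delimited, one row per line); ``labels_path`` holds
    one hemisphere label (``L`` or ``R``) per line.  Mildly asymmetric
    matrices are symmetrized as ``(A + A.T)/2`` with a warning.
    """
    w = _read_matrix(weights_path)
    lg = _read_matrix(lengths_path)
    labels = np.array(
        [ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()]
    )
    if w.shape != lg.shape:
        raise DimensionMismatchError(
            f"weights {w.shape} and lengths {lg.shape} differ in shape"
        )
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DimensionMismatchError(f"weights must be square, got {w.shape}")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise NegativeEntryError(f"negative weights entry at ({i}, {j})")
    w = _symmetrize(w, "weights")
    lg = _symmetrize(lg, "tract_lengths")
    return Connectome(weights=w, tract_lengths=lg, hemisphere=labels)


def write_connectome(conn: Connectome, out_dir: str | Path, fmt: str = "%.10g") -> dict:
    """Write the three standard files (weights, lengths, labels) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": out / "weights.txt",
        "lengths": out / "tract_lengths.txt",
        "labels": out / "hemispheres.txt",
    }
    np.savetxt(paths["weights"], conn.weights, fmt=fmt)
    np.savetxt(paths["lengths"], conn.tract_lengths, fmt=fmt)
    paths["labels"].write_text("\n".join(conn.hemisphere) + "\n")
    return {k: str(v) for k, v in paths.items()}


def delays_from_lengths(conn: Connectome, velocity: float = 5.0) -> DelayMatrix:
    """Propagation delays tau_ij = length_ij[mm] / 1000 / velocity[m/s], seconds."""
    if velocity <= 0:
        raise ValueError(f"velocity must be positive, got {velocity}")
    tau = conn.tract_lengths / 1000.0 / velocity
    return DelayMatrix(tau=tau, velocity=float(velocity))


_NORMALIZATIONS = ("none", "mean-nonzero", "max")


def coupling_matrix(
    conn: Connectome,
    global_coupling: float,
    normalization: str = "none",
) -> CouplingMatrix:
    """Coupling strengths K_ij = global_coupling * w_ij / norm.

    ``normalization``:

    * ``"none"`` (default) — weights used at raw streamline-count scale; with
      the 1/N prefactor of the node models this reproduces the strength range
      the analytic theory operates on.
    * ``"mean-nonzero"`` — divide by the mean non-zero weight.
    * ``"max"`` — divide by the maximum weight.
    """
    if global_coupling < 0:
        raise ValueError("global_coupling must be >= 0")
    if normalization not in _NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
    w = conn.weights
    nz = w[w > 0]
    if normalization != "none" and nz.size == 0:
        raise ZeroWeightsError("all-zero weight matrix: normalisation undefined")
    if normalization == "none":
        norm = 1.0
    elif normalization == "mean-nonzero":
        norm = float(nz.mean())
    else:
        norm = float(nz.max())
    k = global_coupling * w / norm
    np.fill_diagonal(k, 0.0)
    return CouplingMatrix(k=k, global_coupling=float(global_coupling),
                          normalization=normalization)


def node_strengths(K: CouplingMatrix) -> np.ndarray:
    """Per-node strength K_i = sum_{j != i} K_ij (self-links excluded)."""
    k = K.k.copy()
    np.fill_diagonal(k, 0.0)
    return k.sum(axis=1)


def effective_strengths(K: CouplingMatrix) -> np.ndarray:
    """Per-node mean coupling (1/N) sum_j K_ij.

    This is the coupling rate a node actually feels in the models (whose
    coupling term carries a 1/N prefactor) and the strength scale entering
    the analytic phase prediction and synchronization condition.
    """
    return node_strengths(K) / K.n_nodes


def hemisphere_mask(labels: np.ndarray, kind: str) -> np.ndarray:
    """Boolean (n, n) mask of intra- (``"internal"``) or inter-hemispheric
    (``"external"``) node pairs; diagonal always False."""
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    mask = same if kind == "internal" else ~same
    mask = mask.copy()
    np.fill_diagonal(mask, False)
    return mask


def delay_summary(
    conn: Connectome,
    K: CouplingMatrix | None,
    tau: DelayMatrix,
) -> DelaySummary:
    """Coupling-weighted means of intra- and inter-hemispheric link delays.

    Each undirected link is counted once (i < j).  Weights are the coupling
    strengths; if ``K`` is None or all-zero the raw weights are used instead
    (all exposed normalisations are global scalars, so the weighted means
    coincide whenever the global coupling is non-zero).
    """
    w = K.k if (K is not None and np.any(K.k > 0)) else conn.weights
    iu = np.triu_indices(conn.n_nodes, k=1)
    link = w[iu] > 0
    internal = hemisphere_mask(conn.hemisphere, "internal")[iu]
    out = {}
    for name, mask in (("tau_int", link & internal), ("tau_ext", link & ~internal)):
        if not mask.any():
            kind = "intra" if name == "tau_int" else "inter"
            raise NoLinksError(f"no {kind}-hemispheric links present")
        out[name] = float(
            np.average(tau.tau[iu][mask], weights=w[iu][mask])
        )
    return DelaySummary(**out)


def summary_report(
    conn: Connectome, K: CouplingMatrix, tau: DelayMatrix
) -> dict:
    """Small JSON-able report: delay summary plus strength statistics."""
    ds = delay_summary(conn, K, tau)
    s = effective_strengths(K)
    return {
        "n_nodes": conn.n_nodes,
        "velocity_m_s": tau.velocity,
        **ds.to_dict(),
        "strength_min": float(s.min()),
        "strength_mean": float(s.mean()),
        "strength_max": float(s.max()),
    }


def write_summary(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
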