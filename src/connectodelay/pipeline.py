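"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` describes a full run: the connectome (files or
synthetic spec), the node model, the wall-clock frequency, coupling and noise
rates, durations and all analysis knobs.  ``run_experiment`` executes
connectome -> simulation -> phases -> coherence -> theory comparison and
returns (optionally writes) an :class:`ExperimentReport` whose every number
is reproducible from the config and seed.

Unit conventions: ``global_coupling`` and ``noise_intensity`` are wall-clock
rates (s^-1), as are the printed reference values (K = 0.02, D = 0.25).  The
integration runs in dimensionless time; the rescale factor maps the model's
*measured* natural cycle frequency onto ``2*pi*frequency_hz``, so the
principal oscillation lands on the requested frequency for every model
family, and couplings, noise and delays are converted with the same factor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .coherence import (
    NoSignificantLinksError,
    WindowSpec,
    lag_pdfs,
    link_statistics,
    significant_lag_mean,
    surrogate_threshold,
    windowed_cplv,
)
from .connectome import (
    Connectome,
    CouplingMatrix,
    coupling_matrix,
    delay_summary,
    delays_from_lengths,
    effective_strengths,
    hemisphere_mask,
    load_connectome,
    write_connectome,
)
from .models import ModelSpec, natural_frequency
from .phases import (
    amplitude_metric,
    classify_synchronized,
    mean_frequency,
    order_parameter,
    peak_frequency,
    power_spectrum,
    protophase,
    protophase_to_phase,
)
from .simulate import SimConfig, Trajectory, integrate
from .synthetic import SyntheticSpec, generate_connectome
from .theory import (
    TheoryInputs,
    TheoryPrediction,
    antiphase_regime,
    predicted_phase,
    sync_condition,
    theory_vs_simulation,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "sweep",
           "analyze_trajectory", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and config hash."""

    def __init__(self, stage: str, config_hash: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed (config {config_hash}): {cause}")
        self.stage = stage
        self.config_hash = config_hash
        self.cause = cause


@dataclass(frozen=True)
class ExperimentConfig:
    """Flat, schema-validated description of one experiment."""

    # connectome source: either three file paths, or a synthetic spec
    weights_path: Optional[str] = None
    lengths_path: Optional[str] = None
    labels_path: Optional[str] = None
    synthetic: Optional[dict] = field(default_factory=dict)
    connectome_seed: int = 0

    model: str = "ls"
    model_params: dict = field(default_factory=dict)

    frequency_hz: float = 5.0
    global_coupling: float = 0.02  # s^-1
    noise_intensity: float = 0.25  # s^-1
    normalization: str = "none"
    velocity: float = 5.0  # m/s

    duration_s: Optional[float] = None  # steady (post-transient) wall seconds
    dt: Optional[float] = None
    store_stride: Optional[int] = None
    seed: int = 0

    n_phase_bins: int = 64
    window_periods: float = 5.0
    window_overlap: float = 0.25
    coherence_samples_per_period: float = 16.0
    n_surrogates: int = 100
    surrogate_quantile: float = 0.95
    min_significant_windows: int = 5
    drift_max: float = 2.0 * np.pi
    circ_var_max: float = 0.5
    compute_significance: bool = True
    save_trajectory: bool = False

    @property
    def steady_duration_s(self) -> float:
        """Post-transient wall-clock duration; 60 s at/below 10 Hz, 30 s above."""
        if self.duration_s is not None:
            return self.duration_s
        return 60.0 if self.frequency_hz <= 10.0 else 30.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """All tables and summary scalars of one experiment."""

    node_table: pd.DataFrame
    link_table: pd.DataFrame
    summary: dict
    lag_densities: Optional[dict]
    config: ExperimentConfig
    trajectory: Optional[Trajectory] = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.node_table.to_csv(out / "nodes.csv", index=False, float_format="%.10g")
        self.link_table.to_csv(out / "links.csv", index=False, float_format="%.10g")
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2) + "\n")
        self.config.to_yaml(out / "config.yml")
        if self.lag_densities is not None:
            rows = []
            for kind, (centers, dens) in self.lag_densities.items():
                for c, d in zip(centers, dens):
                    rows.append({"type": kind, "lag_rad": c, "density": d})
            pd.DataFrame(rows).to_csv(
                out / "lag_pdfs.csv", index=False, float_format="%.10g"
            )


def _build_connectome(cfg: ExperimentConfig) -> Connectome:
    if cfg.weights_path:
        return load_connectome(cfg.weights_path, cfg.lengths_path, cfg.labels_path)
    spec = SyntheticSpec(
        **{"seed": cfg.connectome_seed, "velocity": cfg.velocity,
           **(cfg.synthetic or {})}
    )
    return generate_connectome(spec)


def _surrogate_seed(seed: int) -> int:
    return int(np.random.SeedSequence([seed, 0x5EED]).generate_state(1)[0] % (2**31))


def analyze_trajectory(
    traj: Trajectory,
    conn: Connectome,
    K_wall: CouplingMatrix,
    cfg: ExperimentConfig,
) -> ExperimentReport:
    """Phase, coherence and theory analysis of an (already computed or
    persisted) trajectory; the coherence stage depends only on the stored
    trajectory, so re-running it on a loaded file reproduces the in-memory
    pipeline output exactly."""
    labels = conn.hemisphere
    n = conn.n_nodes
    ch = cfg.config_hash()
    spec = ModelSpec(kind=cfg.model, **cfg.model_params)
    w_nat = natural_frequency(spec)
    rescale = 2.0 * np.pi * cfg.frequency_hz / w_nat  # dimensionless units per s

    tau = delays_from_lengths(conn, cfg.velocity)
    ds = delay_summary(conn, K_wall, tau)
    strengths = effective_strengths(K_wall)  # s^-1

    t0 = time.perf_counter()
    try:
        phi = protophase(traj)
        theta = protophase_to_phase(phi, n_bins=cfg.n_phase_bins)
        mf = order_parameter(theta, labels)
        Omega_d = mean_frequency(mf)
        sync, mean_rel = classify_synchronized(
            theta, mf, Omega_d, labels,
            drift_max=cfg.drift_max, circ_var_max=cfg.circ_var_max,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("phases", ch, e) from e
    logger.info("phase stage done in %.2f s (Omega=%.4f)", time.perf_counter() - t0, Omega_d)

    Omega_wall = Omega_d * rescale  # rad/s
    x_steady = traj.steady(traj.x)
    amplitude = amplitude_metric(x_steady)
    dt_wall = traj.dt_sample / rescale
    freqs, amps = power_spectrum(x_steady, dt_wall)
    peaks = peak_frequency(freqs, amps)

    t0 = time.perf_counter()
    try:
        stride2 = max(
            1,
            int(round(2.0 * np.pi / Omega_d / cfg.coherence_samples_per_period
                      / traj.dt_sample)),
        )
        theta_dec = theta.theta[::stride2]
        wspec = WindowSpec.from_omega(
            Omega_d, traj.dt_sample * stride2,
            n_periods=cfg.window_periods, overlap_fraction=cfg.window_overlap,
        )
        cplv = windowed_cplv(theta_dec, wspec)
        threshold = None
        if cfg.compute_significance:
            threshold = surrogate_threshold(
                theta_dec, wspec, n_surrogates=cfg.n_surrogates,
                quantile=cfg.surrogate_quantile, seed=_surrogate_seed(cfg.seed),
            )
        stats = link_statistics(
            cplv, threshold, min_significant_windows=cfg.min_significant_windows
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("coherence", ch, e) from e
    logger.info("coherence stage done in %.2f s (%d windows)",
                time.perf_counter() - t0, cplv.shape[0])

    densities = None
    lag_summary: dict = {}
    if cfg.compute_significance:
        try:
            densities = lag_pdfs(stats, labels)
            for kind in ("internal", "external"):
                try:
                    lag_summary[f"{kind}_lag_mean_rad"] = significant_lag_mean(
                        stats, labels, kind
                    )
                except NoSignificantLinksError:
                    lag_summary[f"{kind}_lag_mean_rad"] = None
        except NoSignificantLinksError:
            logger.warning("no significant links; lag PDFs skipped")

    # theory comparison, wall-clock units
    r_per_node = np.array(
        [mf.r_mean(g if g in mf.r else "global") for g in labels]
    )
    tin = TheoryInputs(
        omega0=2.0 * np.pi * cfg.frequency_hz,
        Omega=Omega_wall,
        r=r_per_node,
        strengths=strengths,
        delta_tau=ds.delta_tau,
        tau_tilde=ds.tau_tilde,
    )
    pred = predicted_phase(tin)
    pred_sync = sync_condition(tin)
    regime = antiphase_regime(Omega_wall, ds.tau_ext)
    prediction = TheoryPrediction(mean_phase=pred, synchronized=pred_sync, regime=regime)
    try:
        comparison = theory_vs_simulation(mean_rel, sync, prediction)
    except ValueError as e:
        comparison = {"error": str(e)}

    node_table = pd.DataFrame(
        {
            "node": np.arange(n),
            "hemisphere": labels,
            "strength": strengths,
            "synchronized": sync,
            "mean_rel_phase": mean_rel,
            "amplitude_rms": amplitude,
            "peak_freq_hz": peaks,
            "theory_phase": pred,
            "theory_sync": pred_sync,
        }
    )

    iu = np.triu_indices(n, k=1)
    internal = hemisphere_mask(labels, "internal")[iu]
    link_table = pd.DataFrame(
        {
            "node_i": iu[0],
            "node_j": iu[1],
            "type": np.where(internal, "internal", "external"),
            "mean_plv": stats.mean_plv[iu],
            "lag_mean_rad": stats.lag_mean[iu],
            "one_minus_std": stats.one_minus_std[iu],
            "n_sig_windows": (
                stats.n_significant_windows[iu]
                if stats.n_significant_windows is not None else -1
            ),
            "significant": (
                stats.significant[iu] if stats.significant is not None else False
            ),
        }
    )

    summary = {
        "config_hash": ch,
        "package_version": _pkg_version,
        "model": cfg.model,
        "frequency_hz": cfg.frequency_hz,
        "seed": cfg.seed,
        "n_nodes": n,
        "kernel": traj.provenance.get("kernel"),
        "natural_frequency_dimensionless": w_nat,
        "omega_dimensionless": Omega_d,
        "omega_hz": Omega_wall / (2.0 * np.pi),
        "r_mean_left": mf.r_mean("L") if "L" in mf.r else None,
        "r_mean_right": mf.r_mean("R") if "R" in mf.r else None,
        "r_mean_global": mf.r_mean("global"),
        "n_synchronized": int(sync.sum()),
        "regime": regime,
        "tau_int_s": ds.tau_int,
        "tau_ext_s": ds.tau_ext,
        "delta_tau_s": ds.delta_tau,
        "tau_tilde_s": ds.tau_tilde,
        "strength_min": float(strengths.min()),
        "strength_mean": float(strengths.mean()),
        "strength_max": float(strengths.max()),
        "theory_comparison": comparison,
        **lag_summary,
    }
    return ExperimentReport(
        node_table=node_table,
        link_table=link_table,
        summary=summary,
        lag_densities=densities,
        config=cfg,
    )


def run_experiment(
    cfg: ExperimentConfig, out_dir: Optional[str | Path] = None
) -> ExperimentReport:
    """Run all stages from a single config; idempotent given the seed."""
    ch = cfg.config_hash()
    t0 = time.perf_counter()
    try:
        conn = _build_connectome(cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError("connectome", ch, e) from e
    K_wall = coupling_matrix(conn, cfg.global_coupling, cfg.normalization)

    spec = ModelSpec(kind=cfg.model, **cfg.model_params)
    w_nat = natural_frequency(spec)
    rescale = 2.0 * np.pi * cfg.frequency_hz / w_nat
    f_rescale = cfg.frequency_hz / w_nat  # SimConfig frequency: t_wall = t/(2*pi*f_rescale)

    steady = cfg.steady_duration_s * rescale
    t_total = steady / 0.8  # default 20% transient
    K_dim = CouplingMatrix(
        k=K_wall.k / rescale,
        global_coupling=K_wall.global_coupling / rescale,
        normalization=K_wall.normalization,
    )
    sim_cfg = SimConfig(
        frequency_hz=f_rescale,
        t_total=t_total,
        noise_intensity=cfg.noise_intensity / rescale,
        dt=cfg.dt,
        seed=cfg.seed,
        velocity=cfg.velocity,
        store_stride=cfg.store_stride,
    )
    try:
        traj = integrate(conn, K_dim, spec, sim_cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", ch, e) from e
    logger.info("simulation done in %.2f s", time.perf_counter() - t0)

    report = analyze_trajectory(traj, conn, K_wall, cfg)
    if cfg.save_trajectory:
        report.trajectory = traj
    if out_dir is not None:
        report.write(out_dir)
        write_connectome(conn, Path(out_dir) / "connectome")
        if cfg.save_trajectory:
            from .trajio import save_trajectory

            save_trajectory(Path(out_dir) / "trajectory.h5", traj)
    return report


def sweep(
    configs: list[ExperimentConfig], out_dir: Optional[str | Path] = None
) -> tuple[pd.DataFrame, list]:
    """Run independent seeded experiments and aggregate a summary table.

    Partial failures are recorded (status column) and the sweep continues.
    """
    if not configs:
        raise ValueError("empty config grid")
    rows = []
    reports: list = []
    for i, cfg in enumerate(configs):
        row = {
            "run": i,
            "model": cfg.model,
            "frequency_hz": cfg.frequency_hz,
            "seed": cfg.seed,
            "status": "ok",
        }
        try:
            rep = run_experiment(cfg)
            reports.append(rep)
            s = rep.summary
            nt = rep.node_table
            from scipy.stats import spearmanr

            sync = nt["synchronized"].to_numpy()
            rho_phase = (
                spearmanr(nt.loc[sync, "strength"], nt.loc[sync, "mean_rel_phase"]).statistic
                if sync.sum() >= 3 else np.nan
            )
            rho_amp = spearmanr(nt["strength"], nt["amplitude_rms"]).statistic
            row.update(
                regime=s["regime"],
                omega_hz=s["omega_hz"],
                r_mean_global=s["r_mean_global"],
                n_synchronized=s["n_synchronized"],
                theory_rmse=s["theory_comparison"].get("circular_rmse", np.nan),
                strength_phase_rho=rho_phase,
                strength_amplitude_rho=rho_amp,
            )
        except Exception as e:  # noqa: BLE001
            reports.append(e)
            row["status"] = f"error: {e}"
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "sweep.csv", index=False, float_format="%.10g")
    return table, reports
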