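"""Protophase extraction, phase transformation and mean-field analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectodelay.connectome import coupling_matrix
from connectodelay.models import ModelSpec
from connectodelay.phases import (
    EmptyBinError,
    MeanField,
    PhaseSeries,
    ProtophaseSeries,
    amplitude_metric,
    classify_synchronized,
    circular_mean,
    mean_frequency,
    order_parameter,
    peak_frequency,
    power_spectrum,
    protophase,
    protophase_from_xy,
    protophase_to_phase,
    rotating_frame,
)
from connectodelay.simulate import SimConfig, integrate

from test_simulate import single_node_conn


def uniform_phase_series(omega=1.0, T=400.0, dt=0.02, n_nodes=1):
    t = np.arange(0.0, T, dt)
    phi = omega * t[:, None] * np.ones(n_nodes)
    return ProtophaseSeries(phi=phi, t=t)


class TestProtophase:
    def test_circular_motion_exact(self):
        t = np.linspace(0, 50, 5001)
        omega = 1.3
        phi = protophase_from_xy(np.cos(omega * t), np.sin(omega * t), center=False)
        np.testing.assert_allclose(phi[:, 0], omega * t, atol=1e-9)

    def test_ls_limit_cycle_slope_matches_rotation(self):
        conn = single_node_conn()
        traj = integrate(
            conn, coupling_matrix(conn, 0.0), ModelSpec(kind="ls", q=0.5),
            SimConfig(frequency_hz=1.0, t_total=300.0, dt=0.01, seed=0),
        )
        series = protophase(traj)
        slope = (series.phi[-1, 0] - series.phi[0, 0]) / (series.t[-1] - series.t[0])
        assert np.all(np.diff(series.phi[:, 0]) > 0)
        assert slope == pytest.approx(0.5, rel=0.01)  # omega0 - q

    def test_rossler_mostly_monotone_after_centering(self):
        conn = single_node_conn()
        traj = integrate(
            conn, coupling_matrix(conn, 0.0), ModelSpec(kind="rossler"),
            SimConfig(frequency_hz=1.0, t_total=600.0, seed=2),
        )
        series = protophase(traj, center=True)
        frac_forward = np.mean(np.diff(series.phi[:, 0]) > 0)
        assert frac_forward >= 0.95

    def test_collapsed_trajectory_rejected(self):
        with pytest.raises(ValueError, match="collapsed"):
            protophase_from_xy(np.zeros(100), np.zeros(100))

    def test_too_few_cycles_rejected(self):
        conn = single_node_conn()
        traj = integrate(
            conn, coupling_matrix(conn, 0.0), ModelSpec(kind="ls"),
            SimConfig(frequency_hz=1.0, t_total=30.0, seed=0),
        )
        with pytest.raises(ValueError, match="cycles"):
            protophase(traj, min_cycles=10.0)


class TestProtophaseToPhase:
    def test_uniform_is_identity(self):
        series = uniform_phase_series(omega=0.9)
        ps = protophase_to_phase(series, n_bins=64)
        np.testing.assert_allclose(ps.theta, series.phi, atol=1e-3)

    def test_recovers_known_distortion(self):
        """phi = theta + 0.3 sin(theta) with uniformly growing theta: the
        transform must invert the distortion to better than 0.02 rad RMSE."""
        t = np.arange(0.0, 200 * 2 * np.pi, 0.05)
        theta_true = 1.0 * t
        phi = theta_true + 0.3 * np.sin(theta_true)
        ps = protophase_to_phase(ProtophaseSeries(phi=phi[:, None], t=t), n_bins=64)
        rmse = np.sqrt(np.mean((ps.theta[:, 0] - theta_true) ** 2))
        assert rmse < 0.02

    def test_growth_rate_preserved_exactly(self):
        t = np.arange(0.0, 500.0, 0.03)
        phi = 0.7 * t + 0.25 * np.sin(0.7 * t + 0.4)
        ps = protophase_to_phase(ProtophaseSeries(phi=phi[:, None], t=t), n_bins=32)
        g_phi = (phi[-1] - phi[0]) / (t[-1] - t[0])
        g_theta = (ps.theta[-1, 0] - ps.theta[0, 0]) / (t[-1] - t[0])
        assert g_theta == pytest.approx(g_phi, abs=1e-10)

    def test_table_monotone_and_periodic(self):
        t = np.arange(0.0, 400.0, 0.02)
        phi = t + 0.4 * np.sin(t)
        ps = protophase_to_phase(ProtophaseSeries(phi=phi[:, None], t=t), n_bins=48)
        table = ps.table_theta[0]
        assert np.all(np.diff(table) >= 0)
        assert table[0] == pytest.approx(0.0)
        assert table[-1] == pytest.approx(2 * np.pi)

    def test_empty_bin_raises(self):
        series = uniform_phase_series(T=2.0, dt=0.5)  # almost no samples
        with pytest.raises(EmptyBinError):
            protophase_to_phase(series, n_bins=64)

    def test_min_bins_enforced(self):
        with pytest.raises(ValueError):
            protophase_to_phase(uniform_phase_series(), n_bins=8)

    def test_harmonic_vdp_transform_near_identity(self):
        """m=0 van der Pol traces an ellipse with uniform true phase; after
        centring, protophase-to-phase must be close to the identity."""
        conn = single_node_conn()
        traj = integrate(
            conn, coupling_matrix(conn, 0.0), ModelSpec(kind="vdp", m=0.0),
            SimConfig(frequency_hz=1.0, t_total=300.0, dt=0.01, seed=0),
        )
        series = protophase(traj)
        ps = protophase_to_phase(series, n_bins=64)
        assert np.max(np.abs(ps.theta - series.phi)) < 0.02


class TestOrderParameter:
    def test_all_equal_phases(self):
        theta = np.full((5, 4), 1.234)
        mf = order_parameter(theta, np.array(["L", "L", "R", "R"]))
        np.testing.assert_allclose(mf.r["global"], 1.0)
        np.testing.assert_allclose(mf.r["L"], 1.0)

    def test_antipodal_cancellation(self):
        theta = np.array([[0.0, np.pi]])
        mf = order_parameter(theta)
        assert mf.r["global"][0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_three_phases(self):
        theta = np.array([[0.0, 0.0, np.pi / 2]])
        mf = order_parameter(theta)
        assert mf.r["global"][0] == pytest.approx(np.sqrt(5) / 3)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=8),
        st.floats(-10, 10),
    )
    def test_r_bounded_and_shift_invariant(self, phases, shift):
        theta = np.array([phases])
        mf = order_parameter(theta)
        r0 = mf.r["global"][0]
        assert 0.0 <= r0 <= 1.0 + 1e-12
        mf2 = order_parameter(theta + shift)
        assert mf2.r["global"][0] == pytest.approx(r0, abs=1e-9)


class TestMeanFrequency:
    def test_exact_slope(self):
        t = np.linspace(0, 100, 2001)
        mf = MeanField(t=t, r={"global": np.ones_like(t)}, psi={"global": 3.0 * t + 0.7})
        assert mean_frequency(mf, which="global") == pytest.approx(3.0)

    def test_noisy_slope_within_ci(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 200, 5001)
        est = []
        for _ in range(20):
            psi = 1.5 * t + rng.normal(0, 0.3, t.shape)
            mf = MeanField(t=t, r={"global": np.ones_like(t)}, psi={"global": psi})
            est.append(mean_frequency(mf, which="global"))
        assert np.mean(est) == pytest.approx(1.5, abs=0.01)

    def test_offset_invariance(self):
        t = np.linspace(0, 100, 1001)
        mk = lambda off: MeanField(
            t=t, r={"global": np.ones_like(t)}, psi={"global": 2.0 * t + off}
        )
        a = mean_frequency(mk(0.0), which="global")
        b = mean_frequency(mk(123.0), which="global")
        assert b == pytest.approx(a, rel=1e-6)

    def test_short_segment_rejected(self):
        t = np.linspace(0, 1, 101)
        mf = MeanField(t=t, r={"global": np.ones_like(t)}, psi={"global": 3.0 * t})
        with pytest.raises(ValueError, match="cycles"):
            mean_frequency(mf, which="global")

    def test_hemisphere_average(self):
        t = np.linspace(0, 100, 1001)
        mf = MeanField(
            t=t,
            r={"L": np.ones_like(t), "R": np.ones_like(t)},
            psi={"L": 2.0 * t, "R": 2.2 * t},
        )
        assert mean_frequency(mf) == pytest.approx(2.1)


class TestRotatingFrameAndClassification:
    def test_rotating_frame_constant_and_drift(self):
        t = np.linspace(0, 50, 501)
        np.testing.assert_allclose(rotating_frame(3.0 * t, t, 3.0), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            rotating_frame((3.0 + 0.1) * t, t, 3.0), 0.1 * t, atol=1e-10
        )

    def _make(self, theta_col, t, Omega):
        theta = theta_col[:, None]
        mf = MeanField(
            t=t, r={"L": np.ones_like(t)}, psi={"L": Omega * t}
        )
        ps = PhaseSeries(theta=theta, t=t, table_edges=np.empty(0),
                         table_theta=np.empty((1, 0)))
        return classify_synchronized(ps, mf, Omega, np.array(["L"]))

    def test_constant_relative_phase_synchronized(self):
        t = np.linspace(0, 200, 2001)
        sync, mean_rel = self._make(2.0 * t + 0.5, t, 2.0)
        assert sync[0]
        assert mean_rel[0] == pytest.approx(0.5)

    def test_linear_drift_not_synchronized(self):
        Omega = 2.0
        t = np.linspace(0, 20 * 2 * np.pi / Omega, 4001)  # 20 cycles
        sync, _ = self._make((Omega + Omega / 10) * t, t, Omega)
        assert not sync[0]

    def test_single_slip_not_synchronized(self):
        t = np.linspace(0, 300, 3001)
        slip = 2 * np.pi / (1 + np.exp(-(t - 150)))  # one 2*pi slip mid-run
        sync, _ = self._make(2.0 * t + slip, t, 2.0)
        assert not sync[0]


class TestAmplitudeAndSpectrum:
    def test_rms_of_cosine(self):
        t = np.linspace(0, 100, 10001)
        x = 2.5 * np.cos(1.7 * t)
        assert amplitude_metric(x[:, None])[0] == pytest.approx(2.5 / np.sqrt(2), rel=1e-3)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1000, 3))
        np.testing.assert_allclose(
            amplitude_metric(2 * x), 2 * amplitude_metric(x), rtol=1e-12
        )

    def test_spectral_peak_location(self):
        dt = 0.002
        t = np.arange(0, 8.0, dt)
        f0 = 11.0
        x = np.cos(2 * np.pi * f0 * t)
        freqs, amp = power_spectrum(x[:, None], dt)
        pk = peak_frequency(freqs, amp)[0]
        assert abs(pk - f0) <= freqs[1] - freqs[0]


def test_circular_mean_wraps_correctly():
    a = np.array([np.pi - 0.1, -np.pi + 0.1])
    assert abs(circular_mean(a)) == pytest.approx(np.pi, abs=1e-9)
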