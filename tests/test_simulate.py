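"""Node models and the delay-coupled Euler–Maruyama integrator."""

import numpy as np
import pytest

from connectodelay.connectome import Connectome, CouplingMatrix, coupling_matrix
from connectodelay.models import ModelSpec, model_drift, natural_frequency
from connectodelay.simulate import (
    IntegrationError,
    SimConfig,
    coupling_input,
    dimensionless_delays,
    integrate,
)


def single_node_conn():
    return Connectome(
        weights=np.zeros((1, 1)),
        tract_lengths=np.zeros((1, 1)),
        hemisphere=np.array(["L"]),
    )


class TestModelDrift:
    def test_rossler_at_origin(self):
        spec = ModelSpec(kind="rossler")
        d = model_drift(spec, np.zeros(3), 0.0)
        np.testing.assert_allclose(d, [0.0, 0.0, spec.b])

    def test_vdp_harmonic_limit_conserves_energy(self):
        """m=0 van der Pol is a harmonic oscillator: the drift is tangent to
        the energy surface omega0^2*y^2 + x^2 = const."""
        spec = ModelSpec(kind="vdp", m=0.0, omega0=1.3)
        rng = np.random.default_rng(0)
        state = rng.standard_normal((20, 2))
        d = model_drift(spec, state, 0.0)
        # dE/dt = 2*x*dx + 2*omega0^2*y*dy
        de = 2 * state[:, 0] * d[:, 0] + 2 * spec.omega0**2 * state[:, 1] * d[:, 1]
        np.testing.assert_allclose(de, 0.0, atol=1e-12)

    def test_ls_unit_circle_invariant(self):
        spec = ModelSpec(kind="ls", q=1.7)
        ang = np.linspace(0, 2 * np.pi, 9)
        state = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        d = model_drift(spec, state, 0.0)
        # d|X|^2/dt = 2(x*dx + y*dy) = 0 on |X| = 1
        np.testing.assert_allclose(
            state[:, 0] * d[:, 0] + state[:, 1] * d[:, 1], 0.0, atol=1e-12
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            ModelSpec(kind="kuramoto")

    def test_wrong_state_dim_rejected(self):
        with pytest.raises(ValueError, match="state dimension"):
            model_drift(ModelSpec(kind="rossler"), np.zeros(2), 0.0)

    def test_literal_vdp_differs(self):
        state = np.array([0.3, 1.2])
        d_std = model_drift(ModelSpec(kind="vdp"), state, 0.0)
        d_lit = model_drift(ModelSpec(kind="vdp", literal_vdp=True), state, 0.0)
        assert d_std[0] != d_lit[0]
        assert d_std[1] == d_lit[1]


class TestNaturalFrequency:
    def test_ls_closed_form(self):
        assert natural_frequency(ModelSpec(kind="ls", q=0.5)) == pytest.approx(0.5)
        assert natural_frequency(ModelSpec(kind="ls", q=0.0)) == pytest.approx(1.0)

    def test_vdp_slower_rossler_faster_than_omega0(self):
        assert 0.7 < natural_frequency(ModelSpec(kind="vdp")) < 1.0
        assert 1.0 < natural_frequency(ModelSpec(kind="rossler")) < 1.2


class TestDimensionlessDelays:
    @pytest.mark.parametrize(
        "tau_s,f,expected",
        [(19.6e-3, 20.0, 0.0196 * 40 * np.pi), (6.5e-3, 5.0, 0.0065 * 10 * np.pi)],
    )
    def test_rescaling(self, tau_s, f, expected):
        assert dimensionless_delays(np.array([[tau_s]]), f)[0, 0] == pytest.approx(
            expected
        )

    def test_linear_in_frequency(self):
        tau = np.array([[0.0, 0.01], [0.01, 0.0]])
        np.testing.assert_allclose(
            dimensionless_delays(tau, 10.0), 2 * dimensionless_delays(tau, 5.0)
        )


class TestCouplingInput:
    def test_constant_history_zero(self):
        hist = np.full((5, 3), 1.7)
        k = np.array([[0, 1, 2], [1, 0, 0], [2, 0, 0]], dtype=float)
        lags = np.array([[0, 1, 3], [1, 0, 0], [3, 0, 0]])
        c = coupling_input(hist, 4, lags, k, hist[4])
        np.testing.assert_allclose(c, 0.0, atol=1e-14)

    def test_two_node_frozen(self):
        hist = np.array([[1.0, -1.0]])
        k = np.array([[0.0, 2.0], [2.0, 0.0]])  # K_ij/N factor gives +-1 with N=2
        c = coupling_input(hist, 0, np.zeros((2, 2), dtype=int), k, hist[0])
        np.testing.assert_allclose(c, [-2.0, 2.0])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        n, L = 4, 11
        hist = rng.standard_normal((L, n))
        k = np.abs(rng.standard_normal((n, n)))
        np.fill_diagonal(k, 0.0)
        lags = rng.integers(0, L, size=(n, n))
        pos = 7
        x_now = hist[pos]
        expected = np.zeros(n)
        for i in range(n):
            for j in range(n):
                expected[i] += k[i, j] * (
                    hist[(pos - lags[i, j]) % L, j] - x_now[i]
                )
        expected /= n
        np.testing.assert_allclose(
            coupling_input(hist, pos, lags, k, x_now), expected, rtol=1e-12
        )

    def test_history_too_short(self):
        hist = np.zeros((3, 2))
        with pytest.raises(IntegrationError, match="too short"):
            coupling_input(hist, 0, np.full((2, 2), 5), np.ones((2, 2)), hist[0])


class TestIntegrate:
    def test_ls_amplitude_attracts_to_unity(self):
        conn = single_node_conn()
        traj = integrate(
            conn,
            coupling_matrix(conn, 0.0),
            ModelSpec(kind="ls", q=1.0),
            SimConfig(frequency_hz=1.0, t_total=60.0, dt=0.005, seed=0),
        )
        r_end = np.hypot(traj.x[-1, 0], traj.y[-1, 0])
        assert abs(r_end - 1.0) < 1e-6

    def test_rossler_positive_lyapunov(self):
        """Benettin-style two-trajectory divergence of the uncoupled Rössler
        (the step must resolve the fast z-spikes or chaos is lost)."""
        spec = ModelSpec(kind="rossler")
        dt, renorm, d0 = 0.004, 250, 1e-6
        state = np.array([[5.0, 0.0, 0.02]])
        for _ in range(int(300 / dt)):  # settle onto the attractor
            state = state + dt * model_drift(spec, state, 0.0)
        pair = np.vstack([state, state + [[d0, 0.0, 0.0]]])
        lam_sum, n_ren = 0.0, 0
        for step in range(1, int(600 / dt) + 1):
            pair = pair + dt * model_drift(spec, pair, 0.0)
            if step % renorm == 0:
                d = np.linalg.norm(pair[1] - pair[0])
                lam_sum += np.log(d / d0)
                n_ren += 1
                pair[1] = pair[0] + (pair[1] - pair[0]) * (d0 / d)
        lam = lam_sum / (n_ren * renorm * dt)
        assert lam > 0.02

    def test_sync_manifold_invariant(self):
        """Two identical, symmetrically delay-coupled nodes started at the
        same phase stay identical to machine precision."""
        conn = Connectome(
            weights=np.array([[0.0, 2.0], [2.0, 0.0]]),
            tract_lengths=np.array([[0.0, 40.0], [40.0, 0.0]]),
            hemisphere=np.array(["L", "R"]),
        )
        K = coupling_matrix(conn, 0.3)
        tau_p = dimensionless_delays(conn.tract_lengths / 1000.0 / 5.0, 1.0)
        traj = integrate(
            conn, K, ModelSpec(kind="ls"),
            SimConfig(frequency_hz=1.0, t_total=50.0, seed=0),
            tau_prime=tau_p,
            initial_phases=np.array([0.7, 0.7]),
        )
        np.testing.assert_array_equal(traj.x[:, 0], traj.x[:, 1])
        np.testing.assert_array_equal(traj.y[:, 0], traj.y[:, 1])

    def test_seed_determinism_bit_identical(self, small_synth):
        K = coupling_matrix(small_synth, 0.001)
        cfg = SimConfig(frequency_hz=1.0, t_total=40.0, noise_intensity=0.01, seed=9)
        a = integrate(small_synth, K, ModelSpec(kind="ls"), cfg)
        b = integrate(small_synth, K, ModelSpec(kind="ls"), cfg)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    @pytest.mark.parametrize("kind", ["ls", "vdp", "rossler"])
    def test_numba_matches_numpy_reference(self, small_synth, kind):
        K = coupling_matrix(small_synth, 0.002)
        cfg = SimConfig(frequency_hz=1.0, t_total=30.0, noise_intensity=0.02, seed=4)
        fast = integrate(small_synth, K, ModelSpec(kind=kind), cfg, use_numba=True)
        ref = integrate(small_synth, K, ModelSpec(kind=kind), cfg, use_numba=False)
        assert fast.provenance["kernel"] == "numba"
        assert ref.provenance["kernel"] == "numpy"
        np.testing.assert_allclose(fast.x, ref.x, rtol=1e-9, atol=1e-9)

    def test_zero_coupling_factorizes(self):
        """With K=0 and D=0 each node's trajectory equals the single-node
        integration from the same initial phase."""
        conn = Connectome(
            weights=np.array([[0.0, 1.0], [1.0, 0.0]]),
            tract_lengths=np.array([[0.0, 30.0], [30.0, 0.0]]),
            hemisphere=np.array(["L", "R"]),
        )
        K0 = CouplingMatrix(k=np.zeros((2, 2)), global_coupling=0.0)
        cfg = SimConfig(frequency_hz=1.0, t_total=30.0, dt=0.01, seed=0)
        pair = integrate(conn, K0, ModelSpec(kind="vdp"), cfg,
                         initial_phases=np.array([0.3, 2.1]))
        for col, ph in enumerate([0.3, 2.1]):
            single = integrate(
                single_node_conn(),
                CouplingMatrix(k=np.zeros((1, 1)), global_coupling=0.0),
                ModelSpec(kind="vdp"), cfg, initial_phases=np.array([ph]),
            )
            np.testing.assert_allclose(pair.x[:, col], single.x[:, 0], atol=1e-12)

    def test_phase_diffusion_scales_with_noise(self):
        """Uncoupled isochronous Landau–Stuart: the across-realisations
        variance of the phase grows like 2*D*t."""
        from connectodelay.phases import protophase_from_xy

        conn = single_node_conn()
        K0 = coupling_matrix(conn, 0.0)
        spec = ModelSpec(kind="ls", q=0.0)
        D, T = 0.01, 400.0
        ends = []
        for seed in range(50):
            traj = integrate(
                conn, K0, spec,
                SimConfig(frequency_hz=1.0, t_total=T, t_transient=0.0,
                          noise_intensity=D, dt=0.02, seed=seed),
                initial_phases=np.array([0.0]),
            )
            phi = protophase_from_xy(traj.x, traj.y, center=False)
            ends.append(phi[-1, 0] - phi[0, 0])
        var = np.var(ends)
        assert var == pytest.approx(2 * D * T, rel=0.25)

    def test_dt_precondition_enforced(self, small_synth):
        K = coupling_matrix(small_synth, 0.001)
        with pytest.raises(IntegrationError, match="per natural period|delay"):
            integrate(
                small_synth, K, ModelSpec(kind="ls"),
                SimConfig(frequency_hz=1.0, t_total=10.0, dt=0.2, seed=0),
            )

    def test_nan_aborts_with_step_index(self, small_synth):
        K = CouplingMatrix(k=np.where(small_synth.weights > 0, 1e8, 0.0),
                           global_coupling=1e8)
        with pytest.raises(IntegrationError, match="step"):
            integrate(
                small_synth, K, ModelSpec(kind="ls"),
                SimConfig(frequency_hz=1.0, t_total=50.0, seed=0),
            )

    def test_transient_window_marked(self, small_synth):
        K = coupling_matrix(small_synth, 0.001)
        traj = integrate(
            small_synth, K, ModelSpec(kind="ls"),
            SimConfig(frequency_hz=1.0, t_total=50.0, t_transient=10.0, seed=0),
        )
        assert traj.t[traj.steady_start] >= 10.0
        assert traj.t[traj.steady_start - 1] < 10.0
        assert traj.t_steady.shape[0] == traj.steady().shape[0]
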