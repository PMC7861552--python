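import dataclasses

import numpy as np
import pytest
from scipy.linalg import null_space

from mitoca.mitochondria import (
    MPTP_C0,
    MPTP_O,
    MitoState,
    mcu_flux,
    mito_energetics,
    mito_fluxes,
    mncx_flux,
    mptp_activation_rate,
    mptp_rate_matrix,
    mptp_steady_state,
    mptp_transition_step,
)
from mitoca.params import MitoParams, MPTPParams


@pytest.fixture()
def mptp():
    return MPTPParams()


@pytest.fixture()
def mito():
    return MitoParams()


class TestActivationRate:
    def test_anchor_values(self, mptp):
        a0 = mptp.alpha0
        assert mptp_activation_rate(mptp, 0.0) == pytest.approx(a0)
        assert mptp_activation_rate(mptp, mptp.ca0) == pytest.approx(100.5 * a0)
        assert mptp_activation_rate(mptp, 1e9) == pytest.approx(200.0 * a0, rel=1e-6)

    def test_negative_ca_rejected(self, mptp):
        with pytest.raises(ValueError):
            mptp_activation_rate(mptp, -0.1)


class TestSteadyState:
    def test_limits_in_alpha(self, mptp):
        lo = mptp_steady_state(dataclasses.replace(mptp, alpha_mptp=1e-12), 0.5)
        hi = mptp_steady_state(dataclasses.replace(mptp, alpha_mptp=1e12), 0.5)
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_stationary_vector(self):
        # closed form vs null space of the generator over a rate grid
        rng = np.random.default_rng(11)
        for _ in range(60):
            p = MPTPParams(
                alpha0=10 ** rng.uniform(-6, -3),
                ca0=rng.uniform(0.1, 2.0),
                h_mptp=rng.uniform(1.0, 3.0),
                kc1o0=10 ** rng.uniform(-5, -2),
                koc1=10 ** rng.uniform(-4, -2),
                kc1c0=10 ** rng.uniform(-4, -2),
                alpha_mptp=10 ** rng.uniform(-2, 3),
            )
            ca = rng.uniform(0.0, 3.0)
            q = mptp_rate_matrix(p, ca)
            pi = null_space(q.T)[:, 0]
            pi = pi / pi.sum()
            assert mptp_steady_state(p, ca) == pytest.approx(pi[2], rel=1e-10)

    def test_monotone_in_alpha_and_ca(self, mptp):
        alphas = np.logspace(-1, 3, 40)
        po = [mptp_steady_state(dataclasses.replace(mptp, alpha_mptp=a), 0.5)
              for a in alphas]
        assert np.all(np.diff(po) > 0)
        cas = np.linspace(0.0, 3.0, 40)
        po2 = np.asarray(mptp_steady_state(dataclasses.replace(mptp, alpha_mptp=30.0), cas))
        assert np.all(np.diff(po2) > 0)


class TestTransitionStep:
    def test_alpha_zero_never_opens(self):
        p = MPTPParams(alpha_mptp=0.0)
        st = MitoState.resting(64)
        rng = np.random.default_rng(0)
        for _ in range(5000):
            mptp_transition_step(st, p, 1.0, rng, ca_m=2.0)
            assert not np.any(st.mptp_state == MPTP_O)

    def test_forced_closed_clamp(self):
        p = MPTPParams(alpha_mptp=100.0)
        st = MitoState.resting(32)
        st.mptp_state[:] = MPTP_O
        rng = np.random.default_rng(0)
        mptp_transition_step(st, p, 1.0, rng, forced_closed=True)
        assert np.all(st.mptp_state == MPTP_C0)

    def test_long_run_occupancy_matches_stationary(self):
        p = MPTPParams(alpha_mptp=60.0)
        ca = 0.5
        st = MitoState.resting(256)
        rng = np.random.default_rng(5)
        dt, n_burn, n = 5.0, 20000, 60000
        count = 0
        for i in range(n_burn + n):
            mptp_transition_step(st, p, dt, rng, ca_m=ca)
            if i >= n_burn:
                count += int(np.sum(st.mptp_state == MPTP_O))
        empirical = count / (n * 256)
        assert empirical == pytest.approx(float(mptp_steady_state(p, ca)), rel=0.05)

    def test_probability_cap(self):
        p = MPTPParams(koc1=2.0)
        st = MitoState.resting(4)
        with pytest.raises(RuntimeError):
            mptp_transition_step(st, p, 1.0, np.random.default_rng(0))


class TestMitoFluxes:
    def test_mcu_linear_in_alpha(self, mito):
        j1 = mcu_flux(mito, 0.5, 180.0, alpha_mcu=1.0)
        j2 = mcu_flux(mito, 0.5, 180.0, alpha_mcu=2.0)
        assert j2 == pytest.approx(2 * j1)

    def test_mcu_off_pore_closed_monotone_decay(self, mito):
        st = MitoState.resting(8)
        prev = st.ca_m.copy()
        for _ in range(200):
            mito_fluxes(st, mito, 0.1, dt=1.0, alpha_mcu=0.0)
            assert np.all(st.ca_m <= prev + 1e-15)
            prev = st.ca_m.copy()

    def test_open_pore_drains_toward_cytosol(self, mito):
        st = MitoState.resting(4)
        st.ca_m[:] = 5.0
        st.mptp_state[:] = MPTP_O
        st.dpsi[:] = mito.psi_depolarized
        for _ in range(500):
            mito_fluxes(st, mito, 0.2, dt=1.0, alpha_mcu=0.0)
        assert np.all(st.ca_m < 5.0)

    def test_mncx_scale_zero_disables_efflux(self):
        p = MitoParams(mncx_scale=0.0)
        assert mncx_flux(p, 1.0) == 0.0


class TestEnergetics:
    def test_two_fixed_points(self, mito):
        closed = MitoState.resting(2)
        for _ in range(200):
            mito_energetics(closed, mito, dt=50.0)
        assert np.allclose(closed.dpsi, mito.psi_polarized, atol=1e-6)
        assert np.all(closed.producing_atp(mito))

        opened = MitoState.resting(2)
        opened.mptp_state[:] = MPTP_O
        for _ in range(400):
            mito_energetics(opened, mito, dt=50.0)
        assert np.allclose(opened.dpsi, mito.psi_depolarized, atol=1e-3)
        assert not np.any(opened.producing_atp(mito))
        emission = opened.ros_emission(1e-3, 2e-2, mito)
        assert np.all(emission > 1e-2)

    def test_recovery_time_constant(self, mito):
        st = MitoState.resting(1)
        st.dpsi[:] = mito.psi_depolarized
        dt = 1.0
        n = int(mito.tau_psi_repol / dt)
        for _ in range(n):  # one time constant
            mito_energetics(st, mito, dt=dt)
        target = mito.psi_polarized
        frac = (target - st.dpsi[0]) / (target - mito.psi_depolarized)
        assert frac == pytest.approx(np.exp(-1.0), rel=0.02)


def test_mcu_upregulation_raises_ca_and_open_fraction():
    """Single-mitochondrion harness: higher alpha_MCU raises time-averaged
    mitochondrial Ca2+ and, through it, the time-averaged mPTP open fraction
    at fixed alpha_mPTP."""
    mito = MitoParams()
    mptp = MPTPParams(alpha_mptp=60.0)
    results = []
    for amcu in (0.5, 1.0, 3.0):
        st = MitoState.resting(64)
        rng = np.random.default_rng(9)
        ca_sum = 0.0
        open_sum = 0
        n = 40000
        for i in range(n):
            ci = 0.2 + 0.5 * max(np.sin(2 * np.pi * (i % 500) / 500.0), 0.0)
            mito_fluxes(st, mito, ci, dt=1.0, alpha_mcu=amcu)
            mptp_transition_step(st, mptp, 1.0, rng)
            mito_energetics(st, mito, dt=1.0)
            if i > n // 2:
                ca_sum += st.ca_m.mean()
                open_sum += int(np.sum(st.mptp_state == MPTP_O))
        results.append((ca_sum / (n / 2), open_sum / (n / 2 * 64)))
    cas = [r[0] for r in results]
    opens = [r[1] for r in results]
    assert cas[0] < cas[1] < cas[2]
    assert opens[0] < opens[2]
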