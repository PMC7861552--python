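import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoca.calcium import (
    CRUState,
    buffer_factor,
    cru_flux_update,
    delta_k_camkii,
    delta_k_ros,
    plb_shift,
    ryr_cluster_step,
    ryr_rate_k12,
    serca_atp_factor,
    serca_flux,
    serca_ros_factor,
    total_calcium,
)
from mitoca.geometry import build_lattice
from mitoca.params import CompartmentParams, RyRParams, SercaParams


@pytest.fixture()
def ryr():
    return RyRParams()


@pytest.fixture()
def serca():
    return SercaParams()


class TestRyRRate:
    def test_baseline_quadratic(self, ryr):
        k = ryr_rate_k12(ryr, 2.0)
        assert k == pytest.approx(ryr.k_base * ryr.k_u * 4.0)

    def test_zero_dyadic_ca(self, ryr):
        assert ryr_rate_k12(ryr, 0.0) == 0.0

    def test_linear_in_sensitization(self, ryr):
        base = ryr_rate_k12(ryr, 5.0, 0.0, 0.0)
        # doubling (1 + dk) doubles k12 at fixed Ca
        assert ryr_rate_k12(ryr, 5.0, 0.6, 0.4) == pytest.approx(2 * base)

    def test_negative_input_rejected(self, ryr):
        with pytest.raises(ValueError):
            ryr_rate_k12(ryr, -1.0)


class TestSensitizationIncrements:
    def test_camkii_half_max_at_km(self, ryr):
        assert delta_k_camkii(ryr, ryr.km_cam_ryr) == pytest.approx(
            ryr.dk_camk_max / 2
        )

    def test_camkii_zero_limit(self, ryr):
        assert delta_k_camkii(ryr, 0.0) == 0.0

    def test_ros_half_max_and_off_switch(self, ryr):
        assert delta_k_ros(ryr, ryr.km_ros_ryr) == pytest.approx(ryr.dk_ros_max / 2)
        ryr_off = RyRParams(dk_ros_max=0.0)
        assert np.all(delta_k_ros(ryr_off, np.linspace(0, 10, 50)) == 0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(h=st.floats(1.0, 4.0))
    def test_monotone_saturating(self, h):
        p = RyRParams(h_cam_ryr=h, h_ros_ryr=h)
        grid = np.linspace(1e-4, 20.0, 200)
        dk = delta_k_ros(p, grid)
        assert np.all(np.diff(dk) > 0)
        assert dk[-1] < p.dk_ros_max
        dc = delta_k_camkii(p, np.linspace(1e-4, 1.0, 100))
        assert np.all(np.diff(dc) > 0)


class TestSercaFactors:
    def test_atp_saturation_and_half_max(self, serca):
        assert serca_atp_factor(serca, 1e9, 0.0) == pytest.approx(1.0, abs=1e-6)
        assert serca_atp_factor(serca, serca.km_up_atp, 0.0) == pytest.approx(0.5)

    def test_adp_strictly_inhibits(self, serca):
        f = serca_atp_factor(serca, 2.0, np.linspace(0.0, 4.0, 50))
        assert np.all(np.diff(f) < 0)

    def test_atp_zero_rejected(self, serca):
        with pytest.raises(ValueError):
            serca_atp_factor(serca, 0.0)

    def test_ros_factor_limits(self, serca):
        assert serca_ros_factor(serca, 0.0) == pytest.approx(1.0)
        assert serca_ros_factor(serca, serca.kd_ros) == pytest.approx(0.875)
        assert serca_ros_factor(serca, 1e9) == pytest.approx(0.75, abs=1e-6)

    def test_ros_factor_strictly_decreasing(self, serca):
        f = serca_ros_factor(serca, np.linspace(0.0, 5.0, 200))
        assert np.all(np.diff(f) < 0)


class TestSercaFlux:
    def test_half_max_at_effective_km(self, serca):
        k_eff = serca.k_i - plb_shift(serca, 0.3)
        j = serca_flux(serca, k_eff, camkii_act=0.3, f_atp=0.9, f_ros=0.8)
        assert j == pytest.approx(serca.v_up * 0.9 * 0.8 / 2)

    def test_zero_ca(self, serca):
        assert serca_flux(serca, 0.0) == 0.0

    def test_camkii_raises_uptake(self, serca):
        ca = 0.3
        j = serca_flux(serca, ca, camkii_act=np.linspace(0.0, 1.0, 50))
        assert np.all(np.diff(j) > 0)

    def test_nonpositive_half_max_rejected(self):
        bad = SercaParams(plb_max=1.0, k_i=0.5)
        with pytest.raises(ValueError):
            serca_flux(bad, 0.3, camkii_act=1.0)


class TestRyRClusterStep:
    def test_no_openings_with_zero_rate(self):
        state = CRUState.resting(8)
        rng = np.random.default_rng(0)
        for _ in range(500):
            ryr_cluster_step(state, 0.0, 0.1, rng)
        assert np.all(state.ryr_open == 0)

    def test_two_state_stationary_occupancy(self):
        # one channel, fixed rates: open fraction -> k12/(k12 + k_close)
        state = CRUState.resting(1, n_ryr=1)
        k12, kc = 0.02, 0.05
        rng = np.random.default_rng(42)
        dt, n = 0.5, 200000
        occ = 0
        for _ in range(n):
            ryr_cluster_step(state, k12, dt, rng, k_close=kc, k_recover=None)
            occ += int(state.ryr_open[0])
        expected = k12 / (k12 + kc)
        assert occ / n == pytest.approx(expected, rel=0.05)

    def test_mean_open_fraction_dt_invariant(self):
        k12, kc = 0.01, 0.04
        means = []
        for dt, n in ((0.5, 80000), (1.0, 40000)):
            state = CRUState.resting(16, n_ryr=50)
            rng = np.random.default_rng(7)
            tot = 0
            for _ in range(n):
                ryr_cluster_step(state, k12, dt, rng, k_close=kc, k_recover=None)
                tot += state.ryr_open.sum()
            means.append(tot / (n * 16 * 50))
        assert means[0] == pytest.approx(means[1], rel=0.05)

    def test_three_state_counts_conserved(self):
        state = CRUState.resting(4)
        rng = np.random.default_rng(1)
        for _ in range(2000):
            ryr_cluster_step(state, 0.05, 0.2, rng, k_close=0.1, k_recover=2e-3)
            state.validate()

    def test_probability_cap_enforced(self):
        state = CRUState.resting(2)
        with pytest.raises(RuntimeError, match="reduce dt"):
            ryr_cluster_step(state, 5.0, 1.0, np.random.default_rng(0))


class TestCRUFluxUpdate:
    def test_identity_with_all_fluxes_zero(self):
        comp = CompartmentParams(g_sub_cyt=0, g_tr=0, g_leak=0, d_cyt=0, d_nsr=0)
        ryr = RyRParams(g_rel=0.0)
        serca = SercaParams(v_up=0.0)
        state = CRUState.resting(6)
        before = {k: getattr(state, k).copy() for k in
                  ("ca_sub", "ca_cyt", "ca_nsr", "ca_jsr")}
        cru_flux_update(state, ryr, serca, comp, dt=0.01)
        for k, v in before.items():
            assert np.allclose(getattr(state, k), v)

    def test_closed_cell_conserves_total_calcium(self):
        # no sarcolemmal or mitochondrial fluxes: buffered total is invariant
        grid = build_lattice((4, 2, 2), (4, 1, 1))
        comp = CompartmentParams()
        ryr = RyRParams()
        serca = SercaParams()
        state = CRUState.resting(grid.cru_count)
        state.ryr_open[:] = 10  # ongoing release moves Ca between pools
        rng = np.random.default_rng(3)

        def total(s):
            return float(np.sum(
                total_calcium(s.ca_cyt, comp.buf_cyt_b, comp.buf_cyt_k)
                + comp.v_sub * total_calcium(s.ca_sub, comp.buf_sub_b, comp.buf_sub_k)
                + comp.v_nsr * s.ca_nsr
                + comp.v_jsr * total_calcium(s.ca_jsr, comp.buf_jsr_b, comp.buf_jsr_k)
            ))

        t0 = total(state)
        for i in range(10000):
            k12 = ryr_rate_k12(ryr, state.ca_dyad)
            ryr_cluster_step(state, k12, 0.1, rng, ryr.k_close, ryr.k_recover)
            cru_flux_update(state, ryr, serca, comp, dt=0.1,
                            neighbors=grid.neighbors)
        drift = abs(total(state) - t0) / t0
        assert drift < 1e-3

    def test_single_release_site_raises_neighbors(self):
        grid = build_lattice((4, 2, 2), (4, 1, 1))
        comp = CompartmentParams()
        ryr = RyRParams()
        serca = SercaParams(v_up=0.0)
        state = CRUState.resting(grid.cru_count)
        state.ryr_open[5] = 100
        nb = grid.neighbors[5][grid.neighbors[5] >= 0]
        series = []
        for _ in range(3000):
            cru_flux_update(state, ryr, serca, comp, dt=0.05,
                            neighbors=grid.neighbors)
            state.ryr_open[5] = 100  # hold the cluster open
            series.append(state.ca_cyt[nb].mean())
        diffs = np.diff(np.asarray(series))
        assert series[-1] > series[0] * 1.5
        assert np.all(diffs > -1e-12)


def test_buffer_factor_consistent_with_total_derivative():
    b, k = 50.0, 0.6
    c = np.linspace(0.01, 5.0, 400)
    beta = buffer_factor(c, b, k)
    total = total_calcium(c, b, k)
    num = np.gradient(c, total)  # d(free)/d(total) along the curve
    assert np.allclose(num[2:-2], beta[2:-2], rtol=2e-3)
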