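import numpy as np
import pandas as pd
import pytest

from mitoca import Protocol, SimConfig
from mitoca.params import ConfigError
from mitoca.protocols import (
    ScanSpec,
    _point_seed,
    alternans_amplitude,
    bifurcation_curve,
    measure_mptp_open_fraction,
    onset_pcl,
    run_scan,
    write_outputs,
)


def synthetic_trace(peaks, pcl=500.0, dt=1.0):
    """Triangular Ca2+ transients with prescribed per-beat peak values."""
    t = np.arange(0.0, len(peaks) * pcl + dt, dt)
    ca = np.full_like(t, 0.1)
    for k, p in enumerate(peaks):
        rise = (t >= k * pcl + 10) & (t < k * pcl + 60)
        fall = (t >= k * pcl + 60) & (t < k * pcl + 300)
        ca[rise] = 0.1 + (p - 0.1) * (t[rise] - k * pcl - 10) / 50.0
        ca[fall] = p + (0.1 - p) * (t[fall] - k * pcl - 60) / 240.0
    return pd.DataFrame({"t": t, "ca_i": ca})


class TestAlternansAmplitude:
    def test_constant_peaks_amplitude_zero(self):
        res = alternans_amplitude(synthetic_trace([1.0] * 6), 500.0)
        assert res.amplitude == pytest.approx(0.0, abs=1e-9)
        assert not res.alternating

    def test_alternating_peaks(self):
        res = alternans_amplitude(synthetic_trace([1.0, 0.6] * 4), 500.0)
        assert res.amplitude == pytest.approx(0.4, abs=1e-6)
        assert res.alternating
        assert res.last_two == (pytest.approx(1.0), pytest.approx(0.6))

    def test_rescaling_invariance(self):
        # uniform time rescaling and sub-peak baseline shifts leave the
        # amplitude unchanged
        tr = synthetic_trace([0.9, 0.5] * 4)
        res0 = alternans_amplitude(tr, 500.0)
        tr2 = tr.copy()
        tr2["t"] *= 2.0
        assert alternans_amplitude(tr2, 1000.0).amplitude == pytest.approx(
            res0.amplitude
        )
        tr3 = tr.copy()
        tr3["ca_i"] += 0.05
        assert alternans_amplitude(tr3, 500.0).amplitude == pytest.approx(
            res0.amplitude
        )

    def test_missed_beats_flagged_and_excluded(self):
        tr = synthetic_trace([1.0, 1.0, 0.1, 1.0, 1.0, 1.0])  # beat 2 silent
        res = alternans_amplitude(tr, 500.0)
        assert res.missed_beats >= 1
        assert len(res.peaks) <= 5

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            alternans_amplitude(synthetic_trace([1.0, 1.0]), 500.0)


class TestOnsetPCL:
    def _curve(self, rows):
        return pd.DataFrame(rows, columns=["pcl", "amplitude"])

    def test_no_alternating_point(self):
        assert onset_pcl(self._curve([(600, 0.0), (500, 0.003)])) is None

    def test_definition(self):
        curve = self._curve([(600, 0.0), (550, 0.15), (500, 0.2)])
        assert onset_pcl(curve, threshold=0.01) == 550.0

    def test_non_monotone_warns(self):
        curve = self._curve([(600, 0.2), (550, 0.0), (500, 0.2)])
        with pytest.warns(UserWarning):
            assert onset_pcl(curve) == 600.0


class TestOpenFractionMeasure:
    def test_all_closed(self):
        tr = pd.DataFrame({"t": np.arange(5000.0), "mptp_open": 0.0})
        assert measure_mptp_open_fraction(tr, 2000.0) == 0.0

    def test_terminal_window_only(self):
        tr = pd.DataFrame(
            {"t": np.arange(4000.0),
             "mptp_open": np.r_[np.zeros(2000), np.full(2000, 0.5)]}
        )
        assert measure_mptp_open_fraction(tr, 1000.0) == pytest.approx(0.5)

    def test_window_validation(self):
        tr = pd.DataFrame({"t": np.arange(100.0), "mptp_open": 0.0})
        with pytest.raises(ValueError):
            measure_mptp_open_fraction(tr, 1000.0)


class TestScans:
    def test_single_point_consistent_with_direct_run(self):
        cfg = SimConfig(duration=2100.0, seed=3)
        spec = ScanSpec(axes={"pcl": [500.0]}, base_protocol=Protocol(),
                        config=cfg, preset="small")
        table = run_scan(spec)
        assert len(table) == 1
        row = table.iloc[0]
        from mitoca import run_simulation

        direct, _ = run_simulation(
            SimConfig(duration=2100.0, seed=int(row.seed)),
            Protocol(pcl=500.0), preset="small",
        )
        res = alternans_amplitude(direct, 500.0)
        assert row.amplitude == pytest.approx(res.amplitude)

    def test_seeds_depend_on_coordinates_not_order(self):
        s1 = _point_seed(7, {"pcl": 500.0, "alpha_mptp": 60.0})
        s2 = _point_seed(7, {"alpha_mptp": 60.0, "pcl": 500.0})
        s3 = _point_seed(7, {"pcl": 450.0, "alpha_mptp": 60.0})
        assert s1 == s2 != s3
        assert 0 <= s1 < 2**31 - 1

    def test_empty_axis_rejected(self):
        with pytest.raises(ConfigError):
            ScanSpec(axes={"pcl": []})
        with pytest.raises(ConfigError):
            ScanSpec(axes={"bogus": [1.0]})

    def test_bifurcation_requires_single_axis(self):
        with pytest.raises(ConfigError):
            bifurcation_curve(ScanSpec(axes={"pcl": [500.0], "alpha_mptp": [1.0]}))


class TestWriteOutputs:
    def test_empty_table_header_only(self, tmp_path):
        path = write_outputs(pd.DataFrame(columns=["a", "b"]), tmp_path / "x.csv")
        lines = path.read_text().strip().splitlines()
        assert lines == ["a,b"]

    def test_units_header_and_roundtrip(self, tmp_path):
        df = pd.DataFrame({"t": [0.0, 1.0], "ca_i": [0.1, 0.2]})
        path = write_outputs(df, tmp_path / "y.csv", units={"t": "ms", "ca_i": "uM"})
        back = pd.read_csv(path, comment="#")
        assert list(back.columns) == ["t", "ca_i"]
        assert back.shape == (2, 2)

    def test_config_echo(self, tmp_path):
        cfg = {"protocol": {"pcl": 500.0}}
        path = write_outputs(pd.DataFrame({"x": [1]}), tmp_path / "z.csv", config=cfg)
        assert path.with_suffix(".config.yaml").exists()
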