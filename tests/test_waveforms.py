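"""Boundary waveforms: periodicity, extrema placement, positivity and the
exact branch flow split."""

import numpy as np
import pytest

from dissectflow.waveforms import (Waveform, WaveformError,
                                   branch_outflow_waveform,
                                   inlet_velocity_waveform,
                                   outlet_pressure_waveform)


@pytest.fixture(scope="module")
def inlet():
    return inlet_velocity_waveform()


@pytest.fixture(scope="module")
def outlet():
    return outlet_pressure_waveform()


class TestPeriodicity:
    def test_all_waveforms_periodic_at_random_times(self, inlet, outlet):
        rng = np.random.default_rng(7)
        t = rng.uniform(0.0, 10.0, 100)
        branch = branch_outflow_waveform(inlet, 0.05, 20.0, 6.0)
        for w in (inlet, outlet, branch):
            np.testing.assert_allclose(w.evaluate(t),
                                       w.evaluate(t + w.period),
                                       rtol=1e-10, atol=1e-12)

    def test_peak_systole_phase_repeats_in_fourth_cycle(self, inlet):
        assert inlet.evaluate(3.25) == pytest.approx(inlet.evaluate(0.25),
                                                     abs=1e-14)


class TestInletVelocity:
    def test_peak_at_mid_systole(self, inlet):
        t = np.linspace(0, 1, 10001)
        v = inlet.evaluate(t)
        assert t[np.argmax(v)] == pytest.approx(0.25, abs=1e-9)
        assert inlet.evaluate(0.25) == pytest.approx(1.0)

    def test_diastole_at_baseline(self, inlet):
        assert inlet.evaluate(0.6) == pytest.approx(0.0, abs=1e-12)

    def test_peak_below_baseline_rejected(self):
        with pytest.raises(WaveformError):
            inlet_velocity_waveform(peak=-0.5, baseline=0.0)

    def test_non_positive_period_rejected(self):
        with pytest.raises(WaveformError):
            inlet_velocity_waveform(period=0.0)


class TestOutletPressure:
    def test_extrema_match_configured_levels(self, outlet):
        t, v = outlet.cycle_samples(5000)
        assert v.max() == pytest.approx(16.0e3)
        assert v.min() >= 10.6e3 - 1e-9

    def test_strictly_positive_everywhere(self, outlet):
        t = np.linspace(0, 2, 1000)
        assert (outlet.evaluate(t) > 0).all()

    def test_cycle_mean_between_levels(self, outlet):
        assert 10.6e3 < outlet.cycle_mean() < 16.0e3

    def test_inverted_levels_rejected(self):
        with pytest.raises(WaveformError):
            outlet_pressure_waveform(diastolic=16.0e3, systolic=10.6e3)


class TestBranchSplit:
    def test_flow_balance_exact_at_every_instant(self, inlet):
        branch = branch_outflow_waveform(inlet, 0.05, 20.0, 6.0)
        t = np.linspace(0, 1, 200)
        q_in = inlet.evaluate(t) * 20.0
        q_br = branch.evaluate(t) * 6.0
        np.testing.assert_allclose(q_br, 0.05 * q_in, rtol=1e-12, atol=1e-15)

    def test_flat_inlet_arithmetic(self):
        # 0.05 * (1.0 m/s * 20 mm) / 6 mm = 0.1667 m/s
        flat = Waveform(1.0, "velocity", ((0.0, 1.0), (0.5, 1.0)))
        branch = branch_outflow_waveform(flat, 0.05, 20.0, 6.0)
        assert branch.evaluate(0.33) == pytest.approx(0.16667, rel=1e-4)

    def test_zero_inlet_gives_zero_branch(self):
        zero = Waveform(1.0, "velocity", ((0.0, 0.0), (0.5, 0.0)))
        branch = branch_outflow_waveform(zero, 0.05, 20.0, 6.0)
        assert np.all(branch.evaluate(np.linspace(0, 1, 50)) == 0.0)

    def test_doubling_inlet_doubles_branch(self):
        a = branch_outflow_waveform(inlet_velocity_waveform(peak=1.0),
                                    0.05, 20.0, 6.0)
        b = branch_outflow_waveform(inlet_velocity_waveform(peak=2.0),
                                    0.05, 20.0, 6.0)
        t = np.linspace(0, 1, 100)
        np.testing.assert_allclose(b.evaluate(t), 2 * a.evaluate(t),
                                   rtol=1e-12, atol=1e-15)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_fraction_outside_unit_interval_rejected(self, inlet, frac):
        with pytest.raises(WaveformError):
            branch_outflow_waveform(inlet, frac, 20.0, 6.0)


class TestWaveformValidation:
    def test_phases_must_increase(self):
        with pytest.raises(WaveformError):
            Waveform(1.0, "velocity", ((0.5, 1.0), (0.2, 0.0)))

    def test_pressure_must_be_positive(self):
        with pytest.raises(WaveformError):
            Waveform(1.0, "pressure", ((0.0, 1000.0), (0.5, -5.0)))
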