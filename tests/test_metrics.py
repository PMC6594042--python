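"""Normalization, pulse metrics, multiphasic decomposition, onset detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csdquant.metrics import (
    NormalizedTrace,
    default_phase_windows,
    detect_onset,
    multiphasic_metrics,
    normalize,
    pulse_metrics,
)
from csdquant.segmentation import AreaTrace


def make_trace(area, dt=0.25, label="endfoot"):
    area = np.asarray(area, dtype=float)
    return AreaTrace(t_s=np.arange(len(area)) * dt, area_um2=area, label=label)


def triangle_trace(
    peak_pct, t_rise, t_fall, onset=20.0, dt=0.25, total_s=400.0, baseline=100.0
):
    t = np.arange(int(total_s / dt)) * dt
    pct = np.interp(
        t, [onset, onset + t_rise, onset + t_rise + t_fall], [0, peak_pct, 0]
    )
    pct[t < onset] = 0
    return AreaTrace(t_s=t, area_um2=baseline * (1 + pct / 100), label="x")


class TestNormalize:
    def test_constant_trace_is_zero(self):
        ntr = normalize(make_trace([50.0] * 40), (0.0, 5.0), 5.0)
        np.testing.assert_allclose(ntr.pct_change, 0.0)
        assert ntr.baseline_area_um2 == 50.0

    def test_forced_arithmetic_peak(self):
        """A0 = 100, peak 166.7 -> +66.7%."""
        area = np.full(40, 100.0)
        area[30] = 166.7
        ntr = normalize(make_trace(area), (0.0, 5.0), 5.0)
        assert ntr.pct_change[30] == pytest.approx(66.7)

    def test_scale_invariance(self):
        area = 100.0 + 30 * np.sin(np.arange(60) / 5)
        n1 = normalize(make_trace(area), (0.0, 3.0), 4.0)
        n2 = normalize(make_trace(2 * area), (0.0, 3.0), 4.0)
        np.testing.assert_allclose(n1.pct_change, n2.pct_change, atol=1e-9)

    def test_not_invariant_to_raw_area_shift(self):
        """Percent change depends on A0: adding a constant to raw areas
        changes the normalized trace (documented non-invariance)."""
        area = 100.0 + 30 * np.sin(np.arange(60) / 5)
        n1 = normalize(make_trace(area), (0.0, 3.0), 4.0)
        n2 = normalize(make_trace(area + 50.0), (0.0, 3.0), 4.0)
        assert not np.allclose(n1.pct_change, n2.pct_change)

    def test_baseline_overlapping_onset_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            normalize(make_trace([1.0] * 40), (0.0, 6.0), 5.0)

    def test_tiny_baseline_window_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            normalize(make_trace([1.0] * 40), (0.0, 0.3), 5.0)


class TestPulseMetrics:
    def test_triangle_width20_closed_form(self):
        """Rise 10 s, fall 51.6 s -> width20 = 0.8 (10 + 51.6) = 49.28 s."""
        tr = triangle_trace(60.0, 10.0, 51.6)
        ntr = normalize(tr, (0.0, 19.0), 20.0)
        pm = pulse_metrics(ntr, direction="increase", smooth_frames=1)
        assert pm.peak_pct == pytest.approx(60.0, abs=0.5)
        assert pm.t_peak_s == pytest.approx(10.0, abs=0.25)
        assert pm.width20_s == pytest.approx(49.28, abs=0.25)

    def test_flat_trace_reports_no_pulse(self):
        ntr = normalize(make_trace([100.0] * 200), (0.0, 10.0), 12.0)
        pm = pulse_metrics(ntr, direction="increase")
        assert pm.no_pulse and np.isnan(pm.width20_s)

    def test_decrease_direction_finds_constriction(self):
        tr = triangle_trace(-50.0, 8.0, 30.0)
        ntr = normalize(tr, (0.0, 19.0), 20.0)
        pm = pulse_metrics(ntr, direction="decrease", smooth_frames=1)
        assert pm.peak_pct == pytest.approx(-50.0, abs=0.5)
        assert pm.width20_s == pytest.approx(0.8 * 38.0, abs=0.25)

    def test_right_censored_width_flagged(self):
        """Pulse that never recrosses 20% before the recording ends."""
        tr = triangle_trace(60.0, 10.0, 500.0, total_s=120.0)
        ntr = normalize(tr, (0.0, 19.0), 20.0)
        pm = pulse_metrics(ntr, direction="increase")
        assert pm.censored
        assert pm.width20_s <= 120.0  # observable lower bound only

    def test_extremum_tie_resolves_to_earliest_frame(self):
        area = np.full(120, 100.0)
        area[60:70] = 150.0  # plateau peak
        ntr = normalize(make_trace(area), (0.0, 10.0), 12.0)
        pm = pulse_metrics(ntr, direction="increase", smooth_frames=1)
        assert pm.t_peak_s == pytest.approx(60 * 0.25 - 12.0)

    def test_metrics_converge_with_frame_rate(self):
        """4 Hz and 50 Hz samplings agree within one 4-Hz frame interval."""
        results = {}
        for hz in (4.0, 50.0):
            tr = triangle_trace(60.0, 12.7, 153.05, dt=1.0 / hz)
            ntr = normalize(tr, (0.0, 19.0), 20.0)
            results[hz] = pulse_metrics(ntr, direction="increase", smooth_frames=1)
        assert results[4.0].t_peak_s == pytest.approx(
            results[50.0].t_peak_s, abs=0.25
        )
        assert results[4.0].width20_s == pytest.approx(
            results[50.0].width20_s, abs=0.25
        )


class TestWidth20Property:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        t_rise=st.floats(2.0, 30.0),
        t_fall=st.floats(2.0, 120.0),
        peak=st.floats(10.0, 90.0),
    )
    def test_closed_form_holds_for_any_triangle(self, t_rise, t_fall, peak):
        """width20 of a piecewise-linear pulse is 0.8 (t_rise + t_fall),
        independent of peak height, to within a sample interval."""
        dt = 0.1
        tr = triangle_trace(peak, t_rise, t_fall, dt=dt)
        ntr = normalize(tr, (0.0, 19.0), 20.0)
        pm = pulse_metrics(ntr, direction="increase", smooth_frames=1)
        assert pm.width20_s == pytest.approx(0.8 * (t_rise + t_fall), abs=dt)


class TestMultiphasic:
    def _lumen_like(self, dt=0.25):
        """Early +20 at 4 s, nadir -60 at 13 s, late +60 plateau, +65 at 300 s."""
        t = np.arange(int(500 / dt)) * dt
        onset = 60.0
        knots_t = np.array([0.0, 4.0, 13.0, 80.0, 240.0, 300.0]) + onset
        knots_v = np.array([0.0, 20.0, -60.0, 60.0, 60.0, 65.0])
        pct = np.interp(t, knots_t, knots_v, left=0.0, right=65.0)
        pct[t < onset] = 0.0
        return AreaTrace(t_s=t, area_um2=100 * (1 + pct / 100), label="lumen"), onset

    def test_phases_and_offsets(self):
        tr, onset = self._lumen_like()
        ntr = normalize(tr, (0.0, onset), onset)
        m = multiphasic_metrics(ntr, smooth_frames=1)
        assert m.early_dilation_pct == pytest.approx(20.0, abs=1.0)
        assert m.constriction_pct == pytest.approx(60.0, abs=1.0)
        assert m.constriction_metrics.t_peak_s == pytest.approx(13.0, abs=0.25)
        assert m.late_dilation_peak_pct == pytest.approx(60.0, abs=1.0)
        assert m.value_5min_pct == pytest.approx(65.0, abs=0.5)
        assert m.value_20min_pct is None  # recording shorter than 20 min

    def test_short_recording_censors_5min_value(self):
        tr, onset = self._lumen_like()
        cut = int((onset + 200) / 0.25)
        short = AreaTrace(t_s=tr.t_s[:cut], area_um2=tr.area_um2[:cut], label="lumen")
        ntr = normalize(short, (0.0, onset), onset)
        assert multiphasic_metrics(ntr).value_5min_pct is None

    def test_out_of_order_windows_rejected(self):
        tr, onset = self._lumen_like()
        ntr = normalize(tr, (0.0, onset), onset)
        with pytest.raises(ValueError, match="window"):
            multiphasic_metrics(ntr, phase_windows=((0, 10), (5, 60), (60, 240)))

    def test_awake_windows_are_faster(self):
        (w0, w1), *_ = default_phase_windows(awake=True)
        (a0, a1), *_ = default_phase_windows(awake=False)
        assert w1 < a1


class TestDetectOnset:
    def _ntrace(self, pct, dt=0.25, baseline_end=30.0):
        t = np.arange(len(pct)) * dt
        return NormalizedTrace(
            t_s=t,
            pct_change=np.asarray(pct, dtype=float),
            baseline_window_s=(0.0, baseline_end),
            onset_s=baseline_end,
            label="neuron",
        )

    def test_clean_step_detected_at_step_time(self, rng):
        dt = 0.25
        n = 400
        noise = rng.normal(0, 1.0, n)
        pct = noise.copy()
        pct[int(60 / dt) :] += 10.0  # 10-SD step at t = 60 s
        onset = detect_onset(self._ntrace(pct, dt))
        assert onset == pytest.approx(60.0, abs=dt)

    def test_pure_noise_not_detected(self, rng):
        pct = rng.normal(0, 1.0, 400)
        assert detect_onset(self._ntrace(pct)) is None

    def test_short_baseline_rejected(self):
        pct = np.zeros(50)
        ntr = self._ntrace(pct, dt=0.25, baseline_end=1.0)
        with pytest.raises(ValueError, match="10 baseline"):
            detect_onset(ntr)

    def test_synthetic_neuron_channel_onset(self):
        """Detected onset on a rendered neuron channel (default noise)
        lands within two frames of the programmed event time."""
        from csdquant.pipeline import neuron_pct_trace, simulate_recording
        from csdquant.synthetic import default_movie_spec

        spec = default_movie_spec("wt_awake", n_frames=720)  # 120 s is enough
        rec = simulate_recording("wt_awake", seed=5, spec=spec)
        ntr = neuron_pct_trace(rec.stack, rec.spec, (0.0, 30.0))
        onset = detect_onset(ntr)
        assert onset is not None
        assert onset == pytest.approx(
            rec.spec.onset_s, abs=2.0 / rec.spec.frame_rate_hz
        )
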