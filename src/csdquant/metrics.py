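"""Pulse metrics on baseline-normalized area traces.

Converts raw area traces into the quantities reported for CSD-evoked
vascular and endfoot dynamics: percent change from a pre-onset baseline,
peak amplitude, time to peak, width at 20% of peak, the multiphasic
decomposition of the lumen response (early dilation, constriction, late
dilation, value at fixed post-onset offsets), and event-onset detection
from a neuronal fluorescence trace.

Conventions
-----------
* "Width at 20% of peak" is measured on the percent-change-from-baseline
  curve, between the first crossing of 0.2x the peak change before the
  extremum and the first after it, with crossing times linearly
  interpolated between samples.
* A light 3-frame moving median is applied before extremum search to
  suppress single-frame spikes; pass ``smooth_frames=1`` to disable.
* Ties for the extremum resolve to the earliest frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .segmentation import AreaTrace

__all__ = [
    "NormalizedTrace",
    "PulseMetrics",
    "MultiphasicMetrics",
    "normalize",
    "pulse_metrics",
    "multiphasic_metrics",
    "detect_onset",
]

DEFAULT_NOISE_FLOOR_PCT = 5.0
DEFAULT_SMOOTH_FRAMES = 3


@dataclass(frozen=True)
class NormalizedTrace:
    """Percent area change from the pre-onset baseline mean."""

    t_s: np.ndarray
    pct_change: np.ndarray
    baseline_window_s: tuple[float, float]
    onset_s: float
    baseline_area_um2: float = np.nan
    label: str = ""
    recording_id: str = ""

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.t_s)))


@dataclass(frozen=True)
class PulseMetrics:
    """Summary of a single pulse relative to event onset.

    ``peak_pct`` is signed (negative for a constriction); ``width20_s`` is
    NaN when no pulse exceeds the noise floor, and holds the observable
    lower bound when the trace never recrosses 20% of peak before the
    recording ends (``censored`` is then True).
    """

    peak_pct: float
    t_peak_s: float
    width20_s: float
    direction: str
    censored: bool = False
    no_pulse: bool = False


@dataclass(frozen=True)
class MultiphasicMetrics:
    """Decomposition of the multiphasic lumen response.

    ``constriction_pct`` is reported as a positive reduction.  Offset
    values are None when the recording ends before the offset.
    """

    early_dilation_pct: float
    constriction_pct: float
    constriction_metrics: PulseMetrics
    late_dilation_peak_pct: float
    value_5min_pct: float | None
    value_20min_pct: float | None


def normalize(
    trace: AreaTrace,
    baseline_window_s: tuple[float, float],
    onset_s: float,
) -> NormalizedTrace:
    """Express a trace as percent change from its pre-onset baseline mean."""
    b0, b1 = baseline_window_s
    if b1 > onset_s:
        raise ValueError("baseline window must end at or before onset")
    in_base = (trace.t_s >= b0) & (trace.t_s <= b1)
    if in_base.sum() < 3:
        raise ValueError("baseline window must contain at least 3 frames")
    a0 = float(trace.area_um2[in_base].mean())
    if a0 <= 0:
        raise ValueError("baseline mean area must be > 0")
    return NormalizedTrace(
        t_s=trace.t_s,
        pct_change=100.0 * (trace.area_um2 - a0) / a0,
        baseline_window_s=(b0, b1),
        onset_s=onset_s,
        baseline_area_um2=a0,
        label=trace.label,
        recording_id=trace.recording_id,
    )


def _smoothed(pct: np.ndarray, smooth_frames: int) -> np.ndarray:
    if smooth_frames and smooth_frames > 1:
        k = smooth_frames + 1 if smooth_frames % 2 == 0 else smooth_frames
        return medfilt(pct, kernel_size=k)
    return np.asarray(pct, dtype=float)


def _cross_time(t: np.ndarray, y: np.ndarray, i0: int, i1: int, level: float) -> float:
    """Linear-interpolated time where y crosses `level` between i0 and i1."""
    y0, y1 = y[i0], y[i1]
    if y1 == y0:
        return float(t[i1])
    f = (level - y0) / (y1 - y0)
    return float(t[i0] + f * (t[i1] - t[i0]))


def pulse_metrics(
    ntrace: NormalizedTrace,
    direction: str = "increase",
    search_window_s: tuple[float, float] | None = None,
    noise_floor_pct: float = DEFAULT_NOISE_FLOOR_PCT,
    smooth_frames: int = DEFAULT_SMOOTH_FRAMES,
) -> PulseMetrics:
    """Peak, time to peak and width at 20% of peak of one pulse.

    The extremum (max for ``direction='increase'``, min for
    ``'decrease'``) is searched inside ``search_window_s`` (seconds,
    absolute; default: onset to end of trace).  Crossings of 20% of the
    peak change are then located by walking outward from the extremum
    along the full trace and interpolating linearly.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    t = ntrace.t_s
    if search_window_s is None:
        search_window_s = (ntrace.onset_s, float(t[-1]))
    w0, w1 = search_window_s
    if w0 < ntrace.onset_s - 1e-9:
        raise ValueError("search window must start at or after onset")
    in_win = (t >= w0) & (t <= w1)
    if not in_win.any():
        raise ValueError("search window contains no frames")

    y = _smoothed(ntrace.pct_change, smooth_frames)
    sign = 1.0 if direction == "increase" else -1.0
    yw = sign * y
    win_idx = np.nonzero(in_win)[0]
    i_peak = win_idx[int(np.argmax(yw[win_idx]))]  # argmax: earliest tie wins
    peak = float(y[i_peak])

    if sign * peak < noise_floor_pct:
        return PulseMetrics(
            peak_pct=peak,
            t_peak_s=float(t[i_peak] - ntrace.onset_s),
            width20_s=np.nan,
            direction=direction,
            no_pulse=True,
        )

    level = 0.2 * sign * peak  # on the rectified curve
    below = yw < level
    # first crossing before the extremum
    pre = np.nonzero(below[: i_peak + 1])[0]
    if pre.size:
        i0 = pre[-1]
        t_lo = _cross_time(t, yw, i0, i0 + 1, level)
    else:
        t_lo = float(t[0])
    # first crossing after the extremum
    post = np.nonzero(below[i_peak:])[0]
    censored = post.size == 0
    if censored:
        t_hi = float(t[-1])
    else:
        i1 = i_peak + post[0]
        t_hi = _cross_time(t, yw, i1 - 1, i1, level)
    return PulseMetrics(
        peak_pct=peak,
        t_peak_s=float(t[i_peak] - ntrace.onset_s),
        width20_s=t_hi - t_lo,
        direction=direction,
        censored=censored,
    )


def default_phase_windows(awake: bool = False) -> tuple[tuple[float, float], ...]:
    """Phase windows (s after onset) for the multiphasic lumen response.

    Early dilation, constriction, late dilation.  The early window is
    shorter for the awake state, where the whole constriction cycle runs
    on a ~3x faster clock.
    """
    early_end = 3.0 if awake else 6.0
    return ((0.0, early_end), (early_end, 120.0), (120.0, 240.0))


def multiphasic_metrics(
    ntrace: NormalizedTrace,
    phase_windows: tuple[tuple[float, float], ...] | None = None,
    noise_floor_pct: float = DEFAULT_NOISE_FLOOR_PCT,
    smooth_frames: int = DEFAULT_SMOOTH_FRAMES,
) -> MultiphasicMetrics:
    """Early dilation, constriction (with pulse metrics), late dilation,
    and percent change at onset + 300 s / + 1200 s.

    ``phase_windows`` are (start, end) pairs in seconds after onset,
    ordered and non-overlapping; offset values fall back to the nearest
    frame and are None when the recording is shorter than the offset.
    """
    if phase_windows is None:
        phase_windows = default_phase_windows()
    if len(phase_windows) != 3:
        raise ValueError("expected three phase windows (early, constriction, late)")
    prev_end = -np.inf
    for w0, w1 in phase_windows:
        if w1 <= w0 or w0 < prev_end:
            raise ValueError("phase windows must be ordered and non-overlapping")
        prev_end = w1

    t = ntrace.t_s
    y = _smoothed(ntrace.pct_change, smooth_frames)
    t_rel = t - ntrace.onset_s

    def window_extreme(win: tuple[float, float], mode) -> float:
        sel = (t_rel >= win[0]) & (t_rel <= win[1])
        if not sel.any():
            raise ValueError(f"phase window {win} contains no frames")
        return float(mode(y[sel]))

    early = window_extreme(phase_windows[0], np.max)
    cons = pulse_metrics(
        ntrace,
        direction="decrease",
        search_window_s=(
            ntrace.onset_s + phase_windows[1][0],
            ntrace.onset_s + phase_windows[1][1],
        ),
        noise_floor_pct=noise_floor_pct,
        smooth_frames=smooth_frames,
    )
    late = window_extreme(phase_windows[2], np.max)

    def value_at(offset_s: float) -> float | None:
        if ntrace.onset_s + offset_s > t[-1]:
            return None
        i = int(np.argmin(np.abs(t - (ntrace.onset_s + offset_s))))
        return float(y[i])

    return MultiphasicMetrics(
        early_dilation_pct=early,
        constriction_pct=-cons.peak_pct,
        constriction_metrics=cons,
        late_dilation_peak_pct=late,
        value_5min_pct=value_at(300.0),
        value_20min_pct=value_at(1200.0),
    )


def detect_onset(
    neuron_ntrace: NormalizedTrace,
    k: float = 5.0,
    min_sustained_frames: int = 2,
) -> float | None:
    """First time the neuronal trace rises k baseline-SDs above baseline.

    Noise statistics come from the trace's baseline window (>= 10 frames
    required).  The crossing must stay above threshold for at least
    ``min_sustained_frames`` consecutive frames.  Returns the crossing
    time in seconds, or None when no event is detected.
    """
    t = neuron_ntrace.t_s
    y = np.asarray(neuron_ntrace.pct_change, dtype=float)
    b0, b1 = neuron_ntrace.baseline_window_s
    base = (t >= b0) & (t <= b1)
    n_base = int(base.sum())
    if n_base < 10:
        raise ValueError("need >= 10 baseline frames to estimate noise")
    mu = float(y[base].mean())
    sd = float(y[base].std(ddof=1))
    if sd == 0:
        warnings.warn("zero baseline variance; any increase will trigger detection")
    thresh = mu + k * sd
    above = (y > thresh) & (t > b1)
    if min_sustained_frames > 1:
        # require a run of consecutive above-threshold frames
        kernel = np.ones(min_sustained_frames, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid")
        starts = np.nonzero(runs == min_sustained_frames)[0]
    else:
        starts = np.nonzero(above)[0]
    if starts.size == 0:
        return None
    return float(t[starts[0]])
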