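"""Synthetic two-photon movie generator.

Renders seeded two- or three-channel time-lapse stacks of a penetrating
arteriole seen in cross-section (channel 1: intravascular dye filling the
lumen) surrounded by an astrocytic endfoot annulus (channel 2: cytosolic
astrocyte reporter), with exactly known ground-truth area time courses.
An optional channel 3 carries a neuronal activity reporter whose brightness
steps up sigmoidally at event onset, for onset-detection tests.

The programmed dynamics emulate cortical-spreading-depression-evoked
vascular and endfoot responses: the lumen follows a multiphasic course
(brief early dilation, deep constriction, prolonged late dilation) and the
endfoot a single swell-and-recover pulse.  Pulse limbs are piecewise
linear, so peak amplitude, time to peak and width at 20% of peak are
analytically exact and every downstream stage can be validated by
parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MovieSpec",
    "VesselPhantom",
    "DynamicsPreset",
    "TimeCourse",
    "NoiseModel",
    "PRESET_NAMES",
    "build_preset",
    "timecourse_from_preset",
    "render_movie",
    "default_movie_spec",
]

# Late-phase anchors of the lumen time course, seconds after event onset.
# The recovery ramp ends in a plateau at the late-dilation peak which lasts
# until LATE_PLATEAU_END_S, then runs linearly to the programmed value at
# FIVE_MIN_S and holds it for the rest of the recording.
LATE_PLATEAU_END_S = 240.0
FIVE_MIN_S = 300.0

# Early-dilation peak time as a fraction of the constriction nadir time.
EARLY_PEAK_FRACTION = 0.3


@dataclass(frozen=True)
class MovieSpec:
    """Acquisition geometry and timing for one recording."""

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 0.2
    frame_rate_hz: float = 4.0
    n_frames: int = 2400
    onset_s: float = 60.0
    channel_order: tuple[str, ...] = ("lumen", "endfoot")

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) < 1:
            raise ValueError("width_px, height_px and n_frames must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if not 0 <= self.onset_s < self.duration_s:
            raise ValueError("onset_s must lie inside the recording")
        known = {"lumen", "endfoot", "neuron"}
        if not set(self.channel_order) <= known:
            raise ValueError(f"unknown channel labels in {self.channel_order!r}")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def n_channels(self) -> int:
        return len(self.channel_order)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_order.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in channel_order {self.channel_order!r}"
            ) from None


@dataclass(frozen=True)
class VesselPhantom:
    """Geometry and brightness of the rendered arteriole cross-section.

    The endfoot annulus sits outside the lumen, separated by a thin dark
    ``wall_gap_um`` (vessel wall plus paravascular cleft).  The annulus is
    deliberately thicker than a biological endfoot sheath so that its
    pixel-count area is large relative to rasterization jitter; see the
    methods note for the error budget.
    """

    center_um: tuple[float, float] | None = None  # (x, y); None = field center
    lumen_radius_um: float = 8.0
    endfoot_thickness_um: float = 7.5
    wall_gap_um: float = 0.5
    lumen_intensity: float = 150.0
    endfoot_intensity: float = 120.0
    background_intensity: float = 10.0
    neuron_baseline_intensity: float = 20.0
    neuron_peak_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.lumen_radius_um <= 0 or self.endfoot_thickness_um <= 0:
            raise ValueError("radii and thickness must be > 0")
        if self.wall_gap_um < 0:
            raise ValueError("wall_gap_um must be >= 0")
        for name in (
            "lumen_intensity",
            "endfoot_intensity",
            "background_intensity",
            "neuron_baseline_intensity",
            "neuron_peak_intensity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def baseline_lumen_area_um2(self) -> float:
        return float(np.pi * self.lumen_radius_um**2)

    @property
    def annulus_inner_radius_um(self) -> float:
        return self.lumen_radius_um + self.wall_gap_um

    @property
    def baseline_endfoot_area_um2(self) -> float:
        r_in = self.annulus_inner_radius_um
        r_out = r_in + self.endfoot_thickness_um
        return float(np.pi * (r_out**2 - r_in**2))

    def center_in_um(self, spec: MovieSpec) -> tuple[float, float]:
        if self.center_um is not None:
            return self.center_um
        return (
            spec.width_px * spec.pixel_size_um / 2.0,
            spec.height_px * spec.pixel_size_um / 2.0,
        )


@dataclass(frozen=True)
class DynamicsPreset:
    """Programmed group-mean dynamics: amplitudes in %, times in seconds.

    Each packaged preset encodes the published group means for one
    genotype x state group (wild-type or Aqp4-knockout, anesthetized or
    awake).  Zero amplitudes everywhere give the no-event identity.
    """

    name: str
    lumen_early_dilation_pct: float
    lumen_constriction_pct: float
    lumen_constriction_t_peak_s: float
    lumen_constriction_width20_s: float
    lumen_late_dilation_pct: float
    lumen_value_5min_pct: float
    endfoot_peak_pct: float
    endfoot_t_peak_s: float
    endfoot_width20_s: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name != "name" and not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite")
        if not 0 <= self.lumen_constriction_pct <= 100:
            raise ValueError("lumen_constriction_pct must be in [0, 100]")
        for f in (
            "lumen_constriction_t_peak_s",
            "lumen_constriction_width20_s",
            "endfoot_t_peak_s",
            "endfoot_width20_s",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")

    @property
    def is_awake(self) -> bool:
        return "awake" in self.name


# Packaged presets: one per published experimental group.  Amplitudes are
# percent area change from baseline, times are seconds from event onset.
_PRESETS: dict[str, DynamicsPreset] = {
    p.name: p
    for p in (
        DynamicsPreset(
            name="wt_anesthetized",
            lumen_early_dilation_pct=20.0,
            lumen_constriction_pct=61.4,
            lumen_constriction_t_peak_s=13.3,
            lumen_constriction_width20_s=49.1,
            lumen_late_dilation_pct=62.6,
            lumen_value_5min_pct=69.1,
            endfoot_peak_pct=66.7,
            endfoot_t_peak_s=12.7,
            endfoot_width20_s=132.6,
        ),
        DynamicsPreset(
            name="ko_anesthetized",
            lumen_early_dilation_pct=20.0,
            lumen_constriction_pct=85.0,
            lumen_constriction_t_peak_s=13.3,
            lumen_constriction_width20_s=49.1,
            lumen_late_dilation_pct=15.8,
            lumen_value_5min_pct=11.9,
            endfoot_peak_pct=75.2,
            endfoot_t_peak_s=16.8,
            endfoot_width20_s=41.9,
        ),
        DynamicsPreset(
            name="wt_awake",
            lumen_early_dilation_pct=22.1,
            lumen_constriction_pct=62.2,
            lumen_constriction_t_peak_s=5.1,
            lumen_constriction_width20_s=19.4,
            lumen_late_dilation_pct=56.7,
            lumen_value_5min_pct=27.9,
            endfoot_peak_pct=64.7,
            endfoot_t_peak_s=5.7,
            endfoot_width20_s=11.0,
        ),
        DynamicsPreset(
            name="ko_awake",
            lumen_early_dilation_pct=26.8,
            lumen_constriction_pct=48.3,
            lumen_constriction_t_peak_s=5.1,
            lumen_constriction_width20_s=14.1,
            lumen_late_dilation_pct=56.7,
            lumen_value_5min_pct=27.9,
            endfoot_peak_pct=50.3,
            endfoot_t_peak_s=9.9,
            endfoot_width20_s=15.5,
        ),
    )
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)


def build_preset(name: str) -> DynamicsPreset:
    """Return the packaged preset for one experimental group."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        ) from None


def default_movie_spec(preset: DynamicsPreset | str, **overrides) -> MovieSpec:
    """Default acquisition spec for a preset.

    600 s recordings with onset at 60 s; 4 Hz for anesthetized groups,
    6 Hz for awake groups (awake specs also carry the neuron channel).
    """
    if isinstance(preset, str):
        preset = build_preset(preset)
    if preset.is_awake:
        kw = dict(
            frame_rate_hz=6.0,
            n_frames=3600,
            channel_order=("lumen", "endfoot", "neuron"),
        )
    else:
        kw = dict(frame_rate_hz=4.0, n_frames=2400)
    kw.update(overrides)
    return MovieSpec(**kw)


@dataclass(frozen=True)
class TimeCourse:
    """Dimensionless area multiplier s(t), with s = 1 at baseline."""

    t_s: np.ndarray
    scale: np.ndarray
    structure_label: str

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        s = np.asarray(self.scale, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("t_s and scale must be 1-D and the same length")
        if np.any(s <= 0):
            raise ValueError("scale must be > 0 everywhere")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "scale", s)


@dataclass(frozen=True)
class NoiseModel:
    """Imaging imperfections applied at render time.

    photon_noise adds signal-dependent shot noise with variance equal to
    the per-pixel mean count (the Gaussian approximation to Poisson
    counting noise, accurate at the >=10-count levels rendered here);
    read_noise_sd adds signal-independent Gaussian read noise (counts);
    bleach_rate_per_s decays all fluorescence exponentially; the field
    drifts laterally as a slow sub-pixel sinusoid of amplitude
    drift_amplitude_px and period drift_period_s.
    """

    photon_noise: bool = True
    read_noise_sd: float = 2.0
    bleach_rate_per_s: float = 2e-4
    drift_amplitude_px: float = 1.5
    drift_period_s: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.bleach_rate_per_s < 0:
            raise ValueError("read_noise_sd and bleach_rate_per_s must be >= 0")
        if self.drift_amplitude_px < 0 or self.drift_period_s <= 0:
            raise ValueError("drift amplitude must be >= 0 and period > 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(
            photon_noise=False,
            read_noise_sd=0.0,
            bleach_rate_per_s=0.0,
            drift_amplitude_px=0.0,
        )


class InfeasiblePresetError(ValueError):
    """The programmed pulse shape cannot be realised; names the constraint."""


def _pulse_knots_endfoot(preset: DynamicsPreset) -> list[tuple[float, float]]:
    """Knots (t after onset, pct change) of the endfoot swelling pulse.

    An asymmetric triangle rising from onset over t_r = t_peak and falling
    over t_f has width at 20% of peak equal to 0.8 * (t_r + t_f); the fall
    time is therefore width20 / 0.8 - t_r.
    """
    t_r = preset.endfoot_t_peak_s
    t_f = preset.endfoot_width20_s / 0.8 - t_r
    if t_f <= 0:
        raise InfeasiblePresetError(
            f"endfoot pulse infeasible: width20 ({preset.endfoot_width20_s} s) must "
            f"exceed 0.8 * t_peak (0.8 * {t_r} s); no falling limb remains"
        )
    peak = preset.endfoot_peak_pct
    return [(0.0, 0.0), (t_r, peak), (t_r + t_f, 0.0)]


def _pulse_knots_lumen(preset: DynamicsPreset) -> list[tuple[float, float]]:
    """Knots of the multiphasic lumen course (t after onset, pct change).

    Early dilation peaks at EARLY_PEAK_FRACTION of the nadir time; a linear
    limb then descends to the constriction nadir.  The recovery limb's
    slope is solved so the constriction pulse's width at 20% of peak equals
    the programmed value, and continues to the late-dilation peak.  The
    peak holds as a plateau until LATE_PLATEAU_END_S, then a linear segment
    reaches the programmed +5 min value at FIVE_MIN_S, held thereafter.
    """
    e = preset.lumen_early_dilation_pct
    c = preset.lumen_constriction_pct
    t_n = preset.lumen_constriction_t_peak_s
    w20 = preset.lumen_constriction_width20_s
    late = preset.lumen_late_dilation_pct
    v5 = preset.lumen_value_5min_pct

    t_e = EARLY_PEAK_FRACTION * t_n
    # Descending limb crosses -0.2c between the early peak and the nadir.
    t_down = t_e + (e + 0.2 * c) * (t_n - t_e) / (e + c)
    t_up = t_down + w20  # recovery limb must cross -0.2c here
    if t_up <= t_n:
        raise InfeasiblePresetError(
            f"constriction pulse infeasible: width20 ({w20} s) smaller than the "
            f"descending-limb portion ({t_n - t_down:.3f} s); nadir would fall "
            "outside its own pulse"
        )
    slope_up = 0.8 * c / (t_up - t_n)  # pct per second, rising
    t_late = t_up + (late + 0.2 * c) / slope_up
    if t_late >= LATE_PLATEAU_END_S:
        raise InfeasiblePresetError(
            f"late-dilation ramp infeasible: recovery reaches the late peak at "
            f"{t_late:.1f} s after onset, beyond the plateau end "
            f"({LATE_PLATEAU_END_S} s)"
        )
    return [
        (0.0, 0.0),
        (t_e, e),
        (t_n, -c),
        (t_late, late),
        (LATE_PLATEAU_END_S, late),
        (FIVE_MIN_S, v5),
    ]


def timecourse_from_preset(
    preset: DynamicsPreset, spec: MovieSpec, structure: str
) -> TimeCourse:
    """Sample the programmed area-scale curve on the spec's frame grid.

    The returned curve is exactly 1 before onset.  Analyzed at infinite
    resolution it reproduces the preset's peak amplitudes at
    onset + t_peak and its widths at 20% of peak; discretization to the
    frame grid perturbs these by at most one frame interval.
    """
    if structure == "endfoot":
        amps = (preset.endfoot_peak_pct,)
        knot_fn = _pulse_knots_endfoot
    elif structure == "lumen":
        amps = (
            preset.lumen_early_dilation_pct,
            preset.lumen_constriction_pct,
            preset.lumen_late_dilation_pct,
            preset.lumen_value_5min_pct,
        )
        knot_fn = _pulse_knots_lumen
    else:
        raise ValueError(f"structure must be 'lumen' or 'endfoot', got {structure!r}")

    t = spec.times
    if all(a == 0 for a in amps):
        return TimeCourse(t_s=t, scale=np.ones_like(t), structure_label=structure)

    knots = knot_fn(preset)
    last_knot = knots[-1][0]
    post_onset = spec.duration_s - spec.onset_s
    if structure == "endfoot" and last_knot > post_onset:
        raise InfeasiblePresetError(
            f"endfoot pulse ends {last_knot:.1f} s after onset but only "
            f"{post_onset:.1f} s of recording remain"
        )
    kt = np.array([k[0] for k in knots]) + spec.onset_s
    kv = np.array([k[1] for k in knots])
    pct = np.interp(t, kt, kv, left=0.0, right=kv[-1])
    pct[t < spec.onset_s] = 0.0
    return TimeCourse(t_s=t, scale=1.0 + pct / 100.0, structure_label=structure)


def _neuron_brightness(spec: MovieSpec, phantom: VesselPhantom) -> np.ndarray:
    """Uniform-field neuronal-reporter brightness: sigmoidal step at onset.

    The logistic is centered 3 time constants after onset so that its
    leading tail at the programmed onset is ~5% of the step; a threshold
    crossing at a few baseline-SDs then lands within a frame or two of the
    programmed onset rather than far out on the tail.
    """
    t = spec.times
    tau = 0.25  # s, step time constant
    step = 1.0 / (1.0 + np.exp(-(t - (spec.onset_s + 3.0 * tau)) / tau))
    return phantom.neuron_baseline_intensity + (
        phantom.neuron_peak_intensity - phantom.neuron_baseline_intensity
    ) * step


def render_movie(
    spec: MovieSpec,
    phantom: VesselPhantom,
    lumen_tc: TimeCourse,
    endfoot_tc: TimeCourse,
    noise: NoiseModel | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the stack and its ground-truth area table.

    Returns ``(stack, truth)`` where ``stack`` has shape
    (n_frames, n_channels, height, width), dtype uint16, and ``truth`` has
    columns frame, t_s, lumen_area_um2, endfoot_area_um2 (true areas from
    the scale curves, independent of noise settings).

    Pixel intensity encodes sub-pixel edge coverage: a pixel whose center
    lies a distance d from a structure edge of radius r receives coverage
    clip(0.5 + (r - d), 0, 1) with d, r in pixels, so the half-intensity
    level set sits on the true circle.
    """
    if noise is None:
        noise = NoiseModel()
    for tc, lbl in ((lumen_tc, "lumen"), (endfoot_tc, "endfoot")):
        if len(tc.t_s) != spec.n_frames or not np.allclose(tc.t_s, spec.times):
            raise ValueError(f"{lbl} time course is not sampled on the spec's grid")

    psz = spec.pixel_size_um
    r0_px = phantom.lumen_radius_um / psz
    gap_px = phantom.wall_gap_um / psz
    a0_end_px2 = phantom.baseline_endfoot_area_um2 / psz**2

    r_lum_px = r0_px * np.sqrt(lumen_tc.scale)
    r_in_px = r_lum_px + gap_px
    r_out_px = np.sqrt(endfoot_tc.scale * a0_end_px2 / np.pi + r_in_px**2)

    cx_um, cy_um = phantom.center_in_um(spec)
    cx0, cy0 = cx_um / psz, cy_um / psz
    t = spec.times
    if noise.drift_amplitude_px > 0:
        ph = 2 * np.pi * t / noise.drift_period_s
        dx = noise.drift_amplitude_px * np.sin(ph)
        dy = noise.drift_amplitude_px * np.sin(ph + np.pi / 3)
    else:
        dx = dy = np.zeros_like(t)

    # Everything (plus drift and a 1-px soft edge) must stay in the field.
    margin = noise.drift_amplitude_px + 1.0
    r_max = float(r_out_px.max())
    for c0, extent in ((cx0, spec.width_px), (cy0, spec.height_px)):
        if c0 - r_max - margin < 0 or c0 + r_max + margin > extent:
            raise ValueError(
                "phantom exceeds the field of view at maximal dilation/swelling "
                f"(needs radius {r_max:.1f} px plus {margin:.1f} px margin)"
            )

    yy, xx = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    xx = xx.astype(np.float32)
    yy = yy.astype(np.float32)

    bg = phantom.background_intensity
    bleach = np.exp(-noise.bleach_rate_per_s * t).astype(np.float32)
    neuron = _neuron_brightness(spec, phantom) if "neuron" in spec.channel_order else None

    # all per-frame scalars pre-cast to float32 so the hot loop never
    # promotes the 2-D arrays to float64
    f32 = lambda a: np.asarray(a, dtype=np.float32)
    dx32, dy32 = f32(dx + cx0), f32(dy + cy0)
    r_lum32, r_in32, r_out32 = f32(r_lum_px), f32(r_in_px), f32(r_out_px)
    half = np.float32(0.5)
    one = np.float32(1.0)

    rng = np.random.default_rng(noise.seed)
    stack = np.empty(
        (spec.n_frames, spec.n_channels, spec.height_px, spec.width_px),
        dtype=np.uint16,
    )
    add_noise = noise.photon_noise or noise.read_noise_sd > 0
    rn_var = np.float32(noise.read_noise_sd**2)
    u16max = np.iinfo(np.uint16).max
    frame_mean = np.empty(
        (spec.n_channels, spec.height_px, spec.width_px), dtype=np.float32
    )
    idx = {lbl: spec.channel_index(lbl) for lbl in spec.channel_order}
    for i in range(spec.n_frames):
        b = bleach[i]
        d = np.sqrt((xx - dx32[i]) ** 2 + (yy - dy32[i]) ** 2)
        cov_lum = np.clip(half + (r_lum32[i] - d), 0, one)
        cov_ann = np.clip(half + (r_out32[i] - d), 0, one)
        cov_ann -= np.clip(half + (r_in32[i] - d), 0, one)
        frame_mean[idx["lumen"]] = b * bg + np.float32(
            b * (phantom.lumen_intensity - bg)
        ) * cov_lum
        frame_mean[idx["endfoot"]] = b * bg + np.float32(
            b * (phantom.endfoot_intensity - bg)
        ) * cov_ann
        if neuron is not None:
            frame_mean[idx["neuron"]] = np.float32(b * neuron[i])
        out = frame_mean
        if add_noise:
            sd = np.sqrt(out + rn_var) if noise.photon_noise else np.float32(
                noise.read_noise_sd
            )
            out = out + sd * rng.standard_normal(out.shape, dtype=np.float32)
        np.rint(out, out=out)
        stack[i] = np.clip(out, 0, u16max)

    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "t_s": t,
            "lumen_area_um2": phantom.baseline_lumen_area_um2 * lumen_tc.scale,
            "endfoot_area_um2": phantom.baseline_endfoot_area_um2 * endfoot_tc.scale,
        }
    )
    return stack, truth
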