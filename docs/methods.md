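# Methods

`csdquant` quantifies how the cross-sectional area of a penetrating
arteriole's lumen and of its surrounding astrocytic endfeet evolves during
cortical spreading depression (CSD), from two-photon time-lapse movies.
Because no raw in-vivo data are distributed with the published group
means, every stage of the pipeline is validated by *parameter recovery*:
a synthetic movie generator renders an arteriole phantom whose area
dynamics are known exactly, and the pipeline must read those dynamics
back out.

## The measurement model

Cross-sectional area is used as a proxy for arteriolar tone (lumen) and
endfoot volume (endfoot).  For one recording:

1. **Segmentation.**  Each frame of the relevant channel is smoothed with
   a light Gaussian blur (`blur_sigma_px`, default 1 px), then
   contrast-normalized per frame: the lowest and highest
   `saturation_fraction` of pixels (default 0.35%, the conventional
   "enhance contrast" saturation) map to 0 and 1 and the rest stretch
   linearly.  A single fixed threshold (default 0.5 in normalized units;
   an Otsu-based suggestion is available via `suggest_threshold`) is
   applied inside a static ROI; 4-connected components smaller than
   `min_component_px` (default 4) are discarded; pixels exactly at the
   threshold count as signal.  Area = pixel count x `pixel_size_um`².
   Per-frame normalization, not threshold adaptation, provides robustness
   to slow photobleaching.
2. **Normalization.**  A(t) becomes 100·(A(t) − A₀)/A₀, with A₀ the mean
   over a baseline window (default: the 60 s preceding event onset).
3. **Pulse metrics.**  After an optional 3-frame moving median (default
   on; suppresses single-frame spikes; ties at the extremum resolve to
   the earliest frame), the peak percent change, the time from onset to
   the extremum, and the *width at 20% of peak* — the interval between
   the crossings of 0.2x the peak change on either side of the extremum,
   located by linear interpolation between samples — are reported.  A
   pulse whose trace never recrosses the 20% level before the recording
   ends is right-censored: the observable lower bound is returned with a
   flag, and censored widths are excluded from group summaries with a
   logged count.  Peaks below a 5-percentage-point noise floor report
   "no pulse".
4. **Multiphasic lumen decomposition.**  The lumen response is read out
   in three ordered post-onset windows — early dilation (max), constriction
   (min, reported as a positive reduction, with full pulse metrics), late
   dilation (max) — plus the percent change at onset + 300 s and, when the
   recording is long enough, onset + 1200 s (nearest frame; absent
   otherwise).  Defaults: (0–6, 6–120, 120–240) s after onset for
   anesthetized recordings and (0–3, 3–120, 120–240) s for awake ones,
   where the constriction cycle runs roughly three times faster.
5. **Event onset.**  Anesthetized recordings take the trigger time (the
   DC-shift) as input.  Awake recordings detect onset from the neuronal
   Ca²⁺-reporter trace: the first time it exceeds the baseline mean by
   k·SD (default k = 5) for at least 2 consecutive frames, with noise
   statistics from ≥ 10 baseline frames.
6. **Group statistics.**  Mean ± SEM with the recording (one CSD wave) as
   the unit of analysis, matching the published "n waves in m mice"
   convention; mouse IDs are carried but not modeled.  Within-specimen
   comparisons use a one-tailed paired Student's t; between-group
   comparisons a two-tailed pooled-variance Student's t (Welch behind a
   flag).  No multiple-testing correction is applied, matching the
   original analysis.  Within-specimen tests operate on raw areas by
   default (normalized values are an option).

## The synthetic phantom

`synthetic.render_movie` draws, per frame, a bright lumen disc
(channel 1, intravascular dye) of radius r₀·√s_lum(t) and an endfoot
annulus (channel 2, astrocyte reporter) whose inner radius tracks the
lumen wall plus a 0.5 um dark gap and whose area is the baseline annulus
area x s_end(t) — endfoot swelling is rendered as outward growth, a
rendering convention only, since the imaging literature does not resolve
whether endfeet expand inward or outward.  Optional channel 3 is a
spatially uniform neuronal reporter with a sigmoidal brightness step at
onset (time constant 0.25 s, centered 3τ after onset so the leading tail
is negligible at the programmed time).

Pixel intensity encodes sub-pixel edge coverage (clip(0.5 + r − d) with
r, d in pixels), so the half-intensity level set sits on the true circle
and mid-level thresholding recovers areas to well under 1%.

**Programmed dynamics.**  Pulse limbs are piecewise linear, which makes
every target quantity analytic: an asymmetric triangle rising over t_r
and falling over t_f has width at 20% of peak equal to 0.8·(t_r + t_f),
so the solver sets t_f = width20/0.8 − t_r.  The endfoot curve is a
single such triangle.  The lumen curve rises to the early-dilation peak
at 0.3x the nadir time, descends linearly to the constriction nadir,
recovers with the slope that makes the constriction's width-at-20% exact,
continues to the late-dilation peak, holds a plateau to onset + 240 s,
runs linearly to the programmed +5 min value at onset + 300 s and holds
it.  The plateau-then-ramp construction lets the late-dilation peak and
the +5 min value be encoded independently (the published WT means have
the +5 min value *above* the peak-dilation mean).  Infeasible parameter
combinations (e.g. width20 ≤ 0.8·t_peak) raise an error naming the
violated constraint.

**Presets.**  One preset per published group (`wt_anesthetized`,
`ko_anesthetized`, `wt_awake`, `ko_awake`) carries that group's printed
means (amplitudes in %, times in s).  Where a group's value was not
printed, the closest printed stand-in is used: the anesthetized
early-dilation amplitude is set to 20% (the awake value, 22.1%, is the
only printed one); the KO-anesthetized constriction timing reuses the WT
values (the constriction duration was reported as not differing between
genotypes); the awake-WT constriction time-to-peak, late-dilation peak
and +5 min value reuse the printed awake-KO values (reported as not
differing between states' genotypes).  These stand-ins shape phases that
are not recovery targets.

**Noise model.**  Shot noise with variance equal to the per-pixel mean
count (the Gaussian approximation to Poisson counting noise, accurate at
the ≥ 10-count levels rendered), Gaussian read noise (default SD 2
counts), exponential bleaching (default 2·10⁻⁴ s⁻¹, ~11% over a 600 s
recording) and slow sinusoidal lateral drift (default 1.5 px amplitude,
180 s period).  All randomness flows from one seed; fixed seed gives
bit-identical stacks.  The ground-truth area table is computed from the
scale curves and is independent of the noise settings.

**Geometry and the error budget.**  Defaults: 256 x 256 px at 0.2 um/px
(~51 x 51 um field), lumen radius 8 um, annulus thickness 7.5 um, 600 s
recordings with onset at 60 s, 4 Hz (anesthetized) or 6 Hz (awake).  The
annulus is deliberately thicker than a biological endfoot sheath (~1 um):
areas are integer pixel counts, and the timing targets require the
20%-crossing times of slowly falling limbs (slope ~0.4 %/s for the WT
endfoot pulse) to be stable to a fraction of a frame, so the structures
are sized to keep pixel-count quantization (tens of px² on structures of
5–15·10³ px²) below ~0.2% of baseline area.  What the phantom does *not*
emulate: out-of-focus motion, neighboring structures and autofluorescence,
intensity heterogeneity within the endfoot sheath, non-circular lumina,
and ROI-exiting drift — so passing recovery demonstrates the correctness
of the measurement chain, not robustness to every in-vivo artifact.
Static ROIs require drift to stay inside the ROI margin (documented
limitation; no motion correction is attempted).

## Numerical conventions

Pixels are indexed from 0, origin top-left, x rightward, y downward;
areas in um² via `pixel_size_um`².  Frame times are frame_index /
frame_rate.  Offset values fall back to the nearest frame.  A constant
frame normalizes to all zeros with a warning rather than an error.
Degenerate t-tests are guarded (identical pairs: t = 0, p = 0.5;
zero-variance nonzero differences: smallest representable p with a
warning).  Gaussian kernels are truncated at 3σ in both the per-frame
and vectorized stack paths so the two agree.

## Validation scale

The packaged validation renders full-scale movies (600 s at 4–6 Hz,
256 x 256 px).  Amplitude recovery is averaged over 10 seeded noisy
recordings per preset; time recovery additionally uses single noiseless
renders, where every recovered time lands within one frame interval of
the programmed value and every pulse amplitude within 3% relative.
Offset values (percent change at onset + 300 s) carry an extra absolute
tolerance of 0.6 percentage points in the noiseless round-trip check:
pixel-count quantization of the lumen disc contributes ~0.3–0.4 points
of baseline area, which exceeds 3% of the smallest encoded offset
(11.9%) while remaining far inside the perimeter-bound rasterization
allowance.
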