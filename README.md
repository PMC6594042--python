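# csdquant

Quantification of cortical-spreading-depression (CSD)–evoked volume
dynamics of periarteriolar astrocytic endfeet and arteriolar lumina from
two-photon time-lapse movies — together with a seeded synthetic phantom
generator so that the entire measurement chain can be validated by
parameter recovery, without any animal data.

**Who it is for.**  Labs measuring vessel tone and perivascular astrocyte
swelling in vivo: during CSD a penetrating arteriole shows a multiphasic
lumen response (brief early dilation → deep constriction → prolonged
dilation) while the surrounding endfoot sheath swells and recovers.
Cross-sectional areas in a fixed imaging plane serve as proxies for
arteriolar tone and endfoot volume.

**The measurement.**  Per frame: light Gaussian blur → per-frame contrast
normalization (small saturated fraction) → fixed intensity threshold
inside a static ROI → area = pixel count x pixel size².  Traces are
expressed as percent change from the pre-onset baseline mean,
100·(A(t) − A₀)/A₀, and summarized by the field's standard pulse metrics:

* peak amplitude (%), signed by direction (swelling vs constriction);
* time to peak (s) from event onset (DC-shift trigger, or onset detected
  from a neuronal Ca²⁺ reporter in awake recordings);
* **width at 20% of peak** (s): the interval between the two
  linearly-interpolated crossings of 0.2x the peak change;
* the lumen's multiphasic decomposition (early dilation, constriction,
  late dilation, value at onset + 5 min / + 20 min).

Group summaries are mean ± SEM over recordings, with one-tailed paired
and two-tailed two-sample Student's t-tests.  See `docs/methods.md` for
the full model, defaults and limitations.

## Worked example

Render one synthetic wild-type (anesthetized) recording — 600 s at 4 Hz,
256 x 256 px, default noise — and run the full pipeline on it:

```python
from csdquant import simulate_recording, analyze_recording

rec = simulate_recording("wt_anesthetized", seed=1)
rm = analyze_recording(rec.stack, rec.spec, onset_s=rec.spec.onset_s,
                       phantom=rec.phantom)
print(f"endfoot peak        {rm.endfoot.peak_pct:5.1f} % at {rm.endfoot.t_peak_s:.2f} s")
print(f"endfoot width20     {rm.endfoot.width20_s:5.1f} s")
print(f"lumen constriction  {rm.lumen.constriction_pct:5.1f} %")
print(f"late dilation peak  {rm.lumen.late_dilation_peak_pct:5.1f} %")
print(f"value at +5 min     {rm.lumen.value_5min_pct:5.1f} %")
```

```
endfoot peak         66.6 % at 12.75 s
endfoot width20     132.6 s
lumen constriction   60.9 %
late dilation peak   62.8 %
value at +5 min      69.0 %
```

The `wt_anesthetized` preset programs a 66.7% endfoot swelling peaking
12.7 s after onset with a 132.6 s width at 20% of peak, a 61.4% lumen
constriction, a 62.6% late dilation and a 69.1% area increase at
onset + 5 min — so a single noisy recording already recovers each value
to within a couple of percent.  The same works from the shell:

```
csdquant simulate --preset wt_anesthetized --seed 1 --out movie.tif
csdquant extract  --stack movie.tif --rois movie_rois.json --out traces.csv
csdquant metrics  --traces traces.csv --onset 60 --out metrics.csv
csdquant stats    --metrics metrics.csv --groups groups.yaml --out summary.csv
```

plus `csdquant run --config config.yaml --out-dir out/` for the
end-to-end pipeline with a provenance record, and
`csdquant recover-report` for a recovered-vs-programmed comparison over
all presets.

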