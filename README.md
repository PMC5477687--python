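# thermoroi

Quantifying brown-adipose-tissue (BAT) thermogenesis from infrared thermal
video of the cervical–supraclavicular (C-SCV) region.

Active BAT warms the overlying skin, so a thermal camera sees a circumscribed
"hot" region above each supraclavicular depot. `thermoroi` turns a sequence
of per-pixel skin-temperature frames into a physical heat-output estimate:

1. **ROI detection** — a modified *seeded region growing* (SRG) segmentation.
   The seed is the hottest pixel in a pre-defined search window. Let `A_i` be
   the current region and `H = {x ∉ A_i : N(x) ∩ A_i ≠ ∅}` its 8-connected
   frontier. Each step admits the frontier pixel `z` minimising

   `δ(x) = | T(x) − mean_{y∈A_i} T(y) |`,

   provided `δ(z) ≤ T_t`, updating the running mean after every admission.
   Growth stops when the closest frontier pixel deviates by more than the
   tolerance `T_t`, i.e. at a sharp change in the dermal temperature gradient
   — yielding a single closed region, where plain top-quartile thresholding
   (the provided baseline, threshold = median of the hottest 25 % of window
   pixels) scatters into disconnected clusters.
2. **Metric calibration** — four cool aluminium-foil fiducial disks
   (~28–31 °C against ~33 °C skin) mark an 18 cm × 8 cm rectangle on the
   chest. Their detected centroids give an exact 4-point homography (3×3
   matrix) from pixels to centimetres, so ROI pixel counts convert to
   physical areas and pose drift is separated from real temperature change.
3. **Radiometry** — per-frame ROI pixel count and mean temperature are
   averaged over a 5 s, 30 Hz video sequence (150 frames) and converted to
   radiated power with the Stefan–Boltzmann law

   `W = ε σ A T⁴`,  ε = 0.98 (human skin), σ = 5.676 × 10⁻⁸ W m⁻² K⁻⁴,

   with `A` the mean ROI area in m² and `T` the mean ROI temperature in
   kelvin. Left and right C-SCV outputs are summed to a total.
4. **Study statistics** — cohorts are split into low-BAT / high-BAT groups by
   the *mean + 1 SE* rule on the percent change of heat output under cold
   stimulation, with paired t tests and Pearson correlations for the
   surrounding analyses.

Real thermograms of this protocol are not publicly available, so the package
ships a first-class synthetic generator (`thermoroi.synthetic`) producing
scenes with known ground truth — warm skin background, sharp-edged hot
plateaus, foil-disk fiducials, pixel noise, pose drift — plus subject-level
cohorts with planted responders. Everything downstream is validated against
that ground truth.

## Worked example

```python
from thermoroi import (HotspotSpec, SceneSpec, SearchWindow, SegmentationParams,
                       generate_sequence, measure_sequence)

spec = SceneSpec(
    shape=(140, 200),
    fiducial_centers=((20.0, 40.0), (20.0, 160.0), (125.0, 40.0), (125.0, 160.0)),
    hotspots=(HotspotSpec(center=(70.3, 100.6), semi_axes=(12.0, 16.0),
                          delta_t_c=2.0, side="left"),),
    noise_sd_c=0.1, n_frames=150, seed=42,
)
seq, truth = generate_sequence(spec)          # 5 s of video at 30 Hz
window = {"left": SearchWindow(40, 105, 60, 140, side="left")}
params = SegmentationParams(t_t=0.5, seed_tolerance=0.5)
res = measure_sequence(seq, window, params)["left"]
m = res.measurement
print(f"mean ROI area        : {m.area_m2 * 1e4:.2f} cm^2")
print(f"mean ROI temperature : {m.temperature_k:.2f} K")
print(f"radiated heat output : {res.watts:.3f} W")
```

prints

```
mean ROI area        : 6.88 cm^2
mean ROI temperature : 308.15 K
radiated heat output : 0.345 W
```

The detected ROI averages 6.88 cm² at 35.00 °C over the 150 frames; by
`W = ε σ A T⁴` that skin patch radiates 0.345 W. A stimulated scene (plateau
0.4 °C hotter and slightly larger) yields 0.402 W, a **+16.6 %** change
against this baseline — the per-subject quantity the low/high-BAT
classification operates on:

```python
from thermoroi import classify_groups, generate_cohort
table = generate_cohort(n_subjects=24, responder_fraction=0.25, seed=7)
ga = classify_groups(table["pct_change"].to_numpy())
print(f"cutoff {ga.cutoff_pct:.2f} % -> {ga.n_high} high-BAT / {ga.n_low} low-BAT")
# cutoff 26.80 % -> 6 high-BAT / 18 low-BAT
```

## Command line

```sh
thermoroi simulate  --config scene.toml --out scene/
thermoroi segment   --seq scene/sequence.tif --window side=left,45,30,100,95 --tt 0.5 --out roi.json
thermoroi calibrate --seq scene/sequence.tif --out cal.json
thermoroi quantify  --roi roi.json --area-m2 6.9e-4 --out heat.json
thermoroi study     --table subjects.csv --out summary.json
```

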