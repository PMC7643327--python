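# pvq — perivascular quantification

`pvq` is an image-analysis pipeline for studying how cerebral amyloid
angiopathy (CAA) affects perivascular clearance in the mouse cortex. It
re-implements, as tested and reusable code, the quantification steps used in
two-photon and slice-microscopy studies of vascular pulsation and
CSF-tracer transport:

* **Vascular-wall pulsatility** from two-photon line-scan kymographs: the
  vessel diameter trace `D(t)` is tracked per scan line, its moving-average
  baseline `d(t)` is formed, and two indices are integrated over 3000-ms
  epochs:

  ```
  pulsatility index          = ∫₀³⁰⁰⁰ |D(t) − d(t)| dt            [µm·ms]
  relative pulsatility index = ∫₀³⁰⁰⁰ |D(t) − d(t)| / D̄ dt       [ms]
  ```

  where `D̄` is the static mean diameter over the record.
* **Immunofluorescence coverage**: per-vessel smooth-muscle (SMA) and
  amyloid (MX04) coverage inside threshold-derived vessel masks, collagen-IV
  vascular density in a fixed 0.4 × 0.4 mm ROI, parenchymal plaque burden
  (`100 · thresholded MX04 pixels / brain-ROI pixels`), and sub-pixel line
  intensity profiles.
* **Clearance read-outs**: counts of arteries with co-localized SMA and
  tracer signal (intramural periarterial drainage, IPAD), whole-slice
  background-subtracted CSF-influx signal, counts of tracer-positive
  penetrating vessels perpendicular to the cortex, and a dorsal / lateral /
  ventral partition of the cortical band with linearization into an
  arclength profile.
* **Statistics**: ordinary-least-squares regression of tracer influx on
  amyloid burden across slice × region observations, and tidy mean ± SEM
  group tables (inferential ANOVA is left to standard statistical software).

Because no raw imaging data are publicly deposited for this kind of study,
`pvq` ships a first-class synthetic-data module that renders kymographs,
multi-channel slice images and cortical phantoms with exact ground truth,
so every stage of the pipeline is verifiable end to end.

## Worked example

```python
import numpy as np
from pvq import (KymographSpec, make_kymograph, extract_diameter_trace,
                 moving_average_baseline, pulsatility_index)

spec = KymographSpec(baseline_diameter_um=10.0, pulse_amplitude_um=1.0,
                     pulse_frequency_hz=1.0, duration_ms=4000.0,
                     line_period_ms=1.0)
kymo, truth = make_kymograph(spec)            # rendered image + analytic D(t)
trace = extract_diameter_trace(kymo)          # half-maximum wall tracking
trace = moving_average_baseline(trace, 1000.0)
res = pulsatility_index(trace)
print(f"{res.pulsatility_index:.1f} um*ms, {res.relative_pulsatility_index:.2f} ms")
```

prints

```
1910.8 um*ms, 191.08 ms
```

For this 1-Hz, 1-µm-amplitude sinusoid the epoch integral of |D − d| has the
closed form 3·(2/π)·1000 ≈ 1909.86 µm·ms, so the tracked index is within
0.1% of the analytic value, and the relative index is the absolute index
divided by the 10-µm mean diameter.

The full pipeline can be exercised from the shell:

```bash
pvq demo --out demo_run --seed 7
```

which simulates a cohort (kymographs for two genotype groups, a vessel
slice, seven cortical slices with a ventral-high tracer gradient and a
dorsal-high plaque gradient), quantifies everything, fits the
burden–influx regression for both tracers (negative slopes, e.g.
slope ≈ −13.1, R² ≈ 0.99 for the 3-kDa tracer in the bundled
configuration) and writes a `manifest.json` from which the run can be
reproduced byte-for-byte.

## Layout

```
src/pvq/
  synthetic.py    ground-truth generators (kymographs, slices, cortical phantoms, tables)
  pulsatility.py  diameter tracking, moving-average baseline, both indices
  quant.py        vessel masks, coverage, density, plaque burden, line profiles
  clearance.py    IPAD counts, influx signal, penetrating vessels, partition, linearization
  stats.py        OLS regression, group summaries, plots
  cli.py          `pvq` command-line entry point
  io.py           TIFF / YAML / JSON / CSV round-trips
docs/methods.md   model assumptions, parameter choices, numerical notes
```
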