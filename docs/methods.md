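# Methods

This note documents the models, parameter choices and numerical decisions
behind `pvq`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show
about real data.

## Vascular pulsatility

### Model

A line-scan kymograph records one spatial line across a vessel repeatedly
(rows = positions along the line, columns = time lines). With an
intravascular dye the lumen is bright, so at each time line the diameter is
the distance between the two wall crossings of the spatial intensity
profile. From the diameter trace `D(t)` and its moving-average baseline
`d(t)` the absolute index integrates `|D − d|` over 3000-ms epochs
(µm·ms); the relative index divides the integrand by the static mean
diameter over the whole record (ms), so it measures wall movement as a
fraction of vessel calibre. Both are reported as the mean over all complete
epochs; an incomplete trailing epoch is discarded.

### Wall tracking

Each spatial profile is smoothed with a Gaussian (default σ = 1.5 px),
and the diameter is taken between the two half-maximum crossings (a fixed
absolute threshold is available as an alternative for cross-image
comparability). Crossings are refined to sub-pixel precision by solving an
interpolating cubic through the four samples around the bracket; plain
linear interpolation leaves a periodic bias of ~0.03 px that correlates
with the wall oscillation and inflates the rectified integral noticeably at
small amplitudes (≈ 6% at 0.2 µm amplitude versus ≈ 1.7% with the cubic).
The σ = 1.5 px profile smoothing serves the same purpose: a wider, smoother
edge is interpolated more accurately, and the structures of interest
(lumina tens of pixels wide) are far larger than the kernel. Lines without
two crossings are flagged invalid, never imputed; a trace with more than
20% invalid lines is rejected with a diagnostic. The diameter trace is then
low-pass filtered (zero-phase 4th-order Butterworth, default cutoff 25 Hz)
to suppress tracking noise well above the mouse cardiac band (5–10 Hz).

### Baseline and epoch placement

The moving-average baseline uses a centered window, default 500 ms —
several cardiac periods, long enough to track slow drift while averaging
out the pulse. At the record edges the window shrinks symmetrically
(half-width limited by the distance to the nearer record end), which makes
the baseline exactly invariant under time reversal. Near the edges the
shrunken window tracks the oscillation itself, so `|D − d|` is biased
there; epochs are therefore tiled inside the full-window-support region
whenever at least one complete epoch fits (for the 4000-ms default records
with a 500-ms window that region spans 3500 ms, giving one clean epoch).
Only when the record is too short does the layout fall back to starting at
the first sample, and the result is flagged `edges_included`. With
epoch placement in the supported interior, the tracked index on a noiseless
1-Hz unit-amplitude sinusoid is within 0.1% of the closed form
3·(2/π)·1000 µm·ms.

The integral is a rectangle (Riemann) sum with step equal to the line
period; the test suite checks it against an independent trapezoidal
integration (agreement within 0.1%, the residual being the half-sample
end-point difference between the two rules). Invalid samples inside an
epoch are excluded with the step renormalized, but only while they make up
under 5% of the epoch; beyond that the epoch is rejected.

Unstated quantities in the emulated acquisition — line rate, record
length, baseline window, how epochs combine — are declared defaults here:
1 kHz line rate, 4000-ms records, 500-ms window, mean over non-overlapping
complete epochs. All are configurable and recorded in output provenance,
since the indices depend on them.

## Synthetic data

The generators define the conditions under which the pipeline is verified.

* **Kymographs**: `D(t) = baseline + amplitude·sin(2πft) + drift·t`, a
  sinusoid at cardiac frequency plus linear drift — the minimal waveform
  exercising both indices and the baseline. The lumen is rendered bright
  over background (100 vs 1000 intensity units), wall edges are
  area-weighted so sub-pixel tracking is testable, then blurred (σ = 1 px)
  and optionally corrupted by Gaussian or Poisson noise. Because the blur
  is symmetric, the half-maximum crossings of the noiseless profile sit at
  the analytic wall positions, so the analytic `D(t)` is the exact ground
  truth for the default extraction method.
* **Slice images**: vessels are annular walls whose MX04 arc occupies a
  requested fraction of wall pixels, with SMA as its complement
  (independent arcs are possible); tracer-positive vessels are filled with
  3k-FITC over wall and lumen so the co-localization rule sees full
  overlap. The collagen-IV stroke network and the parenchymal plaques are
  trimmed pixel-exactly to the requested area fractions, and parenchymal
  plaques keep a 10-px clearance from vessels so vascular and parenchymal
  amyloid stay distinct objects. Ground truth is measured from the rendered
  boolean masks, which makes noise-free recovery exact by construction.
* **Cortical phantoms**: the brain is a disk, the cortical band its outer
  annulus, and angles from the dorsal midline define dorsal / lateral /
  ventral sectors (landmarks default 60° and 120°). Tracer influx is a
  per-sector intensity step (defaults ventral 80 > lateral 45 > dorsal 20
  for the 3-kDa tracer, 60/35/15 for the 40-kDa tracer, emulating the
  ventral-to-dorsal CSF entry route), plaque burden the reverse gradient
  (dorsal 6% > lateral 4% > ventral 1.5%), and penetrating vessels are
  bright radial stripes. A uniform base level covers the whole canvas so
  the outside-brain median equals the in-tissue baseline. Slice-level
  content is mirrored to the opposite hemisphere for appearance, but
  ground truth refers to the analysed hemisphere.
* **Tabular regional datasets** draw slice × region rows from the same
  gradient means with Gaussian within-region noise (defaults: influx sd 5,
  burden sd 0.8 over 7 slices), clipping negative draws at zero and
  flagging them.

What these phantoms deliberately do **not** emulate: out-of-focus light and
shading, anatomically realistic cortical contours, vessel tortuosity and
branching, motion artifacts, and spatially correlated noise. Passing the
recovery tests shows the measurement code is correct and well-conditioned,
not that segmentation thresholds transfer to any particular microscope.

## Coverage and clearance measurements

Thresholds are explicit policy objects — fixed value, Otsu, or percentile —
and every coverage number is returned with the threshold that produced it.
Otsu is the default for the synthetic benchmarks; a fixed constant is the
appropriate choice when comparing across images, and both per-image and
global modes are available. Vessel masks merge SMA and MX04 pixel-wise by
maximum (sum available), and polygons rasterize by the pixel-center rule.
Background subtraction uses the median of a designated background region
(outside the brain mask by default), clipping at zero — a choice that makes
whole-slice influx invariant to adding a constant offset to the image.

IPAD counting accepts SMA connected components (≥ 20 px) whose
tracer-positive pixel fraction reaches 30%; the original workflow counted
manually, so both numbers are explicit, configurable stand-ins, and the
full component table is returned for audit. Penetrating-vessel counting
operationalizes "perpendicular to the cortex" as: principal axis within
±30° of the local surface normal (approximated radially from the brain-mask
centroid) and aspect ratio ≥ 2. Before thresholding, the merged tracer
channels pass through a white top-hat (radius 5 px) that removes the smooth
regional influx background — without it a global threshold merges the
bright ventral band into one component and swallows the vessels inside it.

The cortical partition assigns band pixels by angle about the centroid;
the three sector masks are disjoint and cover the analysed hemisphere's
band exactly. Linearization bins band pixels in 2° steps and reports the
mean intensity per bin against arclength (angle × mean surface radius),
dorsal to ventral. Landmark angles are inputs, standing in for the manual
template registration of the original workflow; atlas-based registration is
out of scope.

## Regression and summaries

The burden–influx analysis pools every slice × region observation of one
tracer and fits ordinary least squares of influx on burden (statsmodels),
reporting slope, intercept, R², p, n, residual SD and the slope standard
error; a per-region stratified mode is available. Pooling slice × region
rows treats them as independent observations — the same convention as the
emulated analysis — and is flagged here because rows within a slice share
acquisition conditions. Group tables report mean, SEM (sd/√n, sample sd)
and n; ANOVA and post-hoc comparisons are intentionally delegated to
standard statistical software.

When the predictor carries noise (as in the tabular generator), OLS
consistently estimates the attenuated population slope
cov(x,y)/(var(x)+σₓ²), not the noise-free mean-implied slope; the tests
compare against that population value.

## Problem sizes and determinism

The bundled demo and the verification scripts use 4000-ms kymographs at
1 kHz, 512² slice images with 10 vessels, and seven 384² cortical slices —
sizes chosen so a full end-to-end run completes in seconds while every
count and coverage remains exactly recoverable. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
specs and seeds give bit-identical images, tables and manifests, and the
demo's `manifest.json` records seed, version, parameters and SHA-256 of
every output.

## Known limitations

* Wall tracking assumes a single bright lumen per scan line; overlapping
  vessels or dark-lumen contrast need the threshold method and care.
* The radial approximation of the cortical normal is exact for the disk
  phantom and adequate for convex slices, but degrades where the real
  cortical surface curves sharply relative to the mask centroid.
* The per-epoch 3000-ms convention makes indices comparable across vessels
  only at equal window settings; window and smoothing parameters are
  therefore carried in the output provenance.
* Counts depend on explicit stand-in criteria (30% co-localization, ±30°,
  aspect ≥ 2) for judgments the original workflow made by eye.
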