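# Methods

This note documents the models, calibrations and design choices behind
`mucoct`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Image model of the phantom

A B-scan is rendered as

```
I(r, c) = [ R(r, c) · T(r, c) + I_floor ] · S(r, c)
```

* `R` — piecewise-constant mean reflectivity per tissue class.  Defaults
  (arbitrary linear units): epithelium 0.25, lamina propria 0.75,
  keratinized cap 1.30, hyporeflective inclusions 0.08, follicle germinal
  centre 0.30.  The tonsil preset lowers the lamina propria to 0.33 so
  that the epithelium/lamina contrast `(µ_LP − µ_EP)/µ_EP ≈ 0.32` falls in
  the detector's "unsharp" band — the phantom's rendering of the weak
  demarcation characteristic of tonsillar mucosa.
* `T` — cumulative single-pass attenuation, `exp(−Σ µ_layer · l)` down
  each column; defaults 0.0008 /µm (epithelium) and 0.0015 /µm (lamina
  propria) of optical path.  These keep every preset's membrane above the
  SNR floor while letting deliberately thick/attenuating overrides model
  the depth-limited case.
* `S` — fully developed speckle: i.i.d. unit-mean exponential intensity,
  multiplicative (the standard single-look model).  The noise floor
  (default 0.02) is *inside* the speckled term so that the background has
  estimable mean and SD; with speckle disabled the model reduces to the
  plain additive-floor form.  The intensity histogram inside a uniform
  band is exponential (Kolmogorov–Smirnov checked in the suite).

Coordinates: row 0 shallowest; traces are 0-based row indices; the
epithelial band per column is `[surface, bm)` (surface row included, BM
row excluded), so the band thickness in pixels is `bm − surface` and the
geometric thickness is `(bm − surface) · l / n` with `l = 5 µm`,
`n = 1.37`.  The drawn band is `round(d_true · n / l)` rows, so phantom
truths are quantized to one axial row (≈ 3.65 µm geometric).

### Region presets

Thickness means/SDs are the published regional reference values (µm):
labial 243 ± 25, alveolar 142 ± 15, buccal 336 ± 25, sublingual 120 ± 15,
hard palate 198 ± 26 (male 218 ± 19 / female 175 ± 11), soft palate &
oropharynx 130 ± 11, tonsil 125 ± 17.  Vessel-density targets are the
published regional means (0.39, 0.41, 0.21, 0.82, –, 0.34, 0.19); no
hard-palate ratio was reported, so its preset target is 0.  Surface
features, keratinization and component rates follow the regional
descriptions: palatal ridges and a keratin cap for the hard palate,
tonsillar crypts and lymphoid follicles for the tonsil, lesions for the
mechanically stressed buccal mucosa and hard palate, salivary glands
elsewhere.  Poisson rates are set so that the presence probability over
the 2.4 mm field matches the published percentage distributions (e.g.
follicles in ~86% of tonsil scans).

Stated-world choices the source protocol does not pin down:

* **Feature shape** — flat-topped excursions with 30 µm cosine shoulders,
  so that a feature's detectable lateral extent equals its nominal
  diameter and the true surface slope stays within the detector's
  smoothness bound (3 rows/column).  Ridge/crypt amplitudes are drawn
  from 45–55 µm around the 50 µm default; lesion notches are 25–35 µm
  deep over 80–140 µm.  Features do not overlap laterally.
* **Lesion semantics** — a lesion is a surface defect: a trace notch plus
  a *subtle* (×0.8) local backscatter reduction.  It is not a
  reflectivity anomaly of the deep epithelium, so the truth-implied
  homogeneity label depends only on the keratin cap.  This matches the
  source's attribution of inhomogeneity to keratinization.
* **Inclusion geometry** — vessel lumina are ≤ ~100 µm across; glands and
  follicles are 150–300 µm and sit close below the membrane (within
  ~500 µm optical), as described for minor salivary glands, which also
  keeps them above the SNR-limited depth.  All inclusions keep a 16-row
  clearance below the membrane so the BM's intensity step is not
  confounded by a lumen's edge; that clearance is what the two-pass BM
  search (below) relies on.
* **Handheld jitter** — per-B-scan rigid surface offset, Gaussian with
  σ = 3 rows; one thickness draw per series (same tissue in all five
  scans).
* The scan protocol's nominal field (2.4 mm × 0.6 mm) is recorded
  verbatim in `ScanGeometry.nominal_field_um` and never reconciled with
  the pixel-count product (64 × 10 µm = 0.64 mm on the slow axis).

## Surface detection

Noise mean/SD are estimated from the top 8 (air) rows; a pixel is
suprathreshold above `mean + k·SD` (k = 4).  The initial trace is the
first suprathreshold row of a 3×7 median-filtered image, regularized by a
minimal-cost path (dynamic program minimizing Σ|trace − raw| subject to
|Δrow| ≤ 3 between columns).  Two refinements follow, each re-regularized:

1. per-column first crossing of a column-only median within ±2 rows of
   the path (undoes the lateral blur of the 2-D median at sloped
   surfaces — this makes the noiseless detector exact);
2. per-column argmax of the air-to-tissue step of the *log* intensity
   (±2 rows, 5-row windows).  Threshold crossing under speckle is biased
   deep by a fraction of a row; on the log scale the multiplicative
   noise has the same distribution in every window, so the step argmax
   is unbiased (residual bias ≈ 0.2 rows, measured on the phantom).

## Basement-membrane detection

Per column, the BM score at row r is `mean(I[r, r+w)) − mean(I[max(r−w,
surface), r))` on a laterally smoothed image (w = 6 rows, 21 columns);
clipping the upper window at the surface keeps the air region from
outscoring a weak membrane.  Search window: surface + 3 rows to
surface + 1200 µm OPL.

A plain global argmax locks onto the lower edge of any dark inclusion
(stronger dark→bright step than a weak BM), so the search is two-pass:

1. the surface-aligned mean score profile over all columns (averaging
   ~480 columns cancels speckle) gives the typical membrane depth;
2. the per-column argmax is taken within ±12 rows of that depth, the
   picks are median-filtered over 31 columns, and the outer 15 columns
   (which lack lateral support) take the nearest interior row.

Status per column from the step contrast `(below − above)/above`,
measured with wider (51-column) windows than the localization so that
fixed cut-offs are compared against a lower-variance ratio: `found` at
≥ 0.5, `unsharp` in [0.2, 0.5), `absent` below 0.2 or when the epithelial
level at the membrane falls under 2× the noise mean.  Columns under steep
surface topography (≥ 1.5 rows/column on a smoothed trace, dilated by the
widest lateral support) are never graded better than `unsharp` unless the
contrast exceeds 3 × c_hi — lateral smoothing mixes depths there and
border-of-crypt steps can mimic a membrane.  All constants live in
`SegmentationConfig`; they are phantom-tuned calibrations, not published
values (the source's assessments were visual).

Measured on the phantom (20 seeds per preset, default geometry): surface
mean absolute error ≈ 0.6 rows; BM error ≤ 2 rows averaged over `found`
columns for every preset; noiseless renders are recovered exactly.

## Quantification

`opl_to_geometric` is the exact linear map `p · l / n`.  Sampling columns
are centers of equal lateral bins, `floor((i + 0.5)·N/5)` → columns
48, 144, 240, 336, 432 at N = 480 (avoids image-edge columns; an
endpoint-inclusive alternative is selectable).  Columns with `absent` BM
are skipped and counted; a series with no usable sample is *not
assessable* (no mean).  Thickness samples at lesion columns are kept.
The vascularization denominator is the epithelial band area
Σ(bm − surface) over located columns — the same convention the phantom's
vessel placement uses.  The `moderate` class includes both endpoints
([0.10, 0.30]); the printed bounds ("<0.10", "0.10–0.30", ">0.30") are
consistent with the closed interval, and the choice is centralized in
`classify_vascularization`.  Whether the published manual protocol
included the BM pixel in the measured OPL is unstated; this package uses
`bm − surface` rows and documents that convention.

Automatic vessel *segmentation* is out of scope: vessel regions come from
annotations or phantom truth; only the epithelial denominator is
detector-derived in auto mode.

## Scoring calibrations

All constants in `ScoringConfig`; the published judgements were visual,
so these are artifact-owned and tuned on the phantom:

* lesions: trace ≥ 3 rows below a running-median baseline over a lateral
  extent of 50–150 µm; runs inside detected crypt/ridge-scale features
  are not lesions (a crypt floor is not a "single lesion").  The
  intact/with-alterations boundary sits exactly at counts 1 vs 2.
* baseline: running median over **1200 µm** (not 600 µm): the window must
  exceed twice the widest feature (~450 µm palatal ridges), otherwise the
  median tracks the feature itself and ridges go undetected.
* features: seeded at ≥ 25 µm amplitude; extent measured where the
  deviation stays ≥ 0.75 rows, so a flat-topped feature reports its full
  width (within ±2 lateral pixels on the phantom); uneven iff any
  diameter > 200 µm (strictly greater).
* homogeneity: local masked mean (7×31) compared against a 3× larger
  masked background window; anomalies at |z| > 4 with area ≥ 2000 µm².
  The local background absorbs the smooth axial attenuation gradient that
  a single band-wide reference would misread as an anomaly in thick
  epithelium.
* BM label: `not_assessable` when fewer than half the columns have a
  *located* membrane (status `found` or `unsharp`); else `unsharp` when
  unsharp columns form the majority of located ones.  (Reading
  "found-fraction" as literally the `found` status would misclassify a
  uniformly weakly demarcated membrane as not assessable.)
* components: hyporeflective lamina-propria blobs on a row-normalized
  image (reference = 65th percentile / 1.0498 per row — robust to the
  dark blobs themselves), closed and hole-filled (a follicle's bright
  germinal centre makes its blob a ring), gated by area ≥ 320 px and
  minor axis ≥ 20 px (excludes vessel-scale lumina), classified follicle
  when the blob's centre is ≥ 1.3× brighter than its body.

## Aggregation

The unit of analysis is the subject's series mean; B-scans are never
pooled into cohort SDs.  Quartiles interpolate between closest ranks with
Weibull plotting positions (`numpy` method `"weibull"`): {1,2,3,4,5} →
Q1 = 1.5, Q3 = 4.5.  Percentages print to one decimal.  Missing
measurement points are explicit absences.  Between-strata significance
testing is out of scope; only descriptive statistics are reported.

## What a green test establishes — and what it does not

The phantom emulates layered reflectivity, fully developed speckle,
depth attenuation, rigid jitter, and the regional morphology above.  It
does **not** emulate partially developed speckle, beam-geometry effects
(defocus, roll-off), non-rigid motion, refraction at tilted interfaces,
multiple scattering, or biological texture within layers.  Parameter
recovery on the phantom therefore validates the pipeline's correctness
under the stated model, not its clinical accuracy on real endoscopic
data.  Detector calibration constants are honest only in that same sense.

## Numerical choices

* All randomness flows from one root seed through `numpy` `SeedSequence`
  substreams; renders are bit-reproducible.
* Degenerate inputs raise typed errors (all-zero image → surface not
  found; empty epithelium → no vessel ratio; zero usable thickness
  samples → not-assessable result rather than NaN).
* Vessel placement stops within ±0.01 of the target ratio or saturates
  with a warning and the achieved ratio recorded.
* Sample SD uses ddof = 1 and is reported as 0 with an n = 1 flag for
  singletons.
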