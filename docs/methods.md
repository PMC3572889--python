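# Methods

## Measurement model

A radiochromic film read in transmission attenuates the scanner lamp's
light; the red channel of a 48-bit RGB scan carries the strongest dose
response. The pipeline treats the scanner as a densitometer:

* Absolute optical density of a film piece is `OD = log₁₀(white / P̄)`
  with `P̄` the mean red-channel pixel value and `white` the
  full-transmission pixel level (default 65535, the 16-bit maximum; the
  choice only shifts OD by an additive constant and cancels from every
  difference-based statistic).
* Net optical density is a per-pixel difference of the post-irradiation
  and background scans, `NOD = log₁₀ P_back − log₁₀ P_cal`. It depends
  only on the pixel ratio, so no white reference enters.
* Repeated scans of the same film are averaged in raw pixel space before
  the log transform. The log of a mean has lower variance than the mean
  of logs for multiplicative-free additive CCD noise, which is the noise
  regime modelled here.

Axis convention: the first array index is the longitudinal direction
(scan-head travel), the second transverse. All direction-tagged
statistics use this convention.

## Dose-response curve

Dose versus NOD is modelled as `D(x) = a·e^{bx} + c·e^{dx}` with dose the
response variable, fitted by unweighted Levenberg–Marquardt least squares
(relative tolerance 1e-10, iteration budget 10 000). Initialization
exploits the curve's structure — the rising exponential dominates at high
NOD, so `(a, b)` start from a log-linear fit to the upper half of the
data and `(c, d)` from the negative low-NOD residual; signs are free but
start as `(a>0, b>0, c<0, d<0)`.

A fitted curve is only accepted if its derivative
`a·b·e^{bx} + c·d·e^{dx}` is positive on a 512-point grid over the data's
NOD range; monotonicity makes the curve invertible. Inversion uses a
4097-point forward table for a first guess and Newton polishing to
|ΔD| ≤ 1e-9 Gy. Doses outside the representable range either raise (with
the achievable range attached) or clip, by caller's choice.

The bundled reference coefficient set for EBT film,
`(0.7424, 3.094, −0.8355, −4.848)` over NOD ∈ [0.1, 1.2], represents
doses of roughly 0.50–30.4 Gy. The curve deliberately does not pass
through the origin (D(0) = −0.0931 Gy); it is kept as-is — a known
imperfection of this functional form at low dose — and negative
reconstructed doses are clamped to zero only at the dose-map stage, with
the clamp count recorded.

## QA statistics

* `CV = 100·σ/μ` over the ROI, with the population (divide-by-N)
  standard deviation; at the ~2.7·10⁵ pixels of the standard
  16 × 11 cm ROI at 100 dpi the n vs n−1 distinction is immaterial and
  is fixed here for reproducibility. CV is computed in the dose domain.
* `ΔOD_peak = 100·(max − min)/central` of the 1-D mean OD profile
  obtained by collapsing the ROI along the orthogonal axis; "central" is
  the middle index (left of center for even lengths). Collapsing before
  taking extremes gives one robust number per direction per film instead
  of a per-line maximum dominated by noise.
* Both statistics are computed on Wiener-filtered maps by default
  (filtering is switchable), matching a protocol that denoises scans
  before analysis; CV on the filtered dose map, ΔOD_peak on the filtered
  OD map.
* Per-scan drift divides the last-minus-first OD change of a scan series
  by the number of scans n, not by the n−1 intervals; only this
  convention reproduces the standard worked example (0.00157 over 15
  scans → 0.000105 per scan). The off-by-one alternative would give
  0.000112. For before/after protocols the scan count can be passed
  separately from the series length.

## Adaptive Wiener filter

The 5×5 adaptive filter computes local mean m and variance v over the
window (symmetric-reflection edge handling) and outputs
`m + max(v − v_n, 0)/v · (x − m)`, with noise power v_n defaulting to
the global mean of local variances — the conventional adaptive
estimator. Zero-variance windows return the local mean. The
implementation is validated against an independent brute-force
sliding-window oracle.

## Isodose contours and map comparison

Contours are extracted by marching squares with linear interpolation
along cell edges; vertices are emitted in physical mm with pixel centers
at (i + 0.5)·spacing from the map origin (the applicator tip when known,
else the image corner).

The comparison metric between two maps: extract each level's contour
from the reference map, sample the other map bilinearly at every contour
vertex, and average `100·|D_other − L|/L`. It measures dose discrepancy
at matched isodose locations, is robust to differing grid spacings
(comparison happens in physical coordinates; the reference is never
resampled), and the reference/other roles are explicit and swappable.
The default ladder is 1.25–7.5 Gy in 1.25 Gy steps; the overall
aggregate excludes the 1.25 Gy rung by default because relative dose
errors blow up at low dose (scanner noise and the calibration curve's
low-dose deviation), and the per-level numbers remain available.

## Synthetic study conditions

The generator renders every input the pipeline consumes; its defaults
are the study conditions the tests and the acceptance script run under.

* **Source**: two 2 mm × 1 mm Co-60 pellets at ±3 mm on the applicator
  axis, each discretized into ≥10 point elements with kernel
  `S·t·e^{−μr}/r²` (r in cm), μ = 0.06 cm⁻¹ as an effective attenuation
  in near-water plastic, exposure 671.3 s, and strength calibrated so
  that 5 Gy is delivered at 2 cm axial / 2 cm lateral — the in-phantom
  irradiation prescription. This kernel is ground truth for pipeline
  testing, not a transport calculation: anisotropy, scatter build-up and
  applicator shadowing are deliberately absent.
* **Film plane**: 100 × 40 mm half-plane at 0.5 mm spacing, offset
  12 mm laterally so every dose (≈0.59–27 Gy) stays inside the
  calibration curve's representable range; `render_film` refuses doses
  above it and renders doses below it as unexposed background.
* **Scanner model**: total OD = (background OD 0.10 + NOD) × smooth
  multiplicative gain profiles; pixel = white·10^(−OD) per channel
  (green/blue at 20% of the red OD so channel-selection bugs are
  visible), additive Gaussian noise of σ = 80 counts (a realistic
  flatbed CCD figure at 16 bits), clipped to [1, 65535] and rounded.
  Scan k of a series adds (k−1)·δ of drift OD.
* **QA films**: nine 20.3 × 12.7 cm films at 100 dpi, nominal 10 Gy
  (mid of the 0.5–25 Gy uniformity-study range), scanned 3×. Directional
  nonuniformity is injected as sine gain profiles with unity central
  value, so the injected peak-to-peak survives central-ROI cropping
  exactly; the CV nonuniformity is a Gaussian-smoothed random field
  (correlation ~12 px, well above the 5-px filter window so the filter
  does not remove it), doubly centered over the ROI so it is orthogonal
  to the collapsed directional profiles, and scaled to the requested
  dose-domain CV. Realized ground truths — including the propagation of
  OD gain profiles into dose CV through the calibration slope
  (d ln D / d ln x ≈ 1.6–3 over the working range) — are recorded on
  each generated film.

## Numerical choices and degenerate inputs

* 16-bit quantization bounds the dose round trip at ≈2·10⁻⁴ relative;
  the analytic-chain identity is therefore checked with quantization
  disabled (`quantize=False`), and the quantized path has its own
  quantization-limited check.
* cm→pixel ROI conversion rounds to the nearest pixel (16 × 11 cm at
  100 dpi → 630 × 433 px).
* Zero or negative pixels under a log, zero ROI means, degenerate ROIs,
  non-monotone fits, out-of-range doses and non-overlapping maps all
  raise typed errors naming the offending value or location.
* Missing TIFF resolution metadata (or a unit of "none") falls back to
  100 dpi with a logged warning.

## What passing tests do and do not show

The synthetic generator shares the calibration curve with the
reconstruction path, so round-trip tests validate the pipeline's
internal consistency, its statistics and its geometry handling — not the
physical accuracy of any particular film lot, scanner lamp, or source
model. Real films add post-irradiation density growth, temperature and
humidity response, lot-to-lot variation and scan-position dependence,
none of which the generator emulates. Film-vs-ground-truth comparison
figures from the synthetic chain are correspondingly tighter
(sub-percent) than film-vs-calculation agreement achievable with
physical films (a few percent).

## Problem sizes

Tests and the acceptance script use a 200 × 80 px film plane for the
line-source study and full-size (799 × 500 px) nine-film QA sets — the
sizes at which the recovered statistics are stable to well within the
stated tolerances across seeds.
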