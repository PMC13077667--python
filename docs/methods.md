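# Methods

## Scope and coordinate conventions

The package analyzes integrated EPID images of QA deliveries. Pixels are in
calibrated units (CU), the panel's vendor-calibrated dose-response unit; no
dark/flood-field calibration, ghosting correction or panel-sag modelling is
attempted (images are assumed already corrected, and absolute dosimetry
beyond a user-supplied scalar is out of scope).

Continuous panel coordinates are in mm with the origin at the projection of
the beam central axis: x is crossplane (transverse), increasing with column
index; y is inplane (radial), increasing toward the gantry, with image
row 0 at the most positive y. Every ROI dimension and off-axis distance is
declared in the isocenter plane and projected to the panel by the
magnification SID/SAD (default 1500/1000 = 1.5). `axial` symmetry refers to
the inplane/radial axis (y), `transverse` to the crossplane axis (x).

## ROI sampling

`roi_mean` computes an area-weighted mean: pixels fully inside the
projected ROI weigh 1, boundary pixels weigh the fraction of their area
inside the ROI. Rectangles/bands use exact interval-overlap products;
circles use midpoint subpixel supersampling, default 32×32 per boundary
pixel (configurable, floor 16). The weighted mean of a constant image is
exact to 1e-9 for any sub-pixel ROI placement; against an independent
quasi-Monte-Carlo area-integration oracle (scrambled Sobol, 2^16 points)
the engine agrees to better than 1e-3 CU on random step images. Note the
discrete mean evaluates the image at pixel centers, so against *continuous*
closed forms (e.g. disk averages of an analytic profile) agreement is
quadrature-limited at roughly 1e-5 relative for the default 0.8 mm pitch;
tests against such oracles use 5e-4 absolute tolerances for this reason.

Degenerate inputs raise explicit errors rather than returning NaN: ROIs
projecting outside the image, zero-area ROIs, zero denominators in ratio
metrics.

## Field-edge detection

Profiles are averaged over a 5 mm central strip. The plateau is estimated
as the mean of the central 50% of the above-threshold region, and each
field edge is the linearly interpolated crossing of 50% of that plateau
(threshold configurable). The 50%-of-plateau definition is the standard
radiation field-edge convention. Profiles with no crossing or with more
than one above-threshold region ("multiple plateaus") raise errors. With
the logistic penumbra model the 50% point is an inflection, so linear
interpolation is third-order accurate; beam horns bias the plateau estimate
and hence the detected width by ~0.06 mm per edge at the default horn
coefficient — negligible for field centers (the bias is symmetric) but
visible in widths, which is why edge-location ground-truth tests use a
horn-free beam.

## The QA analyses

* **Wedge factor** — ratio of wedged to open readings in a central band
  5 mm wide along the wedge-gradient axis (default y) spanning 80% of the
  detected field length along the unwedged axis. Keeping the 5 mm extent
  along the gradient samples the exponential wedge essentially at the axis
  (the band average differs from the axis value by sinh(aw/2)/(aw/2) − 1 ≈
  1e-6 at 30°); orienting the band the other way would average the full
  gradient and shift WF by ~0.1%. Orientation and dimensions are
  configurable.
* **Central-axis dose** — mean CU in a 5 mm-radius circle at the axis
  (radius configurable to match the reference chamber); percent change
  against a stored baseline.
* **Symmetry** — five 5 mm-diameter circles: axis, (±75, 0), (0, ±75) mm.
  The 75 mm offset (83.33% of the 90 mm CAX-to-edge distance of the 18×18
  cm reference field) is fixed by default; scaling with field size is an
  option, off by default. The circle diameter here is 5 mm while the
  central-dose ROI uses a 5 mm *radius* — both read literally from the
  test battery's definitions, both configurable.
* **Focal spot** — the two-field form is the profile-offset formula
  −(CA90 − CA270)/2 per axis. The four-field form detects field centers of
  an MLC-defined and a jaw-defined opposing-collimator pair, averages each
  pair (cancelling device miscentering — verified by construction in the
  simulator), and solves s = (A_MLC − A_jaw)/[SID·(1/h_jaw − 1/h_MLC)]
  with the jaw height of the matching axis. Default heights h_MLC = 509,
  h_jaw_x = 367, h_jaw_y = 279 mm are typical C-arm values, not
  machine-specific ones, and must be configured per machine; geometries
  with |1/h_jaw − 1/h_MLC| below a floor raise an error. Because real jaws
  and MLCs are not thin planes, height choice is a genuine uncertainty of
  the method; exposing the heights lets that bias be studied, but no
  panel-specific (e.g. arm-backscatter) bias is modelled.
* **VMAT band tests** — leaf-speed bands centered at x = −4.5, −1.5, 1.5,
  4.5 cm with 1×16 cm ROIs; dose-rate/gantry-speed bands at x = −5.1,
  −3.1, −1.1, 0.9, 2.9, 4.9, 6.9 cm with 0.75×17 cm ROIs (the first
  center's sign follows the ascending sequence; all centers are
  configurable). Rcorr = 100·R_LS/R_open, Diff = Rcorr − mean(Rcorr),
  pass iff |Diff| ≤ tolerance (default 2%). Diff sums to zero by
  construction and this is enforced as an invariant.

All metrics are ratios or differences of ROI means and are invariant to
global image rescaling.

## Synthetic image generator

The simulator defines the study conditions under which the analyses are
validated: 18×18 cm fields at SAD 1000/SID 1500 mm on a 512×512, 0.8 mm
panel; flattened profile P(r) = 1 + c·(r/r_f)² with c = 0.03 (3% horns) or
FFF P(r) = 1 − c·(r/r_f)²; logistic penumbra with 3 mm 80–20% width (the
50% point falls exactly at the geometric edge); additive Gaussian pixel
noise, default 0.005 CU (0.5% of the plateau — ROI averaging then
reproduces sub-0.1% metric-level reproducibility, the scale reported for
real integrated images), seeded and bit-reproducible.

Injected errors: a multiplicative output scale (MU changes, exercised over
the 50–60 MU range), linear tilts in fraction per 100 mm (beam steering up
to 10% asymmetry), lateral source shifts up to 0.6 mm (edges ray-projected
per device height), wedge transmission G(y;θ) = exp(−γ·tanθ·(y − y_heel))
with γ = 0.002/mm and heel at −90 mm — an assumed minimal EDW model whose
only contractual property is monotone WF(θ), with WF(10°)=0.969 down to
WF(60°)=0.732 — and VMAT pairs whose dynamic image carries disjoint
hard-edged bands proportional to per-segment MU fractions, against a
uniform open image. Two band conventions exist: `normalize=True` scales by
the segment count so the equal-fraction baseline reproduces the open
plateau (Rcorr ≈ 100), `normalize=False` leaves band = fraction × plateau
(the unscaled convention in which 16/21/29/34% gives Diff = −9, −4, +4,
+9). The modified dose-rate/gantry-speed fractions default to (0.08, 0.14,
0.15, 0.15, 0.16, 0.16, 0.16) — a choice within the stated 8–16% envelope,
not a published vector.

What the simulator deliberately does not reproduce: detector energy
response, arm backscatter, ghosting, flood-field structure, Monte-Carlo
transport, or the radial/transverse response asymmetries of specific panel
generations. Passing the recovery tests therefore demonstrates the
*analysis* chain is correct and sensitive, not that a physical EPID will
match a reference detector; on real images the analyses inherit the
detector's own response errors.

## Plan modification

VMAT errors are injected by editing the cumulative meterset weights of a
beam's DICOM RT Plan control points. Segments are tracked as boundary
weights in [0, 1]; `redistribute` maps each segment's span onto the
requested fraction piecewise-affinely in weight space, which preserves the
relative spacing of interior control points (the delivery shape) while
changing segment MU shares, leaves every non-meterset element bit-exact,
and is exactly invertible (redistributing back to the equal partition
recovers the original weights). The beam's total MU is left untouched.
Baseline segment inference assumes control points land exactly on the
equal-partition grid; otherwise the caller supplies the segment count or
explicit boundaries. `make_demo_plan` builds a minimal synthetic VMAT test
plan (gantry sweep, sliding MLC window) for fixtures and demos.

## Statistics

Reproducibility is the sample SD (n−1) of repeated measurements, default
n = 5. First-order uncorrelated error propagation is provided for ratios,
sd(a/b) = sqrt((σ_a/b)² + (a·σ_b/b²)²), and differences,
sqrt(σ_a² + σ_b²); both are verified against 1e5-sample Monte-Carlo
propagation (the first-order ratio form is adequate at the few-percent
relative-SD scale of these metrics). Sensitivity analysis subtracts the
first (pre-steering baseline) entry from both vectors, then fits ordinary
least squares and Pearson r; OLS rather than an errors-in-variables fit,
matching the simple slope/r reporting convention, and a constant response
is flagged degenerate rather than fitted. Trend analysis normalizes each
device to its first measurement, Δ_t = 100·(m_t/m_1 − 1), and for a device
pair reports paired differences of those deltas with mean ± SD; time
points missing for one device are dropped pairwise with a warning.

## Validation harness and problem sizes

The acceptance script and test suite run the full error-injection →
detection loop on noise-free images (except where noise is the point):
MU scalings 50–60 MU recovered to <1e-4 percentage points; tilt sweeps to
10% recover slope 1 ± 0.01 with r > 0.9999 against the closed-form
injected symmetry; source shifts 0–0.6 mm in 0.1 mm steps recovered within
0.01 mm (achieved ≈ 1.6e-3 mm). Simulations use the 512×512 / 0.8 mm
panel and the sweep sizes above, which resolve every tolerance tested
while keeping the whole validation in seconds.

## Known limitations

- The EDW fluence model is a one-parameter exponential, not a golden-STT
  reconstruction; only relative/monotone wedge behaviour is meaningful.
- Collimating devices are modelled as thin planes at a single height.
- The simulator's noise is white and additive; real EPID noise has
  structure (gain map, ghosting) that flood-field calibration only partly
  removes.
- Segment inference in plans requires grid-aligned control points.
- `detect_edges` is strict about multiple plateaus; heavily modulated
  profiles must be analyzed band-wise, not with the edge detector.
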