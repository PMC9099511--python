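# Methods

## Constitutive model

All quantification is built on the local quadratic expansion of the
stress–strain relation about a chosen stress σ₀,

    σ = σ₀ + E(σ₀)·(ε + β·ε²),

with compressive strain ε and pressure σ taken positive.  E(σ₀) is the
tangent Young's modulus (slope of the stress–strain curve at σ₀) and β the
dimensionless quadratic nonlinearity.  The expansion is deliberately
model-agnostic: it is the lowest-order local description of any smooth
stiffening law, so no exponential or hyperelastic constitutive family
(Neo-Hookean etc.) is assumed anywhere.  Two identities follow and are used
throughout as analytic oracles:

- E(σ) = E₀·√(1 + 4βσ/E₀) = E₀·(1 + 2βε), with E₀ = E(σ→0);
- β(σ₀) = β / (1 + 2β·ε(σ₀)) — the apparent nonlinearity measured at a
  finite standardized stress is reduced relative to the zero-stress β.

`extrapolate_zero_stress` inverts the pair (E(σ₀), β(σ₀)) back to (E₀, β)
via E₀² = E(σ₀)² − 4·β(σ₀)·E(σ₀)·σ₀ and β·E₀ = β(σ₀)·E(σ₀); this is exact
under the quadratic law and is how parameter-recovery results are reported.

## Signal model and phantom

The simulator builds a two-layer medium: a linear reference silicone
(default 100 kPa, 360 µm geometric thickness) over a laterally heterogeneous
tissue zone whose regions each follow the quadratic law.  The probe is much
wider than the imaging depth, so the axial stress is depth-independent per
lateral column; each column's per-frame pressure schedule plus the
constitutive parameters determine all strain and displacement fields in
closed form (the quadratic root is evaluated in the cancellation-free form
2s/(1+√(1+4βs)), stable down to β = 0).

The axial image axis is sampled in air-equivalent optical depth (2 mm over
256 rows by default).  This choice makes the phase-to-strain conversion
refractive-index free: the interframe phase advance per pixel row is
4π·Δz_opt·ε/λ₀ regardless of the layer index, which removes per-layer
pixel-pitch bookkeeping.  The indices (n = 1.4 for both layers by default)
remain in the metadata and convert geometric window sizes in µm to pixels.

Two rendering modes exist:

- `"phase"` (default): a fully developed speckle envelope is rendered once
  as the coherent sum of ≥3 random complex scatterers per resolution cell
  (Gaussian PSF, 10 µm axial × 15 µm lateral FWHM), and every frame is that
  envelope with the per-pixel phase advanced by the exact
  displacement-induced optical-path change.  The per-pixel interframe phase
  advance is exact by construction, which is what makes machine-precision
  strain oracles possible.  It does not model speckle decorrelation from
  scatterers migrating between resolution cells at large strains.
- `"scatterer"`: every frame is re-rendered from the displaced scatterers;
  this produces genuine decorrelation (and correspondingly noisier
  estimates) and serves as the realism cross-check.

Additive noise is circular complex Gaussian, with SNR defined against the
mean tissue-signal power.  Rendering refuses schedules whose single-frame
axial phase *step* (the strain signal) reaches π anywhere — the total
interframe phase advance may span many radians at depth and is harmless,
since the conjugate products cancel it.  Ground-truth generation separately
refuses cumulative strains beyond 30 % (default), the validity bound of the
fixed-grid strain accumulation.

What passing on these phantoms does and does not show: the phantoms share
the measurement physics (phase-displacement coupling, speckle statistics,
sensor linearity, windowed processing) but have exactly quadratic columns,
depth-independent stress, no lateral displacement, no attenuation or
refraction, and no tissue relaxation.  Results on them validate the
estimator chain, not clinical performance on real tissue.

## Strain estimation (vector method)

Interframe strain is the axial gradient of the interframe phase difference.
The vector method forms axial-lag conjugate products of the interframe
product map, d(z) = P(z+lag)·conj(P(z)), and complex-averages them over the
processing window before taking the angle; averaging happens on phasors, so
no unwrapping is needed, and the product magnitudes act as amplitude
weights that de-emphasize dim speckle.  The window defaults to 96 µm
(geometric, in tissue), giving a mapping resolution of about half that.

Lag 1 is always computed first: it is wrap-safe up to the full bound
|ε| < λ₀/(4·Δz_opt) (≈ 4 % per frame at defaults), and provides the quality
map q = |⟨d⟩|/⟨|d|⟩ ∈ [0,1] plus per-pixel wrap flags (q is zeroed where
single-pixel phase steps approach ±π).  Where the lag-1 estimate leaves
headroom below the wrap bound, longer lags (2, 4, 8, capped at half the
axial window) refine the value: an L-pixel lag multiplies the phase signal
by L at constant phase noise, reducing strain noise nearly L-fold.  This
matters most in stiff regions, whose per-frame strains are smallest; it
extends the effective axial support to at most 1.5 windows.  `max_lag=1`
recovers the plain lag-1 estimator.  On noise-free phantoms all lags agree
with the ground truth and with a brute-force least-squares phase-slope fit
to machine precision.

Cumulative strain is the Eulerian sum of interframe maps on the fixed pixel
grid (no re-registration).  This is the standard choice for the ≤ 30 %
regime; a warning is logged above 10 % cumulative strain.  Wrap violations
propagate as zero-quality pixels, never exceptions.

## Stress sensing and curves

The silicone ROI excludes a 2-pixel geometric guard at both layer
boundaries, plus a processing guard of half a strain window at the
tissue-side interface: the windowed estimator mixes tissue strain into
silicone rows within half a window of the boundary, which would bias the
sensor by several percent wherever tissue and silicone stiffness differ
strongly.  (The same guard applies to the first tissue rows used for
curves.)  Silicone strain is depth-collapsed by the arithmetic mean over
the ROI rows and converted by Hooke's law per lateral window; frames with
negative mean silicone strain beyond 1e-4 are flagged as loss of contact
and dropped pairwise from all curves.  An automatic interface detector
(largest jump of the column-median strain profile) exists but metadata is
authoritative; detection refuses cleanly when no discontinuity exists.

Curves are assembled per processing window (stride = half window in both
axes): windowed cumulative tissue strain against the lateral window's
stress trace, re-based so the first valid frame is (0, 0); fewer than 5
valid frames makes a curve unusable.

## Fitting and the (E, β) readout

Two fit backends are provided; both satisfy σ̂(0)=0, monotonicity on the
validity range, and the analytic oracles above.

- `quadratic` (default): nonlinear least squares of the constitutive law
  itself in the strain-on-stress orientation, ε(σ; E₀, β).  The orientation
  is deliberate: essentially all measurement noise lives in the OCT-derived
  strain, while the stress trace is ROI-averaged and comparatively clean,
  so regressing strain on stress satisfies the least-squares error model,
  whereas σ(ε) fits suffer errors-in-variables attenuation.  Differentiation
  is analytic.
- `spline`: shape-agnostic least-squares cubic spline of σ(ε) with sparse
  interior knots, anchored at the origin; if its derivative goes
  non-positive inside the data range it falls back to a monotone PCHIP
  through isotonically projected stresses.  Use it when the quadratic form
  should not be imposed (e.g. visibly non-quadratic curves); its
  twice-differentiated β readout is markedly noisier at realistic SNR.

Fits whose residual RMS exceeds 10 % of the peak stress are marked
unusable.  The tangent modulus at a pressure window [σ₀−tol, σ₀+tol] is the
mean slope over the mapped strain interval (the chord), collapsing to the
point derivative as tol→0.  β is half the least-squares slope of the
sampled E(σ) within the window, widened symmetrically (×1.5 steps, capped
at 4× the original half-width) until it holds ≥3 samples — a finite-window
slope rather than a point second derivative, because noise forbids the
latter.  The default window is 0.5 ± 0.5 kPa; 4.0 ± 0.5 kPa ships as the
second preset.  Negative β estimates are retained (flagged unusable only if
the fitted law loses monotonicity inside the observed range).  Map pixels
whose local stress never enters the window carry NaN plus a False mask —
never 0, which is a legal modulus value.  Each curve paints the central
stride-sized block of the map, so blocks tile the grid without mixing
neighbouring windows.

## Segmentation

Each tissue class occupies an axis-aligned box on the (E, β) plane.
Boxes are calibrated from labelled samples as the [2.5, 97.5] percentile
interval per axis, expanded by 10 % of the box width with absolute floors
(5 % of the centre for E; 0.25 for β) so that noise-free clusters of
near-zero spread still produce usable boxes; classes with fewer than three
samples are excluded with a warning.  Numeric class boundaries are always a
calibration artifact loaded from / written to JSON, never constants of the
package.  Priorities default to descending β_min, so residual overlaps
resolve deterministically toward the more nonlinear class; pixels outside
all boxes stay "unclassified" and masked pixels stay "masked" — neither is
merged into a tissue class, and area fractions over all pixels sum to 1.

The two-class overlap phantom used in validation places the *observed*
tangent moduli of both classes on one interleaved grid (solving the
quadratic law backwards for each stripe's E₀ given its β), so the
class-conditional stiffness distributions coincide by construction while β
stays disjoint — the scenario where single-parameter thresholds must fail
and the two-parameter boxes must not.

## Problem sizes and numerical defaults

Validation experiments run on the default scan format (256×256 px, 4 mm
lateral, 2 mm depth in air) with 50-frame ramps to 3 kPa and 20 dB SNR for
the noisy conditions; the strain-oracle checks use smaller noise-free
uniform phantoms where size is immaterial.  Curve inversion uses Brent's
method on the monotone fit (xtol 1e-12); the constitutive root uses the
stable quadratic form; HDF5 artifacts are written without modification
times so identical seeds reproduce byte-identical files.  All randomness
derives from a single top-level seed through named substreams.

## Known limitations

- The Eulerian accumulation degrades gradually above ~10 % cumulative
  strain; no re-registration is attempted.
- The phase rendering mode omits speckle decorrelation; noise-robustness
  figures at a given SNR are therefore optimistic relative to a real
  instrument at the same SNR.
- Depth-independent stress is assumed, as appropriate for a probe much
  wider than the imaging depth; lateral and shear strains are not modelled
  or estimated.
- The quadratic readout is local: tissues whose behaviour deviates from
  the quadratic law within the fitted stress range are better served by the
  spline backend, at the cost of β noise.
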