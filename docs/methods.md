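# Methods

## Model and assumptions

The package treats a white-light endoscopy frame as a per-pixel observation
of a smooth reflectance spectrum R(λ) on 380–780 nm, seen through an
unknown but stable camera. Two assumptions carry the whole method:

1. **Camera errors are low-order polynomial in tristimulus space.** The
   deviation of camera XYZ from spectrometer XYZ is modelled as a degree-2
   polynomial map (10 monomial terms including a constant). This absorbs
   dark current (constant), channel crosstalk and colour shift (cross
   terms) and mild response nonlinearity (squares). With 24 checker
   patches the system is over-determined about 7:1 per output channel; the
   minimum-norm pseudoinverse solution is used throughout so rank-deficient
   inputs (duplicate patches) degrade gracefully rather than fail.
2. **Scene reflectances live near a low-dimensional linear manifold.**
   Natural and mucosal reflectances are smooth, so a mean-centred PCA basis
   fit to the 24 calibration spectra spans pixel spectra well. The score
   vector of a pixel is predicted from the polynomial expansion of its
   corrected colour; reconstruction is mean + EV·scores, clipped to [0, 1].

Because a 3-channel observation cannot determine more than a few spectral
degrees of freedom, reconstruction fidelity is fundamentally limited by the
basis dimension, not by the regression: the method recovers the projection
of the true spectrum onto the calibration manifold.

### Centering

The literal score-times-basis product without the mean cannot reproduce the
mean spectrum, so centering is on by default: scores are defined about the
PCA mean and the mean is added back at reconstruction. `fit_basis(...,
center=False)` exposes the uncentred variant for comparison.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| expansion degree (correction and colour) | 2 | — | 10 terms vs 24 patches; degree 3 (20 terms) available but close to the data budget |
| PCA variance target | 0.999 | fraction | matches the reconstruction-limited regime; cap of 12 components prevents fitting noise with 24 samples |
| band centres | 415, 540, 600, 700, 780 | nm | haemoglobin absorption peaks plus three long-wave anchors that reproduce the brown cast of hardware narrow-band video |
| band HWHM γ | 15 (415/540), 10 (600/700/780) | nm | ≈30 nm FWHM, typical of narrow-band interference filters; tighter on the red side where bands are auxiliary |
| mixing matrix | 415→G+B, 540→R, 600/700/780→0.15/0.10/0.05 into R | — | classic narrow-band display convention; exposed fully in `SAVEConfig` |
| illuminant | CIE D65 | relative SPD | the endoscope lamp spectrum is not specified anywhere; D65 is sRGB's native white, and any measured illuminant is injectable |
| pseudoinverse cutoff | numpy default (machine-eps scaled) | — | documented, not tuned |

Tristimulus values follow the 0–100 brightness convention: the luminance
ratio k normalises the perfect reflector to Y = 100 under the active
illuminant, and all XYZ-scale RMSE values are reported on that scale. The
Lab white point is derived from the active illuminant via the perfect
reflector, so renders and colour differences stay self-consistent when a
custom illuminant is supplied.

### Colour data

The CIE 1931 2° observer and D65 are shipped as the standard 10 nm
tabulations and upsampled to the 1 nm grid with a shape-preserving PCHIP
interpolant clipped at zero. At this smoothness the interpolation error is
far below every tolerance used in the package. CIEDE2000 is implemented
natively (full formula with the hue-rotation term) and is verified in the
test suite against both the published reference pair and an independent
implementation (`skimage.color.deltaE_ciede2000`) to 1e-9.

## The synthetic data, and what it does not show

The spectrometer measurements and the clinical endoscopy dataset behind
this method are not publicly available, so the package generates synthetic
stand-ins (all deterministic given a seed):

* **Checker spectra** — six flat grays (0.031–0.95) and eighteen chromatic
  patches built from 1–3 Gaussian bumps with documented centres, lightly
  jittered per seed. They are smooth, span the visible range, and are
  moderately saturated so that most patches stay inside the sRGB gamut
  under D65 (a few saturated patches clip slightly, which realistically
  stresses the correction). They are *not* measurements of any physical
  X-Rite chart.
* **Virtual camera** — crosstalk rows (0.92, 0.05, 0.03)-style, response
  exponent 1.05, dark offset 0.01, additive Gaussian noise σ = 0.005 on the
  linear signal. This is the seeded condition used by the calibration
  quality study. The degenerate camera (identity crosstalk, exponent 1, no
  offset/noise) reproduces the ideal colorimetric path to 1e-10, which
  anchors the forward model.
* **Phantom endoscopy images** — three classes (normal / dysplasia / scc)
  differing in base mucosal colour, vessel density, and lesion blob count
  and irregularity, each image with its own patient identifier.

Passing tests on these fixtures demonstrate that the pipeline's algebra,
bookkeeping and statistics are correct and that calibration quality behaves
as expected under a controlled distortion. They do **not** demonstrate
clinical performance: phantom classes are far more separable than real
mucosal pathology, the camera model omits optics (vignetting, chromatic
aberration, specular highlights), and the checker spectra are tamer than
tissue reflectance. Classification accuracies measured on phantoms carry no
clinical meaning and are deliberately excluded from any claims.

## Calibration quality study

`savehsi.pipeline.calibration_quality_study(seed)` is the package's
self-check, evaluated by resubstitution on the 24 training patches (the
appropriate protocol when the question is "how much information survives
the camera", not "how well does it generalise"): mean per-patch spectral
RMSE, mean corrected-XYZ RMSE (0–100 scale), and mean CIEDE2000 between
narrow-band renders of reconstructed versus true spectra. At seed 42 these
are 0.023, 0.29 and 2.71 respectively; across seeds the render colour
difference fluctuates roughly between 2.1 and 3.0 because it is dominated
by how the per-seed noise realisation projects onto the narrow bands.

## Numerical choices and degenerate inputs

* All least-squares solves use `numpy.linalg.pinv` (minimum-norm); fewer
  samples than terms warns and still solves.
* Zero-variance spectra degrade to a one-component basis with a warning;
  an identically zero illuminant is an error for colorimetry but is
  handled in the camera simulation (the sensor then sees dark current
  only).
* Reconstructed reflectance is clipped to [0, 1]; rendered linear RGB is
  clipped to [0, 1] before gamma encoding; 8-bit quantisation happens only
  at image boundaries, never inside the pipeline.
* Precision of a class with no predicted positives is reported as 0 with a
  warning; the pooled two-proportion z-test returns p = 1 when the pooled
  proportion is degenerate (0 or 1).
* The vectorised cube reconstruction precomputes EV·M; it is verified
  against the per-pixel loop to 1e-6 (float32 output).

## Design choices where the design was open

* **Variable-matrix composition.** The monomial family (all monomials of
  X, Y, Z up to degree d plus a constant) is a deliberate choice; the
  error sources it models are listed above. The colour expansion for score
  regression uses the same family, independently configurable.
* **Regression domain.** Correction regresses on linearised camera XYZ
  rather than gamma-encoded RGB; the alternative would fold the display
  nonlinearity into the polynomial and waste expansion capacity on it.
* **Band-to-channel mixing.** Hardware vendors do not publish their
  display mapping; the default matrix is a documented convention, not a
  claim about any vendor's weights.
* **Neural-network option.** The classification harness offers random
  forests (plain and grid-search tuned), an RBF SVM, and a multilayer
  perceptron on downscaled pixels (`mlp`, with `cnn` accepted as a config
  alias). Features for the classical models — flattened 16×16 pixels plus
  per-channel histograms — are a documented stand-in, as there is no
  canonical featurisation of endoscopy frames for non-convolutional
  models.
* **Split policy.** Splits are patient-level: patients are shuffled and
  greedily assigned to partitions to match image-count fractions;
  augmented images are kept only when their source patient is in training,
  otherwise dropped entirely, so no augmented view of an evaluation image
  can leak into training.

## Known limitations

* Reconstruction is linear-in-basis; pixels whose true spectra leave the
  calibration manifold (specularities, bile, blood pools) reconstruct to
  their nearest manifold point.
* The calibration quality study is resubstitution on 24 patches by design;
  held-out spectral generalisation would need a second measured chart.
* The CIE tables are 10 nm tabulations interpolated to 1 nm, adequate for
  smooth reflectances but not for spiky emission sources used as
  illuminants.
* No chromatic adaptation transform is applied; all colorimetry is
  relative to the single active illuminant.
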