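# Methods

## Scope and model overview

The package is a synthetic re-creation of a phantom experiment: how well
does imaged Cherenkov emission reproduce the planned surface dose across
skin tones and delivery techniques? Everything is simulated on a single
co-registered 2-D grid (default 256×256 pixels at 2 mm spacing); the
camera-projection geometry of a real installation is collapsed into that
shared grid, with a random rigid "setup perturbation" standing in for
residual misalignment after re-positioning the phantom.

The chain is:

1. **Skin-tone phantoms** (`optics`, `synthetic.make_phantom_presets`).
   Six presets, Fitzpatrick types I–VI, with melanin index running from 37
   to 120. The endpoints are the study's anchors; interior values are an
   even interpolation and should not be quoted as measurements. Reflectance
   follows from `MI = 100·log₁₀(1/R)` and the CIE L\* of that reflectance
   supplies a lightness coordinate. Note a real colorimeter reads L\* of
   the full visible spectrum, not of the 680 nm band; the two disagree for
   very dark tones (the preset VI L\* here is 30.2, whereas a measured
   value for such a phantom can be in the low 20s). The generator does not
   force agreement.
2. **Melanin attenuation** (`optics.EmissionModel`). The effective optical
   attenuation coefficient is taken linear in MI, so the escaping radiant
   emission falls exponentially: `T(MI) = exp(−k·(MI − 37))`. The default
   `k = ln(10)/83` is calibrated so that T(120)/T(37) is exactly one decade,
   the signal loss reported across typical human skin tones. `T` is applied
   as a single surface factor; `depth_emission_weight` documents the
   `exp(−μ_eff z)` depth dependence with a 5 mm escape cutoff but depth is
   not simulated per voxel, because the comparison operates on surface maps.
3. **Dose maps** (`synthetic.generate_dose_map`). One shared "breast"
   footprint (two oblique bands clipped to an ellipse, mirror-symmetric)
   for all plans. Dose is a function of the signed distance to the
   footprint boundary: a Gaussian-CDF penumbra anchored so the dose at the
   boundary is exactly 30% of the map maximum — hence the ≥30% isodose
   footprint is pixel-identical across plans by construction, isolating
   technique effects from footprint effects. Tangent plans carry a 110%
   interior hotspot, field-in-field caps it at 105% (sub-field trimming),
   VMAT has no hotspot, a slightly tighter penumbra (σ 1.5 px vs 2 px) and
   a uniform 2% out-of-field bath as an integral-dose proxy.
4. **Camera acquisition** (`synthetic.simulate_frames`). The planned dose
   is delivered over `n_frames` gated frames (tangent 60, field-in-field
   80, VMAT 240; exact clinical frame counts are hardware-specific, these
   encode "VMAT accumulates several times more frames"). Per frame and
   pixel: `Poisson(dose·T/n_frames + ambient + leakage·mu_factor)` plus
   Gaussian read noise, clipped at zero; the cumulative image is the frame
   sum. `mu_factor` (2 for VMAT) scales leakage with the monitor units the
   technique needs. Background fractions are 1% (ambient), 1% (leakage)
   and 0.5% (read σ) of the tangent per-frame in-field peak — an absolute
   camera floor shared by all techniques, sized so that light-skin contrast
   is high while the darkest tone under VMAT sinks to the background floor.
5. **Comparison** (`comparison`). Plan mask at 30% of the raw plan maximum;
   image mask swept 15–45% in 1-point steps against the image's
   99.5th-percentile reference (robust to hot pixels; plan maps are
   noiseless so the raw max is used there). Thresholds are inclusive (≥).
   The largest Dice wins; ties resolve to the smallest threshold. Both
   masks empty counts as agreement (DSC 1), exactly one empty as total
   disagreement (0) — degenerate cases the study never reaches, fixed for
   continuity.
6. **Trends and summaries** (`regression`). Intensity vs CIE-L is fitted by
   ordinary least squares; intensity vs MI by exponential decay, fitted in
   log space by default (deterministic; nonlinear refinement available) with
   r² reported in log space and the original-scale r² kept alongside.
   ROI intensities entering the trend fits are background-corrected (an
   out-of-field corner ROI) and normalised to the type I phantom. Replicate
   summaries use the population standard deviation. Tukey HSD across cells
   is delegated to `scipy.stats.tukey_hsd` and reported as-is.

## Units and the counts scale

Dose maps are expressed directly in expected accumulated camera counts at
the reference tone, making Poisson noise physically meaningful without a
separate gain. The default prescription peak is 500 accumulated counts
(≈9 counts/frame/pixel for the 60-frame tangent delivery) — the
photon-starved regime of pulse-gated Cherenkov cameras, where shot noise
visibly blurs the field edge for dark tones.

## Randomness and the paired design

All streams derive from one master seed through `SeedSequence` keyed on
fixed (phantom, plan, replicate) indices, so adding cells never shifts
other cells' streams, and every seed is logged in the run manifest.

Two choices make across-tone contrasts statistically efficient
(common random numbers), without changing any cell's marginal distribution:

* the setup perturbation is seeded per (plan, replicate) and therefore
  shared across phantoms — each "re-setup" is imaged for all tones;
* by default (`paired_acquisition=True`) the six tones' acquisitions are
  coupled per (plan, replicate): each frame draws the darkest tone's
  Poisson counts first and adds independent `Poisson(Δsignal)` increments
  tone by tone, with one shared read-noise field. Each tone's image remains
  exactly `Poisson(signal+background) + Gaussian`, but shot noise is as
  common across tones as the physics allows.

This matters because the systematic Dice separation between adjacent light
presets is tiny (≈5·10⁻⁵, consistent with light tones being statistically
indistinguishable in practice) while one replicate's setup error moves the
Dice by ~10⁻². Unpaired, the melanin ordering would be unresolvable at any
practical replicate count. `paired_acquisition=False` restores fully
independent per-cell acquisitions.

## Numerical choices and degenerate inputs

* Sweep step 1 percentage point (31 thresholds); finer than any observed
  Dice plateau, configurable.
* The zero-clip of read noise adds a small positive bias to the expected
  background floor (~8% of the floor at defaults) because a Poisson count
  of zero cannot go negative; analytic background expectations are exact
  only with read noise off.
* "Exact" calibration identities (transmission ratio 10, k recovery) hold
  to IEEE-double precision (≈1e-15 relative), since `exp(ln 10)` is not
  bitwise 10.
* All-zero grids have no reference maximum and are rejected; empty frame
  stacks, empty ROIs, non-positive intensities in the exponential fit, and
  constant predictors in the linear fit raise errors rather than returning
  NaN.
* `shot_noise=False` on a delivery spec replaces Poisson draws by their
  expectation; combined with zero background it produces the noiseless
  images used for calibration identities.

## Problem sizes used by the tests

Unit tests run on 64×64 grids with reduced frame counts. The full-grid
ordering check runs the default 256×256 study with 60 paired replicates per
cell — sized by a power analysis so the smallest adjacent-tone Dice gap
(≈5·10⁻⁵, standard error 1.25·10⁻⁴ per paired replicate) is resolved at
z ≈ 3. The acceptance script averages 10 independently seeded acquisitions
per reported Dice value.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms*: exponential signal loss with MI,
fluence conservation across delivery techniques, background accumulation
growing with frame count and monitor units, threshold geometry of the
sweep, and re-setup variability. It does not reproduce: phantom surface
curvature and camera perspective (flat co-registered grids), spectral
response of camera or pigments, measured colorimetry of particular
phantoms (types II–V are interpolations), room-light variations, or
treatment-planning-system dose engines (the dose shapes are parametric).
Quantities that depend on those physical specifics — measured r² values of
the intensity trends, absolute CIE-L/ITA values per type, the measured
replicate standard deviation, significance levels — are represented here
only by the weaker property checks the tests assert (trend recovery under
noise, replicate spread ≤ 0.03, ordering of Dice with MI). In particular,
the darkest-tone VMAT Dice collapses to ≈0.40 in this simulation — a
stronger degradation than physical measurements show (~0.75–0.80), because
the synthetic background floor fully swamps the tenfold-attenuated signal
at every sweep threshold, while a real camera's background is structured
and partially separable.

## Known limitations

* Dice between light tones differs at the 10⁻⁴–10⁻⁵ level; conclusions at
  that resolution depend on the paired design and are not claims about
  physically distinguishable image quality.
* The rigid setup perturbation has fixed bounds (±2 px, ±1°); real setup
  error scales with anatomy and immobilisation.
* 16-bit TIFF output quantises grids to the sidecar-recorded scale; CSV
  output is lossless to 8 significant digits.
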