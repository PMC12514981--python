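# Methods

## Problem

Cycloplegic refraction is the clinical gold standard for measuring refractive
error in children, because accommodative tonus at the phoropter inflates
myopia (or masks hyperopia) by a few tenths of a diopter — more in younger
children. Cycloplegia, however, costs clinic time and causes hours of blurred
vision and photophobia, which limits its use in school screening. `cycloref`
implements a pipeline that predicts the cycloplegic sphere S′ from quantities
measurable *without* cycloplegia: demographics, the non-cycloplegic
autorefraction (S, C, axis), IOP, and optical biometry (AL, CCT, ACD, LT, K1,
K2, Km). Its distinguishing ingredient is a set of crystalline-lens features
derived from routine biometry through the SRK/T intraocular-lens formula,
motivated by the physical observation that the cycloplegic shift originates
in the lens, and predominantly in its anterior surface.

## Lens-feature derivation (optics module)

All powers are in diopters (m⁻¹), lengths in millimetres; lengths are
rescaled by 1000 where they enter dioptric terms.

1. Mean corneal radius: r = 337.5 / Km (keratometric index constant).
2. Retina-corrected axial length: LOPT = AL + 0.65696 − 0.02029·AL.
3. Emmetropic lens-power proxy (SRK/T with the *measured* ACD as the lens
   plane):

       IOL_e = 1000·n_a (n_a r − Δn·LOPT) / [(LOPT − ACD)(n_a r − Δn·ACD)],

   with n_a = 1.336 (aqueous/vitreous) and Δn = 0.333.
4. Retained-refraction variant IOL_m: the same expression with the vertex
   correction term −0.001·SE·[12(n_a r − Δn·LOPT) + L·r] inserted in the
   numerator bracket (L = LOPT) and its ACD analogue in the denominator
   bracket, where SE = S + C/2 is the **non-cycloplegic** spherical
   equivalent (the feature must exist before cycloplegia) and 12 mm is the
   spectacle vertex distance.
5. Contact-lens variant IOL_cl: vertex-transpose the refraction to the
   cornea, F_c = SE/(1 − 0.012·SE), fold it into the cornea,
   r_cl = 337.5/(Km + F_c), and evaluate the emmetropic formula with r_cl.
6. Anterior-surface decomposition: with the posterior surface fixed at its
   schematic-eye value F_p = 9.26 D and lens index n_L = 1.40, the Gullstrand
   thick-lens equation F = F_a + F_p − (LT/1000/n_L)·F_a·F_p is inverted for
   F_a, and r_a = 1000(n_L − n_a)/F_a.

Step 6 deserves a note: the published rendering of the thick-lens inversion
and the radius relation is typographically corrupted, so the package uses the
standard paraxial forms above, which are dimensionally consistent, reduce to
the printed symbols, and are the only reading under which F_p = 9.26 D and
n_L = 1.40 make sense. The lens index (1.40) and the aqueous index (1.336)
are kept as separate constants. All constants live in `OpticalConstants` and
can be overridden.

Monotonicity of the emmetropic proxy: IOL_e decreases with AL (longer eyes
need less lens power) and **increases** with r (a flatter cornea contributes
less power, so the lens must contribute more). Both directions are asserted
numerically in the tests.

## Feature tables

The control table carries 14 routine features (gender, age, S, IOP, AL, CCT,
IOP/CCT, AL/CCT, K1, K2, Km, r, AL/CR, VCD); each experimental table adds
ACD, LT, the variant's IOL, F_a and r_a, and the ratios AL/ACD, AL/LT,
AL/VCD, LT/r_a, ACD/r_a. VCD is not measured directly and is derived as
AL − CCT − ACD − LT. CCT is carried in millimetres (an explicit `cct_unit`
flag accepts micrometre input); gender is encoded 0 = male, 1 = female.
Rows with underivable values carry NaN and are never dropped — imputation is
the pipeline's job, not the feature builder's.

## Synthetic cohort

No clinical dataset ships with the package; the generator produces cohorts
with the statistical structure the method assumes, for development, testing
and calibration experiments. Defaults (all in `CohortConfig`):

- 306 eyes, 153 subjects, ages uniform on 4–15 years (shared by fellow eyes).
- Non-cycloplegic sphere: mean −1.53 D, SD 2.17 D, truncated to (−7.5, +10.5).
- Cycloplegic shift ΔS: mean +0.34 D, SD 0.53 D, nonnegative, declining with
  age at −0.04 D/year.
- Cylinder: mean −0.87 D, SD 0.75 D, minus convention; its cycloplegic shift
  −0.03 ± 0.30 D.
- Within-subject correlation 0.8 for all eye-level latent draws (fellow eyes
  are strongly alike).
- Biometry: age-trended normals for AL, ACD, LT, Km, CCT, IOP inside
  physiologic ranges; AL additionally tracks the cycloplegic refraction at
  −0.35 mm/D (axial ametropia), and Km is negatively correlated (−0.4) with
  the AL residual.

The tonus model is the scientific core of the generator. The latent shift is

    ΔS* = μ₀ + β_age·(age − 9.5) + λ·Lᵢ + σ·ε,   ΔS = max(0, ΔS*),

where Lᵢ = (z_LT − z_ACD)/√2 is a standardized lens-geometry factor (thicker
lens and shallower chamber → more tonus) and ε is noise. `lens_share` (the
fraction of the non-age variance carried by L, default 0.5) makes the shift
partially recoverable from lens-related features but not from the control
set — the qualitative property the prediction experiment tests. The measured
(non-cycloplegic) anterior segment feeds back the tonus at literature
accommodation coefficients: ACD shrinks by 0.047 mm/D and LT grows by
0.063 mm/D of tonus. The intercept μ₀ is solved with `brentq` on the exact
truncated-normal mean averaged over the age distribution, so the configured
mean of +0.34 D is the *population* mean after the floor at zero; the
sphere and cylinder truncation locations are solved the same way. The
configured SDs are latent scales; the realized SD of ΔS is smaller (≈0.43 D)
because of the floor.

What the generator does **not** emulate: measurement error structure of real
autorefractors, longitudinal progression, axis-resolved corneal topography,
non-Gaussian tails of refraction distributions, or any anatomical covariance
beyond the couplings listed. Passing tests therefore demonstrate that the
pipeline recovers a lens-mediated signal *when one is present by
construction*, not that the clinical effect size is reproduced.

The accommodation-series generator emulates AS-OCT runs on 16 eyes over a
0–6 D stimulus grid. Curvature changes are expressed as magnitude decreases
(positive = steepening); the generating quadratics stimulus = a·Δ² + b·Δ + c
default to (0.01, 1.21, −0.02) for the anterior and (−2.40, 9.30, −0.60) for
the posterior surface. (On a signed radius-change axis the anterior linear
coefficient would print as −1.21; the magnitude convention flips the sign of
the odd term and leaves |b| and every derived statistic unchanged.) The
zero-stimulus row is anchored exactly at the baseline radii, which sits off
the generating curve by its intercept; zero-noise round-trip fits therefore
use the positive-stimulus points, which lie exactly on the curve. Default
measurement noise is 0.15 mm (ACR) and 0.05 mm (PCR), a calibration choice,
not an empirical claim; at these levels pooled fits recover the anterior
slope 1.21 D/mm to within a few percent.

## Prediction pipeline

- **Split**: one shared 80/20 split for all four groups (train size
  round(0.8·n): 306 → 245/61), optionally grouped by subject so fellow eyes
  never straddle the split. Eye-level splitting is the default to match the
  per-eye analysis; the grouped option is recommended when inference about
  subjects is intended.
- **Imputation**: per-column training-set medians, reused verbatim on the
  test rows. Deterministic, order-free, leakage-safe.
- **Screening**: LASSO on standardized training features, penalty chosen by
  k-fold CV mean squared error (CV-min rule, which retains more features
  than the 1-SE rule); if the chosen penalty empties the model, the screen
  falls back to the least-penalized grid point with at least one survivor.
- **Model**: XGBoost regression, grid-searched over learning rate
  {0.05, 0.1, 0.3} × max depth {2, 3, 4} × subsample {0.7, 1.0} × L2
  regularization {0.1, 1, 10} with 5-fold CV (RMSE), refit on all training
  rows at the best cell. Single-threaded `hist` trees with a fixed seed make
  reports byte-reproducible. A compact grid ({0.1, 0.3} × {2, 3} × {1.0} ×
  {1.0}, 150 trees) is provided for repeated-seed experiments where the full
  sweep is not the object of study; the repeated-seed ordering experiment in
  the test suite uses it with 10 seeds at n = 306.
- **Evaluation**: MAE, MSE, RMSE = √MSE, coefficient of determination,
  percent of |error| ≤ 0.50 D, a two-sided paired t-test of predicted vs
  true values (α = 0.05, no multiplicity correction across groups),
  Bland–Altman 95 % limits of agreement (mean ± 1.96·SD of differences),
  age-subgroup metrics (4–8 vs 9–15 years, bins under 5 eyes flagged), and
  linear-regression and RBF-SVR baselines fitted on the same selected
  features and evaluated on the same test split.

Leakage discipline is structural — imputation statistics, screening, and all
hyperparameter selection are computed from training rows only — and is also
tested behaviourally with a canary feature that equals the target on test
rows only: its presence must not improve test RMSE.

## Accommodation analysis

`delta_radii` references every series to its compulsory zero-stimulus
baseline (magnitude-decrease convention). `fit_quadratic` is an ordinary
least-squares degree-2 polynomial fit; an all-zero design returns the zero
polynomial flagged degenerate (r² undefined) rather than raising.
`slope_at_zero` = |b| is the small-accommodation sensitivity in D/mm and its
reciprocal the radius change per diopter: 1/1.21 ≈ 0.83 mm/D for the
anterior surface versus 1/9.30 ≈ 0.11 mm/D for the posterior — the anterior
surface does the work at the low accommodation levels relevant to
cycloplegia. Because the posterior curve is strongly curved, its full-range
mean mm-per-diopter (reported by `mm_per_diopter_full_range`, ≈0.15–0.19
over 0–6 D) exceeds the origin reciprocal; both are reported and neither is
claimed to be the other.

The principal-plane analysis treats the lens as a thick lens immersed in
media of index n′ = 1.336. The distance from the back vertex to the image
principal point is p′ = −(n′/F)·F_a·(LT/n_L) (mm; Descartes sign convention,
negative toward the cornea), and re-referencing to the lens centre through
the posterior sagitta gives OP′ = [r_p − √(r_p² − (LT/2)²)] + p′. On any
grid with r_p ≥ LT/2, OP′ strictly decreases in F_a and strictly increases
in F_p: anterior steepening pulls the principal plane toward the cornea
(reducing the accommodation demand), posterior steepening pushes it toward
the retina. This asymmetry is the physical argument for anterior-surface
dominance, and for lens-feature sets built around F_a and r_a.

## Numerical choices and edge cases

- Array inputs mask invalid entries as NaN; scalar inputs raise `ValueError`
  on violated preconditions (degenerate geometry, vertex singularity,
  nonpositive radii).
- Ratio features guard division by zero with NaN missing markers.
- Quadratic inversion for series generation follows the root branch
  continuous with Δ = 0 at zero stimulus; a stimulus beyond the quadratic's
  range (negative discriminant) is a configuration error.
- Truncated sampling redraws only the eye-level component, preserving the
  subject factor; after 200 sweeps stragglers (probability ≈ 1e−6 per
  cohort) are clipped.
- Degenerate paired t-tests (zero-variance differences) return NaN with an
  explicit flag instead of infinity.
- Axis 0° and 180° are identified; angles convert to radians only inside
  the trigonometry.

## Known limitations

- The SRK/T-based lens power is a proxy, not a measurement; its absolute
  scale (and hence F_a, r_a) inherits the formula's schematic-eye
  assumptions. Very long eyes can drive the derived F_a near zero, making
  r_a arbitrarily large; such rows survive as valid (if extreme) feature
  values or NaN.
- Synthetic performance numbers are not clinical performance numbers: the
  generator's noise floor is optimistic and its lens-mediated share is a
  design parameter.
- The age-subgroup and baseline tables summarize a single split per seed;
  no variance over resampling schemes is claimed.
- The accommodation analysis is paraxial; no gradient-index lens structure,
  ray tracing, or ciliary-muscle mechanics.
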