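# Methods

## Scope and data model

The package analyses a *material library*: a set of pharmaceutical
materials, each characterised as an ungranulated powder and as the
granule produced from it by high shear wet granulation, compacted into
tablets at several pressures.  Raw inputs are two CSV tables — a
material-property table (one row per material × form with 19 physical
descriptors) and a tablet table (one row per tablet with applied force,
mass, dimensions and diametrical crush force).  All downstream
quantities are derived from these.

Unit conventions are fixed package-wide: applied force kN, crush force
N, lengths mm, mass g, densities g·cm⁻³ (≡ g·mL⁻¹), pressure and
tensile strength MPa.  All conversions live in `mechanics`.

## Tablet mechanics

For a flat-faced cylindrical tablet of diameter D and thickness H:

* compaction pressure P = 1000·F/(π(d/2)²) from the punch force F (kN)
  and punch diameter d (mm).  For the 10 mm punch used throughout,
  1 kN ↦ 12.732 MPa (the exact value; rounded presentations of
  12.74 MPa/kN appear in the literature).
* tensile strength TS = 2F/(πDH) from the crush force F (N).
* apparent density ρapp = m/(π(D/2)²H), porosity ε = 1 − ρapp/ρt with
  ρt the helium (true) density of the material, and solid fraction
  SF = 1 − ε exactly.  A porosity definition equating ε with the
  *relative* density occasionally appears in print; it contradicts
  SF = 1 − ε and every compression model, so the complement form is
  used.

Tablets denser than the true density are physically impossible;
measurement noise can still produce them.  Such records are flagged
suspect (configurable tolerance, default 2% relative) and kept — a
config switch excludes them from fitting.  Replicate tablets at the
same nominal force are aggregated by mean (default) or median before
curve fitting; pooling instead of averaging changes OLS weights only
when replicate counts are unbalanced.

## Compression models and the CBCS parameter set

Six classical models are fitted per material × form, each over its
conventional pressure window — 0–50 MPa for Shapiro, 10–140 MPa for the
rest — by ordinary least squares on the model's linearised form:

| model | form | fitted quantities |
|---|---|---|
| Kawakita | P/C = P/a + 1/(ab), C = 1 − Da/ρapp | a, b (and ab, b⁻¹) |
| Shapiro | ln ε = ln ε0 − kP − f√P, intercept fixed | f, k |
| Heckel | ln(1/ε) = kP + A | Py = 1/k, A |
| Gurnham | ε = −(1/K)·ln(P/P0) | K, P0 |
| Ryshkewitch–Duckworth | ln TS = ln TS0 − kb·ε | kb, TS0 |
| power | TS = d·P^g | d, g |

The nine CBCS descriptors are a, ab, b⁻¹, f, Py, K, kb, d, g.
Notes on estimator choices:

* All porosity-based fits use **out-of-die** tablet porosity (tablets
  characterised after 24 h relaxation).  Heckel analysis is often
  described against in-die data; no in-die displacement data exist in
  this data model, so the out-of-die variant is what is fitted — a
  deliberate, documented deviation from the in-die convention.
* The Kawakita engineering strain uses the loose-bed volume implied by
  the bulk density: C = 1 − Da/ρapp.  Points with C ≤ 0 (tablet no
  denser than the bed) are excluded with a warning.
* The Shapiro intercept is fixed at ln ε0 with ε0 = 1 − Da/Dt, because
  the initial bed porosity is an independently measured quantity; k and
  f come from a two-regressor no-intercept least squares.  P and √P are
  nearly collinear on 0–50 MPa, so k is poorly conditioned (its
  variance is an order of magnitude larger than f's); f is the CBCS
  descriptor and is well identified.
* The power model is fitted by log-log OLS; a direct nonlinear
  least-squares route is available (`method="nls"`) and serves as the
  independent oracle in tests.  RMSE for the power fit is reported on
  the original TS scale.
* A failed fit (wrong-signed slope, too few points, non-positive TS) is
  a *value* — a `FitResult` with `ok=False` and NaN parameters — never
  an exception, so a library run always completes.  Only a curve on
  which all six models fail raises.
* R² is computed on the linearised response (centred total sum of
  squares); on noise-free model-generated data every fit reaches
  R² = 1 to machine precision, which the tests assert.

## Change-of-tabletability indices

The tabletability of a form is summarised by the area under its
TS–pressure profile.  The default is the closed-form integral of the
fitted power curve over 10–140 MPa,

AUC = d·(140^{g+1} − 10^{g+1})/(g+1),

with composite-trapezoid quadrature over the measured points as the
config alternative; the two agree to ≤1e-4 relative on dense grids and
are cross-checked in tests.  The integration window is the tableting
range itself; no other bound is canonical, and the window is part of
the run configuration and manifest.

* **Reworking potential** RP = 100·AUCg/AUCp (percent).  A ratio: it
  amplifies changes in weak materials (a small absolute loss on a tiny
  AUCp reads as a catastrophic RP) and cannot distinguish materials
  with equal ratios but very different absolute changes.
* **Relative change of tabletability**
  CoTr = 100·(AUCg − AUCp)/(AUCmax − AUCmin), where AUCmax/AUCmin are
  taken over *every* powder and granule profile in the library (the
  envelope).  Loss of tabletability is negative by this sign
  convention — the granule-minus-powder numerator is used even where
  prose descriptions reverse the order, because every reported loss
  carries a negative sign.  The envelope is computed once per run and
  stored in the manifest so CoTr values are reproducible and comparable
  across analyses of the same library.  An all-equal library (Amax = 0)
  makes CoTr undefined and is signalled explicitly.

## Classification

**CBCS tabletability categories.**  Category 1 requires d ≥ 0.2 with
0 < g < 0.95 *and* TS(50) ≥ 3 MPa — good tabletability already at the
20–50 MPa band.  The extra band condition is needed because the d/g
gate alone admits flat weak curves (e.g. d = 0.5, g = 0.1 never reaches
1 MPa).  Otherwise the fitted curve TS = d·P^g is evaluated at the band
upper edges (TS is monotone in P for g > 0, so attainment anywhere in a
band is equivalent to attainment at its upper edge): 2A requires
TS(100) ≥ 2 MPa and TS(140) ≥ 3 MPa; 2B requires TS(140) ≥ 2 MPa; 2C is
the floor.  The published d/g numeric ranges for 2A/2B/2C mutually
overlap and cannot alone be decisive; the band evaluation reproduces
the published worked assignments, including the steep-weak-curve case
d = 9.85×10⁻⁴, g = 1.68 → 2A.  The thresholds (2 MPa acceptable,
3 MPa good) are configurable.  Classification is monotone in d at
fixed g, a property the tests sweep.

**TCCS types.**  From CoTr in percent: Ia on (−∞, −15) (large loss),
Ib on [−15, −5) (moderate loss), II on [−5, 5] (unchanged, closed on
both ends), III on (5, ∞) (gain).  The four intervals partition the
real line; boundary inclusivity follows the quoted inequalities.

**Downgrades.**  Category quality is ordered 1 > 2A > 2B > 2C; a
powder→granule transition to a lower rank is a downgrade.

## Multivariate stage

* **Autoscaling**: mean-centring and scaling to unit variance with the
  sample (n−1) convention (documented choice; the alternative
  population convention rescales all loadings uniformly and changes no
  conclusion).  Zero-variance columns are an error naming the column.
* **PCA** via singular value decomposition on the autoscaled matrix,
  components ordered by explained variance, with a fixed sign
  convention (largest-magnitude loading entry positive) so outputs are
  reproducible.  Explained variances equal the correlation-matrix
  eigenvalues, asserted against an independent eigendecomposition.
* **Group score ellipses**: Hotelling T² prediction regions at 95%
  confidence, c = 2(n−1)(n+1)/(n(n−2))·F₀.₉₅(2, n−2) applied to the
  group score covariance; Monte-Carlo coverage on 10⁵ simulated points
  falls in [94%, 96%].
* **Data-fusion design**: each material contributes five rows, one per
  compression force (3, 5, 7, 9, 11 kN → MPa via the punch geometry).
  X has 31 columns — the 19 powder physical properties, the 9 powder
  CBCS parameters, RP and CoTr, and pressure — replicated down each
  material's rows; Y holds TS1 (powder) and TS2 (granule) evaluated
  from the two fitted power curves at the row's pressure, which puts
  both routes on a common pressure grid that raw data (recorded at
  whatever pressure the press delivered) cannot provide.  With the full
  29-material library the design is 145 × 31.
* **PLS2** by NIPALS: per latent variable, the X-weight vector is
  iterated against a Y-score to convergence (relative score change
  < 1e-10; the iteration cap is 5000 because nearly degenerate latent
  directions converge slowly), X is deflated by its rank-one
  reconstruction, and Y is residualised for the cumulative R²Y
  diagnostic.  Regression coefficients are B = W(PᵀW)⁻¹Qᵀ.  Successive
  X-scores are orthogonal; a single-column Y reduces exactly to PLS1.
  Non-convergence raises, naming the latent variable.
* **Q² by 7-fold cross-validation**: fold membership is deterministic
  round-robin over row order (a seeded random assignment exists behind
  config), scaling parameters are re-estimated on each training fold,
  PRESS pools both Y columns in original units, and
  Q²cum(A) = 1 − PRESS(A)/SS with SS the column-mean-centred total sum
  of squares of Y.  Five latent variables are the default report; the
  drop of Q² beyond the useful rank signals overfitting and guides LV
  selection.

## Synthetic material library

The generator is first-class, tested code: it defines the study
conditions under which every pipeline stage is validated.

* **Size and composition**: 29 materials (17 excipient-like, 12
  natural-product-like), two forms each, six pressures
  (10, 25, 40, 70, 105, 140 MPa — chosen so the Shapiro window contains
  three levels; the original six pressures are not printed anywhere),
  two replicate tablets per pressure, 1% relative measurement noise.
  The noise level is a calibration choice (no measurement SDs are
  published) and is exposed in config.
* **Porosity curves** are generated from the Gurnham form — the
  preferred compressibility description among the six models —
  parameterised by ε(140) and Δε = ε(10) − ε(140) per deformation
  archetype (plastic/brittle/elastic), which guarantees physical
  curves: K = ln(14)/Δε, P0 = 140·exp(K·ε(140)).  Consequently the
  Gurnham and power fits on generated data are exact, while
  Kawakita/Shapiro/Heckel fit the same curve through their own forms
  (R² ≈ 0.92–0.999, mirroring the "almost all R² > 0.9" fit quality of
  real libraries); parameter-recovery tests for those models use
  model-matched generation instead.
* **Tabletability planting**: each roster entry fixes a powder CBCS
  category, a granule category, a TCCS type, a powder-AUC band and a
  CoTr band.  Powder (d, g) are drawn inside the category cell; CoTr
  targets are drawn inside the type band; the granule areas then solve
  a fixed point with the envelope (the envelope depends on the granule
  areas it is used to plant — the iteration is a contraction for
  |CoTr| < 100% and converges in a handful of steps); finally each
  granule's g is chosen from a grid to land in its planted category
  with the largest classification margin, which is what makes the
  1%-noise round trip stable.  The AUC and CoTr bands were sized by
  the feasibility geometry of the category gates (e.g. a 2B granule
  is only reachable for areas between roughly 100 and 265 MPa²).
* **Planted census** mirrors the granulation-study book-keeping:
  powder categories {1: 7, 2A: 15, 2B: 6, 2C: 1}, granule categories
  {1: 3, 2A: 13, 2B: 10, 2C: 3} (ten downgrades ≈ 34%), TCCS types
  {Ia: 5, Ib: 7, II: 14, III: 3} — i.e. ≈40% loss, ≈50% unchanged,
  ≈10% gain.
* **Physical-property block**: a three-factor latent model (particle
  size/flow, densification, hygroscopicity) drives 19 descriptors.
  Particle size anticorrelates with flow time, inter-particle porosity
  and the cohesion index; natural-product rows are finer and more
  hygroscopic than excipient rows; granule rows are coarser and
  better-flowing than their powders.  Structural identities hold
  exactly by construction: span = (D90 − D10)/D50, IH = Dc/Da,
  IC = 100(1 − Da/Dc), Ie = (Dc − Da)/(Dc·Da), εp = 1 − SFp,
  Da ≤ Dc ≤ Dt.  The bulk/true densities double as the Kawakita and
  Shapiro inputs of the compression stage, with the loose-bed porosity
  centred at 0.68 so fitted Kawakita a values land in the physically
  observed 0.708–1.05 span.  Factor loadings and the density-factor
  coupling are set so roughly 70% of the block's variance concentrates
  in three principal components, the structure observed in real
  libraries of this kind; the realised value varies by seed
  (≈0.69–0.79 at n = 58).
* **Noise model**: multiplicative log-normal on porosity and TS, so
  both stay positive.  Raw tablet rows are back-computed from the noisy
  states (thickness from apparent density at a 0.300 g fill mass, crush
  force from TS, applied force from nominal pressure), so the mechanics
  stage recovers exactly the simulated states.
* **Determinism**: all draws flow from one master seed through named
  child streams (powder parameters, porosity/densities, property-block
  noise, curve noise, latent factors); regeneration from the same seed
  is bit-identical, which the tests assert.

### What the generator does and does not emulate

It emulates the *structure* of a real library — correlated descriptors,
archetype-dependent compression behaviour, a realistic envelope and
census, measurement noise.  It does not simulate granulation physics
(binder amount, impeller speed, granule-size distributions), capping or
other failure modes, pressure-dependent model misspecification beyond
the Gurnham/power choice, or descriptor measurement error.  Passing
round-trip tests therefore demonstrates that the pipeline is correct
and stable under the stated noise, not that it would reproduce any
particular laboratory's numbers.  In the same spirit, the PLS2
R²Y/Q² values on synthetic data characterise the synthetic structure
only; published per-study values depend on data that only exist in the
original laboratory.

## Problem sizes and runtime

Default analyses are small by construction: 29 materials × 2 forms ×
6 pressures × 2 replicates = 696 tablets, 348 model fits, a 145 × 31
PLS2 design.  A full pipeline run takes well under a second; the
complete test suite, including a 20-seed noisy round trip and a
10⁵-point ellipse coverage check, runs in seconds.

## Known limitations

* No uncertainty propagation from fit covariance into AUC/CoTr.
* The Shapiro k estimate is reported but ill-conditioned on the
  low-pressure window (see above); interpret f, not k.
* Exact reproduction of any published per-material table requires that
  study's raw measurements; the package reproduces worked examples,
  design arithmetic and structural results instead.
* CSV is the only interchange format; figures are left to the user
  from the emitted tables.
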