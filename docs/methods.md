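# Methods

This note records the models behind `salixnmr`, the defaults and why they
were chosen, what the synthetic cohort does and does not emulate, and the
numerical choices a maintainer would want to know about.

## Spectral model

Spectra are synthesised directly in the frequency domain as sums of
Lorentzians. A multiplet with centre δ₀ (ppm), couplings J (Hz), n protons
and full width at half maximum w (Hz) expands into lines at
δ₀ ± J/(2·ν) combinations (ν the spectrometer frequency in MHz) with
binomial weights: d → 1:1, t → 1:2:1, q → 1:3:3:1, dd → four equal lines.
Each line is a unit-area Lorentzian scaled so the multiplet's total area is

    area = c · n_protons · K

with c the tube concentration in mM and K a library-wide constant (K = 1).
This is the quantitative-NMR identity that makes internal-standard
calibration work. Two rendering conventions:

- **"m" (unresolved multiplet)**: one Lorentzian at 3× the natural width.
  The field reports shift *ranges* for such signals, and a broadened
  singlet is the right zeroth-order shape for them.
- **"ab"**: one half of an AB system rendered as a plain doublet. The roof
  effect is ignored — at 600 MHz the citrate shift separation is large
  against J, so second-order distortion is a sub-percent effect.

Synthesis is frequency-domain rather than FID + FFT because every
downstream stage consumes frequency-domain data; the 0.5 Hz exponential
apodisation of the acquisition protocol is folded into the linewidth
(rendered width = natural width + 0.5 Hz).

The default axis is 65,536 points across 12 ppm (−1 to 11 ppm, ascending;
display reversal is a plotting concern). TSP enters every spectrum at
0.557 mM: 0.01% w/v of the d₄-TSP sodium salt (0.1 mg/mL ÷ 172.27 g/mol
= 0.580 mM) diluted 700→730 µL by the buffer and EDTA additions.

## Matrix chemistry

Four effects of the buffered extract matrix are modelled explicitly:

- **pH shifts.** Multiplets may carry a two-state model (pKa, acid-state δ,
  base-state δ); the centre is the Henderson–Hasselbalch-weighted mean at
  the sample pH. Citrate and malate carry such models with state shifts
  chosen to reproduce their pH 7.4 positions.
- **Ca²⁺ broadening.** Free Ca²⁺ (total Ca − EDTA, floored at 0) multiplies
  the width of Ca-sensitive signatures (citrate, malate) by 1 + β·[Ca²⁺],
  β = 2.0 mM⁻¹ by default. No quantitative Ca/broadening relationship is
  published for this matrix; the linear model is a simulator convention,
  configurable and recorded in metadata.
- **H/D exchange.** Exchange-labile multiplets (catechin H-6 at δ6.09 and
  H-8 at δ6.00, exchanging via keto-enol tautomerism in buffered deuterated
  solvent) decay as exp(−k·t) with standing time t; k = ln(100)/12 ≈
  0.384 h⁻¹ so that exchange is ≥99% complete at 12 h, matching the
  observed completion time at pH 7.4.
- **EDTA speciation.** Complexed EDTA (min(EDTA, Ca)) contributes the
  Ca-EDTA quartet at δ3.10 and singlet at δ2.55; excess EDTA contributes
  free-EDTA singlets. Both are ordinary library signatures, so the
  quantitation stage fits them like any metabolite.

## The synthetic cohort

`simulate_cohort` reproduces the study design: 2 genotypes (Tora,
Resolution) × 2 tissues × 3 stem/leaf positions × 2 biological × 3
technical replicates = 72 spectra. Its composition model encodes the
source/sink physiology the platform was built to resolve: sugars high in
leaf and falling down the stem with sucrose alone rising toward the stem
base; organic acids accumulating in older leaves; amino acids and
2-phenylethylamine richer in young stem tissue; Resolution elevated in
glutamine/asparagine/2-phenylethylamine/glutamate/quinate and Tora in
sucrose/glucose/dihydromyricetin. Magnitudes are scaled
(`COMPOSITION_SCALE = 0.55`) so the quantified leaf total sits near
90 mg/g d.w. — about 30% of a ~30%-extractable pool, the level reported
for field-grown willow leaf.

Variability has three layers: biological (lognormal, CV 12%), technical
(lognormal per metabolite, CV drawn once per cohort from U[3%, 6%] — placing
bucket-level %RSDs in the 2–8% band the platform achieves), and spectral
(Gaussian noise, sd 0.5 intensity units against peak heights of order
10²–10³). Extract masses draw from per-genotype, tissue × position normal
models with the reported means and spreads (leaf ≈ 26–32% extractable
throughout; stem 32% at the top falling to ~13% at the base, a ≈2.5-fold
gradient). Prep variant "b" (direct deuterated extraction, no dry-down)
raises ascorbate and acetate by 60% and changes nothing else.

What the generator does **not** emulate: real phasing/baseline artifacts,
temperature drift, ¹³C satellites, radiation damping, peak shapes beyond
Lorentzian, untargeted unknowns, and any metabolite correlation structure
beyond the planted factorial effects. Passing tests therefore demonstrate
correctness of the pipeline's algebra and estimator behaviour under
realistic signal/noise structure, not performance on real instrument data.

## Processing

Referencing shifts the axis so the tallest peak within ±0.3 ppm of zero
sits at δ0.00 (ties break toward 0; failure if nothing exceeds the window's
median + 5 MAD). Scaling divides by the trapezoidal integral over
δ[−0.05, 0.05] and stores the TSP area. Bucketing integrates half-open
0.015 ppm intervals anchored at −0.05 (so the TSP region tiles cleanly,
covering −0.05 to 10.0); integration is trapezoidal via an interpolated
cumulative integral, which makes the bucket sum telescope exactly to the
full-range integral. Buckets intersecting the water (δ4.775–4.865),
methanol (δ3.285–3.335) or TSP (δ±0.05) regions are dropped whole —
truncating would break the spreadsheet-style bucket bookkeeping. The
optional catechin guard removes the buckets containing δ6.09 and δ6.00,
the H/D-exchange false-positive risk.

## Quantitation

The fit solves, over the union of per-multiplet windows
(multiplet span + 0.02 ppm pad + shift tolerance),

    y ≈ Σ_m c_m · T_m(Δ, w) + solvent templates + per-window linear baseline

with c_m ≥ 0, per-multiplet shift offsets |Δ| ≤ 0.01 ppm and widths within
[0.5, 6] Hz. Key choices:

- **Full templates.** Each metabolite's column carries *all* its multiplets
  evaluated at *every* fit point, so heavy Lorentzian tails crossing window
  boundaries are attributed, not absorbed by baselines. This is what takes
  noise-free recovery from percent-level to optimizer-tolerance exactness.
- **Two-stage deterministic solve.** A bounded-variable least squares at
  Δ = 0 (via QR reduction, then BVLS on the triangular system), followed by
  coordinate-wise bounded scalar refinement of each multiplet's Δ and width
  factor against its partial residual, re-solving the linear problem after
  each pass (2 passes). Refinements are accepted only on strict improvement,
  so an already-exact fit is never perturbed. No randomness anywhere.
- **Shared offset per multiplet, not per line** — pH moves whole spin
  systems.
- **Exchangeable and solvent-obscured multiplets are excluded from
  templates**: quantitation rests on stable protons only, so catechin is
  quantified from its 5 non-exchanging protons regardless of sample age.
- **Calibration.** c_m = α_m · c_TSP/α_TSP with α the fitted amplitudes
  against 1 mM templates — invariant to any global intensity scaling.
- Metabolites whose fitted peak height stays below 3× the spectrum's noise
  floor (MAD of the signal-free axis extremes) report 0 mM with a
  `below_noise` flag; boundary-hitting offsets/widths and window overlaps
  are flagged, and the windowed residual spectrum is exportable per sample
  for manual inspection.

Tissue units follow the prep volume chain: µmol/g d.w. =
c_tube × (V_tube/V_aliquot) × V_extraction / m_tissue (for the default
recipe, 1 mM → 69.52 µmol/g); mg/g = µmol/g × MW/1000.

## Statistics and normalisation

Percent extractable scales the dried 700 µL aliquot mass back to the whole
1 mL extract: % = m_aliquot × (1000/700) / 15 mg × 100. Pool normalisation
multiplies by 3 mg / extract mass; since the stem pool falls ~2.5–3-fold
from top to bottom, any raw metabolite decrease smaller than that ratio
reverses direction under normalisation, and larger changes keep direction
attenuated — the property tests verify this on constructed profiles.

Technical %RSD is 100·sd/mean (n−1 denominator) within each biological
sample, averaged across samples of a tissue; zero-mean cells are reported
missing. The genotype screen averages technical replicates first, runs a
classical one-way ANOVA per tissue × position × metabolite, and reports raw
p-values sorted ascending (with two biological replicates per genotype the
screen is deliberately liberal; a Benjamini–Hochberg option exists but is
off by default, matching screening practice where raw p-values feed manual
triage). Trajectory error bars over two biological replicates are ranges —
a standard deviation of n = 2 would suggest precision that is not there.
The compound-class pool accounting floors the "unquantified/NMR-invisible"
remainder at zero and flags samples whose quantified total exceeds the
measured pool rather than hiding them.

## Multivariate

Unit-variance scaling uses the n−1 standard deviation; constant columns are
centred, given scale 1 and flagged. PCA is the SVD of the scaled matrix
with a deterministic sign convention (largest-|loading| element positive).
OPLS is the two-class discriminant variant: the predictive weight is
w ∝ Xᵀy; orthogonal components (p − (wᵀp)w, normalised) are deflated before
the single predictive component. Because w ∝ Xᵀy, orthogonal scores satisfy
yᵀXw_o = 0 exactly — uncorrelatedness with y is structural, not numerical.
The S-line reports cov(x_j, t_p) and corr(x_j, t_p) per variable, oriented
so positive means elevated in the +1 class.

One calibration caveat worth stating: the *training* R²Y of a PLS-family
model on pure-noise data grows like p/(n+p) with the number of variables —
overfitting, not signal. Null checks of R²Y are therefore only meaningful
at small p (the tests use p = 5 at n = 72); on full bucket tables,
permutation testing or cross-validated Q² would be required, which is out
of scope here.

## Numerical choices and degenerate inputs

- Bucket/integration arithmetic tolerances: bucket sums conserve the total
  integral to better than 10⁻⁶ relative (exactly, up to float association).
- ANOVA: zero between-group variance returns (F = 0, p = 1); zero
  within-group variance with distinct means returns (∞, 0); fewer than two
  groups or fewer than one residual degree of freedom raise.
- Referencing ties break toward 0 ppm deterministically.
- The library loader validates arity (s→0, d→1, dd→2, t→1, q→1 couplings),
  positive proton counts and widths, pH-state bracketing and name
  uniqueness; sub-resolution line spacings (below the 12 ppm/65,536-point
  digital resolution) produce warnings, not errors.
- JCAMP-DX support covers the plain AFFN `(X++(Y..Y))` form, which is what
  the simulator writes; compressed (DIF/DUP/SQZ) encodings are not parsed.
- Axes with stored-precision jitter below 10⁻³ of a point spacing are
  treated as uniform on read; anything worse is resampled with a warning.

## Known limitations

- The builtin library anchors to the handful of shifts the protocol
  literature prints; all other multiplets are standard reference values for
  pH 7.4 aqueous-methanolic conditions (marked `provenance: "reference"`),
  covering ~50 of the 90 signatures a full instrument-matched database
  would hold.
- The linear Ca²⁺-broadening law and the solvent-residual shapes are
  simulator conventions, not measured physics.
- The fitter has no pH-predictive shift adjustment (a Chenomx "pH wand"
  analogue); bounded per-multiplet offsets absorb residual misalignment up
  to 0.01 ppm only.
- No phasing or global baseline correction of real instrument data: input
  spectra are assumed phased and baseline-flat apart from what the
  per-window linear baseline absorbs.
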