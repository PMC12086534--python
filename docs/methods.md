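# Methods

## Measurement model

An ion with elemental formula F is monitored at nominal mass shifts m0–mK
(K = 3 throughout the shipped configuration, because triple-quadrupole MRM
panels monitor four isotopologues). Its natural-abundance MID is the
convolution of per-atom isotope patterns; we ship a single authoritative
table of IUPAC representative abundances (`data/isotope_abundances.csv`,
elements C, H, N, O, S) and compute the convolution exactly, truncating at
mK. Because mass shifts only add, truncation at every intermediate step
leaves the retained entries exact; the probability mass beyond mK is kept
in `truncated_mass`, never silently dropped.

During ²H₂O labeling, a fraction f of molecules is newly synthesized and
carries j ~ Binomial(n, p) excess deuterium atoms at its n exchangeable
positions, where p is the body-water ²H mol-fraction excess. The observed
MID is

    observed = natural ⊛ [(1 − f)·δ₀ + f·Binomial(n, p)]

**Exactness choice.** Natural deuterium (≈1.15 × 10⁻⁴) at the exchangeable
positions is carried inside the natural MID — every hydrogen of the formula
sits at natural abundance there — and the excess labeling of new molecules
convolves on top independently. The alternative parameterization (new
molecules draw from Binomial(n, p + a₂H) replacing their exchangeable
hydrogens) differs at order n·p·a₂H ≈ 10⁻⁴ relative, far below instrument
precision; the factored form has the advantage that deconvolving an
observed MID by the full natural MID returns *exactly* the mixture
(1 − f)·δ₀ + f·Binomial(n, p), which keeps the whole pipeline consistent to
machine precision on noiseless data.

## Natural-abundance correction

The correction matrix is lower-triangular with column j the natural MID
shifted down j rows. Two provenances:

* **empirical** (default when unlabeled baseline samples are supplied):
  baseline rows are normalized and averaged — averaging several baseline
  animals reduces baseline noise;
* **theoretical**: computed from the ion formula and the isotope table.

The solve uses non-negative least squares by default: with noisy data a
plain triangular back-substitution can return negative isotopologue
fractions, and clipping after the fact distorts the solution more than
constraining it during the fit. Back-substitution remains available
(`solver="triangular"`) for clean data. The solution is renormalized to
sum 1; the solve residual is reported per row and flagged (never swallowed)
when it exceeds the tolerance (default 1e-8, generous for noiseless data
and routinely exceeded — and flagged — on noisy data).

## Fractional synthesis and the truncation-bias correction

Analyte enrichment is the weighted excess-label sum m1 + 2·m2 + 3·m3 of the
corrected MID (extended to Σ i·mᵢ for K > 3), and fractional synthesis is

    f (%) = enrichment / (p · n) × 100.

At K = 3 this classic estimator is biased low: a new molecule's label atoms
beyond m3 are invisible, so the expected enrichment per new molecule is
Σ_{i≤K} i·bᵢ(n, p) rather than n·p. The ratio of those two quantities is
the truncation-bias factor (≈0.95 at n = 22, p = 4%; 0.92 at p = 5%). The
pipeline divides the Eq.-style estimate by this factor by default
(`truncation_correction=True`), which reduces the residual error to the
renormalization term f·tail/(1 − f·tail) ≤ ~1.4% relative over
f ∈ [2, 60]%, p ∈ [2, 5]%, n ∈ [10, 22] — and to ~0 at K = 8. The
uncorrected value is always stored alongside (`f_uncorrected_percent`), so
users who want the verbatim ratio formula have it. Values above 100% are
flagged, never clipped in stored results.

A second estimator, `estimate_f_mixture`, fits the two-component mixture
directly and is exactly truncation-unbiased on noiseless data; it serves as
an internal cross-check rather than the pipeline default.

## Exchangeable-hydrogen (n) estimation

n is estimated per analyte on pooled study MIDs (single per-analyte
assignment, matching field practice; per-sample estimation is available via
`pool=False`). For each integer candidate the non-negative two-parameter
mixture α·δ₀ + β·Binomial(n, p) is fitted to the pooled corrected MID and
the candidate with the smallest residual wins; ties resolve to the smallest
n with an explicit tie report. The candidate grid defaults to 1..40.

Residuals are weighted by 1/value ("relative" weighting) by default: MS
peak-area noise is multiplicative, and the n information lives entirely in
the small m2/m3 channels once α and β are free, so unweighted least squares
lets m0/m1 noise drown it. The closed-form diagnostic
n̂ = 1 + 2·(m2/m1)·((1 − p)/p) is reported alongside.

**What recovery can and cannot promise.** On noiseless data the estimator
is exact across the full grid (the acceptance script demonstrates this for
all five panel assignments). Under per-isotopologue multiplicative noise
the limit is the noise of the corrected m2/m1 and m3/m1 ratios relative to
the unit spacing of the grid: with 8 samples pooled at p = 4%, integer-exact
recovery is reliable (≥95%) at ~1% CV, while at a routine 5% CV the
estimate is localized to ±2 — bile acids, whose excess signals sit on much
larger natural backgrounds (S, O-rich ions), are the hardest case. Strongly
labeled pools (higher f) sharpen the estimate proportionally.

## Calibrations

* **Body water**: serum exchanges ²H into acetone under alkaline
  conditions; the m1/m0 acetone signal ratio is linear in the water ²H mol
  fraction. Gravimetric standards (natural water mixed with 99.9% ²H₂O,
  shipped defaults 0–6%) are fitted by OLS and inverted at each animal's
  ratio. The specific signal-reduction convention is immaterial as long as
  standards and samples share it. Samples outside the standards' range are
  flagged as extrapolation. p can be used per animal (default) or as the
  cohort mean; the choice is recorded per result row.
* **Concentration**: analyte/internal-standard area ratio against known
  amounts, OLS by default with optional 1/x weighting; slope, intercept and
  r are echoed to the QC report. Responses below the curve floor to 0 with
  a flag (blank-level biology is real); flat or inverted curves are
  rejected.
* **Totals**: compartment concentration × compartment mass / body mass
  (µg/g body mass), for intestinal and fecal total content.

## Synthetic cohorts

`simulate_study` generates what the measurement model assumes: per-animal
p ~ Normal(0.04, 0.003) truncated to (0, 1) — the ~4% dosing target with
realistic inter-animal spread; per-sample true f drawn logit-normally
around the group mean (σ = 0.10 on the logit scale) so biological
variability keeps fractions in (0, 1); pool concentrations lognormal
(CV 25%); observed areas = forward MID × an internal-standard-tied scale ×
per-isotopologue lognormal noise (CV 5% default — multiplicative, as MS
peak-area error is). Unlabeled baseline animals (4 by default), water
standards with 0.5% relative ratio noise, and noiseless internal-standard
curves are emitted alongside a truth table the pipeline never reads.

What the generator does *not* emulate: chromatographic interference and
integration error, detector saturation, isotope effects on ionization,
drift between batches, and within-window label kinetics (the single
overnight-label, single-ratio design assumes the plateau). Passing tests
therefore validate the mathematics and the statistical behavior under the
stated error model, not robustness to those instrument pathologies.

Preset designs mirror common study structures (two-group wheel running of
8+8; an 8-cell strain × diet × feeding design of 8 each; a 4-group
control/knockout × sedentary/exercise design of 7 per sex with knockout
pool concentrations shrunk to 30%). Their effect sizes are synthetic
defaults chosen for plausibility, not measured values.

## Numerical choices and degenerate inputs

* Solver: scipy NNLS; tolerance 1e-8; residuals reported per row.
* All-zero spectra, zero internal-standard areas, singular correction
  matrices (natural m0 = 0), degenerate calibrations (fewer than 2 distinct
  known quantities, non-positive slope) raise errors naming the problem.
* Severe truncation (forward-model mass beyond mK above 5%) warns.
* MID validation tolerates solver round-off below 1e-9 but rejects real
  negativity or mass imbalance.
* All randomness flows through explicit integer seeds
  (default 20250407); identical config + seed reproduces byte-identical
  tables.
* Validation problem sizes (e.g., 100 replicate studies of 8 + 8 animals
  for group-recovery checks, 40–60 replicates for n-recovery rates) were
  chosen to make the checked proportions stable across seeds while keeping
  the suite fast.

## Known limitations

* Nominal-mass treatment only: no isotopic fine structure or
  resolution-dependent correction.
* Single-pool, single-timepoint estimator: no multi-compartment turnover
  kinetics.
* The truncation-bias correction assumes the panel's n and the calibrated
  p; a misassigned n propagates into both f and the correction factor.
* Group statistics (ANOVA and friends) are deliberately out of scope; the
  tidy per-sample output is designed to feed external statistical tools.
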