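# Methods

## Model

`pegprec` treats PEG-induced protein precipitation as a fast, reversible
mass-action equilibrium. Adding PEG to a protein solution excludes protein
from solvent regions occupied by the polymer; the attractive driving force
is hydrophobic: when protein–protein interfaces form, well-ordered water on
hydrophobic patches is released into the bulk, raising entropy. The
precipitate formed from *n* protein molecules and one PEG molecule is
stabilized by *nβ* bulk-like ordered water molecules. With activity
coefficients absorbed into the constants and the water activity replaced
by a term proportional to the precipitated protein, the equilibrium
collapses to one implicit isotherm per condition,

    k_eq = q^(1+nβ) / (c_p^n · c_PEG),
    β    = β₀ · exp(β₁ c_PEG + β₂ c_p0),

with the mass balance q + c_p = c_p0 closing the system. The mass balance
is adopted as a modeling decision (consistent with measuring supernatant
depletion after centrifugation); it is not implied by the equilibrium
alone. Assumptions inherited from the derivation: constant temperature,
pressure, and buffer composition; negligible electrostatic contributions
(each fitted parameter set is specific to one protein, pH, and PEG type);
equilibrium attained within the incubation (no kinetics); no salt-induced
precipitation.

All internal concentrations — protein, PEG, q — are mol/L. This makes
β₁, β₂ carry L/mol and puts k_eq on a molar scale; k_eq is stored and
fitted as ln k_eq. The unit convention matters because published parameter
magnitudes are only meaningful on one scale; the package's recovery tests
are internally consistent regardless of the convention chosen.

### Parameters

| symbol   | meaning                                     | units  | typical range  |
|----------|---------------------------------------------|--------|----------------|
| ln k_eq  | lumped equilibrium coefficient (log)        | —      | 10 – 35        |
| n        | proteins affected per PEG molecule          | —      | 2.6 – 5.6      |
| β₀       | hydration number at infinite dilution       | —      | 4e-4 – 4e-2    |
| β₁       | PEG dependence of hydration number          | L/mol  | 90 – 250       |
| β₂       | initial-protein dependence                  | L/mol  | 1.5e3 – 1.1e4  |

Five reference sets spanning lysozyme, myoglobin, BSA, and a mAb at two pH
values ship in `pegprec.reference` and anchor the tests. Molecular weights
for the mg/mL↔mol/L conversion come from a config registry; lysozyme
(14,600 g/mol) and myoglobin (17,000 g/mol) are standard values, while the
BSA (66,500) and mAb (150,000) defaults are editable conventions. The
%(w/w)→mol/L PEG conversion assumes a solution density of 1.0 g/mL
(dilute-aqueous), configurable; with PEG 6000 a 12 %(w/w) solution is
0.020 mol/L and 33.6 %(w/w) is 0.056 mol/L, matching the screen ceilings.

## Equilibrium solving

For c_p0, c_PEG > 0 the residual f(q) = q^(1+nβ) − k_eq (c_p0−q)^n c_PEG
satisfies f(0) < 0 < f(c_p0) and is strictly increasing on [0, c_p0] for
sub-molar concentrations, so the root is unique. The scalar solver uses
Brent's bracketed method on [0, c_p0] (relative q tolerance 1e-12 by
default, configurable), with powers evaluated in log space; degenerate
conditions (c_PEG = 0 or c_p0 = 0) short-circuit to q = 0. The solution is
verified by an absolute residual tolerance (1e-14, scaled by the endpoint
residual magnitude when that exceeds unity); for extremely steep residuals
— hydration exponents of order 100, where even a machine-precision q
cannot produce a small residual — a sign-enclosure check in a ±10·rtol
window around the root is used instead.

The fitting loop uses a vectorized solver: with rhs = ln k_eq + ln c_PEG,
the root of (1+nβ)·ln q − n·ln(c_p0−q) = rhs is found by Newton iteration
in log space. The iteration runs on whichever phase variable (q or
c_p = c_p0−q) is the smaller one — the branch is selected by the
closed-form residual sign at q = c_p0/2 — so nearly-complete and
barely-started precipitation are both resolved without catastrophic
cancellation. In each branch the objective function is increasing and
convex in the log variable and the start point (the closed-form
depletion-free upper bound) lies on the non-negative side, so Newton
converges monotonically within the bracket. Tests pin the batch path to
the scalar Brent path and both to a 200-iteration bisection oracle.

## Calibration workflow

Replicate supernatant readings are first cleaned by the pretreatment
filter: if the percentage standard error of a replicate set — 100 × (SEM /
mean), SEM computed with the sample standard deviation — exceeds 5 %, the
replicate farthest from the median is dropped, iterating but never below
two retained replicates; sets still above threshold at two replicates (or
with zero mean and nonzero spread, where the percentage is undefined) are
flagged, not emptied. The literal "percentage standard error" reading (SEM
over mean) is used rather than relative SD; the elimination rule
(farthest-from-median, keep ≥ 2) is this package's concretization of
"possible outliers are eliminated", and the filter is idempotent by
construction.

The calibration/validation split is level-based: records at the three
highest distinct initial-protein levels or the two highest distinct PEG
levels go to validation, the rest to calibration. On the standard
8-protein × 12-PEG screen this yields 50 calibration and 46 validation
conditions; validation therefore probes extrapolation beyond the
calibration range in both directions.

Fitting minimizes the sum of squared differences between replicate-mean
and predicted supernatant concentration (mol/L) — the loss variable is the
quantity UV-280 actually measures after centrifugation. The search runs in
(ln k_eq, n, ln β₀, β₁, β₂) coordinates: the log scale for the two
constants spanning many orders of magnitude, linear for the rest. Default
bounds are ln k_eq ∈ [0, 60], n ∈ [0.5, 10], ln β₀ ∈ [−12, 0],
β₁ ∈ [0, 10³], β₂ ∈ [0, 10⁵] L/mol, covering the reference sets with wide
margin. Each of the (default 10) restarts runs seeded dual annealing
(simulated-annealing family) followed by a bounded trust-region
least-squares polish with residuals scaled by the data maximum, so the
optimizer sees O(1) numbers for any protein; restart seeds derive
deterministically from the base seed, making fits bit-reproducible.
Restarts stop early once the calibration RMSE falls below 1e-10 mol/L,
which effectively only triggers on noise-free data. Validation error is
reported as RMSEP = sqrt(mean squared prediction error) in mol/L.

No uncertainty quantification (bootstrap, profile likelihood) is provided,
and each fit covers a single protein/pH; these are out of scope.

## Synthetic screens

The simulator emulates the high-throughput screen the workflow was
designed for: a full-factorial grid (default 8 protein levels, 1.5–12
mg/mL, × 12 PEG levels) in triplicate, randomized to well positions across
96-well plates. The 12 PEG levels are equidistant and end at the ceiling
(0.056 mol/L for small proteins, 0.02 mol/L for mAb-like systems, which
precipitate at lower PEG); the grid starts one spacing above zero
(max/12), since a zero-precipitant well carries no information about the
isotherm — the ceiling values are stated by the screen design, the
nonzero start is this package's choice.

Measurement noise is multiplicative lognormal (UV absorbance after 1:3 to
1:6 dilution scales with signal), parameterized by its coefficient of
variation and mean-one so expectations are unbiased; the default cv = 2 %
is a plausible plate-reader figure, config-exposed, not a measured value.
Gross errors (pipetting faults, bubbles) are modeled by replacing a
replicate, with probability 2 % by default, with the true value scaled by
a factor drawn from [1.5, 3] in a random direction — these are what the
pretreatment filter exists to catch.

What the simulator does **not** emulate: buffer chemistry and pH shifts,
incubation kinetics, incomplete phase separation at centrifugation,
UV-calibration nonlinearity, correlated (plate-position or channel)
errors, and protein loss to surfaces. Passing recovery tests on synthetic
screens therefore demonstrates the identifiability of the isotherm's
parameters and the correctness of the pipeline under the stated error
model — not that the model fits any particular real protein's data.

## Numerical and design notes

- Cohn baseline log base: 10 (the historical semi-log convention),
  configurable.
- Non-integer n is permitted throughout; no rounding.
- Replicate means are arithmetic means of retained replicates, computed
  after filtering.
- Duplicate conditions always land on the same side of the split because
  membership is decided per level, not per record.
- Problem sizes used by the shipped checks: 96-condition standard screens,
  1000 random solver instances, 10 fit restarts — each full workflow run
  takes seconds on one core.
- Degenerate datasets (fewer than 5 conditions, or fewer than 2 distinct
  levels on either axis) are rejected as structurally non-identifiable
  before any optimizer runs.

## Known limitations

- ln k_eq and n are strongly correlated along a flat objective valley;
  under realistic noise, individual estimates of ln k_eq can deviate
  noticeably while predicted curves remain essentially unchanged. Interpret
  single-parameter values with care; n is the better-identified quantity.
- The hydration-number exponential means extreme parameter/composition
  combinations overflow; these are rejected explicitly rather than
  clipped.
- The model inherits the constant-activity-coefficient assumption; it is
  not expected to extrapolate across pH or PEG molecular weight — refit
  per condition family.
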