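# Methods

## Three-body equilibrium model

The system comprises a ligase L, a target T and a bifunctional ligand P
with binary dissociation constants K_LP (ligase–PROTAC) and K_TP
(target–PROTAC), and a ternary constant K_LPT defined from the
dissociation LPT ⇌ L + TP. Cooperativity α = K_LP/K_LPT rescales the
ternary association: LPT = α·L·T·P/(K_LP·K_TP). All concentrations are
nM; unit conversion belongs at the I/O boundary.

The coupled equilibrium is solved exactly by one-dimensional
root-finding on free P over [0, P_t]. At fixed free P the two remaining
conservation laws reduce to a quadratic in free T (stable-root form),
and the total-P residual is strictly monotone in free P, so a bracketed
Brent solve finds the unique physical state. Because in tight-binding
regimes the root can sit many orders of magnitude below P_t — where an
absolute x-tolerance under-resolves the extremely steep residual — the
bracketed solution is polished with secant iterations to relative
machine precision. Degenerate inputs (any total = 0) short-circuit to
closed-form binary or empty states, avoiding 0/0 in mass-action ratios.
Every returned state is conservation-checked at relative 1e-8.

An independent oracle (bisection on free P with damped fixed-point inner
iteration, no quadratic closed form) backs the solver in the test suite;
the two agree to relative 1e-8 over random parameter sweeps.

### Maximal ternary fraction

On an SPR surface with trace immobilised ligase and target held in
excess (T_t ≈ 25·K_TP, the excess used to maintain the preformed binary
complex; exposed as a configurable factor, default 25), the peak of the
bell-shaped [LPT] dose curve follows α/(α+β) with
β = (√(K_LP/K_TP)+1)²/25. The surface limit is modeled simply as
L_t → small (tests use 1e-3–1e-2 nM); no mass-transport/diffusion-layer
model is included. Note that the formula gives β = 4/25 = 0.16 for
matched binary affinities, although the value is conventionally rounded
to 0.2 in discussion; the formula is implemented as written and the
α = 2, β = 0.2 landmark evaluates the closed form at β = 0.2 directly.
The numeric hook-curve maximum reproduces the closed form within 5%
across α ∈ [0.1, 100] and K_LP/K_TP ∈ [0.1, 10].

## Ubiquitination initial-rate model

The rapid-equilibrium rate expression and its cooperativity form are
algebraically identical (verified to relative 1e-10 in tests); both are
implemented, sharing a cancellation-safe evaluation of
D = (P+T+K) − √((P+T+K)² − 4PT) via the factored form 4PT/((P+T+K)+√·),
without which the saturation regime loses all precision. Zero dose or
zero target returns the analytic limit 0 rather than raising, so curves
can start at P_t = 0.

The saturation approximation α·T_t/(2·P_t) is implemented verbatim. Its
printed factor differs from the exact P_t→∞ asymptote of the full
expression, which is α·T_t/P_t (twice the approximation); the ratio is
asserted to converge to 2 in the tests and the approximation is not
"corrected". The linear regime P_t/(2·K_LPT) agrees with the exact rate
within 1% once P_t is three orders below every other scale.

## SPR simulation and fitting

The 1:1 binding ODE is solved in closed form per injection phase;
simulation and fitting both use the analytic expressions (no numerical
integration). Single-cycle schedules carry the response at each
injection boundary forward as the next phase's initial condition (no
regeneration); multi-cycle schedules reset to baseline. The ternary
assay is interpreted as 1:1 in PROTAC concentration because the target
is in saturating excess in the preformed mix; the fitted KD is then
K_LPT and t½ = ln2/k_off is the ternary-complex half-life. Kinetic fits
run in log10(k) space with a shared Rmax; non-identifiable inputs
(single concentration, flat trace) raise a structured fit-failure
instead of returning garbage. Double-referencing is reduced to a
single-pass pointwise subtraction; solvent correction and drift terms
are omitted as instrument-specific.

Synthetic-data study conditions: 5-point five-fold dilution from
100 nM, contact 60 s, dissociation 120 s (300 s final in single-cycle),
Gaussian noise 1 RU on Rmax 100 RU, truth kon = 1e-3 1/(nM·s),
koff = 5e-3 1/s. A seeded 50-replicate study recovers k_off within 10%
per replicate with mean bias under 5%.

## Degradation metrics

POC = 100·(signal − background)/(vehicle − background). The AUC is the
unit-spacing trapezoid sum over the dose-indexed POC curve — fit-free,
order-reversal invariant, and equal to 100·(n−1) for a flat 100-POC
curve; the dose count defaults to 10 (1:3 dilution), the only count
consistent with the non-degrader ceiling of 900.

Dose-response fitting uses the variable-slope four-parameter logistic on
log10 concentration. DC50 is the dose where the fitted curve crosses
50 POC, solved on the fitted parameters; if the curve never crosses 50
within the tested range the value is censored and rendered as
">top-dose". Dmax is reported as 100 − min(fitted bottom, observed
minimum), with both constituents also exposed since the reporting
convention is ambiguous. Points above 100 POC at the top doses
(hook-effect distortion) always enter the AUC; the 4PL fit can mask the
top m doses by option. The Hill-slope is initialised on the side of zero
indicated by the data to avoid the flat hill = 0 saddle.

Time courses are fitted with a one-phase decay
POC(t) = span·e^(−kt) + plateau; t½ is the 50-POC crossing interpolated
on the fitted curve in closed form, and the initial degradation rate is
100·(0.693/t½) %/min — the constant 0.693 is kept literal so
rate·t½ = 69.3 exactly. A fitted plateau at or above 50 POC censors the
rate with a reason.

Generator conditions: 10-point 1:3 titration from 10 µM, truth
DC50 = 8 nM (inflection; the 50-POC crossing truth is recorded
separately), Dmax = 98, Hill 1, noise 3 POC; time-course truth
k = 0.0195 1/min, plateau 2 POC, noise 2 POC — a potent, fast degrader.
The hook option replaces the 4PL truth with a curve driven by the exact
equilibrium solver. The generators emulate replicate-averaged curves
with i.i.d. Gaussian noise; they do not model plate effects, drift, or
signal-dependent variance, so recovery results bound estimator behaviour
under idealised noise only.

## Correlation analysis

Pearson and Spearman coefficients come from scipy.stats with two-tailed
significance; Spearman additionally offers an exact permutation p-value
by full enumeration for n ≤ 10. Axis scales (linear vs log10) are
per-pair configuration, not hard-coded: the packaged analysis records
the scale that reproduces each published coefficient on the BRD4-BD2
table (log10 α vs rate → 0.99; linear K_LPT vs rate → −0.90). Censored
DC50 values are excluded by default, with an option to include them at
the censoring bound for sensitivity analysis. Record validation accepts
a 3% inconsistency between tabulated α and K_LP/K_LPT to absorb the
rounding of all three printed values.

## Geometry

Clash counting is a strict Euclidean cutoff (default 2.2 Å) over heavy
atoms via a KD-tree, verified against a quadratic scan. The assembly
filter keeps models with ≤5 protein-protein and ≤2 protein-PROTAC
clashes (configurable). Pose pruning superposes models on the ligase
(Kabsch, SVD with determinant correction), then compares warhead
centers of geometry (< 6 Å) and the first and second principal axes of
the warhead coordinate scatter, each folded to [0°, 90°] for eigenvector
sign ambiguity and compared axis-to-axis (< 20° each) — the most literal
reading of a two-axis deviation test. Linker strain energies are inputs
from an external force-field calculation; only the two-stage gate
(prune ≤ 4 kcal/mol; select ≤ 0.6 kcal/mol and warhead RMSD < 3 Å)
is implemented, and a missing strain prunes the model explicitly.

SASA is Shrake-Rupley with a deterministic Fibonacci sphere lattice
(default 960 points, probe 1.4 Å, Bondi radii pinned in a versioned
fixture, hydrogens ignored by default) — reproducible bit-for-bit, with
1- and 2-sphere closed forms matched within 0.5% at the default density.
Because the lattice is fixed in space, rigid-motion invariance holds to
the quadrature-error level (~0.3% at 960 points), not exactly. BSA is
the sum of component SASAs minus the complex SASA; the protein-protein
term is the burial of the PROTAC-removed two-protein sub-system and the
protein-PROTAC term is the remainder, so the decomposition sums to the
total by construction. Tiny negative quadrature remainders are clamped
at zero.

## Packaged tables and fixtures

The per-compound tables (binding constants, cooperativities, AUCs,
initial rates for one SMARCA2 series and two BRD4 bromodomain series,
plus DC50/Dmax with censoring) are transcribed once into CSV fixtures,
guarded by SHA-256 checksums, and never recomputed. One compound's
ternary affinity is only approximate (~500 nM) and its AUC/rate are
absent in the source; the fixture records the absence rather than
imputing. The toy structural fixture is a linear triatomic whose burial
is known exactly from spherical-cap formulas, including the non-obvious
fact that the cap an outer sphere loses to the far sphere lies entirely
inside the cap it loses to the middle one.

## Known limitations

- No mass-transport, rebinding, heterogeneous-ligand or bivalent SPR
  models; the ternary dissociation is fitted 1:1 even though it may be
  bi-phasic in reality.
- No enzymology beyond the rapid-equilibrium initial-rate expression:
  E2 kinetics, ubiquitin chains and proteasome steps are out of scope.
- No conformational search, docking, MD or force-field energies; the
  geometry module scores and filters externally generated models.
- Correlation analysis reports pairwise coefficients only — no
  regression, multiple-testing correction, or causal claims.
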