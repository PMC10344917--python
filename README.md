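# ternary-sar

Quantitative structure-activity analysis for heterobifunctional degraders
(PROTACs). A PROTAC links an E3-ligase ligand to a target-protein warhead,
and degradation begins with a three-body ternary complex
ligase·PROTAC·target (LPT). This package connects the biophysics of that
complex to cellular degradation readouts for scientists characterising
degrader series by SPR and cell-based assays.

## What it computes

**Ternary-complex equilibrium.** The three mass-action laws

    [LP] = [L][P]/K_LP,   [TP] = [T][P]/K_TP,
    [LPT] = α [L][T][P] / (K_LP K_TP),      α = K_LP / K_LPT

have no closed-form solution, but the total-PROTAC conservation residual
is strictly monotone in free [P], so the exact state is found by scalar
root-finding (`solve_ternary_equilibrium`, `hook_curve`). The maximal
ternary fraction on an SPR surface follows the closed form

    [LPT]_max/[L]_t ≈ α/(α + β),   β = (√(K_LP/K_TP) + 1)² / 25,

with the 25 the target excess over K_TP that maintains the binary complex.

**Ubiquitination initial rate.** Under rapid equilibrium,
v/V_max = α / (α + 2(K_LP+[P]_t)/D − 1) with
D = ([P]_t+[T]_t+K_TP) − √(([P]_t+[T]_t+K_TP)² − 4[P]_t[T]_t), plus its
linear ([P]_t/2K_LPT) and saturation (α[T]_t/2[P]_t) regimes.

**SPR data reduction.** 1:1 Langmuir kinetic fits (multi-cycle or
single-cycle without regeneration), steady-state affinity fits, and the
ternary-complex half-life t½ = ln2/k_off.

**Degradation metrics.** Percent-of-control normalisation, variable-slope
4PL dose-response fits (DC50 with ">top-dose" censoring, Dmax),
unit-spacing trapezoid AUC (a 10-point flat 100-POC curve scores 900),
and one-phase-decay time courses (initial rate = 100·0.693/t½, %/min).

**SAR correlations.** Pearson/Spearman coefficients with two-tailed
significance over per-compound tables, with per-pair linear/log10 scale
configuration. The packaged BRD4-BD2 table reproduces r = 0.99 for
log10(α) vs initial rate and r = −0.90 for K_LPT vs rate.

**Ternary-model geometry.** Steric clash counting (2.2 Å cutoff; keep at
≤5 protein-protein and ≤2 protein-PROTAC contacts), warhead-pose pruning
(COG distance < 6 Å, first two principal axes within 20°), the linker
strain / warhead-RMSD selection gate, Kabsch superposition RMSD, and
Shrake-Rupley SASA on a deterministic Fibonacci lattice with buried
surface area split into protein-protein and protein-PROTAC terms.

## Worked example

`examples/` holds one short script per capability. For instance:

```sh
$ python examples/sar_correlations.py
k_lpt_nM~auc                     r = +0.99  (p = 0.00018, n = 6, x: linear)
k_lpt_nM~dc50_nM                 r = +1.00  (p = 0.0019, n = 4, x: linear)
alpha~initial_rate               r = +0.99  (p = 0.00013, n = 6, x: log10)
k_lpt_nM~initial_rate            r = -0.90  (p = 0.013, n = 6, x: linear)
t_half_spr_s~initial_rate        skipped: only 0 complete records
```

Cooperativity (log scale) correlates near-perfectly with the initial
degradation rate in this series, while weaker ternary affinity (higher
K_LPT) slows degradation; censored DC50 entries (">10000") are excluded,
which is why that pair has n = 4.

```sh
$ python examples/hook_curve.py
cooperativity alpha = 2.0, beta = 0.16
closed-form maximal ternary fraction alpha/(alpha+beta) = 0.9259
numeric maximum of [LPT]/[L]_t = 0.9258 at [P]_t = 1.42e+03 nM
[LPT]/[L]_t at the top dose (1e+06 nM) = 4.99e-03  <- hook-effect collapse
```

The exact solver's bell-shaped dose response peaks at the closed-form
maximum and collapses at excess PROTAC (the hook effect).

A thin CLI mirrors the library (`ternary-sar equilibrium|rate-curves|
fit-spr|fit-dr|fit-tc|sar-correlate|bsa|simulate`).

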