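# glp1pharm

Quantitative pharmacology of GLP-1 receptor (GLP-1R) agonists: a Python
package for quantifying signal bias, receptor-binding kinetics, receptor
trafficking, and their relationship to insulin secretion across a panel of
peptide agonists.

The GLP-1R is a class B GPCR and a major type 2 diabetes drug target.
Agonists differ not only in potency but in *which* pathways they engage
(G-protein/cAMP vs. β-arrestin recruitment), how long they stay bound
(residence time = 1/k_off), and what they make the receptor do afterwards
(internalize, recycle, or degrade). Those differences, not acute cAMP
potency, predict prolonged insulin secretion. This package implements the
analysis chain a bench pharmacologist needs to characterize such a panel
from plate-reader and flow-cytometry readouts, and ships a synthetic-data
module that generates every input from known ground truth so the whole
chain is testable end to end.

## What it computes

**Signal bias** (`bias_quant`). Concentration-response panels are fitted
globally with the operational model of agonism, parameterized directly in
the transduction coefficient:

    E([A]) = basal + (E_m − basal) / (1 + ((1 + [A]/K_A) / (R·[A]))^n),
    R = 10^log(τ/K_A)

with E_m, basal and the transducer slope n shared across agonists within a
pathway, and log(τ/K_A), log K_A free per agonist. Per experiment,
log(τ/K_A) is normalized to the reference agonist (Δlog(τ/K_A)); the
between-pathway contrast ΔΔlog(τ/K_A) = Δ_A − Δ_B carries a propagated
standard error √(SEM_A² + SEM_B²) and a 95% CI; an agonist is called biased
when the CI excludes zero. 10^ΔΔ is the bias factor; radar-plot ("web of
bias") coordinates 10^Δ (normalized to a reference pathway) are also
emitted.

**Binding kinetics** (`binding_kinetics`). One-phase exponential decay fits
of surface dissociation (plateau fixed at zero after nonspecific
subtraction); the closed-form competitive-association model for a labeled
tracer plus unlabeled competitor (Motulsky–Mahan), with an analytic branch
for the repeated-root degeneracy; global fitting across ≥4 competitor
concentrations; residence time = 1/k_off and K_d = k_off/k_on.

**Trafficking** (`trafficking_quant`). Stripping-corrected flow-cytometry
internalization,

    % internalized = 100 · [r(t_x) − r(t₀)] / [1 − r(t₀)],
    r(t) = F₊Me(t)/F₋Me(t),

recycling as the fraction of the 15-min internalized pool returned to the
surface, plate-reader surface loss/recovery, DERET (diffusion-enhanced RET)
surface-loss time courses, surface downregulation, and endosomal pH from
FITC-agonist fluorescence calibrations anchored on bafilomycin-neutralized
endosomes (pH 7.4).

**Response indices** (`response_quant`). Four-parameter logistic fits,
normalization to a reference agonist's fitted maximum, insulin stimulation
index (fold over glucose-only control), percent release, F/F_baseline trace
normalization and baseline-referenced AUC.

**Profiles** (`profiling` + `pipeline`). Per-agonist feature matrices
(k_off normalized to reference, Δlog(τ/K_A) for cAMP and β-arrestin-2,
internalization %, recycling %), standardized PCA, and OLS regressions such
as internalization vs. prolonged insulin stimulation index.

## Worked example

```bash
glp1pharm run-all --demo --outdir demo_run --seed 1
```

runs the bundled six-agonist demonstration: synthetic data are generated
from a planted ground truth (operational parameters per agonist × pathway,
binding rate constants, compartmental trafficking rates), written as tidy
CSV, read back, and pushed through every fitting stage. Key outputs in
`demo_run/results/`:

`bias_delta.csv` — cross-experiment Δlog(τ/K_A) (excerpt):

```
agonist       pathway  mean    sem    n
exendin-phe1  barr2   -1.406   0.043  5
exendin-phe1  cAMP    -0.348   0.029  5
exendin-asp3  barr2    0.611   0.028  5
exendin-asp3  cAMP    -0.169   0.037  5
```

The phe1-like analog loses ~1.4 log units of β-arrestin-2 transduction but
only ~0.35 of cAMP — G-protein bias; the asp3-like analog gains
β-arrestin-2 — the opposite. Its β-arrestin-1 row is absent for
exendin-phe1: the response never rises above the noise floor, so the cell
is flagged unquantifiable rather than imputed.

`kinetic_constants.csv` — e.g. exendin-4: k_on 1.01e8 /(M·min), k_off
0.051 /min, residence time 19.7 min, K_d 0.50 nM (planted: 1e8, 0.05,
20 min, 0.5 nM).

`profile_summary.json` — the headline relationship:

```
slope -0.046, r² 0.97, p 3.5e-4   (internalization % vs. ISI)
```

a negative, significant association between maximal internalization and
prolonged insulin secretion, and a PCA in which the slow-internalizing,
fast-recycling agonist separates at one extreme of PC1 (score −4.1 vs.
−0.3…1.8 for the rest; PC1 carries ~77% of the variance).

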