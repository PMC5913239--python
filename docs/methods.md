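# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `glp1pharm`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Operational model and bias statistics

Concentration-response data for one signaling pathway are fitted globally
with the operational model of agonism in its transduction-coefficient
parameterization,

    E([A]) = basal + (E_m − basal) / (1 + ((1 + [A]/K_A) / (R·[A]))^n),
    R = 10^log(τ/K_A),

with E_m (system maximum), basal, and transducer slope n shared across all
agonists within a pathway × experiment, and log(τ/K_A), log K_A free per
agonist. Fitting log(τ/K_A) directly (rather than τ and K_A separately and
taking the ratio) makes the quantity of interest a fit parameter with its
own standard error. Replicates within an experiment enter the residual
jointly; cross-experiment statistics treat each experiment's estimate as a
single observation, so intra-experiment replication never inflates n.

**Identifiability.** With n = 1 the model collapses to a hyperbola per
agonist: only basal, top, and EC50 are observable, so E_m, K_A and τ/K_A
trade off along an exact one-dimensional degeneracy and the *absolute*
log(τ/K_A) is not identified — only within-panel differences are. This is
precisely why bias analysis reports Δ and ΔΔ rather than raw transduction
coefficients. Two consequences for this package:

- the fit bounds E_m to [0.5, 3] × the observed maximal response, which
  cuts off the flat direction and keeps the optimizer from wandering along
  it (the reported Δ values are unaffected — the degeneracy shifts all
  log(τ/K_A) in a panel by a common constant);
- tests assert absolute recovery only for n ≠ 1 panels (identifiable) and
  exact Δ recovery for n = 1 panels.

**Quantifiability.** An agonist whose replicate-averaged response span
stays below a noise floor (default 5% of the panel-wide span) is flagged
`quantifiable = False`, excluded from the global fit, and propagated as an
explicit flag — never imputed, never silently zero.

**Bias statistics.** Δlog(τ/K_A) is computed within each experiment
against the reference agonist (removing day-to-day assay-sensitivity
shifts, which enter the synthetic data as a common per-experiment
log-potency offset), then averaged across experiments with SEM.
ΔΔlog(τ/K_A) = Δ_A − Δ_B with SE = √(SEM_A² + SEM_B²) and a 95% CI using
z = 1.96 (default) or Student-t with Welch–Satterthwaite degrees of freedom
(`ci_method="t"`); `significant` records whether the CI excludes zero. On a
null panel (equal τ/K_A shifts in both pathways; 5 experiments, 10%
response noise) the z-based call fires at ~6% over 500 simulations and the
t-based call at ~4%, bracketing the nominal 5%. Web-of-bias coordinates are
10^Δ after re-centering each agonist on its own reference-pathway Δ, so the
reference agonist maps to 1 on every axis.

## Competitive binding kinetics

The tracer-occupancy solution for simultaneous addition of labeled tracer
(k1, k2, concentration [L]) and unlabeled competitor (k3, k4, [I]) uses the
aggregates K_A = k1[L] + k2, K_B = k3[I] + k4,
S = √((K_A − K_B)² + 4·k1·k3·[L]·[I]), K_F/K_S = ½(K_A + K_B ± S):

    RL(t) = Q·[ k4(K_F − K_S)/(K_F·K_S) + ((k4 − K_F)/K_F)·e^(−K_F·t)
              − ((k4 − K_S)/K_S)·e^(−K_S·t) ],   Q = Bmax·k1·[L]/(K_F − K_S).

When (K_F − K_S)/K_F < 1e−9 the formula is replaced by its analytic
repeated-root limit (the derivative form of the two decaying exponentials),
avoiding catastrophic cancellation; just above that threshold the direct
formula's cancellation error is ≤ ~2e−7 relative, within the 1e−6 oracle
tolerance used in tests. The closed form matches numerical integration of
the two-ligand ODE system (solve_ivp, rtol 1e−11) to < 1e−6 relative error
over 100 random parameter sets including the degenerate regime, and reduces
exactly to one-phase association at [I] = 0.

Global fits across competitor concentrations optimize log k3, log k4
(positivity by construction) with Levenberg–Marquardt; Bmax is shared
within a plate and, by default, estimated from the competitor-free trace
given known tracer rates (a linear one-parameter projection). Dissociation
traces are fitted as B(t) = B₀·e^(−k_off·t) with the plateau fixed at zero,
since specific binding under complete blockade must vanish; a
non-decreasing trace is flagged `no_dissociation` instead of fitted.
Residence time = 1/k_off and K_d = k_off/k_on are exact arithmetic
identities of the fitted rates.

## Trafficking model and metrics

The synthetic generator drives all trafficking readouts from a three-state
linear compartment model (surface S, internalized I, degraded D):

    dS/dt = −k_e·S + k_r·I,  dI/dt = k_e·S − (k_r + k_d)·I,  dD/dt = k_d·I,

solved analytically (eigendecomposition of the 3×3 generator; matrix
exponential fallback near defective cases), so S + I + D is conserved to
round-off and round-trip tests carry no integrator tolerance. Default rates
put endocytosis on a minutes scale (k_e 0.012–0.06 /min), recycling on a
tens-of-minutes scale (k_r 0.004–0.04 /min) and degradation on an hours
scale (k_d 0.0002–0.002 /min), mirroring a receptor whose internalized pool
is intact within the 1-h assay window but substantially degraded after
16 h.

The flow-cytometry emulation assumes surface stripping removes 90% of the
surface label (configurable) and that degradation destroys the label. The
stripping-corrected formula then returns exactly 100·I/(S + I) on noiseless
data; its deviation from the true internalized fraction I/(S + I + D) is the
computable degraded-pool term, small at the 15–60 min readout times under
the default rates. Computed percentages outside [0, 100] beyond a 2-point
tolerance are flagged, not clipped, preserving the error structure.

Recycling is reported as the fraction of the 15-min internalized pool that
returned to the surface (loss of internal label between the two strips);
the alternative convention — absolute percentage points of total receptor —
is available via `absolute=True`, since the verbal definition of the assay
admits both readings.

DERET processing ratios the 620 nm donor over the 520 nm acceptor channel,
anchors each well at its own t₀ (removing labeling variation), and reports
the course relative to vehicle; internalization relieves fluorescein
quenching of the terbium donor, so surface loss increases the ratio.

Endosomal pH uses a per-ligand linear fluorescence–pH calibration and the
control/bafilomycin signal ratio: bafilomycin collapses the endosomal
proton gradient, anchoring its condition at pH 7.4, and the ratio rescales
the calibrated intensity at 7.4 to the intensity at the unknown pH,
cancelling well-to-well loading. Estimates outside the calibration range
carry an extrapolation flag. The generator emits 12 serial readings per
well (the estimator averages them), emulating the repeated fluorescence
reads of the hour-long measurement; with single readings at 1% noise the
estimator SD would be ~0.14 pH units, dominated by the two-well ratio.

## Secretion coupling in the generator

No quantitative model links trafficking to secretion in the emulated
system; the generator's coupling law is an explicit stand-in chosen only to
plant a monotone relationship, not a mechanistic claim:

    secreted = r₀·T + κ·ρ·∫₀ᵀ S(t)/S(0) dt,

with basal rate r₀ (control releases ~2% of content over 16 h), receptor
occupancy ρ = [A]/([A] + K_d), and coupling κ = 5 for all agonists, so that
fast-internalizing/slow-recycling agonists (small surface integral) secrete
less over prolonged exposure. The insulin stimulation index of the control
is 1 by construction and the planted internalization–ISI relationship is
negative.

## Synthetic noise and what passing tests show

Measurement noise is Gaussian on the linear readout scale, CV- or
SD-parameterized, truncated at zero where the readout is physically
non-negative. Defaults per readout: 10% CV dose-response, 1% CV binding
traces, 3% CV trafficking fluorescences, 1% CV pH intensities, 8% CV
secretion. A single global seed fans out to per-generator streams
(SeedSequence-style child keys), making full pipeline runs byte-stable.

The generator emulates replicate structure, day-to-day sensitivity drift,
imperfect stripping and nonspecific binding, but **not**: heteroscedastic
or correlated plate effects, receptor reserve differences between cell
lines, ligand depletion, cooperative or two-site binding, β-arrestin
signaling mechanics, or cell-to-cell heterogeneity. Passing round-trip
tests therefore demonstrates estimator correctness under the stated noise
model, not robustness to every artifact of real plate data.

## Problem sizes

Study-scale checks use 6 agonists × 3 pathways × 5 experiments × 8
concentrations × 2 replicates for bias, 4 competitor concentrations × 61
time points for kinetics, and 500 simulations for the null-panel
calibration of the bias call — sizes chosen to match the emulated study
design while keeping a full run within a few minutes on one CPU.

## Known limitations

- Absolute log(τ/K_A) values are reported but, for n ≈ 1 panels, are
  meaningful only up to a panel-wide constant (see identifiability above);
  consume Δ and ΔΔ.
- The operational fit assumes E_m, basal, n shared within a pathway ×
  experiment; receptor-reserve differences between agonist batches would
  violate this.
- Tracer k1/k2 are treated as known plate constants; co-fitting them with
  a single tracer concentration is not identifiable and is not attempted
  (Bmax co-fitting is available).
- The FACS recycling readout conflates degradation with recycling at the
  margin (internal label lost to degradation during the recycling period is
  counted as recycled), as in the physical assay.
- PCA drops agonists with any masked feature (logged); it never imputes.
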