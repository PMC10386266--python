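# Methods

## The controlled-release reading of biphasic dissolution

A biphasic dissolution run reports, over ~4.5 h, the fraction of dose that
has crossed from an aqueous donor phase into an organic acceptor phase kept
under sink conditions.  For poorly soluble drugs, (re-)dissolution in the
aqueous phase — not membrane permeation — is rate-limiting, so the organic
partitioning profile is treated exactly like the release curve of an
extended-release product: a cumulative function `R(t)` whose derivative is
the absorbable flux and whose plateau is the fraction absorbed, `Fa`.  This
sidesteps any mechanistic dissolution/precipitation/re-dissolution model;
whatever supersaturation, precipitation or Ostwald ripening the formulation
exhibits is already integrated in the measured profile.

Assumptions worth stating explicitly:

* **1:1 time mapping.** One assay minute equals one in vivo minute, with the
  plateau held constant afterwards.  A linear `time_scale` factor is
  available on `AbsorptionInput` but defaults to 1.0; nothing in the
  workflow calibrates it.
* **Plateau = Fa.** The organic sink stands in for the gut wall; drug that
  never partitions is never absorbed.
* **Monotone envelope.** Partitioning into a sink is physically cumulative,
  so analytical scatter is removed by a running-maximum envelope rather
  than smoothing; the envelope preserves every knot it keeps and is exactly
  testable.  Readings up to 1.05 (5% analytical overshoot) are accepted and
  clamped to 1.0; larger values are treated as unit errors and rejected.
* **Gastric lag.** Synthetic profiles expose the organic phase only after a
  30-minute gastric stage, matching the assay protocol.

Four parametric shape classes cover the observed profiles: zero-order
(linear ramp; nano/microcrystal formulations), first-order→plateau,
square-root/Higuchi-like (first-generation ASDs), and a steep Hill-type
sigmoid (precipitation followed by redissolution of ripening nano-droplets).
Defaults (ramp end 270 min, k = 0.025 min⁻¹, Higuchi coefficient
0.08 min^−1/2, sigmoid midpoint 120 min with Hill coefficient 10) were
chosen so that each noiseless curve visibly levels off inside the assay
window — the plateau estimator (mean over the last 60 min, stability flag
if the in-window range ≤ 0.02) then recovers `f_inf` within 0.01.

## Permeability

`Peff [cm/s] = 265.8 · MW_eff^−4.5 · MA`, `MA = 10^logP`,
`MW_eff = MW − 17·n_F − 22·n_Cl − 62·n_Br − 98·n_I` (g/mol).  Two unit and
convention choices are forced numerically rather than documented anywhere
authoritative: the raw power-law output is interpreted as cm/s (×60 gives
the cm/min convention used for absorption rate constants), and the halogen
corrections follow the whole-body-PBPK convention listed above.  With
these, the three reference drugs whose permeability derives from the
correlation (aprepitant, celecoxib, itraconazole) are reproduced within
1%.  Ionization is ignored (no logD correction): for the reference set, it
is not needed for the reproducible entries, and no simple correction
reproduces the remaining ones (fenofibrate's listed value corresponds to
logP 4.4 rather than its measured 5.4; fenofibric acid and ritonavir are
also off the power law by large factors).  Where permeability is known from
another route (nimodipine, converted from Caco-2 data), `peff_override`
bypasses the correlation entirely.  `Peff` only enters simulations in the
optional lumen-transit mode (`k_a = 2·Peff/r`); in the default
direct-coupling mode the release function alone controls absorption.

## PBPK engine

A deliberately minimal, auditable surrogate for full organ-level PBPK
engines: mammillary disposition (1–3 compartments; CL, Vc, Q_i, V_i) plus an
explicit liver-first-pass gate applied once to orally absorbed drug, so
`F = Fa·(1 − E_h)`.  The first-pass is a fixed extraction ratio, not a
well-stirred CLint model — the workflow only ever needs "X% inactivated on
first passage".  Plasma concentrations are total drug (the unbound fraction
is carried but unused); i.v. drug sees hepatic elimination only through CL.

* **Routes.** Bolus (initial condition), constant-rate infusion, oral
  solution (first-order gastric emptying, half-time 15 min fasted), and
  controlled-release driven by an `AbsorptionInput` (piecewise-constant
  flux `dose·dR/dt`).
* **Coupling modes.** `direct` (default): absorbable flux goes straight
  through the liver gate, reflecting the premise that dissolution is
  rate-limiting.  `lumen_transit` (sensitivity only): the flux feeds a
  7-segment small-intestine chain (total transit 3.32 h, radius 1.25 cm)
  absorbing at `k_a = 2·Peff/r` per segment; drug exiting the last segment
  is lost faecally unless colon absorption is enabled.
* **Prodrug activation.** Default instantaneous presystemic conversion with
  molar-mass scaling (`mw_active/mw_parent`), reflecting esterase-activated
  prodrugs whose parent is undetectable in plasma; a first-order plasma
  conversion pool is available.  The mass difference of conversion is
  tracked in an explicit `conversion_loss` state so the audit stays exact.
* **Enterohepatic recirculation.** A fraction `f_bile` of the systemic
  clearance flux accumulates in a gallbladder store; at each scheduled
  emptying time the store empties first-order over the window (rate set to
  void 99.9%), re-enters the gut and is reabsorbed through the liver gate
  with fraction `f_reabsorbed`.  Defaults: single emptying at 12 h over
  0.5 h, complete reabsorption — a parsimonious reading of secondary plasma
  rises in the 10–30 h range.  `f_bile = 0` reduces exactly to the base
  model.
* **Numerics.** LSODA with rtol 1e−8, atol 1e−10 mg; every structural
  discontinuity (dose start, infusion end, release knot, emptying edge) is
  an integration breakpoint, so trajectories are deterministic.  Every
  outflow lands in an explicit sink state (`eliminated`, `unabsorbed`,
  `conversion_loss`, plus the analytic `unreleased`/`uninfused`
  remainders), and `mass_balance` audits dose conservation; ≤1e−6 relative
  error is enforced in the tests.
* **Closed form.** For the linear sub-class used in fitting (i.v. and
  direct-coupled oral solution without recirculation), concentrations are
  also available by eigendecomposition of the rate matrix
  (`disposition_concentrations`) — exact, ~100× faster than the ODE path,
  and cross-checked against it in the tests.  Coinciding eigenvalues (a
  measure-zero configuration) fall back to the ODE path.

## Parameter identification

Loss is the unweighted sum of squared log-concentration residuals: plasma
curves span orders of magnitude and log residuals weight the terminal phase
on a par with the peak.  Observations below the LLOQ are excluded (no
censoring likelihood).  Optimization is multistart (default 8 starts, one
at the physiologic midpoint, the rest log-uniform within ±1.5 decades,
seeded) trust-region least squares in log-parameter space, bounded to
[1e−3, 1e3] × midpoints (CL 5 L/h, Vc 50 L, Q 5 L/h, V 50 L).  Compartment
count is chosen by AICc computed from the log-residual SSE; the SSE is
floored at 1e−12 per observation so that numerically-zero losses compare as
ties (resolved toward fewer compartments) rather than by floating-point
noise.  `E_h` is structurally unidentifiable from oral data alone (only
`Fa·(1−E_h)` enters the curve) and from i.v. data it is invisible, so it is
always a fixed input to the fitter.  One-compartment oral fits are subject
to the classic flip-flop ambiguity (absorption and elimination rate
constants interchangeable); CL remains identifiable and the tests assert
exactly that.

Asymptotic CVs are reported from the Gauss–Newton covariance at the
optimum (standard deviations of log-parameters).

## Non-compartmental metrics and validation

Cmax/tmax come from the dense simulation grid (default step 0.05 h over the
absorption window and the first two days; a coarser tail extends to eight
terminal half-lives, capped at 3000 h, so the log-linear extrapolation
operates on a genuinely terminal stretch).  AUC is linear-trapezoid;
`lambda_z` is an unweighted log-linear regression over the last three
positive points (configurable; flagged and omitted when fewer than three
positive points exist or the slope is non-negative), and
`AUC_inf = AUC_last + C_last/lambda_z`.  Bioavailability is
`F = AUC_inf·CL/dose`.  Fold errors `FE = predicted/observed` are
classified against the 2-fold (0.5–2.0; pass/fail) and 1.25-fold (0.8–1.25;
informational) bands; the classification is symmetric under `FE ↔ 1/FE`.

## Synthetic virtual drugs

`make_virtual_drug(seed)` draws an internally consistent ground-truth
bundle: CL log-uniform 1–50 L/h, Vc log-uniform 10–500 L, E_h uniform
0–0.95, Fa uniform 0.05–0.9, 1 or 2 compartments (peripheral Q = 0.2–2×CL,
V = 0.5–5×Vc, log-uniform), one of the four shape classes with the profile
plateau set equal to Fa (the consistency law of the controlled-release
reading), and doses uniform 25–250 mg.  These ranges bracket the reference
products, including the severe-first-pass corner.  Observation noise is
multiplicative lognormal with `sigma = sqrt(log(1+cv²))` so the sample CV
equals the nominal `cv` (default 0.15); the lognormal is median-unbiased
(mean bias ~1% at cv 0.15).  Because virtual terminal half-lives span
~0.2–350 h, the sampling schedule is generated per drug — 12 log-spaced
times from a tenth of the fastest disposition half-life to four terminal
half-lives — as a real ADME study would place samples; a fixed clock cannot
serve that range.  Randomness is split with `SeedSequence.spawn` per drug
and per arm, so adding a drug never perturbs earlier draws.

`recovery_experiment(n, seed, cv)` closes the loop for each drug: noisy
i.v. observations → AICc model selection (1 vs 2 compartments, 8 starts) →
consistent partitioning profile → release function → product prediction
with the fitted disposition (E_h fixed at truth) → fold errors against the
noise-free truth prediction.  With cv = 0 the loop is an identity to
numerical tolerance (fold errors 1 ± 0.5%, CL/Vc recovered within 1%,
compartment count recovered); with cv = 0.15 and 12 samples the fold errors
stay well inside the 2-fold band (typical worst-case ratio ~115–120%).
The panel size of 20 drugs keeps the experiment within seconds while
spanning all four shapes and both compartment counts.

What the generator does **not** emulate: inter-individual variability
(observations stand in for study-mean curves), food effects, nonlinear or
saturable elimination, transporters, assay-specific artifacts (acceptor
saturation, pump rates), and any mismatch between the parametric shapes and
real measured profiles.  Passing the closed loop therefore demonstrates
that the pipeline's inference and coupling are self-consistent under its
own model class — not that the model class captures any particular real
formulation.

## Known limitations

* The controlled-release reading ignores back-partitioning from the organic
  phase and any in vivo process faster than the assay resolves.
* The fixed-`E_h` gate has no enzyme saturation, so bioavailability is
  dose-independent by construction.
* AICc selection can over-parameterize under noise (an occasional
  one-compartment truth fitted as two); the fold-error boundary absorbs
  this, but individual parameter estimates from such fits should be read
  with their CVs.
* The lumen-transit mode is a sensitivity tool, not a validated absorption
  model; colonic absorption is all-or-nothing.
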