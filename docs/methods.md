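# Methods

This note documents the model, the numerical design, the synthetic-data
generator and the open choices made while building the package. It states
no empirical result beyond what the test suite and `scripts/acceptance.py`
compute themselves.

## Deterministic submodel

Blood glucose G (mg/dL) obeys

    dG/dt = -(GEZI + (1+h)·X)·G + EGP - SE·E + RA - FR,
    h = H if G < Gth else 0,
    dSG/dt = (G - SG)/τG,
    FR = 0.003·(G - 162)⁺.

**Hypoglycemia term.** The insulin term is written with the factor
(1 + h): h amplifies insulin action below the threshold Gth, and H → 0
removes the amplification while leaving ordinary insulin action intact. An
alternative reading in which h *gates* insulin action entirely (so insulin
has no effect above Gth) contradicts X's role as the insulin effect and
makes the clinically expected limit H → 0 pathological; we use the
amplifying form.

**Chain normalisation.** Every first-order stage has unit DC gain
(τ·ẏ = u − y), so gains enter only at injection points: a meal injects
0.8·MA·carbs·1000/VG (mg/dL of glucose mass; bioavailability fixed at
0.8), a bolus injects IA·dose (U), exercise injects its P gains, heart
rate enters as the excess over the resting value. This makes all reported
time constants interpretable and conservation testable: VG·∫RA dt equals
the bioavailable carb mass, and the insulin chain's DC gain is exactly
IA·dose.

**Units.** Internal units are minutes, mg/dL and grams; insulin doses in
units (U). No insulin distribution volume is modelled, so the μU/mL → U
conversion is folded into SI's effective gain: model-unit insulin
sensitivities are O(0.4) 1/U rather than O(4e-4) mL/μU. Only SI's scale is
affected. The units of E are bpm-excess and SE carries (mg/dL/min)/bpm;
any consistent convention rescales SE only.

**Initial state.** The window-start glucose (both G and SG) is taken from
the first CGM reading. The insulin chain starts from latent initial
contents: one latent S0 fills both intermediate compartments S1 and S2
(they are not separately identifiable at t=0), Ip0 fills the plasma stage
and X0 the effect stage. Meal-chain initial contents are fixed at zero —
pre-window absorption is absorbed by the CGM-seeded initial glucose and
the sample-level EGP.

**Basal insulin.** One long-acting injection is converted to a constant
infusion dose/1440 U/min into the first insulin compartment for the whole
window, keeping a single insulin pathway (an additive X offset was
rejected).

## Numerics

All linear chains are evaluated in closed form. The cascade response is
computed by partial fractions with three branches: pairwise-distinct
poles, exactly one coincident pair (the confluent form — this is the meal
chain's structural double τD2), and a general multiplicities fallback.
The branch switch happens at a relative pole separation of 1e-7; the
distinct formula's cancellation error at that separation is ~1e-10 of the
peak, so the branches overlap safely (tested against a matrix-exponential
oracle, including triple poles).

The time-varying final insulin stage τI4·Ẋ = SI·Ip − X is integrated by a
first-order-hold exponential integrator on the half-step grid (exact for
piecewise-linear drive, third-order accurate for the smooth closed-form
drive; relative error ~5e-5 against a dt=0.01 min RK4 reference on the
default 1-min grid). The heart-rate chain is propagated by the exact
zero-order-hold map of the repeated pole, matching the piecewise-constant
resampling of the HR stream (last reading held for at most 15 min, then
the resting value). The nonlinear (G, SG) pair is integrated by
fixed-step RK4 on the window grid with forcing evaluated on the half-step
grid; 1 min is the default step, the scaled-down fitting configuration
uses 5 min. The `full_ode` backend integrates the complete compartment
system by RK4 at a fine sub-step with impulses applied at exact event
times; the two backends agree to a fraction of a mg/dL on a busy day and
the analytic path is the production one.

Inside the likelihood, glucose is clamped at a 1 mg/dL floor so that
extreme latent draws produce a finite (terrible) density instead of an
exception; the public simulator raises an integration error carrying the
offending time instead.

## Hierarchy and priors

Latents live on cohort / patient / sample / event levels. A latent
estimated on several levels forms a chain of truncated-normal conditionals
centred on the level above, truncated to the latent's physical support.
Spreads are fixed table values except where the study design estimates
them: per-patient standard deviations for the sample-level spread of EGP,
SIE, SIA, SIφ and X0 (exponential or half-normal priors) and for the
event-level spread of τI1 and τP,long, plus one cohort-level sd for the
across-patient spread of τD1. Exponential "variance" priors are applied
to standard deviations. The CGM noise σ is a nested log-normal
(cohort/patient/sample chain on log σ). The sinusoid phase SIφ has a
uniform cohort prior on [0,1) day; patient and sample offsets are plain
normals — the sinusoid is periodic in its phase, so no wrapping is needed.
Sample-level EGP is drawn from TN(EGPi + EGPm·SIE, σ_EGP, 0, ∞) with
patient-level intercept EGPi and slope EGPm.

Prior locations and bounds that are not pinned by published estimates
(glucose distribution volume, metabolic gain, hypoglycemia threshold and
amplification, SI scale, EGP intercept/slope, event-offset spreads) were
set by prior-predictive calibration: simulated prior trajectories on the
packaged exemplary day must span — and mostly stay inside — the
physiological 0–400 mg/dL band, and under zero-insulin zero-meal
conditioning the terminal glucose must rise toward the
renal-excretion-limited plateau (median above 300 mg/dL). The effective
table ships in `glucotwin.priors` with a `source` flag per entry
("printed" vs "default") and round-trips through YAML.

The event-report offsets TD/TI/TP may be negative (reports can lag
reality); their priors are truncated normals centred at small positive
delays (meal 15 min) on supports like [-30, 90] min.

## Inference

The guide is a Gaussian over the unconstrained latent space with
covariance diag(d²) + WWᵀ (default rank min(50, D); rank 0 is mean-field).
Supports map to the real line by scaled logit (two-sided), shifted log
(half-line) or identity; transform arguments are capped at ±50, which
leaves huge headroom over physical scales while keeping every downstream
quantity finite.

ELBO gradients use the reparameterisation trick with the analytic entropy
of the low-rank Gaussian. Gradients of the joint density with respect to
the latents are obtained by batched central finite differences (step 1e-3
in unconstrained space): the prior-plus-Jacobian part is differenced
densely (no simulation involved), and each window's likelihood is
differenced only along the ~35 sites it actually depends on, so one
iteration costs a few thousand batched window simulations rather than
hundreds of thousands. Gradients are clipped elementwise at 1e4 before
the Adam update — unclipped, a transient overflow in Adam's second moment
permanently freezes coordinates. The optimiser is Adam with a cosine
learning-rate decay; the guide initialises at the transform of the
prior's ancestral-median draw with diagonal scale 0.1 and zero factor.
Non-finite particles are skipped with a logged warning; NaN guide
parameters abort with a diagnostic naming the worst-fitting sample
window. Library defaults mirror a publication-scale fit (15 ELBO
particles, 80,000 iterations, lr 1e-3 → 1e-4). Two optional warm starts
are provided: `moment_match_init` (per-window least squares of the
glucose balance) and `map_init` (L-BFGS to the posterior mode); both land
somewhere on the identifiability ridge discussed below, so they change
*where* on the ridge the guide settles rather than how well the data are
fit.

Posterior-predictive replay holds events, insulin and heart rate fixed.
"Intraday" resampling redraws SIA and SIφ from each draw's own fitted
sample-level conditional (new within-day variability); "interday"
additionally redraws SIE and then EGP through the linkage (a new day for
the patient).

## Data pipeline

Candidate 24 h windows are placed greedily left-to-right with a minimum
stride (default 5 h) inside the CGM span; windows are half-open
[start, start+24 h). The five screening rules: (1) any CGM inter-reading
interval > 12 min fails (exactly 12 min passes); (2) any absolute jump
between consecutive readings ≥ 45 mg/dL fails; (3) ≥ 2 meals; (4) ≥ 1
fast-acting bolus; (5) ≥ 30% of 5-min bins contain a heart-rate reading.
The most recent long-acting injection in the preceding 24 h becomes the
constant basal rate (none → 0 with a warning). The resting heart rate
defaults to the patient's 5th HR percentile. Timestamps are
timezone-naive local; the sinusoid's midnight anchor uses the calendar
date of the window start.

## Synthetic cohorts

The generator emulates a free-living MDI cohort: 2–4 meals/day in
breakfast/lunch/dinner windows (07–09, 12–14, 18–21 h, mean ≈ 2.7/day),
boluses paired with ~70% of meals at 1 U per 10 g ± 20%, exercise on ~33%
of days (20–60 min, +40–80 bpm), one long-acting injection per day, CGM
at 5-min cadence. Latents are drawn from the hierarchical prior, so
recovery checks compare against a fair draw from the model; a per-sample
config override for the CGM noise sd writes the chosen value back into
the latent vector to keep truth and data consistent.

What the generator does *not* emulate: CGM noise is white Gaussian
(real sensor noise is autocorrelated and drifts), days are simulated
independently (so glucose is discontinuous at midnight unless windows are
day-aligned), schedules are stylised, and no events go unreported.
Passing recovery tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to real-data
misspecification. Two construction details serve test exactness: a
window's noise is redrawn (bounded retries) if white noise fabricates a
≥ 45 mg/dL jump that the discontinuity filter would catch, and a sample's
latent subtree is redrawn (bounded retries) if the simulated day leaves
(25, 550) mg/dL; the manifest records per-window designed pass/fail by
construction-time arithmetic.

## Scaled-down study conditions

The parameter-recovery configuration used in the tests: 2 patients × 4
samples, CGM noise sd 10 mg/dL, likelihood on a 5-min grid, 2,000 SVI
iterations with 2 ELBO particles, learning rate 0.02 decaying to 2e-3,
fixed seeds. Sizes were chosen so a single-CPU run finishes in roughly
ten minutes; the larger learning rate compensates for the short schedule
(the publication-scale defaults remain the library defaults). Prediction
scenarios in tests use origins every 120 min (the library default is
30 min) for the same reason.

## Identifiability of the glucose balance

The glucose equation clears glucose through two channels — insulin-
independent (GEZI·G) and insulin-driven (X·G) — and produces it through
EGP. A single CGM stream constrains their *balance* tightly but the split
only weakly: raising SIE while lowering GEZI and raising EGP changes the
simulated trace very little, especially once event-level report
coefficients and initial insulin on board can flex. Profile scans on
synthetic data show the likelihood is sharply peaked at the generating
values along any *single* coordinate, yet a joint mode-finding run can
exceed the truth's likelihood with GEZI near its prior centre and
(SIE, EGP) scaled up by tens of percent — the posterior forms a long
ridge through (GEZI, SIE, EGP), and where its mass sits depends on the
GEZI prior as much as on the data. Consistent with this, glucose
effectiveness is reported to collapse to its lower bound for most real
patients rather than being independently resolved. Practical
consequences: point recovery of SIE from a handful of days is accurate
only up to this ridge (~±30% at four days per patient and 10 mg/dL CGM
noise), variational fits started on different sides of the ridge settle
on different sides of the truth, and credible intervals from a unimodal
low-rank Gaussian guide understate the ridge's width.

## Known limitations

- The low-rank Gaussian guide is unimodal; multimodal posteriors (e.g.
  phase latents) are summarised by one mode, and variational credible
  intervals are typically somewhat narrow.
- The (GEZI, SIE, EGP) ridge above is the dominant error mode for
  parameter point-recovery at small per-patient sample counts; the
  hierarchy and the EGP–SI linkage regularise but do not remove it.
- Finite-difference gradients make an iteration's cost linear in the
  number of sites per window; very event-dense windows fit slower.
- Plasma vs interstitial/tissue glucose pools, ketone dynamics, glycogen
  depletion and exercise-intensity classes are out of scope; physical
  activity is a two-exponential insulin-sensitivity perturbation only.
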