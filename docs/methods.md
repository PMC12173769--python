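# Methods

## Circuit model

Five populations are modeled with firing-rate dynamics, state order
(LA, BAf, BAe, CeAOn, CeAOff), all activities normalized to [0, 1]:

    tau dU/dt = F(net) - U,    F(x) = 1 / (1 + exp(-Ex (x - Th)))

with net inputs

    LA:     -W_LA_inhib·U_LA + W_Thal_LA·I_Thal + Dr_LA
    BAf:    -W_BA_inhib·U_BAe + W_LA_BAf·U_LA + W_Hip_BAf·I_Hip + Dr_BA
    BAe:    -W_BA_inhib·U_BAf + W_PFC_BAe·I_PFC + Dr_BA
    CeAOn:   W_BAf_CeA·U_BAf + W_LA_CeA·U_LA - W_CeA_inhib·U_Off + Dr_CeA
    CeAOff:  W_BAe_CeA·U_BAe - W_CeA_inhib·U_On + Dr_CeA

The shared response function has gain `Ex = 10` and threshold `Th = 0.5`
(one unit of net input corresponds to roughly 100 pA at this calibration).
`tau = 0.05 s`.  Mutual inhibition between the BA projection groups stands
in for interneuron-mediated competition; no spiking, conductances or
explicit interneurons are modeled.

Fixed weights (naive condition): `W_LA_BAf = 0.49`, `W_BA_inhib = 0.13`,
`W_LA_inhib = 1.0`, `W_BAf_CeA = W_LA_CeA = 0.65` (one shared constant —
the electrophysiological data do not separate the LA and BAf afferents to
CeAOn), `W_BAe_CeA = 0.98`, `W_CeA_inhib = 1.5`, all drives 0.

Condition overlays (all other values unchanged, applied for the whole
session):

| condition | substitutions |
|---|---|
| acute   | `W_BA_inhib = 0.25`, `W_LA_inhib = 1.5`, `W_BAf_CeA = W_LA_CeA = 0.4`, `W_BAe_CeA = 0.6`, `W_CeA_inhib = 2.5` |
| chronic | `W_CeA_inhib = 2.5`, `Dr_CeA = -0.5`, `W_LA_BAf = 0.6` |

Because the BLA→CeAOn weight is a single shared calibration constant, the
acute reduction of CeA glutamatergic transmission applies to both the BAf
and LA afferents.  This matters dynamically: if only the BAf afferent were
reduced, the LA alone would keep CeAOn's net input above threshold
throughout extinction and the acute fear state would be inescapable.

## Noise model

Each population receives additive Gaussian background noise with mean 0.03
and amplitude 0.1 (normalized activity units).  We inject it at the
activity level: the mean acts as a tonic background current integrated with
the relaxation (stationary elevation of every population by 0.03), and the
amplitude is a per-step diffusion increment added to the rate, anchored at
the 15 ms reference step and scaled with sqrt(dt) so that ensemble behavior
is insensitive to the integration step.  States are clamped to [0, 1] after
every Euler step; the clamp rectifies negative noise excursions, which
raises the effective baseline of near-silent populations to ~0.1.

This injection site is a deliberate modeling choice.  The alternative —
perturbing the argument of F — leaves baseline activity at
E[F(N(0.03, 0.1))] ≈ 0.019, which is too little Hebbian bootstrap: the
thalamic→LA pathway then never potentiates appreciably (acquisition is
carried entirely by the context pathway), there is no fear recall after the
rest period, and extinction is trivially instantaneous.  Activity-level
noise reproduces the full qualitative course: slow initial weight growth, a
sudden acquisition switch, context-limited recall, and extinction by
competitive takeover.  The rectified baseline is simultaneously the model's
learning bootstrap and a brake on the alcohol conditions (see Limitations).

`NoiseSpec(sd=0)` keeps the deterministic tonic drift (a reproducible,
still-learning-capable control); `enabled=False` removes the noise term
entirely (the classical noise-free circuit, used for fixed-point oracles).
Draws are independent per population and per step, one seeded generator per
session.

## Plasticity

Prediction error `ERR = US - U_CeAOn(readout)`, with the readout taken as
the mean CeAOn activity over the final 10 integration steps of the 15 s
stimulus period (the network's prediction "after 15 seconds"; the short
terminal window suppresses single-step noise).  Weight updates are applied
once per trial:

    fear pathways       dW = ERR · US · α · I_pre · U_post
    extinction pathway  dW = -ERR · α · I_PFC · U_BAe

with `α = 1`.  Postsynaptic rates use the same terminal readout window as
the prediction; presynaptic rates are the trial's input levels (all active
inputs are 1.0 — input magnitude and weight are redundant at equilibrium,
so the calibration lives entirely in the weights).  Terminal rather than
trial-averaged postsynaptic rates keep the LA potentiating during the
post-criterion acquisition trials, when its activity is still rising within
each trial.  Weights start at 0, are floored at 0 after each update, and
have no upper bound (saturation is provided by F).  There is no depression
rule: during extinction (US = 0) the fear-pathway weights are exactly
constant, and suppression of the fear response comes from potentiating the
competing mPFC→BAe pathway.

## Protocol and criteria

Default session: 15 acquisition trials (I_Thal = I_Hip = 1, US = 1), 10
rest trials (all inputs 0, plasticity off), 35 extinction trials
(I_Thal = I_PFC = 1, I_Hip = 0, US = 0).  Trials are 1000 steps of 15 ms
plus a 500-step intertrial relaxation with inputs off and noise on.  The
context change between phases is modeled by silencing the hippocampal input
during extinction; trial 25 therefore acts as fear recall in a new context.

Trials-to-criterion:

* acquisition — 1-based count of acquisition trials until the
  stimulus-period mean CeAOn first reaches 0.5 (the response midpoint);
* extinction — extinction trials elapsed from the recall trial until the
  stimulus-period mean CeAOn first falls to 0.2.

The two thresholds are the model's only free calibration constants.  They
were fixed once against the naive condition (100-session means 5.80 and
9.12, each within two published SDs of the reference statistics) and are
held identical across all conditions.  A "near zero" extinction threshold
of 0.1 is unreachable here because the tonic-plus-rectified noise floor of
CeAOn activity is itself ~0.1; 0.2 is the unique value that both clears
that floor and stays below the naive recall plateau (~0.25).

Ensembles run sessions with consecutive seeds (base, base+1, ...); sessions
that never reach a criterion are excluded from that criterion's mean and
reported as a failure fraction.  Post-criterion extinction trials whose mean
CeAOn re-crosses 0.5 are tallied separately as reactivation events.  The
integrator is vectorized across sessions, so a 100-session ensemble costs
about as much as a single session (~3 s on one CPU); each session's noise
stream is identical to its standalone run.

## Reduced CeA subsystem

Freezing the BLA rates at late-extinction levels reduces the circuit to the
mutually inhibiting CeAOn/CeAOff pair.  Nullcline intersections are located
by sign-change bracketing of the composed scalar map on a 2001-point grid
plus Brent refinement; stability comes from the eigenvalues of the 2×2
Jacobian (eigenvalues (-1 ± w²·F'_on·F'_off)/tau-scaled; a zero real part is
reported as unstable).  Frozen rates are harvested from a full simulation as
the mean over the last 5 pre-criterion extinction trials.  The
extinction-robustness inequality

    W_CeA_inhib > (W_BAf_CeA·U_BAf + W_LA_CeA·U_LA + Dr_CeA - Th) / U_Off

has right-hand side 0.8 at full activation with the naive weights, leaving a
margin of 0.7 below the naive `W_CeA_inhib = 1.5`.

## Numerical choices

Forward Euler with dt = 15 ms (dt/tau = 0.3; the sigmoid-bounded vector
field is strongly contracting, and halving or doubling dt, or varying the
trial duration between 5 and 60 s, leaves deterministic criteria counts
unchanged).  States are clamped to [0, 1] per step.  Noise-free steady
states are verified against direct root-finding on F(net(U)) - U = 0
(scipy hybrid Powell, tolerance 1e-12); the Euler path agrees to 1e-4.
Initial state is all-zero; the first-trial transient (~20 steps) is
negligible in 1000-step trial averages.  Reduced-system equilibria are
verified against an exhaustive grid scan at 1e-3 resolution.

## What the simulations do and do not emulate

The generator produces the study's synthetic conditions only: fixed trial
structure, binary US, constant unit inputs, and stationary Gaussian
background noise.  It does not emulate renewal, reinstatement or
spontaneous recovery protocols, graded US intensities, within-trial US
timing, habituation, or any fit to animal data; passing tests therefore
certify the circuit mechanism and its statistics under these idealized
conditions, not quantitative agreement with any particular experiment.

## Known limitations

* The rectified noise floor (~0.1) on suppressed populations is multiplied
  by the strengthened CeA inhibition (2.5) in the alcohol conditions.  This
  depresses the CeAOn readout at fear recall (which directly scales the
  extinction learning rate) and the CeAOff baseline (which sets the CeAOn
  plateau during chronic acquisition).  Both alcohol conditions therefore
  reach criterion 1–3 trials later than the naive-calibrated reference
  statistics, while the naive condition and the acute > chronic > naive
  orderings of both phases are reproduced.  Because the same floor is the
  Hebbian bootstrap that the naive statistics require, the two roles cannot
  be separated within this noise description.
* Chronic post-extinction reactivations, defined as trial-mean CeAOn
  re-crossing 0.5, cannot occur here: the chronic fear ceiling during
  extinction is ~0.45 because of the -0.5 tonic CeA drive.  CeAOn
  excursions to 2–3× baseline do occur in chronic sessions and not in
  naive ones — the mechanism is present with a lower amplitude.
* BAf potentiates faster than LA during acquisition (it lacks
  self-inhibition and receives the LA's output on top of the context
  input), so fear memories are more context-weighted than cue-weighted in
  all conditions; the recall contrast (LA at plateau, BAf low) is
  nevertheless robust.
* Session-to-session extinction variability is larger than acquisition
  variability (SD up to ~6 trials in naive ensembles) because the
  extinction switch is a noise-assisted escape in part of the parameter
  range.
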