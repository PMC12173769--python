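# amygsim

Firing-rate model of amygdala circuitry for simulating fear acquisition and
extinction, and how acute and chronic alcohol exposure reshape them.

The package is aimed at computational and behavioral neuroscientists who
want a compact, fully reproducible circuit model linking synaptic-level
alcohol effects (measured in vitro as changes in GABAergic and glutamatergic
transmission) to behavioral-level readouts (trials needed to acquire and to
extinguish a conditioned fear response).

## The model

Five neural populations — lateral amygdala (LA), the fear and extinction
projection groups of the basal amygdala (BAf, BAe), and the pro-fear and
pro-extinction groups of the central amygdala (CeAOn, CeAOff) — evolve by
standard firing-rate dynamics,

    tau dU_i/dt = F(net_i) - U_i,      F(x) = 1 / (1 + exp(-Ex (x - Th))),

with mutual inhibition between BAf/BAe and between CeAOn/CeAOff, LA
self-inhibition, and excitatory projections LA→BAf, LA→CeAOn, BAf→CeAOn,
BAe→CeAOff.  CeAOn is the behavioral output (fear response).  Activities are
normalized to [0, 1]; background noise with mean 0.03 and amplitude 0.1
keeps baseline activity low but nonzero.

Three afferents are plastic, updated once per trial by a prediction-error
(Rescorla–Wagner/Hebbian) rule gated by the shock US:

    ERR = US - U_CeAOn(readout)
    dW_Thal→LA  = ERR · US · α · I_Thal · U_LA        (fear pathway)
    dW_Hip→BAf  = ERR · US · α · I_Hip  · U_BAf       (fear pathway)
    dW_PFC→BAe  = -ERR · α · I_PFC · U_BAe            (extinction pathway)

Extinction is new learning through the mPFC→BAe pathway, not depression of
the fear pathways.  A session is 15 acquisition trials (CS + context, shock),
10 home-cage rest trials, and 35 extinction trials (CS in a new context,
mPFC input, no shock); each trial is 15 s (1000 Euler steps of 15 ms) plus a
7.5 s intertrial interval.

Alcohol enters as parameter overlays: acute exposure strengthens GABAergic
inhibition (~50%) and weakens BLA→CeA glutamatergic transmission; chronic
exposure strengthens CeA inhibition, adds a tonic inhibitory CeA drive, and
strengthens LA→BAf.  See `docs/methods.md` for the full parameter table,
the noise model, calibration choices and known limitations.

## Worked example

```python
>>> from amygsim import make_config, run_session, run_ensemble
>>> result = run_session(make_config("naive", seed=0))
>>> result.trials_to_acquisition, result.trials_to_extinction
(6, 14)
>>> rec = result.records[25]   # fear-recall trial in the new context
>>> print(f"LA={rec.u_la:.2f} BAf={rec.u_baf:.2f} CeAOn={rec.u_on:.2f}")
LA=0.54 BAf=0.14 CeAOn=0.26
```

This naive session acquires the fear response (trial-averaged CeAOn ≥ 0.5)
on the 6th pairing and extinguishes (CeAOn ≤ 0.2) 14 extinction trials after
recall.  At the recall trial LA is still at its acquisition plateau — the
CS-driven fear memory persists — while BAf is low because the hippocampal
context input changed.

Ensemble statistics over 100 noise-perturbed sessions:

```python
>>> s = run_ensemble(make_config("naive", seed=0), n_sessions=100)
>>> print(f"acq {s.acq_mean:.2f}±{s.acq_sd:.2f}  ext {s.ext_mean:.2f}±{s.ext_sd:.2f}")
acq 5.80±0.79  ext 9.12±6.01
```

The same comparison across all three conditions, from the shell:

```bash
amygsim compare --n 100 --seed 0 --out figure_stats.csv
amygsim simulate --condition chronic --seed 0 --out runs/
amygsim phaseplane --condition naive --out naive_pp.csv
```

Acquisition and extinction both take systematically more trials under the
acute and chronic overlays than in the naive condition, and the phase-plane
command shows why: alcohol shifts the reduced CeAOn/CeAOff subsystem's
extinction equilibrium from a deep attractor (CeAOff ≈ 0.98 in naive) to a
shallow one that noise can visibly perturb.

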