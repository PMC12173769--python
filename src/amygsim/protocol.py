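"""Fear-conditioning session protocol: schedule construction, trial and
session execution, condition overlays, and trials-to-criterion statistics.

A default session has 60 trials: 15 acquisition trials (CS + context on,
shock delivered), 10 home-cage rest trials (no inputs, no plasticity), and
35 extinction trials (CS on in a new context, mPFC input on, no shock).
Each trial integrates the circuit for the 15-s stimulus period, reads out
the CeAOn fear prediction, applies the trial-end weight updates, then
relaxes through a 7.5-s intertrial interval with inputs off.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import circuit
from .circuit import CircuitState, InputVector
from .params import (CONDITIONS, CircuitParams, ConditionOverlay,
                     IntegrationSpec, LearningParams, NoiseSpec,
                     apply_overrides)
from .plasticity import PlasticWeights, prediction_error, trial_increments

PHASES = ("acquisition", "rest", "extinction")

ACQUISITION_INPUTS = InputVector(i_thal=1.0, i_hip=1.0, i_pfc=0.0, us=1)
REST_INPUTS = InputVector(i_thal=0.0, i_hip=0.0, i_pfc=0.0, us=0)
EXTINCTION_INPUTS = InputVector(i_thal=1.0, i_hip=0.0, i_pfc=1.0, us=0)

#: Number of terminal stimulus-period steps averaged for the CeAOn readout
#: that enters the prediction error.
READOUT_STEPS = 10

#: Criterion thresholds on the stimulus-period mean CeAOn activity.  The
#: acquisition threshold is the response-function midpoint; the extinction
#: threshold is "near zero" relative to the tonic background activity level.
#: Both were fixed once against the naive condition and are held identical
#: across all conditions.
ACQ_THRESHOLD = 0.5
EXT_THRESHOLD = 0.2


@dataclass(frozen=True)
class TrialSpec:
    """Inputs and durations for one trial."""

    phase: str
    inputs: InputVector
    stimulus_steps: int
    intertrial_steps: int
    plasticity_on: bool

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to run one session reproducibly."""

    condition: str = "naive"
    n_acq: int = 15
    n_rest: int = 10
    n_ext: int = 35
    params: CircuitParams = field(default_factory=CircuitParams)
    learning: LearningParams = field(default_factory=LearningParams)
    integration: IntegrationSpec = field(default_factory=IntegrationSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    acq_threshold: float = ACQ_THRESHOLD
    ext_threshold: float = EXT_THRESHOLD
    initial_weights: PlasticWeights = field(default_factory=PlasticWeights)

    def __post_init__(self) -> None:
        if min(self.n_acq, self.n_rest, self.n_ext) < 0:
            raise ValueError("trial counts must be non-negative")
        for name in ("acq_threshold", "ext_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @property
    def n_trials(self) -> int:
        return self.n_acq + self.n_rest + self.n_ext

    @property
    def extinction_start(self) -> int:
        return self.n_acq + self.n_rest

    def replace(self, **changes) -> "SessionConfig":
        return dataclasses.replace(self, **changes)


def make_config(condition: str = "naive", seed: int = 0,
                base_params: CircuitParams | None = None,
                **changes) -> SessionConfig:
    """Build a SessionConfig for a named condition (naive/acute/chronic),
    applying the condition's parameter overlay to the naive defaults."""
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; expected one of {sorted(CONDITIONS)}")
    params = apply_condition(base_params or CircuitParams(), CONDITIONS[condition])
    return SessionConfig(condition=condition, params=params, seed=seed, **changes)


def apply_condition(base: CircuitParams, overlay: ConditionOverlay | str) -> CircuitParams:
    """Return ``base`` with exactly the overlay's substitutions applied; the
    overlay stays in force for the whole session (both phases)."""
    if isinstance(overlay, str):
        overlay = CONDITIONS[overlay]
    return apply_overrides(base, overlay.overrides)


@dataclass(frozen=True)
class TrialRecord:
    """Stimulus-period summaries of one trial, after the weight update."""

    index: int
    phase: str
    u_la: float
    u_baf: float
    u_bae: float
    u_on: float
    u_off: float
    readout: float
    error: float
    weights: PlasticWeights

    def mean_state(self) -> np.ndarray:
        return np.array([self.u_la, self.u_baf, self.u_bae, self.u_on, self.u_off])


@dataclass(frozen=True)
class SessionResult:
    """Ordered trial records plus the two trials-to-criterion statistics."""

    config: SessionConfig
    records: tuple[TrialRecord, ...]
    trials_to_acquisition: int | None
    trials_to_extinction: int | None

    def phase_records(self, phase: str) -> tuple[TrialRecord, ...]:
        return tuple(r for r in self.records if r.phase == phase)


def build_schedule(config: SessionConfig) -> list[TrialSpec]:
    """Ordered trial specifications for one session.

    Rest trials carry no inputs and no plasticity; the hippocampal context is
    on only during acquisition and the mPFC input only during extinction (the
    context changes between phases).
    """
    integ = config.integration
    def spec(phase, inputs, plastic_on):
        return TrialSpec(phase, inputs, integ.steps_trial, integ.steps_intertrial, plastic_on)

    return ([spec("acquisition", ACQUISITION_INPUTS, True)] * config.n_acq
            + [spec("rest", REST_INPUTS, False)] * config.n_rest
            + [spec("extinction", EXTINCTION_INPUTS, True)] * config.n_ext)


def _run_trial_batch(u, w, spec: TrialSpec, config: SessionConfig, rngs):
    """Advance a batch of sessions through one trial.

    ``u``: (n, 5) states; ``w``: (n, 3) plastic weights.  Returns the new
    state, new weights and the per-session stimulus means, readouts and
    errors.
    """
    params = config.params
    integ = config.integration
    a = integ.dt / params.tau
    A = circuit.connectivity_matrix(params)
    inp = spec.inputs

    bias = np.empty_like(u)
    bias[:, 0] = w[:, 0] * inp.i_thal + params.dr_la
    bias[:, 1] = w[:, 1] * inp.i_hip + params.dr_ba
    bias[:, 2] = w[:, 2] * inp.i_pfc + params.dr_ba
    bias[:, 3] = params.dr_cea
    bias[:, 4] = params.dr_cea

    tonic = circuit.tonic_drift(config.noise)
    eta = circuit._batch_noise(config.noise, integ.dt, spec.stimulus_steps, rngs)
    u, means, tail = circuit._integrate_batch(
        u, A, bias, params.response, a, spec.stimulus_steps, eta,
        config.noise.where, tonic=tonic, tail=READOUT_STEPS)

    readout = np.clip(tail[:, 3], 0.0, 1.0)
    err = prediction_error(np.full(len(u), inp.us), readout)
    err = np.atleast_1d(err)

    if spec.plasticity_on and config.learning.alpha > 0:
        inc = trial_increments(err, inp.us, config.learning.alpha, inp,
                               tail[:, 0], tail[:, 1], tail[:, 2])
        w = np.maximum(w + inc, 0.0)

    if spec.intertrial_steps > 0:
        rest_bias = np.zeros_like(u)
        rest_bias[:, 0] = params.dr_la
        rest_bias[:, 1] = params.dr_ba
        rest_bias[:, 2] = params.dr_ba
        rest_bias[:, 3] = params.dr_cea
        rest_bias[:, 4] = params.dr_cea
        eta = circuit._batch_noise(config.noise, integ.dt, spec.intertrial_steps, rngs)
        u, _, _ = circuit._integrate_batch(
            u, A, rest_bias, params.response, a, spec.intertrial_steps, eta,
            config.noise.where, tonic=tonic, tail=1)

    return u, w, means, readout, err


def run_trial(state: CircuitState, weights: PlasticWeights, spec: TrialSpec,
              config: SessionConfig, rng: np.random.Generator):
    """Run one trial for a single session; returns the post-intertrial state,
    the updated weights and the TrialRecord (index is left at -1)."""
    u = state.as_array()[None, :]
    w = weights.as_array()[None, :]
    u, w, means, readout, err = _run_trial_batch(u, w, spec, config, [rng])
    new_weights = PlasticWeights.from_array(w[0])
    record = TrialRecord(-1, spec.phase, *map(float, means[0]),
                         float(readout[0]), float(err[0]), new_weights)
    return CircuitState.from_array(u[0]), new_weights, record


def run_sessions_batch(config: SessionConfig, seeds: Sequence[int]) -> list[SessionResult]:
    """Run independent sessions (one RNG stream per seed) in lockstep.

    Vectorizing across sessions makes a 100-session ensemble nearly as cheap
    as a single session while keeping each session's noise stream identical
    to what ``run_session`` with that seed would draw.
    """
    n = len(seeds)
    rngs = [np.random.default_rng(int(s)) for s in seeds]
    u = np.zeros((n, 5))
    w = np.tile(config.initial_weights.as_array(), (n, 1))
    schedule = build_schedule(config)

    all_means = np.empty((len(schedule), n, 5))
    all_readout = np.empty((len(schedule), n))
    all_err = np.empty((len(schedule), n))
    all_w = np.empty((len(schedule), n, 3))
    for i, spec in enumerate(schedule):
        u, w, means, readout, err = _run_trial_batch(u, w, spec, config, rngs)
        all_means[i] = means
        all_readout[i] = readout
        all_err[i] = err
        all_w[i] = w

    results = []
    for s in range(n):
        records = tuple(
            TrialRecord(i, schedule[i].phase, *map(float, all_means[i, s]),
                        float(all_readout[i, s]), float(all_err[i, s]),
                        PlasticWeights.from_array(all_w[i, s]))
            for i in range(len(schedule)))
        cfg = config.replace(seed=int(seeds[s]))
        result = SessionResult(cfg, records, None, None)
        result = dataclasses.replace(
            result,
            trials_to_acquisition=trials_to_acquisition(result, config.acq_threshold),
            trials_to_extinction=trials_to_extinction(result, config.ext_threshold))
        results.append(result)
    return results


def run_session(config: SessionConfig) -> SessionResult:
    """Run one full session with the config's seed."""
    return run_sessions_batch(config, [config.seed])[0]


def trials_to_acquisition(result: SessionResult, threshold: float | None = None) -> int | None:
    """1-based count of acquisition trials until the stimulus-period mean
    CeAOn activity first reaches ``threshold``; None if never reached."""
    thr = result.config.acq_threshold if threshold is None else threshold
    if not 0.0 < thr < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    for pos, rec in enumerate(result.phase_records("acquisition")):
        if rec.u_on >= thr:
            return pos + 1
    return None


def trials_to_extinction(result: SessionResult, threshold: float | None = None) -> int | None:
    """Extinction trials elapsed (from the recall trial, which counts as the
    first extinction trial) until the stimulus-period mean CeAOn activity
    first falls to ``threshold``; None if never reached."""
    thr = result.config.ext_threshold if threshold is None else threshold
    if not 0.0 < thr < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    for pos, rec in enumerate(result.phase_records("extinction")):
        if rec.u_on <= thr:
            return pos
    return None


def reactivation_count(result: SessionResult, threshold: float | None = None) -> int:
    """Number of post-criterion extinction trials whose mean CeAOn activity
    rises back above the fear threshold (spontaneous fear reactivation)."""
    thr = result.config.acq_threshold if threshold is None else threshold
    reached = trials_to_extinction(result)
    if reached is None:
        return 0
    ext = result.phase_records("extinction")
    return sum(1 for rec in ext[reached + 1:] if rec.u_on > thr)
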