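"""State, vector field and noisy Euler integrator for the five-population
amygdala circuit (LA, BAf, BAe, CeAOn, CeAOff).

Each population obeys  dU/dt = (F(net input) - U) / tau  with the shared
sigmoidal response F.  Net inputs implement the circuit wiring: LA
self-inhibits and receives the thalamic CS; BAf and BAe mutually inhibit,
with BAf driven by LA and the hippocampal context and BAe by the mPFC;
CeAOn and CeAOff mutually inhibit, with CeAOn excited by LA and BAf and
CeAOff by BAe.  All activities are normalized to [0, 1].
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import CircuitParams, IntegrationSpec, NoiseSpec, ResponseParams
from .plasticity import PlasticWeights

#: State component order used throughout the package.
STATE_VARS = ("u_la", "u_baf", "u_bae", "u_on", "u_off")


@dataclass(frozen=True)
class CircuitState:
    """Instantaneous normalized firing rates of the five populations."""

    u_la: float = 0.0
    u_baf: float = 0.0
    u_bae: float = 0.0
    u_on: float = 0.0
    u_off: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_VARS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CircuitState":
        a = np.asarray(arr, dtype=float)
        return cls(*(float(x) for x in a))


@dataclass(frozen=True)
class InputVector:
    """External inputs for one trial: thalamic CS, hippocampal context,
    infralimbic mPFC drive, and the binary aversive stimulus flag."""

    i_thal: float = 0.0
    i_hip: float = 0.0
    i_pfc: float = 0.0
    us: int = 0

    def __post_init__(self) -> None:
        for name in ("i_thal", "i_hip", "i_pfc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.us not in (0, 1):
            raise ValueError(f"us must be 0 or 1, got {self.us}")


ZERO_INPUTS = InputVector()


def response(x, params: ResponseParams):
    """Sigmoidal response F(x) = 1 / (1 + exp(-gain (x - threshold))).

    Strictly increasing, bounded in (0, 1).  Non-finite input is an error.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("response input must be finite")
    out = 1.0 / (1.0 + np.exp(-params.gain * (arr - params.threshold)))
    return float(out) if out.ndim == 0 else out


def connectivity_matrix(params: CircuitParams) -> np.ndarray:
    """5x5 matrix A with net recurrent input A @ u (state order STATE_VARS)."""
    A = np.zeros((5, 5))
    A[0, 0] = -params.w_la_inhib
    A[1, 0] = params.w_la_baf
    A[1, 2] = -params.w_ba_inhib
    A[2, 1] = -params.w_ba_inhib
    A[3, 0] = params.w_la_cea
    A[3, 1] = params.w_baf_cea
    A[3, 4] = -params.w_cea_inhib
    A[4, 2] = params.w_bae_cea
    A[4, 3] = -params.w_cea_inhib
    return A


def input_drive(plastic: PlasticWeights, params: CircuitParams,
                inputs: InputVector) -> np.ndarray:
    """External plus tonic input per population (the non-recurrent part of
    each net input)."""
    return np.array([
        plastic.w_thal_la * inputs.i_thal + params.dr_la,
        plastic.w_hip_baf * inputs.i_hip + params.dr_ba,
        plastic.w_pfc_bae * inputs.i_pfc + params.dr_ba,
        params.dr_cea,
        params.dr_cea,
    ])


def derivatives(state: CircuitState, plastic: PlasticWeights,
                params: CircuitParams, inputs: InputVector,
                eta=0.0) -> np.ndarray:
    """Noise-free (or response-noise-perturbed) rates of change, one per
    population: (F(net + eta) - U) / tau."""
    u = state.as_array()
    net = connectivity_matrix(params) @ u + input_drive(plastic, params, inputs)
    return (response(net + np.asarray(eta, dtype=float), params.response) - u) / params.tau


def step_noise_moments(noise: NoiseSpec, dt: float) -> tuple[float, float]:
    """Per-step random-draw mean and sd at integration step ``dt``.

    Activity-injected noise splits the two stated moments: the mean is a
    tonic background current handled inside the relaxation term (so the
    draws here are zero-mean), while the sd is a diffusion increment whose
    per-step amplitude is anchored at the reference step and scales with
    sqrt(dt).  Response-injected noise perturbs the sigmoid argument with
    the stated moments per step.
    """
    if noise.where == "activity":
        return 0.0, noise.sd * math.sqrt(dt / noise.reference_dt)
    return noise.mean, noise.sd


def tonic_drift(noise: NoiseSpec | None) -> float:
    """Stationary activity elevation contributed by the noise mean (activity
    injection only; the response injection has no such closed-form shift)."""
    if noise is None or not noise.enabled or noise.where != "activity":
        return 0.0
    return noise.mean


def euler_step(state: CircuitState, plastic: PlasticWeights,
               params: CircuitParams, inputs: InputVector,
               integration: IntegrationSpec, noise: NoiseSpec | None = None,
               rng: np.random.Generator | None = None) -> CircuitState:
    """One clamped Euler step.  With noise enabled, an independent Gaussian
    draw per population is injected at the site selected by ``noise.where``;
    the result is clamped to [0, 1]."""
    u = state.as_array()
    a = integration.dt / params.tau
    eta = None
    if noise is not None and noise.enabled:
        if rng is None:
            raise ValueError("an rng is required when noise is enabled")
        m, s = step_noise_moments(noise, integration.dt)
        eta = rng.normal(m, s, 5)
    net = connectivity_matrix(params) @ u + input_drive(plastic, params, inputs)
    if eta is not None and noise.where == "response":
        net = net + eta
    u_new = u + a * (response(net, params.response) + tonic_drift(noise) - u)
    if eta is not None and noise.where == "activity":
        u_new = u_new + eta
    return CircuitState.from_array(np.clip(u_new, 0.0, 1.0))


def settle(state: CircuitState, plastic: PlasticWeights, params: CircuitParams,
           integration: IntegrationSpec, noise: NoiseSpec | None = None,
           rng: np.random.Generator | None = None, n_steps: int = 500) -> CircuitState:
    """Relax with all external inputs off (intertrial interval) for
    ``n_steps`` Euler steps."""
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    for _ in range(n_steps):
        state = euler_step(state, plastic, params, ZERO_INPUTS, integration, noise, rng)
    return state


def fixed_point(plastic: PlasticWeights, params: CircuitParams,
                inputs: InputVector, drift: float = 0.0,
                x0=None) -> CircuitState:
    """Noise-free equilibrium of the full circuit by root-finding on
    F(net(U) ...) - U = 0 (plus the optional tonic activity ``drift`` that a
    nonzero noise mean contributes).

    Independent of the Euler path; used as an oracle for the integrator.
    """
    A = connectivity_matrix(params)
    b = input_drive(plastic, params, inputs)

    def residual(u):
        return response(A @ u + b, params.response) + drift - u

    start = np.full(5, 0.1) if x0 is None else np.asarray(x0, dtype=float)
    sol = optimize.root(residual, start, method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"fixed-point search failed: {sol.message}")
    return CircuitState.from_array(np.clip(sol.x, 0.0, 1.0))


def _batch_noise(noise: NoiseSpec | None, dt: float, steps: int,
                 rngs) -> np.ndarray | None:
    """Stack per-session noise draws into an (n, steps, 5) array, one
    independent stream per session.  Returns None when noise is disabled."""
    if noise is None or not noise.enabled:
        return None
    m, s = step_noise_moments(noise, dt)
    return np.stack([rng.normal(m, s, (steps, 5)) for rng in rngs])


def _integrate_batch(u: np.ndarray, A: np.ndarray, bias: np.ndarray,
                     resp: ResponseParams, a: float, steps: int,
                     eta: np.ndarray | None, where: str,
                     tonic: float = 0.0, tail: int = 10):
    """Clamped Euler integration of a batch of sessions.

    ``u``: (n, 5) states, modified functionally; ``bias``: (n, 5) external
    drive; ``eta``: (n, steps, 5) noise draws or None; ``tonic``: background
    activity current integrated with the relaxation.  Returns the final
    state, the mean activity over all steps and the mean over the last
    ``tail`` steps.
    """
    g, th = resp.gain, resp.threshold
    At = np.ascontiguousarray(A.T)
    total = np.zeros_like(u)
    tail_n = min(tail, steps)
    tail_sum = np.zeros_like(u)
    tail_start = steps - tail_n
    for t in range(steps):
        net = u @ At + bias
        if eta is not None and where == "response":
            net += eta[:, t]
        f = 1.0 / (1.0 + np.exp(-g * (net - th)))
        u = u + a * (f + tonic - u)
        if eta is not None and where == "activity":
            u = u + eta[:, t]
        u = np.clip(u, 0.0, 1.0)
        total += u
        if t >= tail_start:
            tail_sum += u
    return u, total / steps, tail_sum / tail_n
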