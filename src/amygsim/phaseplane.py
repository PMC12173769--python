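"""Reduced two-variable CeA subsystem: nullclines, equilibria, noisy
trajectories and the extinction-robustness inequality.

Freezing the BLA rates (LA, BAf, BAe) at their late-extinction levels
reduces the circuit to the mutually inhibiting CeAOn/CeAOff pair:

    tau dU_On/dt  = F(w_baf_cea U_BAf + w_la_cea U_LA - w_cea_inhib U_Off + dr_cea) - U_On
    tau dU_Off/dt = F(w_bae_cea U_BAe - w_cea_inhib U_On + dr_cea) - U_Off

Intersections of the two nullclines are the equilibria; the depth of the
extinction equilibrium (high CeAOff, low CeAOn) measures how robustly the
circuit holds fear suppression against noise.  Extinction requires the
mutual-inhibition weight to exceed

    (w_baf_cea U_BAf + w_la_cea U_LA + dr_cea - Th) / U_Off

with Th the response threshold; the margin above this right-hand side is the
robustness margin.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import circuit
from .params import CircuitParams, IntegrationSpec, NoiseSpec, ResponseParams
from .protocol import SessionResult, trials_to_extinction

#: Late-extinction BLA rates of the naive condition (u_baf, u_bae, u_la),
#: the worked reference point for the reduced system.
NAIVE_EXTINCTION_RATES = (0.15, 0.9, 0.8)


@dataclass(frozen=True)
class ReducedSystemSpec:
    """Frozen BLA rates plus the CeA-facing weights and drive."""

    u_baf: float
    u_bae: float
    u_la: float
    w_baf_cea: float = 0.65
    w_la_cea: float = 0.65
    w_bae_cea: float = 0.98
    w_cea_inhib: float = 1.5
    dr_cea: float = 0.0
    tau: float = 0.05
    response: ResponseParams = field(default_factory=ResponseParams)

    def __post_init__(self) -> None:
        for name in ("u_baf", "u_bae", "u_la"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_params(cls, params: CircuitParams, u_baf: float, u_bae: float,
                    u_la: float) -> "ReducedSystemSpec":
        return cls(u_baf=u_baf, u_bae=u_bae, u_la=u_la,
                   w_baf_cea=params.w_baf_cea, w_la_cea=params.w_la_cea,
                   w_bae_cea=params.w_bae_cea, w_cea_inhib=params.w_cea_inhib,
                   dr_cea=params.dr_cea, tau=params.tau,
                   response=params.response)

    @property
    def on_drive(self) -> float:
        """Constant excitatory drive to CeAOn from the frozen BLA."""
        return self.w_baf_cea * self.u_baf + self.w_la_cea * self.u_la + self.dr_cea

    @property
    def off_drive(self) -> float:
        """Constant excitatory drive to CeAOff from the frozen BLA."""
        return self.w_bae_cea * self.u_bae + self.dr_cea


@dataclass(frozen=True)
class Equilibrium:
    u_on: float
    u_off: float
    stability: str  # "stable" | "unstable"


def off_nullcline(u_on, spec: ReducedSystemSpec):
    """CeAOff rate at which dU_Off/dt = 0 for a given CeAOn rate; strictly
    decreasing in u_on whenever the mutual inhibition is nonzero."""
    return circuit.response(spec.off_drive - spec.w_cea_inhib * np.asarray(u_on, float),
                            spec.response)


def on_nullcline(u_off, spec: ReducedSystemSpec):
    """CeAOn rate at which dU_On/dt = 0 for a given CeAOff rate."""
    return circuit.response(spec.on_drive - spec.w_cea_inhib * np.asarray(u_off, float),
                            spec.response)


def _composed(u_on, spec):
    return u_on - on_nullcline(off_nullcline(u_on, spec), spec)


def jacobian(spec: ReducedSystemSpec, u_on: float, u_off: float) -> np.ndarray:
    """Jacobian of the noise-free reduced vector field at (u_on, u_off)."""
    g = spec.response.gain
    f_on = on_nullcline(u_off, spec)
    f_off = off_nullcline(u_on, spec)
    d_on = g * f_on * (1.0 - f_on)    # dF/dx at CeAOn's operating point
    d_off = g * f_off * (1.0 - f_off)
    w = spec.w_cea_inhib
    return np.array([[-1.0, -w * d_on],
                     [-w * d_off, -1.0]]) / spec.tau


def find_equilibria(spec: ReducedSystemSpec, grid_points: int = 2001,
                    tol: float = 1e-10) -> list[Equilibrium]:
    """All nullcline intersections, by sign-change bracketing of
    g(u_on) = u_on - on_nullcline(off_nullcline(u_on)) on a fine grid with
    bisection refinement; stability from the Jacobian eigenvalues."""
    grid = np.linspace(0.0, 1.0, grid_points)
    vals = _composed(grid, spec)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(optimize.brentq(lambda x: _composed(x, spec),
                                               grid[i], grid[i + 1], xtol=tol)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    out = []
    for u_on in roots:
        u_off = float(off_nullcline(u_on, spec))
        eig = np.linalg.eigvals(jacobian(spec, u_on, u_off))
        stability = "stable" if np.all(eig.real < 0) else "unstable"
        out.append(Equilibrium(u_on, u_off, stability))
    return out


def simulate_reduced(spec: ReducedSystemSpec, noise: NoiseSpec | None,
                     n_steps: int, seed: int | None = 0,
                     dt: float = 0.015, u0=(0.5, 0.5)) -> np.ndarray:
    """Euler path of the reduced pair with the full model's noise scheme.

    Returns an (n_steps + 1, 2) array of (u_on, u_off) samples, clamped to
    [0, 1]^2.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    a = dt / spec.tau
    rng = np.random.default_rng(seed)
    eta = None
    if noise is not None and noise.enabled:
        m, s = circuit.step_noise_moments(noise, dt)
        eta = rng.normal(m, s, (n_steps, 2))
    tonic = circuit.tonic_drift(noise)
    path = np.empty((n_steps + 1, 2))
    u_on, u_off = float(u0[0]), float(u0[1])
    path[0] = (u_on, u_off)
    for t in range(n_steps):
        net_on = spec.on_drive - spec.w_cea_inhib * u_off
        net_off = spec.off_drive - spec.w_cea_inhib * u_on
        if eta is not None and noise.where == "response":
            net_on += eta[t, 0]
            net_off += eta[t, 1]
        f_on = circuit.response(net_on, spec.response)
        f_off = circuit.response(net_off, spec.response)
        u_on += a * (f_on + tonic - u_on)
        u_off += a * (f_off + tonic - u_off)
        if eta is not None and noise.where == "activity":
            u_on += eta[t, 0]
            u_off += eta[t, 1]
        u_on = min(1.0, max(0.0, u_on))
        u_off = min(1.0, max(0.0, u_off))
        path[t + 1] = (u_on, u_off)
    return path


def robustness_rhs(spec: ReducedSystemSpec, u_baf: float | None = None,
                   u_la: float | None = None,
                   u_off: float | None = None) -> float:
    """Right-hand side of the extinction inequality,
    (w_baf_cea u_baf + w_la_cea u_la + dr_cea - Th) / u_off.

    Extinction holds when the CeA mutual-inhibition weight exceeds this
    value.  A zero CeAOff rate makes extinction unreachable (+inf).
    """
    u_baf = spec.u_baf if u_baf is None else u_baf
    u_la = spec.u_la if u_la is None else u_la
    if u_off is None:
        raise ValueError("u_off must be supplied")
    numerator = (spec.w_baf_cea * u_baf + spec.w_la_cea * u_la
                 + spec.dr_cea - spec.response.threshold)
    if u_off == 0.0:
        return math.inf
    if u_off < 0:
        raise ValueError("u_off must be non-negative")
    return numerator / u_off


def extinction_margin(spec: ReducedSystemSpec, u_baf: float, u_la: float,
                      u_off: float) -> float:
    """w_cea_inhib minus the inequality's right-hand side; positive means
    the extinction regime."""
    return spec.w_cea_inhib - robustness_rhs(spec, u_baf, u_la, u_off)


def harvest_frozen_rates(result: SessionResult, window: int = 5) -> tuple[float, float, float]:
    """(u_baf, u_bae, u_la) averaged over the last ``window`` pre-criterion
    extinction trials of a full-model session (the whole extinction phase if
    the criterion was never reached)."""
    ext = result.phase_records("extinction")
    if not ext:
        raise ValueError("session has no extinction trials")
    reached = trials_to_extinction(result)
    upto = len(ext) if reached is None else max(reached, 1)
    block = ext[max(0, upto - window):upto]
    u_baf = float(np.mean([r.u_baf for r in block]))
    u_bae = float(np.mean([r.u_bae for r in block]))
    u_la = float(np.mean([r.u_la for r in block]))
    return u_baf, u_bae, u_la


def reduced_spec_for_condition(condition: str, seed: int = 0,
                               window: int = 5) -> ReducedSystemSpec:
    """Run one full session of the condition and freeze its late-extinction
    BLA rates into a reduced-system specification."""
    from .protocol import make_config, run_session
    config = make_config(condition, seed=seed)
    result = run_session(config)
    u_baf, u_bae, u_la = harvest_frozen_rates(result, window=window)
    return ReducedSystemSpec.from_params(config.params, u_baf, u_bae, u_la)
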