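"""Parameter containers for the five-population amygdala circuit.

Synaptic weights and drives are in normalized input units (at the calibrated
gain, one unit of net input corresponds to roughly 100 pA of synaptic
current); time constants are in seconds; firing rates are normalized to
[0, 1].
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class ResponseParams:
    """Sigmoidal rate response ``F(x) = 1 / (1 + exp(-gain * (x - threshold)))``.

    ``gain`` sets neural excitability, ``threshold`` the half-activation
    input.  Both are shared by all populations; they are redundant with the
    synaptic weights, so they stay fixed while weights are calibrated.
    """

    gain: float = 10.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")


@dataclass(frozen=True)
class CircuitParams:
    """Fixed synaptic weights, drives and time constant for one condition.

    Defaults are the calibrated naive values.  Weights are non-negative; the
    sign of each connection (excitatory/inhibitory) is hard-wired in the
    vector field, not in the weight.  Drives may be negative (tonic
    inhibition), e.g. the chronic-alcohol CeA drive of -0.5.
    """

    w_la_baf: float = 0.49      # LA -> BAf excitation
    w_ba_inhib: float = 0.13    # BAf <-> BAe mutual inhibition
    w_la_inhib: float = 1.0     # LA self-inhibition
    w_baf_cea: float = 0.65     # BAf -> CeAOn excitation
    w_la_cea: float = 0.65      # LA -> CeAOn excitation
    w_bae_cea: float = 0.98     # BAe -> CeAOff excitation
    w_cea_inhib: float = 1.5    # CeAOn <-> CeAOff mutual inhibition
    dr_ba: float = 0.0
    dr_la: float = 0.0
    dr_cea: float = 0.0
    tau: float = 0.05           # seconds
    response: ResponseParams = field(default_factory=ResponseParams)

    def __post_init__(self) -> None:
        for name in ("w_la_baf", "w_ba_inhib", "w_la_inhib", "w_baf_cea",
                     "w_la_cea", "w_bae_cea", "w_cea_inhib"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    def replace(self, **changes) -> "CircuitParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian background noise injected into every population.

    ``mean``/``sd`` are the per-step statistics at the reference step size
    ``reference_dt``; both are in normalized activity units.  Two injection
    sites are supported:

    * ``"activity"`` (default): the draw is added to the integrated firing
      rate each Euler step.  Draws are rescaled with the step size like a
      drift-diffusion increment (mean proportional to dt, sd proportional to
      sqrt(dt)), so ensemble behavior is insensitive to the integration step.
      The positive mean acts as a tonic background input that keeps baseline
      activity low but nonzero, which is what bootstraps Hebbian learning.
    * ``"response"``: the draw perturbs the argument of the response function
      (per step, unscaled), a purely synaptic reading of the same noise.

    ``enabled=False`` removes the noise term entirely; setting ``sd=0`` keeps
    the deterministic mean drift, which is the right control when a
    reproducible but still learning-capable session is needed.
    """

    mean: float = 0.03
    sd: float = 0.1
    enabled: bool = True
    where: str = "activity"
    reference_dt: float = 0.015

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"noise sd must be non-negative, got {self.sd}")
        if self.where not in ("activity", "response"):
            raise ValueError(f"unknown noise injection site {self.where!r}")
        if not self.reference_dt > 0:
            raise ValueError("reference_dt must be positive")


@dataclass(frozen=True)
class IntegrationSpec:
    """Euler integration settings: 15 ms steps, 1000 per 15-s trial plus a
    7.5-s intertrial relaxation of 500 steps."""

    dt: float = 0.015
    steps_trial: int = 1000
    steps_intertrial: int = 500

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.steps_trial < 1:
            raise ValueError("steps_trial must be at least 1")
        if self.steps_intertrial < 0:
            raise ValueError("steps_intertrial must be non-negative")

    @property
    def trial_duration(self) -> float:
        return self.dt * self.steps_trial


@dataclass(frozen=True)
class LearningParams:
    """Trial-level plasticity rate constant."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")


#: Config-file key -> CircuitParams field.
CIRCUIT_KEYS: Mapping[str, str] = {
    "W_LA_BAf": "w_la_baf",
    "W_BA_inhib": "w_ba_inhib",
    "W_LA_inhib": "w_la_inhib",
    "W_BAf_CeA": "w_baf_cea",
    "W_LA_CeA": "w_la_cea",
    "W_BAe_CeA": "w_bae_cea",
    "W_CeA_inhib": "w_cea_inhib",
    "Dr_BA": "dr_ba",
    "Dr_LA": "dr_la",
    "Dr_CeA": "dr_cea",
    "tau": "tau",
}


def apply_overrides(params: CircuitParams, overrides: Mapping[str, float]) -> CircuitParams:
    """Return ``params`` with the named entries replaced.

    Keys use the external spelling (``W_CeA_inhib``, ``Dr_CeA``, ``tau``,
    ``Ex``, ``Th``).  Unknown keys raise ``KeyError``.
    """
    updates: dict[str, float] = {}
    resp = params.response
    for key, value in overrides.items():
        if key in CIRCUIT_KEYS:
            updates[CIRCUIT_KEYS[key]] = float(value)
        elif key == "Ex":
            resp = dataclasses.replace(resp, gain=float(value))
        elif key == "Th":
            resp = dataclasses.replace(resp, threshold=float(value))
        else:
            raise KeyError(f"unknown circuit parameter {key!r}")
    return dataclasses.replace(params, response=resp, **updates)


@dataclass(frozen=True)
class ConditionOverlay:
    """Named set of parameter substitutions modeling an alcohol condition."""

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)

    def apply(self, base: CircuitParams) -> CircuitParams:
        return apply_overrides(base, self.overrides)


#: Acute alcohol: ~50% stronger GABAergic inhibition in BA, LA and CeA,
#: weaker glutamatergic BLA->CeA transmission.  The LA->CeAOn and BAf->CeAOn
#: weights are one shared calibration constant (the underlying data do not
#: separate the two afferents), so the acute reduction applies to both.
ACUTE_OVERRIDES: Mapping[str, float] = {
    "W_BA_inhib": 0.25,
    "W_LA_inhib": 1.5,
    "W_BAf_CeA": 0.4,
    "W_LA_CeA": 0.4,
    "W_BAe_CeA": 0.6,
    "W_CeA_inhib": 2.5,
}

#: Chronic alcohol: stronger CeA mutual inhibition, tonic CeA inhibition from
#: elevated ambient GABA, and increased LA->BAf glutamatergic drive.
CHRONIC_OVERRIDES: Mapping[str, float] = {
    "W_CeA_inhib": 2.5,
    "Dr_CeA": -0.5,
    "W_LA_BAf": 0.6,
}

CONDITIONS: Mapping[str, ConditionOverlay] = {
    "naive": ConditionOverlay("naive", {}),
    "acute": ConditionOverlay("acute", ACUTE_OVERRIDES),
    "chronic": ConditionOverlay("chronic", CHRONIC_OVERRIDES),
}
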