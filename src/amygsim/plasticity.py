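"""Prediction-error-gated Hebbian plasticity of the three amygdala afferents.

The three plastic synapses are thalamus->LA and hippocampus->BAf (the fear
pathway, potentiated only when the aversive stimulus is delivered) and
mPFC->BAe (the extinction pathway, potentiated when the fear output
over-predicts the stimulus).  Updates are applied once per trial, after the
prediction readout, in the Rescorla-Wagner style:

    fear pathway        dW = ERR * US * alpha * I_pre * U_post
    extinction pathway  dW = -ERR * alpha * I_PFC * U_BAe
    prediction error    ERR = US - U_CeAOn(readout)

There is no depression rule: extinction works by potentiating the competing
pathway, and weights are floored at zero.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PlasticWeights:
    """The three plastic afferent weights (thalamic, hippocampal, mPFC)."""

    w_thal_la: float = 0.0
    w_hip_baf: float = 0.0
    w_pfc_bae: float = 0.0

    def __post_init__(self) -> None:
        for name in ("w_thal_la", "w_hip_baf", "w_pfc_bae"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_thal_la, self.w_hip_baf, self.w_pfc_bae], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PlasticWeights":
        a = np.asarray(arr, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def replace(self, **changes) -> "PlasticWeights":
        return dataclasses.replace(self, **changes)


def prediction_error(us, u_on_readout):
    """``ERR = US - U_CeAOn``: +1 is a fully unexpected shock, -1 a fully
    unexpected omission.  Accepts scalars or arrays."""
    us_arr = np.asarray(us, dtype=float)
    readout = np.asarray(u_on_readout, dtype=float)
    if np.any((us_arr != 0) & (us_arr != 1)):
        raise ValueError("us must be binary (0 or 1)")
    if np.any(readout < 0) or np.any(readout > 1):
        raise ValueError("CeAOn readout must lie in [0, 1]")
    err = us_arr - readout
    if err.ndim == 0:
        return float(err)
    return err


def fear_pathway_update(err, us, alpha, i_pre, u_post):
    """Weight increment for the shock-gated fear afferents (thalamus->LA and
    hippocampus->BAf).  Vanishes without the US and when the postsynaptic
    population is silent (Hebbian gate)."""
    out = np.asarray(err, dtype=float) * np.asarray(us, dtype=float) * alpha \
        * np.asarray(i_pre, dtype=float) * np.asarray(u_post, dtype=float)
    return float(out) if out.ndim == 0 else out


def extinction_pathway_update(err, alpha, i_pfc, u_bae):
    """Weight increment for the mPFC->BAe extinction afferent.  Positive when
    the shock is omitted but the fear output is still active (err < 0)."""
    out = -np.asarray(err, dtype=float) * alpha \
        * np.asarray(i_pfc, dtype=float) * np.asarray(u_bae, dtype=float)
    return float(out) if out.ndim == 0 else out


def trial_increments(err, us, alpha, inputs, u_la, u_baf, u_bae):
    """All three per-trial increments, as an array with the last axis ordered
    (thal->LA, hip->BAf, pfc->BAe).

    ``inputs`` is the trial's InputVector; presynaptic rates are the input
    levels, postsynaptic rates the trial-averaged activities.
    """
    d_thal = fear_pathway_update(err, us, alpha, inputs.i_thal, u_la)
    d_hip = fear_pathway_update(err, us, alpha, inputs.i_hip, u_baf)
    d_pfc = extinction_pathway_update(err, alpha, inputs.i_pfc, u_bae)
    return np.stack(np.broadcast_arrays(
        np.asarray(d_thal, float), np.asarray(d_hip, float), np.asarray(d_pfc, float)
    ), axis=-1)


def apply_updates(weights: PlasticWeights, increments) -> PlasticWeights:
    """Increment each weight and floor at zero."""
    new = np.maximum(weights.as_array() + np.asarray(increments, dtype=float), 0.0)
    return PlasticWeights.from_array(new)
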