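"""Configuration loading and result serialization.

Configs are flat YAML/JSON key-value files using the external parameter
spellings (``W_CeA_inhib``, ``Dr_CeA``, ``tau``, ``alpha``, ``Ex``, ``Th``,
``noise_mean`` ...); unspecified keys fall back to the calibrated naive
defaults, unknown keys are rejected.  Results are written as a trial-by-trial
CSV, a JSON summary and a JSON run manifest sufficient to reproduce the run
bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .montecarlo import EnsembleSummary
from .params import (CIRCUIT_KEYS, CircuitParams, IntegrationSpec,
                     LearningParams, NoiseSpec, apply_overrides)
from .plasticity import PlasticWeights
from .protocol import SessionConfig, SessionResult, apply_condition, make_config

SCHEMA_VERSION = 1

#: CSV column layout for trial records.
TRIAL_COLUMNS = ["trial", "phase", "U_LA", "U_BAf", "U_BAe", "U_CeAOn",
                 "U_CeAOff", "W_Thal_LA", "W_Hip_BAf", "W_PFC_BAe", "ERR"]

_NOISE_KEYS = {"noise_mean": "mean", "noise_sd": "sd", "noise_enabled": "enabled",
               "noise_where": "where"}
_INTEGRATION_KEYS = {"dt": "dt", "steps_trial": "steps_trial",
                     "steps_intertrial": "steps_intertrial"}
_SESSION_KEYS = {"condition", "n_acq", "n_rest", "n_ext", "seed",
                 "acq_threshold", "ext_threshold"}
_WEIGHT_KEYS = {"W_Thal_LA_init": "w_thal_la", "W_Hip_BAf_init": "w_hip_baf",
                "W_PFC_BAe_init": "w_pfc_bae"}


def config_from_mapping(data: Mapping[str, Any]) -> SessionConfig:
    """Build a SessionConfig from a flat mapping; unknown keys raise."""
    data = dict(data)
    condition = str(data.pop("condition", "naive"))
    session_kwargs: dict[str, Any] = {}
    for key in list(data):
        if key in _SESSION_KEYS:
            session_kwargs[key] = data.pop(key)

    circuit_overrides = {k: data.pop(k) for k in list(data)
                         if k in CIRCUIT_KEYS or k in ("Ex", "Th")}
    noise_kwargs = {_NOISE_KEYS[k]: data.pop(k) for k in list(data) if k in _NOISE_KEYS}
    integ_kwargs = {_INTEGRATION_KEYS[k]: data.pop(k) for k in list(data)
                    if k in _INTEGRATION_KEYS}
    weight_kwargs = {_WEIGHT_KEYS[k]: data.pop(k) for k in list(data) if k in _WEIGHT_KEYS}
    alpha = data.pop("alpha", None)
    if data:
        raise KeyError(f"unknown config keys: {sorted(data)}")

    config = make_config(condition, **session_kwargs)
    if circuit_overrides:
        config = config.replace(params=apply_overrides(config.params, circuit_overrides))
    if noise_kwargs:
        config = config.replace(noise=dataclasses.replace(config.noise, **noise_kwargs))
    if integ_kwargs:
        config = config.replace(integration=dataclasses.replace(config.integration,
                                                                **integ_kwargs))
    if weight_kwargs:
        config = config.replace(
            initial_weights=dataclasses.replace(config.initial_weights, **weight_kwargs))
    if alpha is not None:
        config = config.replace(learning=LearningParams(alpha=float(alpha)))
    return config


def load_config(path: str | Path) -> SessionConfig:
    """Load a session configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_mapping(data)


def config_to_mapping(config: SessionConfig) -> dict[str, Any]:
    """Flat external-key snapshot of a SessionConfig (inverse of
    config_from_mapping up to defaults)."""
    p = config.params
    out: dict[str, Any] = {"condition": config.condition}
    for ext_key, attr in CIRCUIT_KEYS.items():
        out[ext_key] = getattr(p, attr)
    out["Ex"] = p.response.gain
    out["Th"] = p.response.threshold
    out["alpha"] = config.learning.alpha
    out["noise_mean"] = config.noise.mean
    out["noise_sd"] = config.noise.sd
    out["noise_enabled"] = config.noise.enabled
    out["noise_where"] = config.noise.where
    out["dt"] = config.integration.dt
    out["steps_trial"] = config.integration.steps_trial
    out["steps_intertrial"] = config.integration.steps_intertrial
    out.update({
        "n_acq": config.n_acq, "n_rest": config.n_rest, "n_ext": config.n_ext,
        "seed": config.seed, "acq_threshold": config.acq_threshold,
        "ext_threshold": config.ext_threshold,
        "W_Thal_LA_init": config.initial_weights.w_thal_la,
        "W_Hip_BAf_init": config.initial_weights.w_hip_baf,
        "W_PFC_BAe_init": config.initial_weights.w_pfc_bae,
    })
    return out


def session_frame(result: SessionResult) -> pd.DataFrame:
    """Trial-by-trial table of one session (TRIAL_COLUMNS layout)."""
    rows = []
    for rec in result.records:
        rows.append({
            "trial": rec.index, "phase": rec.phase,
            "U_LA": rec.u_la, "U_BAf": rec.u_baf, "U_BAe": rec.u_bae,
            "U_CeAOn": rec.u_on, "U_CeAOff": rec.u_off,
            "W_Thal_LA": rec.weights.w_thal_la,
            "W_Hip_BAf": rec.weights.w_hip_baf,
            "W_PFC_BAe": rec.weights.w_pfc_bae,
            "ERR": rec.error,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def run_manifest(config: SessionConfig, command: str = "",
                 arguments: Mapping[str, Any] | None = None) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "package": "amygsim",
        "version": __version__,
        "command": command,
        "arguments": dict(arguments or {}),
        "config": config_to_mapping(config),
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_session(result: SessionResult, out_dir: str | Path,
                  stem: str = "session", command: str = "",
                  arguments: Mapping[str, Any] | None = None) -> dict[str, Path]:
    """Write trial CSV + criteria JSON + manifest for one session."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    session_frame(result).to_csv(csv_path, index=False)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "condition": result.config.condition,
        "seed": result.config.seed,
        "trials_to_acquisition": result.trials_to_acquisition,
        "trials_to_extinction": result.trials_to_extinction,
    }
    summary_path = out_dir / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    manifest_path = out_dir / f"{stem}_manifest.json"
    manifest_path.write_text(json.dumps(run_manifest(result.config, command, arguments),
                                        indent=2))
    return {"csv": csv_path, "summary": summary_path, "manifest": manifest_path}


def write_summary(summary: EnsembleSummary, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(summary.to_dict())
    path.write_text(json.dumps(payload, indent=2))
    return path
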