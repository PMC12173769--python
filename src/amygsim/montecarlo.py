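"""Session ensembles, condition comparisons and parameter sweeps.

The headline statistics are the mean and SD, over an ensemble of
noise-perturbed sessions, of the number of trials to the fear-acquisition
and fear-extinction criteria, per condition.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import CIRCUIT_KEYS, CONDITIONS
from .protocol import (SessionConfig, SessionResult, make_config,
                       reactivation_count, run_sessions_batch)

DEFAULT_N_SESSIONS = 100


@dataclass(frozen=True)
class EnsembleSummary:
    """Trials-to-criterion statistics over independent sessions.

    Means and SDs are computed over the sessions that reached the criterion;
    sessions that never reach it are reported as a failure fraction instead.
    ``reactivation_counts`` tallies, per session, post-criterion extinction
    trials where the fear output re-crossed the fear threshold.
    """

    condition: str
    n_sessions: int
    base_seed: int
    acq_mean: float | None
    acq_sd: float | None
    ext_mean: float | None
    ext_sd: float | None
    acq_failure_fraction: float
    ext_failure_fraction: float
    acq_counts: tuple
    ext_counts: tuple
    reactivation_counts: tuple

    @property
    def reactivation_fraction(self) -> float:
        """Fraction of sessions showing at least one fear reactivation."""
        return float(np.mean([c > 0 for c in self.reactivation_counts]))

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_sessions": self.n_sessions,
            "base_seed": self.base_seed,
            "trials_to_acquisition": {"mean": self.acq_mean, "sd": self.acq_sd,
                                      "failure_fraction": self.acq_failure_fraction},
            "trials_to_extinction": {"mean": self.ext_mean, "sd": self.ext_sd,
                                     "failure_fraction": self.ext_failure_fraction},
            "reactivation": {"counts": list(self.reactivation_counts),
                             "fraction_of_sessions": self.reactivation_fraction},
            "acq_counts": list(self.acq_counts),
            "ext_counts": list(self.ext_counts),
        }


def _criterion_stats(counts: Sequence[int | None]):
    reached = np.array([c for c in counts if c is not None], dtype=float)
    fail = 1.0 - len(reached) / len(counts)
    if len(reached) == 0:
        return None, None, fail
    sd = float(np.std(reached, ddof=1)) if len(reached) > 1 else 0.0
    return float(np.mean(reached)), sd, fail


def summarize_sessions(results: Sequence[SessionResult], condition: str,
                       base_seed: int) -> EnsembleSummary:
    acq = [r.trials_to_acquisition for r in results]
    ext = [r.trials_to_extinction for r in results]
    acq_mean, acq_sd, acq_fail = _criterion_stats(acq)
    ext_mean, ext_sd, ext_fail = _criterion_stats(ext)
    react = tuple(reactivation_count(r) for r in results)
    return EnsembleSummary(condition, len(results), base_seed,
                           acq_mean, acq_sd, ext_mean, ext_sd,
                           acq_fail, ext_fail, tuple(acq), tuple(ext), react)


def run_ensemble(config: SessionConfig, n_sessions: int = DEFAULT_N_SESSIONS,
                 base_seed: int | None = None) -> EnsembleSummary:
    """Run ``n_sessions`` independent sessions seeded base_seed..base_seed+n-1
    and aggregate both criteria."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be at least 1")
    seed0 = config.seed if base_seed is None else int(base_seed)
    results = run_sessions_batch(config, [seed0 + i for i in range(n_sessions)])
    return summarize_sessions(results, config.condition, seed0)


_LEARNING_KEYS = {"alpha": "alpha"}


def _override_config(config: SessionConfig, param: str, value: float) -> SessionConfig:
    from .params import apply_overrides
    if param in CIRCUIT_KEYS or param in ("Ex", "Th"):
        return config.replace(params=apply_overrides(config.params, {param: value}))
    if param in _LEARNING_KEYS:
        return config.replace(learning=config.learning.__class__(alpha=float(value)))
    raise KeyError(f"unknown sweep parameter {param!r}")


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point ensemble summaries for a one-parameter sweep."""

    param: str
    grid: tuple
    summaries: tuple
    final_activities: tuple  # per grid point: mean last-trial activities (5,)

    def frame(self) -> pd.DataFrame:
        rows = []
        for g, s, act in zip(self.grid, self.summaries, self.final_activities):
            rows.append({
                "param": self.param, "value": g,
                "acq_mean": s.acq_mean, "acq_sd": s.acq_sd,
                "ext_mean": s.ext_mean, "ext_sd": s.ext_sd,
                "acq_failure_fraction": s.acq_failure_fraction,
                "ext_failure_fraction": s.ext_failure_fraction,
                "final_U_LA": act[0], "final_U_BAf": act[1], "final_U_BAe": act[2],
                "final_U_CeAOn": act[3], "final_U_CeAOff": act[4],
            })
        return pd.DataFrame(rows)


def parameter_sweep(config: SessionConfig, param: str, grid: Sequence[float],
                    n_sessions: int = 25, base_seed: int | None = None) -> SweepResult:
    """Ensemble statistics along a one-dimensional parameter grid.

    ``param`` uses the external key spelling (e.g. ``W_CeA_inhib``,
    ``alpha``).  The grid must be strictly monotone.
    """
    grid = tuple(float(g) for g in grid)
    if len(grid) > 1:
        diffs = np.diff(grid)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("grid must be strictly monotone")
    seed0 = config.seed if base_seed is None else int(base_seed)
    summaries, finals = [], []
    for value in grid:
        cfg = _override_config(config, param, value)
        results = run_sessions_batch(cfg, [seed0 + i for i in range(n_sessions)])
        summaries.append(summarize_sessions(results, cfg.condition, seed0))
        finals.append(tuple(np.mean([r.records[-1].mean_state() for r in results], axis=0)))
    return SweepResult(param, grid, tuple(summaries), tuple(finals))


def extinction_phase_activity(results: Sequence[SessionResult]) -> np.ndarray:
    """Mean activities (5,) over all extinction trials and sessions."""
    vals = [rec.mean_state() for r in results for rec in r.phase_records("extinction")]
    return np.mean(vals, axis=0)


def compare_conditions(n_sessions: int = DEFAULT_N_SESSIONS, base_seed: int = 0,
                       conditions: Sequence[str] = ("naive", "acute", "chronic"),
                       **config_kwargs) -> pd.DataFrame:
    """Run matched ensembles for several conditions and tabulate the mean and
    SD of both trials-to-criterion statistics."""
    rows = []
    for name in conditions:
        if name not in CONDITIONS:
            raise KeyError(f"unknown condition {name!r}")
        summary = run_ensemble(make_config(name, seed=base_seed, **config_kwargs),
                               n_sessions=n_sessions, base_seed=base_seed)
        rows.append({
            "condition": name,
            "acq_mean": summary.acq_mean, "acq_sd": summary.acq_sd,
            "ext_mean": summary.ext_mean, "ext_sd": summary.ext_sd,
            "acq_failure_fraction": summary.acq_failure_fraction,
            "ext_failure_fraction": summary.ext_failure_fraction,
            "reactivation_fraction": summary.reactivation_fraction,
        })
    return pd.DataFrame(rows)
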