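"""Trajectory and phase-plane figures.

``plot_session`` renders the standard three-panel session view (BLA
activities, CeA activities, plastic weights) with the rest period shaded and
the recall trial marked; ``plot_phaseplane`` renders the reduced CeA
subsystem's nullclines, equilibria and an exemplar noisy trajectory.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .phaseplane import (ReducedSystemSpec, find_equilibria, off_nullcline,
                         on_nullcline, simulate_reduced)
from .params import NoiseSpec
from .protocol import SessionResult


def plot_session(result: SessionResult, path: str | Path) -> Path:
    """Three stacked panels over trials: LA/BAf/BAe activity, CeAOn/CeAOff
    activity, and the three plastic weights."""
    trials = [r.index for r in result.records]
    cfg = result.config
    rest_lo = cfg.n_acq - 0.5
    rest_hi = cfg.n_acq + cfg.n_rest - 0.5

    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    panels = [
        ("activity", [("LA", "u_la"), ("BAf", "u_baf"), ("BAe", "u_bae")]),
        ("activity", [("CeAOn", "u_on"), ("CeAOff", "u_off")]),
        ("synaptic weight", [("W Thal->LA", None), ("W Hip->BAf", None),
                             ("W PFC->BAe", None)]),
    ]
    for ax, (ylabel, series) in zip(axes, panels):
        if ylabel == "synaptic weight":
            ax.plot(trials, [r.weights.w_thal_la for r in result.records], label="W Thal->LA")
            ax.plot(trials, [r.weights.w_hip_baf for r in result.records], label="W Hip->BAf")
            ax.plot(trials, [r.weights.w_pfc_bae for r in result.records], label="W PFC->BAe")
        else:
            for label, attr in series:
                ax.plot(trials, [getattr(r, attr) for r in result.records], label=label)
        if cfg.n_rest > 0:
            ax.axvspan(rest_lo, rest_hi, color="0.85", zorder=0, label=None)
        if cfg.n_ext > 0:
            ax.axvline(cfg.extinction_start, color="k", linestyle="--", linewidth=1)
        ax.set_ylabel(ylabel)
        ax.legend(loc="best", fontsize=8)
    axes[-1].set_xlabel("trial")
    axes[0].set_title(f"{cfg.condition} session (seed {cfg.seed})")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_phaseplane(spec: ReducedSystemSpec, path: str | Path,
                    noise: NoiseSpec | None = None, n_steps: int = 1000,
                    seed: int = 0) -> Path:
    """Nullclines, equilibria and one noisy trajectory of the reduced CeA
    pair in the (CeAOn, CeAOff) plane."""
    grid = np.linspace(0.0, 1.0, 400)
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.plot(grid, off_nullcline(grid, spec), color="tab:blue",
            label="dU_Off/dt = 0")
    ax.plot(on_nullcline(grid, spec), grid, color="tab:red",
            label="dU_On/dt = 0")
    for eq in find_equilibria(spec):
        marker = "o" if eq.stability == "stable" else "x"
        ax.plot(eq.u_on, eq.u_off, marker, color="k", markersize=8)
    if noise is not None:
        path_arr = simulate_reduced(spec, noise, n_steps, seed=seed)
        ax.plot(path_arr[:, 0], path_arr[:, 1], color="0.6", linewidth=0.6,
                alpha=0.8, label="noisy trajectory")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("U CeAOn")
    ax.set_ylabel("U CeAOff")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
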