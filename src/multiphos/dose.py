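"""Dose-response curves, hysteresis detection, and the LR/MA correspondence.

The dose variable is total kinase K_tot.  A sweep returns, per dose, the
stable and unstable branches of the fully-phosphorylated readout; a
bistable interval is the hull of dose points carrying at least two stable
branches.  The `compare_lr_ma` analysis constructs mass-action twins of a
linear-rate parameter set at increasing Michaelis constants (holding
kcat/K_M at the lumped linear rate) and reports the sup-norm distance
between the two dose-response curves, which shrinks as K_M grows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import ModelConfig, ParameterSet
from .steady import SCREEN_OPTIONS, SolverOptions, sweep_states

logger = logging.getLogger(__name__)

__all__ = ["DoseResponse", "sweep", "compare_lr_ma", "ma_twin"]


@dataclass
class DoseResponse:
    """Readout branches over a K_tot grid."""

    ktot_grid: np.ndarray
    branches: list[list[tuple[float, str]]]    # per dose: (readout, "stable"/"unstable")
    bistable_interval: Optional[tuple[float, float]]
    n_failed_points: int = 0

    def stable_values(self, i: int) -> np.ndarray:
        return np.array([v for v, lab in self.branches[i] if lab == "stable"])


def sweep(config: ModelConfig, params: ParameterSet,
          grid: Optional[Sequence[float]] = None,
          options: SolverOptions = SCREEN_OPTIONS) -> DoseResponse:
    """Steady-state readout branches at each K_tot of the grid."""
    from .screen import default_ktot_grid

    grid = default_ktot_grid() if grid is None else np.asarray(grid, dtype=float)
    sets = sweep_states(config, params, grid, options)
    branches: list[list[tuple[float, str]]] = []
    bist_points = []
    n_failed = 0
    for i, st in enumerate(sets):
        if st.solver_failure:
            n_failed += 1
            branches.append([])
            continue
        reads = st.readout_values(config)
        branches.append([(float(v), "stable" if s else "unstable")
                         for v, s in zip(reads, st.stable)])
        n_stable = int(np.sum(st.stable))
        n_unstable = st.n_states - n_stable
        if st.n_states and n_stable != n_unstable + 1:
            logger.warning("dose point K_tot=%.3g: %d stable vs %d unstable branches "
                           "(expected #stable = #unstable + 1)", grid[i], n_stable, n_unstable)
        if n_stable >= 2:
            bist_points.append(i)
    interval = (float(grid[bist_points[0]]), float(grid[bist_points[-1]])) if bist_points else None
    return DoseResponse(ktot_grid=grid, branches=branches,
                        bistable_interval=interval, n_failed_points=n_failed)


def ma_twin(config: ModelConfig, lr_params: ParameterSet, km_scale: float,
            km_base: Optional[float] = None) -> tuple[ModelConfig, ParameterSet]:
    """Mass-action twin of an LR parameter set at K_M = km_scale * km_base.

    kcat/K_M is pinned to the lumped linear constant (k_i = b_i * K_M), and
    the on/off rates follow from K_M with d_i = k_i (so k_i = 0.5 * a_i * K_M,
    comfortably inside the d_i > 0 regime).  ``km_base`` defaults to A_tot,
    making ``km_scale`` the K_M-to-substrate ratio.
    """
    if config.kinetics != "LR":
        raise ValueError("ma_twin expects the LR configuration as input")
    km_base = lr_params.A_tot if km_base is None else float(km_base)
    km = km_scale * km_base
    n = config.n_sites
    kcat = lr_params.b * km
    d = kcat.copy()
    a = (d + kcat) / km
    kp = lr_params.c * km
    dp = kp.copy()
    ap = (dp + kp) / km
    ma_config = ModelConfig(n_sites=n, kinetics="MA", scaffold=config.scaffold,
                            phos_location=config.phos_location,
                            dephos_location=config.dephos_location,
                            scaffold_rates_uniform=config.scaffold_rates_uniform)
    ma_params = ParameterSet(n=n, a=a, d=d, kcat=kcat, ap=ap, dp=dp, kp=kp,
                             alpha=None if not config.scaffold else lr_params.alpha,
                             beta=None if not config.scaffold else lr_params.beta,
                             A_tot=lr_params.A_tot, B_tot=lr_params.B_tot,
                             K_tot=lr_params.K_tot, P_tot=lr_params.P_tot)
    return ma_config, ma_params


def compare_lr_ma(config: ModelConfig, lr_params: ParameterSet,
                  km_scales: Sequence[float] = (1.0, 10.0, 100.0, 1000.0),
                  grid: Optional[Sequence[float]] = None,
                  options: SolverOptions = SCREEN_OPTIONS) -> dict:
    """Sup-norm distance between the LR and MA dose-response curves for
    increasing K_M scales (at fixed kcat/K_M); distances are reported in
    scale order and normalized by A_tot in ``rel_distances``.

    Points where either model is multistable compare the *largest* stable
    readout branch (the curves' upper envelopes).
    """
    from .screen import default_ktot_grid

    grid = default_ktot_grid() if grid is None else np.asarray(grid, dtype=float)
    lr_curve = sweep(config, lr_params, grid, options)

    def envelope(dr: DoseResponse) -> np.ndarray:
        out = np.full(len(dr.ktot_grid), np.nan)
        for i in range(len(dr.ktot_grid)):
            vals = dr.stable_values(i)
            if vals.size:
                out[i] = np.max(vals)
        return out

    lr_env = envelope(lr_curve)
    distances = []
    for sigma in km_scales:
        ma_config, ma_params = ma_twin(config, lr_params, float(sigma))
        ma_curve = sweep(ma_config, ma_params, grid, options)
        ma_env = envelope(ma_curve)
        ok = ~np.isnan(lr_env) & ~np.isnan(ma_env)
        distances.append(float(np.max(np.abs(lr_env[ok] - ma_env[ok]))))
    return {
        "km_scales": [float(s) for s in km_scales],
        "distances": distances,
        "rel_distances": [d / lr_params.A_tot for d in distances],
    }
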