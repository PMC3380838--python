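"""Bistability screening.

Each sampled parameter set is classified by a dose sweep: the total kinase
K_tot is stepped over a 50-point logarithmic grid (default 1e-3..1e3 uM),
all steady states are computed at every dose, and the set is called
bistable when at some dose at least two stable states coexist whose
fully-phosphorylated readouts differ by at least a fold threshold (default
5).  Screens tabulate the bistable fraction per model topology and
Michaelis-constant bin with its binomial standard error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelConfig, ParameterSet
from .sampling import SamplingPolicy, sample
from .steady import SCREEN_OPTIONS, SolverOptions, sweep_states

logger = logging.getLogger(__name__)

__all__ = [
    "BistabilityCall",
    "ScreenRow",
    "ScreenSummary",
    "default_ktot_grid",
    "classify",
    "run_screen",
    "extract_constraints",
    "binomial_se_percent",
]


def default_ktot_grid(n_points: int = 50, lo: float = 1e-3, hi: float = 1e3) -> np.ndarray:
    """The logarithmic total-kinase dose grid (uM)."""
    return np.exp(np.linspace(np.log(lo), np.log(hi), n_points))


def binomial_se_percent(fraction_percent: float, n: int) -> float:
    """Binomial standard error, in percent, of a percent-scale fraction."""
    p = fraction_percent / 100.0
    return 100.0 * float(np.sqrt(p * (1.0 - p) / n))


@dataclass(frozen=True)
class BistabilityCall:
    """Outcome of the dose-sweep bistability test for one parameter set."""

    bistable: bool
    best_fold_ratio: float        # max over doses of highest/lowest stable readout
    n_stable_max: int
    witness_ktot: Optional[float]  # dose at which best_fold_ratio was attained
    n_failed_points: int = 0

    def bistable_at(self, fold_threshold: float) -> bool:
        return self.n_stable_max >= 2 and self.best_fold_ratio >= fold_threshold


def classify(config: ModelConfig, params: ParameterSet,
             ktot_grid: Optional[Sequence[float]] = None,
             fold_threshold: float = 5.0,
             options: SolverOptions = SCREEN_OPTIONS) -> BistabilityCall:
    """Dose-sweep bistability test for one parameter set.

    Solver failures at individual dose points are counted as monostable
    there and reported in ``n_failed_points`` (this biases against, never
    for, a bistable call).
    """
    grid = default_ktot_grid() if ktot_grid is None else np.asarray(ktot_grid, dtype=float)
    sets = sweep_states(config, params, grid, options)
    floor = 1e-12 * params.A_tot
    best_ratio = 1.0
    witness = None
    n_stable_max = 0
    n_failed = 0
    for ktot, st in zip(grid, sets):
        if st.solver_failure:
            n_failed += 1
            continue
        stable_read = st.readout_values(config)[st.stable]
        n_stable_max = max(n_stable_max, stable_read.size)
        if stable_read.size >= 2:
            ratio = float(np.max(stable_read) / max(np.min(stable_read), floor))
            if ratio > best_ratio:
                best_ratio = ratio
                witness = float(ktot)
    if n_failed:
        logger.warning("classify: %d/%d dose points had solver failures", n_failed, len(grid))
    bistable = n_stable_max >= 2 and best_ratio >= fold_threshold
    return BistabilityCall(bistable=bistable, best_fold_ratio=best_ratio,
                           n_stable_max=n_stable_max,
                           witness_ktot=witness if bistable else None,
                           n_failed_points=n_failed)


def _call_from_branches(values, n_failed, grid, fold_threshold, a_tot) -> BistabilityCall:
    """Fold-ratio classification from per-dose stable readout arrays."""
    floor = 1e-12 * a_tot
    best_ratio = 1.0
    witness = None
    n_stable_max = 0
    for ktot, reads in zip(grid, values):
        n_stable_max = max(n_stable_max, reads.size)
        if reads.size >= 2:
            ratio = float(np.max(reads) / max(np.min(reads), floor))
            if ratio > best_ratio:
                best_ratio = ratio
                witness = float(ktot)
    bistable = n_stable_max >= 2 and best_ratio >= fold_threshold
    return BistabilityCall(bistable=bistable, best_fold_ratio=best_ratio,
                           n_stable_max=n_stable_max,
                           witness_ktot=witness if bistable else None,
                           n_failed_points=n_failed)


def _topology_labels(config: ModelConfig) -> tuple[str, str]:
    """Row labels in the style of the likelihood tables (off/on scaffold)."""
    if not config.scaffold:
        return "ph./deph.", ""
    off = []
    on = []
    if config.phos_off:
        off.append("ph.")
    if config.dephos_off:
        off.append("deph.")
    if config.phos_on:
        on.append("ph.")
    if config.dephos_on:
        on.append("deph.")
    return "/".join(off), "/".join(on)


@dataclass(frozen=True)
class ScreenRow:
    """One table row: a model topology screened under the shared policy."""

    config: ModelConfig
    label: str = ""


@dataclass
class ScreenSummary:
    """Per-row bistable counts and fractions (the machine twin of the
    likelihood tables), plus the per-set calls for downstream analyses."""

    table: pd.DataFrame
    calls: list[list[BistabilityCall]]
    param_sets: list[list[ParameterSet]]
    fold_threshold: float
    seed: int

    def refraction(self, fold_threshold: float) -> pd.DataFrame:
        """Re-tabulate under a different fold threshold using the stored
        calls (paired comparison; no re-solving)."""
        table = self.table.copy()
        for i, calls in enumerate(self.calls):
            n_bist = sum(c.bistable_at(fold_threshold) for c in calls)
            table.loc[i, "n_bistable"] = n_bist
            table.loc[i, "percent"] = 100.0 * n_bist / len(calls)
            table.loc[i, "se_percent"] = binomial_se_percent(table.loc[i, "percent"], len(calls))
        return table


def run_screen(rows: Sequence[ScreenRow | ModelConfig], policy: SamplingPolicy,
               n_samples: int = 500, seed: int = 0, fold_threshold: float = 5.0,
               ktot_grid: Optional[Sequence[float]] = None,
               options: SolverOptions = SCREEN_OPTIONS) -> ScreenSummary:
    """Sample and classify ``n_samples`` parameter sets per row.

    Fully reproducible: parameter draws come from per-(row, sample) seeded
    streams derived from ``seed``, and Newton's random starts from
    ``options.seed``.
    """
    from .steady import ma_screen_sweep

    rows = [r if isinstance(r, ScreenRow) else ScreenRow(r) for r in rows]
    records = []
    all_calls: list[list[BistabilityCall]] = []
    all_params: list[list[ParameterSet]] = []
    bin_lo, bin_hi = (policy.km_bin or policy.km_ratio_bin or (np.nan, np.nan))
    grid = default_ktot_grid() if ktot_grid is None else np.asarray(ktot_grid, dtype=float)
    for irow, row in enumerate(rows):
        rng = np.random.default_rng(np.random.SeedSequence([seed, irow]))
        psets = [sample(row.config, policy, rng) for _ in range(n_samples)]
        if row.config.kinetics == "MA":
            # amortize the vectorized Newton work across chunks of sets
            calls = []
            chunk = 25
            for start in range(0, n_samples, chunk):
                part = psets[start:start + chunk]
                values, failures = ma_screen_sweep(row.config, part, grid, options)
                for s, p in enumerate(part):
                    calls.append(_call_from_branches(values[s], failures[s], grid,
                                                     fold_threshold, p.A_tot))
        else:
            calls = [classify(row.config, p, grid, fold_threshold, options)
                     for p in psets]
        n_bist = sum(c.bistable for c in calls)
        pct = 100.0 * n_bist / n_samples
        off, on = _topology_labels(row.config)
        records.append({
            "n_sites": row.config.n_sites,
            "off_scaffold": off,
            "on_scaffold": on,
            "bin_lo": bin_lo,
            "bin_hi": bin_hi,
            "n_samples": n_samples,
            "n_bistable": n_bist,
            "percent": pct,
            "se_percent": binomial_se_percent(pct, n_samples),
            "n_failures": sum(c.n_failed_points > 0 for c in calls),
        })
        all_calls.append(calls)
        all_params.append(psets)
    table = pd.DataFrame.from_records(records)
    return ScreenSummary(table=table, calls=all_calls, param_sets=all_params,
                         fold_threshold=fold_threshold, seed=seed)


def extract_constraints(bistable_params: Sequence[ParameterSet]) -> dict:
    """Kinetic-constraint pattern over bistable two-site LR-S parameter sets.

    Fractions of sets satisfying each of the four patterns characteristic
    of bistability: (1) the second-site phosphorylation rate b_1 exceeds
    both dephosphorylation rates c_1, c_2; (2) b_1 > b_0; (3) every partial
    phosphoform binds the scaffold more tightly than the full one
    (max_{i<n} Kd_i < Kd_n); (4) A_tot > B_tot.
    """
    n_sets = len(bistable_params)
    out: dict = {"n": n_sets}
    if n_sets == 0:
        out["defined"] = False
        return out
    out["defined"] = True

    def frac(pred) -> float:
        return float(np.mean([bool(pred(p)) for p in bistable_params]))

    out["b1_gt_c1_c2"] = frac(lambda p: p.b[1] > p.c[0] and p.b[1] > p.c[1])
    out["b1_gt_b0"] = frac(lambda p: p.b[1] > p.b[0])
    out["kd_partial_lt_kd_full"] = frac(lambda p: np.max(p.kd[:-1]) < p.kd[-1])
    out["atot_gt_btot"] = frac(lambda p: p.A_tot > p.B_tot)
    return out
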