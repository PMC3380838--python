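"""Randomized kinetic parameter generation.

Every rate constant is drawn log-uniformly over several orders of magnitude
(default 1e-3..1e3 in 1/s or 1/(uM*s)), and total protein concentrations
log-uniformly over 1..10 uM.  Three restrictions reproduce the screening
protocol of the study conditions:

* ``B_tot <= A_tot`` enforced by resampling B_tot only (the substrate
  marginal is untouched);
* phosphostate-dependent scaffold binding: the dissociation constant
  Kd_i = beta_i/alpha_i is drawn log-uniformly from a low range for
  partially phosphorylated forms (i < n) and a high range for the fully
  phosphorylated form (i = n);
* an optional Michaelis-constant bin: each enzymatic (on, off, cat) triple
  is redrawn until its K_M = (off+cat)/on falls in the requested decade
  (equivalently K_M/A_tot for the ratio variant).  Because triples are
  mutually independent, per-triple rejection yields exactly the same
  conditional distribution as whole-set rejection.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .crn import ConfigurationError
from .models import ModelConfig, ParameterSet

__all__ = ["SamplingPolicy", "SamplingError", "sample", "sample_many"]


class SamplingError(RuntimeError):
    """Rejection sampling exhausted its budget."""


def _check_range(name, rng_pair):
    lo, hi = rng_pair
    if not (0 < lo < hi):
        raise ConfigurationError(f"{name} must satisfy 0 < lo < hi, got {rng_pair}")


@dataclass(frozen=True)
class SamplingPolicy:
    """Distributional policy for one screen.

    ``km_bin`` and ``km_ratio_bin`` are mutually exclusive; ``restrict_kd``
    disables the phosphostate-dependent Kd restriction (used by the
    unconstrained pattern-discovery screens).  ``seed`` is a default stream
    seed used when the sampling functions are called without one.
    """

    rate_range: tuple[float, float] = (1e-3, 1e3)
    conc_range: tuple[float, float] = (1.0, 10.0)       # B_tot, P_tot (uM)
    atot_range: tuple[float, float] = (1.0, 10.0)       # substrate total (uM)
    km_bin: Optional[tuple[float, float]] = None        # uM
    km_ratio_bin: Optional[tuple[float, float]] = None  # K_M / A_tot
    enforce_btot_le_atot: bool = True
    restrict_kd: bool = True
    kd_low_range: tuple[float, float] = (1e-3, 1.0)     # Kd_i, i < n (uM)
    kd_high_range: tuple[float, float] = (10.0, 1e3)    # Kd_n (uM)
    seed: int = 0
    max_rejections: int = 100_000

    def __post_init__(self):
        for name in ("rate_range", "conc_range", "atot_range", "kd_low_range", "kd_high_range"):
            _check_range(name, getattr(self, name))
        if self.km_bin is not None and self.km_ratio_bin is not None:
            raise ConfigurationError("km_bin and km_ratio_bin are mutually exclusive")
        for name in ("km_bin", "km_ratio_bin"):
            if getattr(self, name) is not None:
                _check_range(name, getattr(self, name))


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def _triple_in_bin(rng, policy: SamplingPolicy, bin_lo: float, bin_hi: float, budget: list[int]):
    """One (on, off, cat) triple conditioned on K_M in (bin_lo, bin_hi)."""
    lo, hi = policy.rate_range
    while True:
        a = _loguniform(rng, lo, hi)
        d = _loguniform(rng, lo, hi)
        k = _loguniform(rng, lo, hi)
        km = (d + k) / a
        if bin_lo <= km <= bin_hi:
            return a, d, k
        budget[0] += 1
        if budget[0] > policy.max_rejections:
            raise SamplingError(
                f"K_M-bin rejection exceeded {policy.max_rejections} draws "
                f"(acceptance rate < {1 / policy.max_rejections:.2g})")


def sample(config: ModelConfig, policy: SamplingPolicy = SamplingPolicy(),
           rng: Optional[np.random.Generator] = None) -> ParameterSet:
    """Draw one ParameterSet for ``config`` under ``policy``.

    The draw order is fixed (totals, enzymatic constants low-to-high step,
    scaffold binding by phosphoform) so a given seed reproduces the set
    exactly.  ``K_tot`` is set to a nominal 1 uM; it is the dose variable
    of the downstream sweeps.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([policy.seed]))
    n = config.n_sites
    lo, hi = policy.rate_range
    budget = [0]

    A_tot = float(_loguniform(rng, *policy.atot_range))
    B_tot = float(_loguniform(rng, *policy.conc_range))
    if policy.enforce_btot_le_atot:
        while B_tot > A_tot:
            budget[0] += 1
            if budget[0] > policy.max_rejections:
                raise SamplingError("B_tot <= A_tot rejection exceeded the budget")
            B_tot = float(_loguniform(rng, *policy.conc_range))
    P_tot = float(_loguniform(rng, *policy.conc_range))

    kwargs: dict = dict(n=n, A_tot=A_tot, B_tot=B_tot, K_tot=1.0, P_tot=P_tot)

    if config.kinetics == "LR":
        kwargs["b"] = _loguniform(rng, lo, hi, n)
        kwargs["c"] = _loguniform(rng, lo, hi, n)
    else:
        if policy.km_bin is not None:
            bin_lo, bin_hi = policy.km_bin
        elif policy.km_ratio_bin is not None:
            bin_lo, bin_hi = policy.km_ratio_bin[0] * A_tot, policy.km_ratio_bin[1] * A_tot
        else:
            bin_lo, bin_hi = 0.0, np.inf
        a = np.empty(n); d = np.empty(n); k = np.empty(n)
        ap = np.empty(n); dp = np.empty(n); kp = np.empty(n)
        for i in range(n):
            a[i], d[i], k[i] = _triple_in_bin(rng, policy, bin_lo, bin_hi, budget)
        for i in range(n):
            ap[i], dp[i], kp[i] = _triple_in_bin(rng, policy, bin_lo, bin_hi, budget)
        kwargs.update(a=a, d=d, kcat=k, ap=ap, dp=dp, kp=kp)

    if config.scaffold:
        if config.scaffold_rates_uniform:
            alpha = np.full(n + 1, _loguniform(rng, lo, hi))
            beta = np.full(n + 1, _loguniform(rng, lo, hi))
        else:
            alpha = _loguniform(rng, lo, hi, n + 1)
            if policy.restrict_kd:
                kd = np.empty(n + 1)
                kd[:n] = _loguniform(rng, *policy.kd_low_range, n)
                kd[n] = _loguniform(rng, *policy.kd_high_range)
                beta = alpha * kd
            else:
                beta = _loguniform(rng, lo, hi, n + 1)
        kwargs.update(alpha=alpha, beta=beta)

    return ParameterSet(**kwargs)


def sample_many(config: ModelConfig, policy: SamplingPolicy, n_samples: int,
                seed: Optional[int] = None) -> list[ParameterSet]:
    """``n_samples`` independent ParameterSets from one seeded stream."""
    rng = np.random.default_rng(np.random.SeedSequence([policy.seed if seed is None else seed]))
    return [sample(config, policy, rng) for _ in range(n_samples)]
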