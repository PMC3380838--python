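"""Construction of the four multisite-phosphorylation model families.

Substrate S carries n ordered phosphosites and is converted sequentially and
distributively between phosphoforms S_0 .. S_n.  Optionally a scaffold B
binds every phosphoform reversibly (S_i + B <-> S_i:B); phosphorylation then
acts by default only on scaffold-bound substrate, while dephosphorylation
acts both on and off the scaffold unless configured otherwise.  Enzymatics
are either full mass-action Michaelis-Menten mechanisms (MA: explicit kinase
K, phosphatase P, and enzyme-substrate complexes) or lumped linear rates
(LR: first-order conversions with effective constants b_i*K_tot and
c_i*P_tot).  The four families are MA-S, MA-NS, LR-S, LR-NS.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .crn import ConfigurationError, Reaction, ReactionNetwork, as_complex

__all__ = ["ModelConfig", "ParameterSet", "build_network", "readout", "species_order"]

_LOCATIONS = ("on_scaffold_only", "off_scaffold_only", "both")


@dataclass(frozen=True)
class ModelConfig:
    """Topology switchboard for one model variant.

    Parameters
    ----------
    n_sites : number of phosphorylation sites n >= 1.
    kinetics : "LR" (lumped linear rates) or "MA" (full mass action).
    scaffold : whether the scaffold protein B is present.
    phos_location, dephos_location : where the kinase/phosphatase act;
        ignored (treated as off-scaffold) when ``scaffold`` is False.  The
        defaults reproduce the standard topology: phosphorylation on the
        scaffold only, dephosphorylation both on and off.
    scaffold_rates_uniform : force alpha_i, beta_i independent of the
        phosphostate (the provably monostable uniform-binding variant).
    """

    n_sites: int
    kinetics: str = "MA"
    scaffold: bool = True
    phos_location: Optional[str] = None
    dephos_location: Optional[str] = None
    scaffold_rates_uniform: bool = False

    def __post_init__(self):
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.kinetics not in ("LR", "MA"):
            raise ConfigurationError(f"kinetics must be 'LR' or 'MA', got {self.kinetics!r}")
        if self.phos_location is None:
            object.__setattr__(self, "phos_location",
                               "on_scaffold_only" if self.scaffold else "off_scaffold_only")
        if self.dephos_location is None:
            object.__setattr__(self, "dephos_location",
                               "both" if self.scaffold else "off_scaffold_only")
        for loc in (self.phos_location, self.dephos_location):
            if loc not in _LOCATIONS:
                raise ConfigurationError(f"unknown location {loc!r}")

    # effective action flags; without a scaffold there is one compartment,
    # represented by the "free" pool
    @property
    def phos_on(self) -> bool:
        return self.scaffold and self.phos_location in ("on_scaffold_only", "both")

    @property
    def phos_off(self) -> bool:
        return (not self.scaffold) or self.phos_location in ("off_scaffold_only", "both")

    @property
    def dephos_on(self) -> bool:
        return self.scaffold and self.dephos_location in ("on_scaffold_only", "both")

    @property
    def dephos_off(self) -> bool:
        return (not self.scaffold) or self.dephos_location in ("off_scaffold_only", "both")

    @property
    def family(self) -> str:
        return f"{self.kinetics}-{'S' if self.scaffold else 'NS'}"

    def validate_for_build(self) -> None:
        if not self.scaffold:
            if self.phos_location == "on_scaffold_only" or self.dephos_location == "on_scaffold_only":
                raise ConfigurationError(
                    "scaffold=False is incompatible with an on_scaffold_only location")


@dataclass
class ParameterSet:
    """All rate constants and totals for one sampled system.

    Indexing convention: phosphorylation step i (0..n-1) converts phosphoform
    i to i+1; dephosphorylation step i (1..n) converts i to i-1 and is stored
    at array slot i-1.  ``c[i]`` is therefore the paper-style c_{i+1}, and
    ``ap/dp/kp`` the phosphatase triple for step i+1.  Scaffold binding
    on/off rates alpha_i, beta_i are indexed by phosphoform i (0..n).

    Units: first-order rates 1/s, second-order 1/(uM*s), totals uM.
    """

    n: int
    # LR lumped constants (per-uM-enzyme fluxes)
    b: Optional[np.ndarray] = None      # (n,)  phosphorylation
    c: Optional[np.ndarray] = None      # (n,)  dephosphorylation (step i+1)
    # MA kinase triples
    a: Optional[np.ndarray] = None      # (n,)  on
    d: Optional[np.ndarray] = None      # (n,)  off
    kcat: Optional[np.ndarray] = None   # (n,)  catalytic
    # MA phosphatase triples (step i+1)
    ap: Optional[np.ndarray] = None
    dp: Optional[np.ndarray] = None
    kp: Optional[np.ndarray] = None
    # scaffold binding
    alpha: Optional[np.ndarray] = None  # (n+1,)
    beta: Optional[np.ndarray] = None   # (n+1,)
    # totals (uM)
    A_tot: float = 1.0
    B_tot: float = 1.0
    K_tot: float = 1.0
    P_tot: float = 1.0

    def __post_init__(self):
        for name in ("b", "c", "a", "d", "kcat", "ap", "dp", "kp", "alpha", "beta"):
            v = getattr(self, name)
            if v is not None:
                arr = np.asarray(v, dtype=float)
                expected = self.n + 1 if name in ("alpha", "beta") else self.n
                if arr.shape != (expected,):
                    raise ConfigurationError(f"{name} must have shape ({expected},), got {arr.shape}")
                if np.any(arr <= 0):
                    raise ConfigurationError(f"{name} entries must be strictly positive")
                setattr(self, name, arr)
        for name in ("A_tot", "B_tot", "K_tot", "P_tot"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")

    # derived constants -----------------------------------------------------
    @property
    def km(self) -> np.ndarray:
        """Kinase Michaelis constants (d_i + k_i)/a_i, uM."""
        return (self.d + self.kcat) / self.a

    @property
    def kmp(self) -> np.ndarray:
        """Phosphatase Michaelis constants, uM (step i+1 at slot i)."""
        return (self.dp + self.kp) / self.ap

    @property
    def kd(self) -> np.ndarray:
        """Scaffold dissociation constants beta_i/alpha_i, uM."""
        return self.beta / self.alpha

    def to_dict(self) -> dict:
        out: dict = {"n": self.n, "A_tot": self.A_tot, "B_tot": self.B_tot,
                     "K_tot": self.K_tot, "P_tot": self.P_tot}
        for name in ("b", "c", "a", "d", "kcat", "ap", "dp", "kp", "alpha", "beta"):
            v = getattr(self, name)
            if v is not None:
                out[name] = [float(x) for x in v]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        kwargs = dict(data)
        for name in ("b", "c", "a", "d", "kcat", "ap", "dp", "kp", "alpha", "beta"):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = np.asarray(kwargs[name], dtype=float)
        return cls(**kwargs)

    def rate_map(self, config: ModelConfig, ktot: Optional[float] = None) -> dict[str, float]:
        """Numeric values for every rate-constant name of ``build_network(config)``.

        For LR models the (de)phosphorylation conversions carry the lumped
        effective constants b_i*K_tot and c_{i+1}*P_tot; ``ktot`` overrides
        the stored K_tot (the dose variable of the sweeps).
        """
        ktot = self.K_tot if ktot is None else float(ktot)
        n = config.n_sites
        rates: dict[str, float] = {}
        if config.scaffold:
            for i in range(n + 1):
                rates[f"alpha{i}"] = float(self.alpha[i])
                rates[f"beta{i}"] = float(self.beta[i])
        if config.kinetics == "LR":
            for i in range(n):
                for where, active in (("on", config.phos_on), ("off", config.phos_off)):
                    if active:
                        rates[f"bK{i}_{where}"] = float(self.b[i]) * ktot
                for where, active in (("on", config.dephos_on), ("off", config.dephos_off)):
                    if active:
                        rates[f"cP{i + 1}_{where}"] = float(self.c[i]) * self.P_tot
        else:
            for i in range(n):
                for where, active in (("on", config.phos_on), ("off", config.phos_off)):
                    if active:
                        rates[f"a{i}_{where}"] = float(self.a[i])
                        rates[f"d{i}_{where}"] = float(self.d[i])
                        rates[f"k{i}_{where}"] = float(self.kcat[i])
                for where, active in (("on", config.dephos_on), ("off", config.dephos_off)):
                    if active:
                        rates[f"ap{i + 1}_{where}"] = float(self.ap[i])
                        rates[f"dp{i + 1}_{where}"] = float(self.dp[i])
                        rates[f"kp{i + 1}_{where}"] = float(self.kp[i])
        return rates


def _bound(i: int) -> str:
    return f"S{i}_B"


def species_order(config: ModelConfig) -> list[str]:
    """Deterministic species ordering used by every built network."""
    config.validate_for_build()
    n = config.n_sites
    names = [f"S{i}" for i in range(n + 1)]
    if config.scaffold:
        names += [_bound(i) for i in range(n + 1)]
        names.append("B")
    if config.kinetics == "MA":
        names += ["K", "P"]
        for i in range(n):
            if config.phos_off:
                names.append(f"K_S{i}")
            if config.phos_on:
                names.append(f"K_S{i}_B")
        for i in range(1, n + 1):
            if config.dephos_off:
                names.append(f"P_S{i}")
            if config.dephos_on:
                names.append(f"P_S{i}_B")
    return names


def build_network(config: ModelConfig) -> ReactionNetwork:
    """Build the reaction network for one model variant.

    Scaffold binding is S_i + B <-> S_i:B for every phosphoform.  Each MA
    enzymatic step is the three-reaction Michaelis-Menten mechanism (bind,
    unbind, catalyze); the kinase binds scaffold-bound substrate directly
    from solution, and enzyme-substrate complexes neither bind nor release
    the scaffold.  Each LR step is a single first-order conversion.
    """
    config.validate_for_build()
    n = config.n_sites
    rxns: list[Reaction] = []

    if config.scaffold:
        for i in range(n + 1):
            rxns.append(Reaction(as_complex({f"S{i}": 1, "B": 1}), as_complex({_bound(i): 1}), f"alpha{i}"))
            rxns.append(Reaction(as_complex({_bound(i): 1}), as_complex({f"S{i}": 1, "B": 1}), f"beta{i}"))

    def substrate(i: int, on_scaffold: bool) -> str:
        return _bound(i) if on_scaffold else f"S{i}"

    if config.kinetics == "LR":
        for i in range(n):
            for where, active in (("on", config.phos_on), ("off", config.phos_off)):
                if active:
                    on = where == "on"
                    rxns.append(Reaction(as_complex({substrate(i, on): 1}),
                                         as_complex({substrate(i + 1, on): 1}), f"bK{i}_{where}"))
            for where, active in (("on", config.dephos_on), ("off", config.dephos_off)):
                if active:
                    on = where == "on"
                    rxns.append(Reaction(as_complex({substrate(i + 1, on): 1}),
                                         as_complex({substrate(i, on): 1}), f"cP{i + 1}_{where}"))
    else:
        for i in range(n):
            for where, active in (("on", config.phos_on), ("off", config.phos_off)):
                if not active:
                    continue
                on = where == "on"
                sub, prod = substrate(i, on), substrate(i + 1, on)
                cplx = f"K_S{i}_B" if on else f"K_S{i}"
                rxns.append(Reaction(as_complex({"K": 1, sub: 1}), as_complex({cplx: 1}), f"a{i}_{where}"))
                rxns.append(Reaction(as_complex({cplx: 1}), as_complex({"K": 1, sub: 1}), f"d{i}_{where}"))
                rxns.append(Reaction(as_complex({cplx: 1}), as_complex({"K": 1, prod: 1}), f"k{i}_{where}"))
            for where, active in (("on", config.dephos_on), ("off", config.dephos_off)):
                if not active:
                    continue
                on = where == "on"
                sub, prod = substrate(i + 1, on), substrate(i, on)
                cplx = f"P_S{i + 1}_B" if on else f"P_S{i + 1}"
                rxns.append(Reaction(as_complex({"P": 1, sub: 1}), as_complex({cplx: 1}), f"ap{i + 1}_{where}"))
                rxns.append(Reaction(as_complex({cplx: 1}), as_complex({"P": 1, sub: 1}), f"dp{i + 1}_{where}"))
                rxns.append(Reaction(as_complex({cplx: 1}), as_complex({"P": 1, prod: 1}), f"kp{i + 1}_{where}"))

    return ReactionNetwork(tuple(species_order(config)), tuple(rxns))


def readout(config: ModelConfig) -> frozenset[str]:
    """Species summed to form the scalar output: every species carrying the
    fully phosphorylated phosphoform S_n (free, scaffold-bound, and any
    enzyme complex on it)."""
    config.validate_for_build()
    n = config.n_sites
    out = {f"S{n}"}
    if config.scaffold:
        out.add(_bound(n))
    if config.kinetics == "MA":
        if config.dephos_off:
            out.add(f"P_S{n}")
        if config.dephos_on:
            out.add(f"P_S{n}_B")
    return frozenset(out)
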