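"""Steady-state enumeration and stability for all four model families.

The full ODE systems are never solved blindly: every steady state of an MA
model satisfies the enzyme-complex slaving relations (complex = enzyme *
substrate / K_M), which reduces the problem to the free kinase, free
phosphatase and (with scaffold) free scaffold concentrations.  Given that
reduced vector, the substrate ladder is linear and solved exactly
(:mod:`multiphos._reduce`); the remaining unknowns are pinned down by the
K_tot / P_tot / B_tot conservation relations, whose roots are found by
damped Newton iteration from many starting points (MA) or by a bracketed
one-dimensional scan over the free scaffold concentration (LR-S).  LR-NS
has a closed-form unique steady state.  Every candidate is lifted back to
the full species vector, deduplicated, and stability-labeled via the
eigenvalues of the exact mass-action Jacobian (conservation laws contribute
structural zero eigenvalues).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._reduce import chain_steady_log, ladder_steady_dense, ladder_steady_log
from .crn import ConfigurationError, MassActionSystem
from .models import ModelConfig, ParameterSet, build_network, readout, species_order

logger = logging.getLogger(__name__)

__all__ = [
    "SolverOptions",
    "SteadyStateSet",
    "solve",
    "solve_lr_ns",
    "solve_lr_s",
    "solve_ma",
    "sweep_states",
    "integrate_to_steady_state",
    "random_initial_state",
]


@dataclass(frozen=True)
class SolverOptions:
    """Numerical protocol knobs for the steady-state solvers."""

    newton_grid: int = 5          # deterministic starts per reduced coordinate
    newton_random: int = 25       # extra log-uniform random starts
    newton_max_iter: int = 200
    newton_tol: float = 1e-10     # relative conservation-residual convergence
    max_halvings: int = 30        # damping: step-halving rounds per iteration
    lr_grid_points: int = 1000    # scan grid for the LR-S free-scaffold root find
    lr_bisect_iter: int = 100
    dedupe_tol: float = 1e-6      # relative L-inf distance between distinct states
    seed: int = 0                 # random Newton starts
    warm_start: bool = True       # re-seed Newton with roots found elsewhere in a sweep
    anchor_stride: int = 1        # multistart every k-th dose; warm starts fill the rest

    def n_starts(self, dim: int) -> int:
        return self.newton_grid ** dim + self.newton_random


# cheaper profiles used by the screening sweeps (validated call-for-call
# against the default protocol; see docs/methods.md)
SCREEN_OPTIONS = SolverOptions(newton_grid=4, newton_random=8)
FAST_SCREEN_OPTIONS = SolverOptions(newton_grid=3, newton_random=5,
                                    newton_max_iter=120, anchor_stride=2)


@dataclass
class SteadyStateSet:
    """Deduplicated steady states with stability labels.

    ``states`` has one row per steady state in the species order of
    ``species``.  ``residual_norm`` is the maximum relative RHS /
    conservation residual over the returned states.
    """

    species: list[str]
    states: np.ndarray                 # (n_states, n_species)
    stable: np.ndarray                 # (n_states,) bool
    eigvals: list[np.ndarray]
    residual_norm: float
    method: str
    solver_failure: bool = False
    messages: list[str] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_stable(self) -> int:
        return int(np.sum(self.stable))

    def readout_values(self, config: ModelConfig) -> np.ndarray:
        idx = [self.species.index(s) for s in sorted(readout(config))]
        if self.n_states == 0:
            return np.zeros(0)
        return self.states[:, idx].sum(axis=1)

    def as_dicts(self) -> list[dict]:
        out = []
        for i in range(self.n_states):
            out.append({
                "concentrations": {s: float(v) for s, v in zip(self.species, self.states[i])},
                "stable": bool(self.stable[i]),
                "eigenvalues_re": [float(np.real(e)) for e in self.eigvals[i]],
            })
        return out


# ---------------------------------------------------------------------------
# reduced residuals
# ---------------------------------------------------------------------------


class _Reduced:
    """Residuals / lifting of the reduced steady-state system.

    Holds one or several ParameterSets as stacked arrays; every evaluation
    is batched over columns, each column carrying a set index ``sidx`` and
    its own dose K_tot.  Unknowns (natural log): MA with scaffold ->
    (K, P, B); MA without -> (K, P); LR with scaffold -> (B,).
    """

    def __init__(self, config: ModelConfig, params):
        config.validate_for_build()
        self.config = config
        self.params_list: list[ParameterSet] = (
            list(params) if isinstance(params, (list, tuple)) else [params])
        self.n = config.n_sites
        pl = self.params_list

        def stack(attr):
            return np.stack([np.asarray(getattr(p, attr)) for p in pl], axis=-1)

        if config.kinetics == "MA":
            self.km = stack("km")
            self.kmp = stack("kmp")
            self.kk = stack("kcat") / self.km       # kcat/K_M per kinase step
            self.kkp = stack("kp") / self.kmp
        else:
            self.b = stack("b")
            self.c = stack("c")
        if config.scaffold:
            self.alpha = stack("alpha")
            self.beta = stack("beta")
        self.A_tot = np.array([p.A_tot for p in pl])
        self.B_tot = np.array([p.B_tot for p in pl])
        self.P_tot = np.array([p.P_tot for p in pl])
        self.names = species_order(config)

    @property
    def params(self) -> ParameterSet:
        return self.params_list[0]

    # -- substrate ladder at fixed reduced vector ---------------------------
    def _ladder(self, K, P, B, ktot, sidx):
        """Unnormalized log steady state of the substrate ladder.  K, P, B,
        ktot and sidx are 1-d column arrays (K/P unused for LR, B absent
        for NS)."""
        cfg = self.config
        if cfg.kinetics == "MA":
            up = self.kk[:, sidx] * np.asarray(K)[None]
            down = self.kkp[:, sidx] * np.asarray(P)[None]
        else:
            up = self.b[:, sidx] * np.asarray(ktot)[None]
            down = self.c[:, sidx] * self.P_tot[sidx][None]
        u = up if cfg.phos_on else np.zeros_like(up)
        uo = up if cfg.phos_off else np.zeros_like(up)
        v = down if cfg.dephos_off else np.zeros_like(down)
        w = down if cfg.dephos_on else np.zeros_like(down)
        if not cfg.scaffold:
            lnS = chain_steady_log(uo, v)
            return lnS, None
        p = self.alpha[:, sidx] * np.asarray(B)[None]
        q = self.beta[:, sidx]
        if cfg.phos_on and not cfg.phos_off:
            lnS, lnT = ladder_steady_log(u, v, w, p, q)
        elif not cfg.phos_on and not cfg.dephos_on:
            # free chain with dead-end binding
            lnS = chain_steady_log(uo, v)
            lnT = lnS + np.log(p) - np.log(q)
        else:
            S, T = ladder_steady_dense(uo, u, v, w, p, np.ascontiguousarray(q))
            with np.errstate(divide="ignore"):
                lnS, lnT = np.log(S), np.log(T)
        return lnS, lnT

    def _weights(self, K, P, sidx, m):
        """A_tot bookkeeping weights: each substrate unit drags its slaved
        enzyme complexes along (ignored for LR)."""
        cfg = self.config
        n = self.n
        wS = np.ones((n + 1, m))
        wT = np.ones((n + 1, m)) if cfg.scaffold else None
        if cfg.kinetics == "MA":
            km, kmp = self.km[:, sidx], self.kmp[:, sidx]
            if cfg.phos_off:
                wS[:n] += np.asarray(K)[None] / km
            if cfg.dephos_off:
                wS[1:] += np.asarray(P)[None] / kmp
            if cfg.scaffold and cfg.phos_on:
                wT[:n] += np.asarray(K)[None] / km
            if cfg.scaffold and cfg.dephos_on:
                wT[1:] += np.asarray(P)[None] / kmp
        return wS, wT

    def _normalized(self, K, P, B, ktot, sidx, with_weights=False):
        """Ladder solution scaled so total substrate content equals A_tot."""
        lnS, lnT = self._ladder(K, P, B, ktot, sidx)
        wS, wT = self._weights(K, P, sidx, lnS.shape[1])
        A = self.A_tot[sidx]
        if lnT is None:
            L = np.max(lnS, axis=0)
            eS = np.exp(lnS - L)
            Z = np.sum(wS * eS, axis=0)
            return (A * eS / Z, None, wS, wT) if with_weights else (A * eS / Z, None)
        L = np.maximum(np.max(lnS, axis=0), np.max(lnT, axis=0))
        eS, eT = np.exp(lnS - L), np.exp(lnT - L)
        Z = np.sum(wS * eS, axis=0) + np.sum(wT * eT, axis=0)
        S, T = A * eS / Z, A * eT / Z
        return (S, T, wS, wT) if with_weights else (S, T)

    def residual(self, Z: np.ndarray, ktot: np.ndarray, sidx: np.ndarray) -> np.ndarray:
        """Relative conservation residuals at reduced log-vectors Z (d, m).

        MA: rows are (K_tot, P_tot[, B_tot]) mismatches.  LR with scaffold:
        a single row, the B_tot mismatch (the only reduced unknown).
        """
        cfg = self.config
        n = self.n
        if cfg.kinetics == "LR":
            B = np.exp(Z[-1])
            Btot = self.B_tot[sidx]
            S, T = self._normalized(None, None, B, ktot, sidx)
            return np.stack([(B + np.sum(T, axis=0) - Btot) / Btot])
        K, P = np.exp(Z[0]), np.exp(Z[1])
        B = np.exp(Z[2]) if cfg.scaffold else None
        S, T, wS, wT = self._normalized(K, P, B, ktot, sidx, with_weights=True)
        km, kmp = self.km[:, sidx], self.kmp[:, sidx]
        kin = np.zeros_like(K)
        if cfg.phos_on:
            kin += np.sum(T[:n] / km, axis=0)
        if cfg.phos_off:
            kin += np.sum(S[:n] / km, axis=0)
        fK = (K * (1.0 + kin) - ktot) / ktot
        pho = np.zeros_like(P)
        if cfg.dephos_off:
            pho += np.sum(S[1:] / kmp, axis=0)
        if cfg.dephos_on:
            pho += np.sum(T[1:] / kmp, axis=0)
        Ptot = self.P_tot[sidx]
        fP = (P * (1.0 + pho) - Ptot) / Ptot
        if not cfg.scaffold:
            return np.stack([fK, fP])
        Btot = self.B_tot[sidx]
        fB = (B + np.sum(wT * T, axis=0) - Btot) / Btot
        return np.stack([fK, fP, fB])

    def lift(self, Z: np.ndarray, ktot: np.ndarray, sidx: np.ndarray) -> np.ndarray:
        """Full species vectors (m, n_species) for reduced log-vectors Z."""
        cfg = self.config
        n = self.n
        if cfg.kinetics == "LR":
            K = P = None
            B = np.exp(Z[-1]) if cfg.scaffold else None
        else:
            K, P = np.exp(Z[0]), np.exp(Z[1])
            B = np.exp(Z[2]) if cfg.scaffold else None
        S, T = self._normalized(K, P, B, ktot, sidx)
        cols: dict[str, np.ndarray] = {}
        for i in range(n + 1):
            cols[f"S{i}"] = S[i]
        if cfg.scaffold:
            for i in range(n + 1):
                cols[f"S{i}_B"] = T[i]
            cols["B"] = B
        if cfg.kinetics == "MA":
            km, kmp = self.km[:, sidx], self.kmp[:, sidx]
            cols["K"] = K
            cols["P"] = P
            for i in range(n):
                if cfg.phos_off:
                    cols[f"K_S{i}"] = K * S[i] / km[i]
                if cfg.phos_on:
                    cols[f"K_S{i}_B"] = K * T[i] / km[i]
            for i in range(1, n + 1):
                if cfg.dephos_off:
                    cols[f"P_S{i}"] = P * S[i] / kmp[i - 1]
                if cfg.dephos_on:
                    cols[f"P_S{i}_B"] = P * T[i] / kmp[i - 1]
        return np.stack([cols[name] for name in self.names], axis=-1)


# ---------------------------------------------------------------------------
# damped Newton on the reduced system
# ---------------------------------------------------------------------------


def _newton(reduced: _Reduced, Z0: np.ndarray, ktot: np.ndarray, sidx: np.ndarray,
            lo: np.ndarray, hi: np.ndarray, opts: SolverOptions):
    """Vectorized damped Newton with forward-difference Jacobian.

    Z0, lo, hi: (d, m) log-space starts and clip bounds; ktot, sidx: (m,)
    per-column dose and parameter-set index.  Returns (Z, fnorm) over all
    starts; convergence is fnorm <= tol.
    """
    d, m = Z0.shape
    Z = np.clip(Z0, lo, hi)
    F = reduced.residual(Z, ktot, sidx)
    fnorm = np.max(np.abs(F), axis=0)
    active = np.where(fnorm > opts.newton_tol)[0]
    h = 1e-6
    for _ in range(opts.newton_max_iter):
        if active.size == 0:
            break
        Za, Fa, ka, sa = Z[:, active], F[:, active], ktot[active], sidx[active]
        loa, hia = lo[:, active], hi[:, active]
        # all d forward-difference perturbations in one batched evaluation
        Zh = np.tile(Za, (1, d))
        for j in range(d):
            Zh[j, j * active.size:(j + 1) * active.size] += h
        Fh = reduced.residual(Zh, np.tile(ka, d), np.tile(sa, d))
        J = np.empty((active.size, d, d))
        for j in range(d):
            J[:, :, j] = ((Fh[:, j * active.size:(j + 1) * active.size] - Fa) / h).T
        # tiny Tikhonov shift guards exactly singular iterates
        shift = 1e-13 * np.maximum(np.max(np.abs(J), axis=(1, 2)), 1.0)
        J[:, np.arange(d), np.arange(d)] += shift[:, None]
        try:
            delta = np.linalg.solve(J, -Fa.T[..., None])[..., 0]     # (mA, d)
        except np.linalg.LinAlgError:
            delta = np.stack([np.linalg.lstsq(J[i], -Fa[:, i], rcond=None)[0]
                              for i in range(active.size)])
        step = np.clip(delta.T, -4.0, 4.0)                           # cap ~e^4 per move
        old = np.max(np.abs(Fa), axis=0)
        pend = np.arange(active.size)
        fac = 1.0
        newZ, newF = Za.copy(), Fa.copy()
        for _ in range(opts.max_halvings):
            if pend.size == 0:
                break
            cand = np.clip(Za[:, pend] + fac * step[:, pend], loa[:, pend], hia[:, pend])
            Fc = reduced.residual(cand, ka[pend], sa[pend])
            ok = np.max(np.abs(Fc), axis=0) < old[pend]
            take = pend[ok]
            newZ[:, take] = cand[:, ok]
            newF[:, take] = Fc[:, ok]
            pend = pend[~ok]
            fac *= 0.5
        stalled = np.zeros(active.size, dtype=bool)
        stalled[pend] = True
        Z[:, active] = newZ
        F[:, active] = newF
        fa = np.max(np.abs(newF), axis=0)
        fnorm[active] = fa
        active = active[(fa > opts.newton_tol) & ~stalled]
    return Z, fnorm


def _cluster_columns(Z: np.ndarray, tol: float) -> list[np.ndarray]:
    """Greedy clustering of column vectors under L-inf distance tol."""
    m = Z.shape[1]
    order = np.argsort(Z[0], kind="stable")
    reps: list[np.ndarray] = []
    for idx in order:
        col = Z[:, idx]
        for rep in reps:
            if np.max(np.abs(col - rep)) < tol:
                break
        else:
            reps.append(col)
    return reps


def _dedupe_states(states: np.ndarray, tol: float) -> np.ndarray:
    """Indices of pairwise-distinct rows under relative L-inf distance."""
    keep: list[int] = []
    for i in range(states.shape[0]):
        xi = states[i]
        for j in keep:
            xj = states[j]
            scale = max(np.max(np.abs(xi)), np.max(np.abs(xj)), 1e-300)
            if np.max(np.abs(xi - xj)) / scale < tol:
                break
        else:
            keep.append(i)
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# stability labels
# ---------------------------------------------------------------------------


def _n_laws(config: ModelConfig) -> int:
    """Number of independent conservation laws of a built family: substrate
    (+ scaffold) (+ kinase and phosphatase totals for MA)."""
    laws = 1 + int(config.scaffold)
    if config.kinetics == "MA":
        laws += 2
    return laws


def _stoich_basis(system: MassActionSystem) -> np.ndarray:
    """Orthonormal basis of the stoichiometric subspace Im(N).

    The dynamics preserve the affine class x0 + Im(N) and J maps Im(N) into
    itself, so Q^T J Q is exactly the transverse linearization: it carries
    no structural zero eigenvalues from the conservation laws.
    """
    N = system.N.astype(float)
    u, s, _ = np.linalg.svd(N, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    return u[:, :rank]


def _label_states(system: MassActionSystem, n_laws: int,
                  states: np.ndarray, messages: list[str],
                  basis: Optional[np.ndarray] = None):
    """Eigenvalue stability labels via the Jacobian restricted to the
    stoichiometric compatibility subspace.

    The full spectrum is returned for inspection (its ``n_laws`` smallest
    eigenvalues are the structural zeros); the stable/unstable call uses
    only the reduced spectrum, so a slow-but-stable mode is never swamped
    by the scale of a fast binding mode.  Borderline states (a reduced
    eigenvalue with vanishing real part) are conservatively unstable.
    """
    J = system.jacobian(states)
    ev = np.linalg.eigvals(J)
    order = np.argsort(np.abs(ev), axis=1)
    ev_sorted = np.take_along_axis(ev, order, axis=1)
    maxabs = np.maximum(np.max(np.abs(ev), axis=1), 1e-300)
    zeros = ev_sorted[:, :n_laws]
    bad = np.abs(zeros) > 1e-7 * maxabs[:, None]
    if np.any(bad):
        messages.append(f"structural zero eigenvalue check violated for {int(np.sum(np.any(bad, axis=1)))} state(s)")
    Q = _stoich_basis(system) if basis is None else basis
    J_red = Q.T @ J @ Q
    ev_red = np.linalg.eigvals(J_red)
    re = np.real(ev_red)
    maxabs_red = np.maximum(np.max(np.abs(ev_red), axis=1), 1e-300)
    stable = np.all(re < 0, axis=1)
    borderline = np.any(np.abs(re) < 1e-12 * maxabs_red[:, None], axis=1)
    if np.any(borderline & stable):
        messages.append(f"{int(np.sum(borderline & stable))} borderline state(s) labeled unstable")
    stable &= ~borderline
    return stable, [ev_sorted[i] for i in range(states.shape[0])]


def _rhs_residual(system: MassActionSystem, states: np.ndarray) -> float:
    if states.shape[0] == 0:
        return 0.0
    flux = system.flux(states)
    dx = flux @ system.N.T.astype(float)
    scale = np.abs(flux) @ np.abs(system.N.T.astype(float))
    rel = np.abs(dx) / np.maximum(scale, 1e-300)
    return float(np.max(rel))


# ---------------------------------------------------------------------------
# family-specific solvers
# ---------------------------------------------------------------------------


def solve_lr_ns(config: ModelConfig, params: ParameterSet, ktot: Optional[float] = None) -> SteadyStateSet:
    """Closed-form unique steady state of the linear-rate model without
    scaffold: S_{i+1}/S_i = b_i K_tot / (c_{i+1} P_tot), normalized to A_tot."""
    if config.kinetics != "LR" or config.scaffold:
        raise ConfigurationError("solve_lr_ns requires kinetics='LR', scaffold=False")
    ktot = params.K_tot if ktot is None else float(ktot)
    n = config.n_sites
    lnS = np.concatenate([[0.0], np.cumsum(np.log(params.b * ktot) - np.log(params.c * params.P_tot))])
    eS = np.exp(lnS - np.max(lnS))
    S = params.A_tot * eS / np.sum(eS)
    states = S[None, :]
    messages: list[str] = []
    system = MassActionSystem(build_network(config), params.rate_map(config, ktot))
    stable, eigs = _label_states(system, _n_laws(config), states, messages)
    return SteadyStateSet(
        species=species_order(config), states=states, stable=stable, eigvals=eigs,
        residual_norm=_rhs_residual(system, states), method="closed_form", messages=messages)


def _lr_s_roots(reduced: _Reduced, ktot_vals: np.ndarray, opts: SolverOptions):
    """All roots of the free-scaffold conservation residual g(B) for each
    K_tot value; returns a list (per K_tot) of arrays of free-B roots."""
    prm = reduced.params
    nB = opts.lr_grid_points
    Bgrid = np.exp(np.linspace(np.log(prm.B_tot * 1e-9), np.log(prm.B_tot), nB))
    nk = len(ktot_vals)

    def g(Bflat, kflat):
        zero = np.zeros(len(Bflat), dtype=int)
        return reduced.residual(np.log(Bflat)[None], kflat, zero)[0] * prm.B_tot

    Bflat = np.tile(Bgrid, nk)
    kflat = np.repeat(ktot_vals, nB)
    gv = g(Bflat, kflat).reshape(nk, nB)
    roots: list[list[float]] = [[] for _ in range(nk)]
    sign = np.sign(gv)
    lo_idx, hi_idx = [], []
    point = []
    for ik in range(nk):
        exact = np.where(sign[ik] == 0)[0]
        for j in exact:
            roots[ik].append(float(Bgrid[j]))
        flips = np.where(sign[ik, :-1] * sign[ik, 1:] < 0)[0]
        for j in flips:
            lo_idx.append(Bgrid[j])
            hi_idx.append(Bgrid[j + 1])
            point.append(ik)
    if lo_idx:
        lo = np.log(np.array(lo_idx))
        hi = np.log(np.array(hi_idx))
        kb = ktot_vals[np.array(point)]
        glo = g(np.exp(lo), kb)
        for _ in range(opts.lr_bisect_iter):
            mid = 0.5 * (lo + hi)
            gm = g(np.exp(mid), kb)
            left = np.sign(gm) == np.sign(glo)
            lo = np.where(left, mid, lo)
            glo = np.where(left, gm, glo)
            hi = np.where(left, hi, mid)
        for B, ik in zip(np.exp(0.5 * (lo + hi)), point):
            roots[ik].append(float(B))
    return roots


def solve_lr_s(config: ModelConfig, params: ParameterSet, ktot: Optional[float] = None,
               options: SolverOptions = SolverOptions()) -> SteadyStateSet:
    """All steady states of the linear-rate scaffold model via the
    one-dimensional reduction to the free scaffold concentration."""
    if config.kinetics != "LR" or not config.scaffold:
        raise ConfigurationError("solve_lr_s requires kinetics='LR', scaffold=True")
    ktot = params.K_tot if ktot is None else float(ktot)
    return _sweep_lr_s(config, params, np.array([ktot]), options)[0]


def _sweep_lr_s(config: ModelConfig, params: ParameterSet, ktot_grid: np.ndarray,
                options: SolverOptions) -> list[SteadyStateSet]:
    reduced = _Reduced(config, params)
    roots = _lr_s_roots(reduced, np.asarray(ktot_grid, dtype=float), options)
    net = build_network(config)
    n_laws = _n_laws(config)
    basis = None
    out = []
    for ik, ktot in enumerate(ktot_grid):
        messages: list[str] = []
        if not roots[ik]:
            out.append(SteadyStateSet(species=species_order(config),
                                      states=np.zeros((0, len(species_order(config)))),
                                      stable=np.zeros(0, dtype=bool), eigvals=[],
                                      residual_norm=np.nan, method="polynomial_1var",
                                      solver_failure=True,
                                      messages=["no root of the scaffold conservation residual"]))
            continue
        B = np.array(sorted(roots[ik]))
        Z = np.log(B)[None]
        zeros = np.zeros(len(B), dtype=int)
        states = reduced.lift(Z, np.full(B.shape, ktot), zeros)
        keep = _dedupe_states(states, options.dedupe_tol)
        states = states[keep]
        res = reduced.residual(Z[:, keep], np.full(keep.shape, ktot), zeros[: len(keep)])
        system = MassActionSystem(net, params.rate_map(config, float(ktot)))
        if basis is None:
            basis = _stoich_basis(system)
        stable, eigs = _label_states(system, n_laws, states, messages, basis)
        out.append(SteadyStateSet(
            species=species_order(config), states=states, stable=stable, eigvals=eigs,
            residual_norm=max(_rhs_residual(system, states), float(np.max(np.abs(res)))),
            method="polynomial_1var", messages=messages))
    return out


def _empty_set(config: ModelConfig, method: str, msg: str) -> SteadyStateSet:
    names = species_order(config)
    return SteadyStateSet(species=names, states=np.zeros((0, len(names))),
                          stable=np.zeros(0, dtype=bool), eigvals=[],
                          residual_norm=np.nan, method=method, solver_failure=True,
                          messages=[msg])


def _ma_roots_batch(config: ModelConfig, params_list: Sequence[ParameterSet],
                    ktot_vals: np.ndarray, options: SolverOptions):
    """Distinct reduced-system roots for every (parameter set, dose) pair.

    A single vectorized Newton run covers all sets, doses and starts; a
    second run propagates every root found for a set across all its doses
    (a cheap continuation that catches branches whose basin eludes the
    start grid).  Returns ``(reduced, roots)`` with ``roots[s][ik]`` a list
    of reduced log-vectors.
    """
    reduced = _Reduced(config, list(params_list))
    scaffold = config.scaffold
    d = 3 if scaffold else 2
    S = len(reduced.params_list)
    nk_all = len(ktot_vals)
    stride = max(1, options.anchor_stride) if (options.warm_start and nk_all > 1) else 1
    anchor_idx = np.arange(0, nk_all, stride)
    if anchor_idx[-1] != nk_all - 1:
        anchor_idx = np.append(anchor_idx, nk_all - 1)
    anchors = ktot_vals[anchor_idx]
    nk = len(anchors)
    g = options.newton_grid
    nr = options.newton_random
    rng = np.random.default_rng(np.random.SeedSequence([options.seed, 2 ** 20]))

    # per-(set, anchor dose) upper bounds in log space; K's bound follows the dose
    hi = np.empty((d, S, nk))
    hi[0] = np.log(anchors)[None, :]
    hi[1] = np.log(reduced.P_tot)[:, None]
    if scaffold:
        hi[2] = np.log(reduced.B_tot)[:, None]
    lo_start = hi - np.log(1e6)
    frac = np.linspace(0.0, 1.0, g)
    mesh = np.meshgrid(*(frac,) * d, indexing="ij")
    flat = np.stack([m.ravel() for m in mesh])                 # (d, g**d)
    grid = lo_start[..., None] + (hi - lo_start)[..., None] * flat[:, None, None, :]
    unif = rng.random((d, S, nk, nr))
    rand = lo_start[..., None] + (hi - lo_start)[..., None] * unif
    starts = np.concatenate([grid, rand], axis=3)              # (d, S, nk, ns)
    ns = starts.shape[3]

    m = S * nk * ns
    Z0 = starts.reshape(d, m)
    sidx = np.repeat(np.arange(S), nk * ns)
    kflat = np.tile(np.repeat(anchors, ns), S)
    hib = np.repeat(hi.reshape(d, S * nk), ns, axis=1)
    lob = hib - np.log(1e14)
    Z, fnorm = _newton(reduced, Z0, kflat, sidx, lob, hib, options)
    conv = (fnorm <= options.newton_tol).reshape(S, nk, ns)
    Zr = Z.reshape(d, S, nk, ns)

    # scatter anchor results into the full dose grid
    roots = [[[] for _ in range(nk_all)] for _ in range(S)]
    for s in range(S):
        for j, ik in enumerate(anchor_idx):
            roots[s][ik] = _cluster_columns(Zr[:, s, j, conv[s, j]], 1e-6)

    if options.warm_start and nk_all > 1:
        cols_Z, cols_k, cols_s, cols_ik = [], [], [], []
        for s in range(S):
            flat_roots = [r for per_dose in roots[s] for r in per_dose]
            if not flat_roots:
                continue
            W = _cluster_columns(np.stack(flat_roots, axis=1), 1e-4)
            for w in W:
                cols_Z.append(np.repeat(w[:, None], nk_all, axis=1))
                cols_k.append(ktot_vals)
                cols_s.append(np.full(nk_all, s))
                cols_ik.append(np.arange(nk_all))
        if cols_Z:
            Z0w = np.concatenate(cols_Z, axis=1)
            kw = np.concatenate(cols_k)
            sw = np.concatenate(cols_s)
            ikw = np.concatenate(cols_ik)
            hiw = np.empty((d, len(kw)))
            hiw[0] = np.log(kw)
            hiw[1] = np.log(reduced.P_tot)[sw]
            if scaffold:
                hiw[2] = np.log(reduced.B_tot)[sw]
            low = hiw - np.log(1e14)
            Zw, fw = _newton(reduced, Z0w, kw, sw, low, hiw, options)
            okw = fw <= options.newton_tol
            for s in range(S):
                for ik in range(nk_all):
                    sel = okw & (sw == s) & (ikw == ik)
                    if not np.any(sel):
                        continue
                    merged = roots[s][ik] + _cluster_columns(Zw[:, sel], 1e-6)
                    roots[s][ik] = _cluster_columns(np.stack(merged, axis=1), 1e-6)
    return reduced, roots


def _sweep_ma(config: ModelConfig, params: ParameterSet, ktot_grid: np.ndarray,
              options: SolverOptions) -> list[SteadyStateSet]:
    ktot_vals = np.asarray(ktot_grid, dtype=float)
    method = "newton_3var" if config.scaffold else "newton_2var"
    reduced, roots = _ma_roots_batch(config, [params], ktot_vals, options)
    nk = len(ktot_vals)
    out: list[SteadyStateSet] = []
    names = species_order(config)
    # MA rate constants do not involve K_tot: one system serves the sweep
    system = MassActionSystem(build_network(config), params.rate_map(config))
    n_laws = _n_laws(config)
    basis = _stoich_basis(system)
    for ik, ktot in enumerate(ktot_vals):
        reps = roots[0][ik]
        if not reps:
            logger.warning("solver_failure: no Newton start converged (K_tot=%.3g)", ktot)
            out.append(_empty_set(config, method, "no Newton start converged"))
            continue
        Zi = np.stack(reps, axis=1)
        kcol = np.full(Zi.shape[1], ktot)
        zeros = np.zeros(Zi.shape[1], dtype=int)
        states = reduced.lift(Zi, kcol, zeros)
        keep = _dedupe_states(states, options.dedupe_tol)
        states = states[keep]
        res = np.max(np.abs(reduced.residual(Zi[:, keep], kcol[: len(keep)], zeros[: len(keep)])))
        messages: list[str] = []
        stable, eigs = _label_states(system, n_laws, states, messages, basis)
        out.append(SteadyStateSet(
            species=names, states=states, stable=stable, eigvals=eigs,
            residual_norm=max(_rhs_residual(system, states), float(res)),
            method=method, messages=messages))
    return out


def ma_screen_sweep(config: ModelConfig, params_list: Sequence[ParameterSet],
                    ktot_grid: Sequence[float],
                    options: SolverOptions = SCREEN_OPTIONS):
    """Stable-readout branches for many parameter sets in one batched run.

    The workhorse of the screens: returns ``(values, failures)`` where
    ``values[s][ik]`` is the array of stable readout values of set ``s`` at
    dose ``ik`` and ``failures[s]`` counts dose points with no converged
    root.  Equivalent to calling :func:`sweep_states` per set (same Newton
    protocol) but amortizes the vectorized work across sets.
    """
    ktot_vals = np.asarray(ktot_grid, dtype=float)
    params_list = list(params_list)
    reduced, roots = _ma_roots_batch(config, params_list, ktot_vals, options)
    S, nk = len(params_list), len(ktot_vals)
    names = species_order(config)
    ridx = np.array([names.index(s) for s in sorted(readout(config))])
    n_laws = _n_laws(config)

    # lift every root of every (set, dose) in one batched call
    cols_Z, cols_k, cols_s, group = [], [], [], []
    for s in range(S):
        for ik in range(nk):
            for r in roots[s][ik]:
                cols_Z.append(r)
                cols_k.append(ktot_vals[ik])
                cols_s.append(s)
                group.append((s, ik))
    values = [[np.zeros(0) for _ in range(nk)] for _ in range(S)]
    failures = [0] * S
    if not cols_Z:
        return values, [nk] * S
    Zall = np.stack(cols_Z, axis=1)
    kall = np.array(cols_k)
    sall = np.array(cols_s, dtype=int)
    states_all = reduced.lift(Zall, kall, sall)

    basis = None
    for s in range(S):
        mask = sall == s
        if not np.any(mask):
            failures[s] = nk
            continue
        system = MassActionSystem(build_network(config),
                                  params_list[s].rate_map(config))
        if basis is None:
            basis = _stoich_basis(system)
        st_s = states_all[mask]
        grp_s = [group[i] for i in np.where(mask)[0]]
        # dedupe within each dose group
        keep_rows, keep_grp = [], []
        for ik in range(nk):
            rows = [i for i, gkk in enumerate(grp_s) if gkk[1] == ik]
            if not rows:
                failures[s] += 1
                continue
            sub = st_s[rows]
            keep = _dedupe_states(sub, options.dedupe_tol)
            keep_rows.extend(rows[k] for k in keep)
            keep_grp.extend(ik for _ in keep)
        st_kept = st_s[keep_rows]
        messages: list[str] = []
        stable, _ = _label_states(system, n_laws, st_kept, messages, basis)
        reads = st_kept[:, ridx].sum(axis=1)
        for ik in range(nk):
            sel = [i for i, g2 in enumerate(keep_grp) if g2 == ik]
            if sel:
                values[s][ik] = reads[sel][stable[sel]]
    return values, failures


def solve_ma(config: ModelConfig, params: ParameterSet, ktot: Optional[float] = None,
             options: SolverOptions = SolverOptions()) -> SteadyStateSet:
    """All steady states of a full mass-action model at one K_tot, via damped
    Newton on the (K, P[, B]) reduced system from many starting points."""
    if config.kinetics != "MA":
        raise ConfigurationError("solve_ma requires kinetics='MA'")
    ktot = params.K_tot if ktot is None else float(ktot)
    return _sweep_ma(config, params, np.array([ktot]), replace(options, warm_start=False))[0]


def solve(config: ModelConfig, params: ParameterSet, ktot: Optional[float] = None,
          options: SolverOptions = SolverOptions()) -> SteadyStateSet:
    """Dispatch to the family-specific steady-state solver."""
    if config.kinetics == "LR":
        if config.scaffold:
            return solve_lr_s(config, params, ktot, options)
        return solve_lr_ns(config, params, ktot)
    return solve_ma(config, params, ktot, options)


def sweep_states(config: ModelConfig, params: ParameterSet, ktot_grid: Sequence[float],
                 options: SolverOptions = SolverOptions()) -> list[SteadyStateSet]:
    """Steady states at every K_tot of a dose grid (batched across the grid)."""
    grid = np.asarray(ktot_grid, dtype=float)
    if config.kinetics == "LR":
        if config.scaffold:
            return _sweep_lr_s(config, params, grid, options)
        return [solve_lr_ns(config, params, k) for k in grid]
    return _sweep_ma(config, params, grid, options)


# ---------------------------------------------------------------------------
# integration oracle
# ---------------------------------------------------------------------------


def integrate_to_steady_state(config: ModelConfig, params: ParameterSet,
                              init: Mapping[str, float] | np.ndarray,
                              ktot: Optional[float] = None,
                              t_max: float = 1e10, tol: float = 1e-9):
    """Stiff integration of the full ODE system until max|dx/dt|/max(x) < tol.

    Returns ``(state, converged)`` in the species order of the built network.
    Used as the independent oracle for the algebraic solvers.
    """
    net = build_network(config)
    system = MassActionSystem(net, params.rate_map(config, ktot))
    if isinstance(init, Mapping):
        x = np.array([float(init.get(s, 0.0)) for s in net.species])
    else:
        x = np.asarray(init, dtype=float).copy()
    scale = max(params.A_tot, params.B_tot, params.P_tot, params.K_tot)

    # the raw polynomial RHS is smooth through zero; clipping it would put a
    # derivative discontinuity exactly where stiff trajectories graze the
    # boundary and stall the integrator
    def fun(t, y):
        return system.rhs(y)

    def jac(t, y):
        return system.jacobian(np.abs(y) + 1e-30 * scale)

    basis = _stoich_basis(system)

    def polish(x0):
        """Full-dimension damped Newton on the stoichiometric class; only
        attempted once integration is already near the attractor."""
        y = x0.copy()
        fy = system.rhs(y)
        for _ in range(50):
            norm = np.max(np.abs(fy)) / max(np.max(y), 1e-300)
            if norm < tol:
                return y, True
            J_red = basis.T @ system.jacobian(np.abs(y) + 1e-30 * scale) @ basis
            try:
                delta = basis @ np.linalg.solve(J_red, -(basis.T @ fy))
            except np.linalg.LinAlgError:
                return x0, False
            step = 1.0
            for _ in range(40):
                cand = y + step * delta
                if np.all(cand >= 0):
                    fc = system.rhs(cand)
                    if np.max(np.abs(fc)) < np.max(np.abs(fy)):
                        y, fy = cand, fc
                        break
                step *= 0.5
            else:
                return x0, False
        return x0, False

    t_window = 100.0
    t_done = 0.0
    while t_done < t_max:
        span = min(t_window, t_max - t_done)
        # t_eval at the endpoint only: long windows may take many steps and
        # the trajectory itself is never needed
        sol = solve_ivp(fun, (0.0, span), x, method="BDF", jac=jac,
                        rtol=1e-7, atol=1e-11 * scale, t_eval=[span])
        x = np.clip(sol.y[:, -1], 0.0, None)
        t_done += span
        rate = np.max(np.abs(system.rhs(x))) / max(np.max(x), 1e-300)
        if rate < tol:
            return x, True
        if rate < 1e-3:
            # inside the attractor's quadratic basin: sharpen by Newton
            # rather than grinding stiff integrator steps at a fixed point;
            # accepted only if the correction stays microscopic, so the
            # basin choice is still made entirely by the integration
            y, ok = polish(x)
            if ok and np.max(np.abs(y - x)) <= 1e-2 * max(np.max(x), 1e-300):
                return y, True
        t_window *= 10.0
    logger.warning("integrate_to_steady_state: not converged by t_max=%.3g", t_max)
    return x, False


def random_initial_state(config: ModelConfig, params: ParameterSet,
                         rng: np.random.Generator) -> np.ndarray:
    """A random state satisfying all conservation totals: substrate spread
    over phosphoforms (Dirichlet), a random fraction scaffold-bound, free
    enzymes."""
    names = species_order(config)
    idx = {s: i for i, s in enumerate(names)}
    n = config.n_sites
    x = np.zeros(len(names))
    frac = rng.dirichlet(np.ones(n + 1)) * params.A_tot
    if config.scaffold:
        bound_cap = min(1.0, params.B_tot / params.A_tot)
        u = rng.random(n + 1) * bound_cap
        bound = u * frac
        x[[idx[f"S{i}_B"] for i in range(n + 1)]] = bound
        x[[idx[f"S{i}"] for i in range(n + 1)]] = frac - bound
        x[idx["B"]] = params.B_tot - bound.sum()
    else:
        x[[idx[f"S{i}"] for i in range(n + 1)]] = frac
    if config.kinetics == "MA":
        x[idx["K"]] = params.K_tot
        x[idx["P"]] = params.P_tot
    return x
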