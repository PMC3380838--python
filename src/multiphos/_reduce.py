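"""Linear steady-state solvers for the phosphoform ladder.

At fixed free-enzyme and free-scaffold concentrations every remaining
species is linear: the substrate occupies a ladder of 2(n+1) states (free
phosphoforms S_0..S_n and bound T_i = S_i:B) connected by first-order
effective conversions

    u_i  : T_i -> T_{i+1}   (phosphorylation on scaffold)
    uo_i : S_i -> S_{i+1}   (phosphorylation off scaffold)
    w_i  : T_i -> T_{i-1}   (dephosphorylation on scaffold)
    v_i  : S_i -> S_{i-1}   (dephosphorylation off scaffold)
    p_i  : S_i -> T_i       (binding, alpha_i * B)
    q_i  : T_i -> S_i       (unbinding, beta_i)

and its steady state is the unique positive null vector of the resulting
generator.  For the standard topology (phosphorylation on-scaffold only)
the null vector admits an exact backward recursion computed here in log
space, which is overflow-proof over many orders of magnitude of rates; a
dense batched null-space solve covers arbitrary topologies.

All level arrays are stacked on axis 0; any trailing axes are batch axes.
Step arrays (u, uo, v, w) have n rows (step i at row i for phosphorylation
and step i+1 at row i for dephosphorylation); level arrays (p, q and the
returned log-concentrations) have n+1 rows.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    njit = None

__all__ = ["ladder_steady_log", "chain_steady_log", "ladder_steady_dense"]


def ladder_steady_log(u, v, w, p, q):
    """Unnormalized steady state of the ladder with on-scaffold
    phosphorylation only (uo = 0), as log-concentrations.

    Parameters are broadcastable arrays: ``u`` (n, ...) strictly positive;
    ``v``, ``w`` (n, ...) non-negative with v + w > 0 per step; ``p``, ``q``
    (n+1, ...) strictly positive.  Returns ``(lnS, lnT)`` of shape
    (n+1, ...), defined up to a common additive constant.

    Derivation: the net flux through the cut between phospho-levels i and
    i+1 vanishes at steady state (u_i T_i = v_{i+1} S_{i+1} + w_{i+1}
    T_{i+1}), and the per-level free-substrate balance closes the
    recursion from the top level downward.  All summands are positive, so
    the recursion is cancellation-free.
    """
    shapes = [np.shape(a) for a in (u, v, w, p, q)]
    n = shapes[0][0]
    batch = np.broadcast_shapes(*(s[1:] for s in shapes))
    def prep(a, rows):
        a = np.asarray(a, dtype=float)
        if a.shape == (rows,) + batch and a.flags.c_contiguous:
            return a
        return np.ascontiguousarray(np.broadcast_to(a, (rows,) + batch))

    u, v, w = prep(u, n), prep(v, n), prep(w, n)
    p, q = prep(p, n + 1), prep(q, n + 1)
    if _ladder_kernel is not None and len(batch) == 1:
        return _ladder_kernel(u, v, w, p, q)
    return _ladder_numpy(u, v, w, p, q)


def _ladder_numpy(u, v, w, p, q):
    n = u.shape[0]
    batch = u.shape[1:]
    lnS = np.empty((n + 1,) + batch)
    lnT = np.empty((n + 1,) + batch)
    # top level: S_n balance  (p_n + v_n) S_n = q_n T_n
    lnS[n] = 0.0
    lnT[n] = np.log(p[n] + v[n - 1]) - np.log(q[n])
    for i in range(n - 1, -1, -1):
        # cut i:  u_i T_i = v_{i+1} S_{i+1} + w_{i+1} T_{i+1}
        m = np.maximum(lnS[i + 1], lnT[i + 1])
        acc = v[i] * np.exp(lnS[i + 1] - m) + w[i] * np.exp(lnT[i + 1] - m)
        lnT[i] = m + np.log(acc) - np.log(u[i])
        # level i free balance:  (p_i + v_i) S_i = q_i T_i + v_{i+1} S_{i+1}
        m2 = np.maximum(lnT[i], lnS[i + 1])
        acc2 = q[i] * np.exp(lnT[i] - m2) + v[i] * np.exp(lnS[i + 1] - m2)
        denom = p[i] + (v[i - 1] if i >= 1 else 0.0)
        lnS[i] = m2 + np.log(acc2) - np.log(denom)
    return lnS, lnT


if njit is not None:

    @njit(cache=True, fastmath=True)
    def _ladder_kernel(u, v, w, p, q):  # pragma: no cover - exercised via wrapper
        n = u.shape[0]
        m = u.shape[1]
        lnS = np.empty((n + 1, m))
        lnT = np.empty((n + 1, m))
        for j in range(m):
            lnS[n, j] = 0.0
            lnT[n, j] = np.log(p[n, j] + v[n - 1, j]) - np.log(q[n, j])
            for i in range(n - 1, -1, -1):
                a = lnS[i + 1, j]
                b = lnT[i + 1, j]
                mx = a if a > b else b
                acc = v[i, j] * np.exp(a - mx) + w[i, j] * np.exp(b - mx)
                lnT[i, j] = mx + np.log(acc) - np.log(u[i, j])
                c = lnT[i, j]
                mx2 = c if c > a else a
                acc2 = q[i, j] * np.exp(c - mx2) + v[i, j] * np.exp(a - mx2)
                denom = p[i, j] + (v[i - 1, j] if i >= 1 else 0.0)
                lnS[i, j] = mx2 + np.log(acc2) - np.log(denom)
        return lnS, lnT

else:  # pragma: no cover
    _ladder_kernel = None


def chain_steady_log(uo, v):
    """Unnormalized steady state of the single chain S_0..S_n (no scaffold
    compartment): ln S_{i+1} = ln S_i + ln uo_i - ln v_{i+1}.

    ``uo`` and ``v`` have shape (n, ...), strictly positive.
    """
    uo = np.asarray(uo, dtype=float)
    v = np.asarray(v, dtype=float)
    n = uo.shape[0]
    batch = np.broadcast_shapes(uo.shape[1:], v.shape[1:])
    lnS = np.empty((n + 1,) + batch)
    lnS[0] = 0.0
    ratios = np.log(uo) - np.log(v)
    np.cumsum(np.broadcast_to(ratios, (n,) + batch), axis=0, out=lnS[1:])
    return lnS


def ladder_steady_dense(uo, u, v, w, p, q):
    """Steady state of the general ladder by a batched dense null-space
    solve; returns ``(S, T)`` of shape (n+1, ...) normalized to sum 1.

    Any of ``uo``, ``u``, ``v``, ``w`` may be zero arrays; ``p``, ``q``
    must be strictly positive so the ladder is irreducible.
    """
    arrs = [np.asarray(a, dtype=float) for a in (uo, u, v, w, p, q)]
    uo, u, v, w, p, q = arrs
    n = p.shape[0] - 1
    batch = np.broadcast_shapes(*(a.shape[1:] for a in arrs))
    m = 2 * (n + 1)
    M = np.zeros(batch + (m, m))

    def add(rate, src, dst):
        r = np.broadcast_to(rate, batch)
        M[..., dst, src] += r
        M[..., src, src] -= r

    for i in range(n + 1):
        add(p[i], i, n + 1 + i)           # S_i -> T_i
        add(q[i], n + 1 + i, i)           # T_i -> S_i
    for i in range(n):
        if np.any(uo):
            add(uo[i], i, i + 1)          # S_i -> S_{i+1}
        if np.any(u):
            add(u[i], n + 1 + i, n + 2 + i)
        if np.any(v):
            add(v[i], i + 1, i)           # S_{i+1} -> S_i
        if np.any(w):
            add(w[i], n + 2 + i, n + 1 + i)
    # replace the first balance row (redundant) by the normalization sum = 1
    M[..., 0, :] = 1.0
    rhs = np.zeros(batch + (m,))
    rhs[..., 0] = 1.0
    x = np.linalg.solve(M, rhs[..., None])[..., 0]
    x = np.clip(x, 0.0, None)
    x = x / np.sum(x, axis=-1, keepdims=True)
    S = np.moveaxis(x[..., : n + 1], -1, 0)
    T = np.moveaxis(x[..., n + 1 :], -1, 0)
    return S, T
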