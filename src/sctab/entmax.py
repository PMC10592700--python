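"""Exact 1.5-entmax transform and its vector-Jacobian product.

The 1.5-entmax maps a score vector ``z`` to a probability vector by maximizing

    p* = argmax_{p in simplex}  p.z + H_1.5(p),
    H_1.5(p) = (1 / (1.5 * 0.5)) * sum_j (p_j - p_j**1.5)

i.e. the Tsallis entropy with alpha = 1.5. Unlike softmax the maximizer can be
exactly sparse: coordinates whose score falls far enough below the maximum get
probability exactly zero. The solution has the closed form

    p_j = [ (z_j / 2 - tau)_+ ]^2

with the threshold tau fixed by sum_j p_j = 1, which a sort over z locates
exactly (Peters & Martins' sorting algorithm specialized to alpha = 1.5).

`entmax15_oracle` solves the variational problem directly with a constrained
numerical optimizer; it is deliberately independent of the sorting algorithm
and exists so tests can cross-check the exact routine.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "entmax15",
    "entmax15_vjp",
    "entmax15_oracle",
    "tsallis_entropy_15",
    "sparsemax",
]


def _validate(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if z.size == 0:
        raise ValueError("entmax15 requires a non-empty score vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("entmax15 requires finite scores (got NaN or Inf)")
    return z


def entmax15(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Exact 1.5-entmax along ``axis``.

    Parameters
    ----------
    z
        Array of unconstrained scores; the transform is applied along ``axis``.

    Returns
    -------
    Array of the same shape with non-negative entries summing to one along
    ``axis``; entries may be exactly zero. Shift-invariant along ``axis``.
    """
    z = _validate(z)
    one_dim = z.ndim == 1
    z = np.moveaxis(np.atleast_2d(z), axis if not one_dim else -1, -1)
    orig_shape = z.shape
    z2 = z.reshape(-1, orig_shape[-1])

    # work on s = z/2, shifted so max(s) = 0 for numerical stability
    s = z2 / 2.0
    s = s - s.max(axis=-1, keepdims=True)
    s_sorted = -np.sort(-s, axis=-1)  # descending, stable enough: ties equal

    d = s.shape[-1]
    k = np.arange(1, d + 1, dtype=np.float64)
    mean = np.cumsum(s_sorted, axis=-1) / k
    mean_sq = np.cumsum(s_sorted**2, axis=-1) / k
    ss = k * (mean_sq - mean**2)
    delta = (1.0 - ss) / k
    # numerical guard: delta is >= 0 on the valid prefix
    delta_ok = np.clip(delta, 0.0, None)
    tau = mean - np.sqrt(delta_ok)

    # support size = largest k with tau_k <= s_(k)
    support = (tau <= s_sorted).sum(axis=-1)
    idx = support - 1
    tau_star = np.take_along_axis(tau, idx[:, None], axis=-1)

    p = np.clip(s - tau_star, 0.0, None) ** 2
    # renormalize away accumulated floating point error (sum is 1 up to ~1e-15)
    p /= p.sum(axis=-1, keepdims=True)
    p = p.reshape(orig_shape)
    if one_dim:
        return p[0]
    return np.moveaxis(p, -1, axis)


def entmax15_vjp(p: np.ndarray, upstream: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vector-Jacobian product of 1.5-entmax at an output ``p``.

    For the support S = {j : p_j > 0} the Jacobian is
    ``diag(g) - g g^T / sum(g)`` with ``g_j = sqrt(p_j)`` on S and 0 off S,
    so excluded coordinates receive exactly zero gradient.
    """
    p = np.asarray(p, dtype=np.float64)
    upstream = np.asarray(upstream, dtype=np.float64)
    g = np.sqrt(p)
    vg = upstream * g
    corr = vg.sum(axis=axis, keepdims=True) / g.sum(axis=axis, keepdims=True)
    return g * (upstream - corr)


def tsallis_entropy_15(p: np.ndarray) -> float:
    """Tsallis entropy H_1.5(p) = (1/0.75) * sum_j (p_j - p_j^1.5)."""
    p = np.asarray(p, dtype=np.float64)
    return float(np.sum(p - p**1.5) / (1.5 * 0.5))


def entmax15_oracle(z: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Numerically maximize p.z + H_1.5(p) over the simplex (test oracle).

    Uses SLSQP with the simplex constraints; independent of the exact
    sorting-based routine. Intended for small dimensions (<= ~10).
    """
    z = _validate(z).ravel()
    d = z.size
    if d == 1:
        return np.array([1.0])

    def neg_obj(p):
        return -(p @ z + np.sum(p - np.clip(p, 0, None) ** 1.5) / 0.75)

    def neg_grad(p):
        return -(z + (1.0 - 1.5 * np.sqrt(np.clip(p, 0, None))) / 0.75)

    best = None
    # multiple starts: uniform plus vertices near the top scores
    starts = [np.full(d, 1.0 / d)]
    order = np.argsort(-z)
    for k in (1, 2, d):
        p0 = np.zeros(d)
        p0[order[:k]] = 1.0 / k
        starts.append(p0)
    for p0 in starts:
        res = minimize(
            neg_obj,
            p0,
            jac=neg_grad,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * d,
            constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                          "jac": lambda p: np.ones_like(p)}],
            options={"maxiter": 500, "ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    p = np.clip(best.x, 0.0, None)
    return p / p.sum()


def sparsemax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Sparsemax (alpha = 2 entmax), provided as a test comparator only."""
    z = _validate(z)
    one_dim = z.ndim == 1
    z = np.moveaxis(np.atleast_2d(z), axis if not one_dim else -1, -1)
    shape = z.shape
    z2 = z.reshape(-1, shape[-1])
    z_sorted = -np.sort(-z2, axis=-1)
    k = np.arange(1, shape[-1] + 1, dtype=np.float64)
    cs = np.cumsum(z_sorted, axis=-1)
    support = ((1.0 + k * z_sorted) > cs).sum(axis=-1)
    idx = support - 1
    tau = (np.take_along_axis(cs, idx[:, None], axis=-1) - 1.0) / support[:, None]
    p = np.clip(z2 - tau, 0.0, None).reshape(shape)
    if one_dim:
        return p[0]
    return np.moveaxis(p, -1, axis)
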