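"""Independent brute-force oracles used to cross-check the production code.

Everything here is deliberately naive (dense matrices, voxel loops,
brute-force scans) and shares no code with the package's own
implementations.
"""

from __future__ import annotations

from itertools import product

import numpy as np

import petbench as pb
from petbench.acquisition import system_matrix


def erode_min_filter(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Erosion as an explicit voxelwise min filter over the 3^ndim box."""
    out = np.asarray(mask, dtype=bool).copy()
    for _ in range(iterations):
        padded = np.pad(out, 1, constant_values=False)
        new = np.ones_like(out)
        for off in product((0, 1, 2), repeat=out.ndim):
            sl = tuple(slice(o, o + n) for o, n in zip(off, out.shape))
            new &= padded[sl]
        out = new
    return out


def dense_matrix(geom: pb.ProjectorGeometry) -> np.ndarray:
    """Dense copy of the projector (fine for tiny instances only)."""
    return system_matrix(geom).toarray()


def central_diff_grad(f, x0: np.ndarray, h: float) -> np.ndarray:
    """Central finite differences of a scalar function of a flat array."""
    g = np.zeros_like(x0, dtype=float)
    for i in range(x0.size):
        xp = x0.copy()
        xm = x0.copy()
        xp.flat[i] += h
        xm.flat[i] -= h
        g.flat[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def dense_loglik_hessian(
    x: np.ndarray,
    y: np.ndarray,
    geom: pb.ProjectorGeometry,
    factors: pb.AcquisitionFactors,
) -> np.ndarray:
    """Explicit Hessian of the Poisson log-likelihood at image x.

    H = -A^T diag(m^2 y / ybar^2) A over live bins (m > 0).
    """
    a = dense_matrix(geom)
    m = factors.m.values.ravel()
    add = factors.a.values.ravel()
    ybar = m * (a @ x.ravel() + add)
    w = np.zeros_like(ybar)
    live = m > 0
    w[live] = m[live] ** 2 * y.ravel()[live] / ybar[live] ** 2
    return -(a.T * w) @ a


def projected_gradient_ascent(
    y, geom, factors, prior, x0, mask, max_iters=5000, tol=1e-12
):
    """Generic projected gradient ascent with backtracking line search.

    Independent long-run oracle for the MAP optimum: ascends Psi with an
    Armijo backtracking step, projecting onto the constraint set after each
    trial, until the objective stalls.
    """
    x = np.where(mask, np.maximum(x0.values, 0.0), 0.0)
    img = lambda v: x0.with_values(v)
    f = lambda v: pb.objective(img(v), y, geom, factors, prior).total
    fx = f(x)
    g = pb.full_grad(img(x), y, geom, factors, prior).values
    step = 1.0 / max(np.linalg.norm(g), 1e-30)
    stalled = 0
    for _ in range(max_iters):
        g = pb.full_grad(img(x), y, geom, factors, prior).values
        accepted = False
        s = step * 4.0
        for _ in range(60):
            trial = np.where(mask, np.maximum(x + s * g, 0.0), 0.0)
            ft = f(trial)
            if ft >= fx + 1e-4 * np.vdot(g, trial - x) and ft >= fx:
                gain = ft - fx
                x, fx, step, accepted = trial, ft, s, True
                break
            s *= 0.5
        if not accepted:
            break
        stalled = stalled + 1 if gain <= tol * max(abs(fx), 1.0) else 0
        if stalled >= 5:
            break
    return img(x), fx


def pass_time_bruteforce(times, passes, persistence, cap):
    """Literal re-statement of the pass-time rule: scan every start index."""
    n = len(times)
    candidates = []
    for i in range(n):
        if i + persistence > n:
            break
        window_ok = all(passes[i : i + persistence])
        in_cap = times[i + persistence - 1] <= cap
        if window_ok and in_cap:
            candidates.append(times[i])
    if candidates:
        return candidates[0], False
    return cap, True


def rank_bruteforce(cells: dict, algos: list[str], cap: float):
    """Per-cell ranks from first principles: count strictly-slower algorithms.

    ``cells`` maps cell id -> {algo: [times (cap if censored)]}.  Rank of
    algorithm a in a cell is 1 + (#strictly slower) + (#ties - 1)/2, which
    equals the average-of-tied-positions convention with slowest = 1.
    """
    out = {}
    for cell, per_algo in cells.items():
        med = {a: float(np.median(np.clip(per_algo[a], None, cap))) for a in algos}
        ranks = {}
        for a in algos:
            slower = sum(1 for b in algos if med[b] > med[a])
            ties = sum(1 for b in algos if med[b] == med[a])
            ranks[a] = 1.0 + slower + (ties - 1) / 2.0
        out[cell] = ranks
    return out
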