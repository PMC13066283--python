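"""Penalised-likelihood (MAP) objective for PET reconstruction.

The objective being maximised over the constraint set C (non-negative
inside the support mask, zero outside) is

    Psi(x; y) = L(y; ybar(x)) - beta * R(x)

with the Poisson log-likelihood, up to image-independent terms,

    L(y; ybar) = sum_k  y_k log(ybar_k) - ybar_k

(bins with m_k = 0 contribute exactly zero) and the smoothed relative
difference prior

    R(x) = 1/2 sum_i sum_{j in N_i} w_ij kappa_i kappa_j
           (x_i - x_j)^2 / (x_i + x_j + gamma |x_i - x_j| + epsilon).

The neighbourhood N_i is the 8 in-plane neighbours in 2-D and the 26
nearest neighbours in 3-D; the weight w_ij is the horizontal voxel pitch
divided by the Euclidean inter-voxel distance, so direct in-plane
neighbours have weight 1 on an isotropic grid.  kappa makes the effective
regularisation strength spatially uniform and is derived from the
likelihood's Hessian row-sums at an initial OSEM image; epsilon keeps the
prior differentiable where neighbours are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .acquisition import (
    AcquisitionFactors,
    ProjectionData,
    ProjectorGeometry,
    SubsetScheme,
    back_project,
    forward_project,
    predict,
    subset_back,
    subset_forward,
)
from .grids import ImageVolume

__all__ = [
    "PriorParams",
    "ObjectiveValue",
    "loglik",
    "loglik_grad",
    "rdp_value",
    "rdp_grad",
    "kappa_from_osem",
    "epsilon_from_osem",
    "objective",
    "subset_grad",
    "full_grad",
    "neighbour_offsets",
]


@dataclass(frozen=True)
class PriorParams:
    """Parameters of ``beta * R(x)``.

    ``beta`` trades data fit against smoothness; ``gamma`` (default 2)
    controls edge preservation; ``epsilon > 0`` smooths the penalty at
    equal neighbours; ``kappa`` is the voxel-dependent weight image.
    """

    beta: float
    kappa: ImageVolume
    gamma: float = 2.0
    epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if np.any(self.kappa.values < 0):
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class ObjectiveValue:
    """Decomposed objective: total = loglik - beta * prior."""

    loglik: float
    prior: float
    beta: float

    @property
    def total(self) -> float:
        return self.loglik - self.beta * self.prior


def neighbour_offsets(ndim: int) -> list[tuple[int, ...]]:
    """All nonzero offsets in {-1,0,1}^ndim: 8 neighbours in 2-D, 26 in 3-D."""
    return [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]


def _pair_slices(shape: tuple[int, ...], off: tuple[int, ...]):
    """Slices (si, sj) so x[si] pairs with its neighbour x[sj] at offset off."""
    si = tuple(
        slice(max(0, -o), n - max(0, o)) for o, n in zip(off, shape)
    )
    sj = tuple(
        slice(max(0, o), n - max(0, -o)) for o, n in zip(off, shape)
    )
    return si, sj


def _offset_weight(off: tuple[int, ...], voxel_size: tuple[float, ...]) -> float:
    dist = float(np.sqrt(sum((o * v) ** 2 for o, v in zip(off, voxel_size))))
    return voxel_size[0] / dist


def rdp_value(x: ImageVolume, p: PriorParams) -> float:
    """Smoothed relative-difference penalty R(x) >= 0; zero on constants."""
    if np.any(x.values < 0):
        raise ValueError("RDP requires a non-negative image")
    if not x.same_grid(p.kappa):
        raise ValueError("kappa must share the image grid")
    xv, kv = x.values, p.kappa.values
    total = 0.0
    for off in neighbour_offsets(x.ndim):
        si, sj = _pair_slices(x.shape, off)
        xi, xj = xv[si], xv[sj]
        d = xi - xj
        denom = xi + xj + p.gamma * np.abs(d) + p.epsilon
        w = _offset_weight(off, x.voxel_size)
        total += w * float(np.sum(kv[si] * kv[sj] * d * d / denom))
    return 0.5 * total


def rdp_grad(x: ImageVolume, p: PriorParams) -> ImageVolume:
    """Analytic gradient of :func:`rdp_value` with respect to x."""
    if np.any(x.values < 0):
        raise ValueError("RDP requires a non-negative image")
    if not x.same_grid(p.kappa):
        raise ValueError("kappa must share the image grid")
    xv, kv = x.values, p.kappa.values
    grad = np.zeros_like(xv)
    for off in neighbour_offsets(x.ndim):
        si, sj = _pair_slices(x.shape, off)
        xi, xj = xv[si], xv[sj]
        d = xi - xj
        denom = xi + xj + p.gamma * np.abs(d) + p.epsilon
        # d/dxi [ d^2/denom ] with denom = xi+xj+gamma|d|+eps
        num = 2.0 * d * denom - d * d * (1.0 + p.gamma * np.sign(d))
        w = _offset_weight(off, x.voxel_size)
        grad[si] += w * kv[si] * kv[sj] * num / denom**2
    return x.with_values(grad)


def loglik(
    y: ProjectionData, ybar: ProjectionData, factors: AcquisitionFactors
) -> float:
    """Poisson log-likelihood sum_k y_k log(ybar_k) - ybar_k over live bins.

    Virtual-crystal bins (m = 0) contribute exactly zero; live bins with
    y = 0 contribute -ybar.  A zero expectation at a live bin with a
    recorded count signals a broken model (the background must be positive
    there) and raises.
    """
    live = factors.live
    yv = y.values[live]
    yb = ybar.values[live]
    bad = (yb <= 0) & (yv > 0)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} live bins have zero expectation but recorded "
            "counts; additive background must be strictly positive there"
        )
    out = -float(np.sum(yb))
    pos = yv > 0
    out += float(np.sum(yv[pos] * np.log(yb[pos])))
    return out


def _ratio_term(
    y: np.ndarray, ybar: np.ndarray, factors: AcquisitionFactors
) -> np.ndarray:
    """m * (y/ybar - 1) with virtual bins exactly zero."""
    live = factors.live if y.shape == factors.m.values.shape else None
    m = factors.m.values
    out = np.zeros_like(ybar)
    mask = m > 0 if live is None else live
    yb = ybar[mask]
    if np.any(yb <= 0):
        raise ValueError("zero expectation at a live bin")
    out[mask] = m[mask] * (y[mask] / yb - 1.0)
    return out


def loglik_grad(
    x: ImageVolume,
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
) -> ImageVolume:
    """Gradient of the log-likelihood: A^T [ m (y/ybar - 1) ]."""
    ybar = predict(x, geom, factors)
    g = _ratio_term(y.values, ybar.values, factors)
    return back_project(ProjectionData(g, geom), geom)


def _subset_loglik_grad(
    x: ImageVolume,
    views: tuple[int, ...],
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
) -> ImageVolume:
    """A_s^T [ m_s (y_s/ybar_s - 1) ] for one angular subset."""
    v = list(views)
    ax = subset_forward(x, geom, views)
    m_s = factors.m.values[..., v, :]
    a_s = factors.a.values[..., v, :]
    y_s = y.values[..., v, :]
    ybar_s = m_s * (ax + a_s)
    out = np.zeros_like(ybar_s)
    live = m_s > 0
    yb = ybar_s[live]
    if np.any(yb <= 0):
        raise ValueError("zero expectation at a live bin")
    out[live] = m_s[live] * (y_s[live] / yb - 1.0)
    return subset_back(out, geom, views)


def subset_grad(
    x: ImageVolume,
    subset_index: int,
    scheme: SubsetScheme,
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    p: PriorParams,
) -> ImageVolume:
    """Subset objective gradient: n_subsets * grad L_s(x) - beta * grad R(x).

    The likelihood term is upscaled by the subset count so the average over
    all subsets equals the full gradient of Psi exactly; the prior gradient
    is carried in full at every update.
    """
    if not (0 <= subset_index < scheme.n_subsets):
        raise ValueError(f"subset index {subset_index} out of range")
    gl = _subset_loglik_grad(x, scheme.subsets[subset_index], y, geom, factors)
    gr = rdp_grad(x, p)
    return x.with_values(scheme.n_subsets * gl.values - p.beta * gr.values)


def kappa_from_osem(
    x_osem: ImageVolume,
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
) -> ImageVolume:
    """Prior weight map: sqrt of minus the likelihood-Hessian row sums.

    With H = -A^T diag(m^2 y / ybar^2) A evaluated at the OSEM image,
    kappa = sqrt( A^T [ m^2 y / ybar^2 (A 1) ] ), clamped at zero against
    round-off.  Virtual bins are excluded.
    """
    ybar = predict(x_osem, geom, factors)
    live = factors.live
    yb = ybar.values[live]
    if np.any((yb <= 0) & (y.values[live] > 0)):
        raise ValueError("zero expectation at a live bin with counts")
    w = np.zeros_like(ybar.values)
    ok = live & (ybar.values > 0)
    w[ok] = factors.m.values[ok] ** 2 * y.values[ok] / ybar.values[ok] ** 2
    ones = x_osem.with_values(np.ones(x_osem.shape))
    a_one = forward_project(ones, geom).values
    k2 = back_project(ProjectionData(w * a_one, geom), geom).values
    return x_osem.with_values(np.sqrt(np.clip(k2, 0.0, None)))


def epsilon_from_osem(x_osem: ImageVolume, rel: float = 1e-4) -> float:
    """Prior smoothing constant as a fraction of the OSEM image maximum."""
    if rel <= 0:
        raise ValueError("rel must be > 0")
    peak = float(x_osem.values.max())
    if peak <= 0:
        raise ValueError("OSEM image must have a positive maximum")
    return rel * peak


def objective(
    x: ImageVolume,
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    p: PriorParams,
) -> ObjectiveValue:
    """Full decomposed MAP objective Psi = L - beta R at the image x."""
    ybar = predict(x, geom, factors)
    return ObjectiveValue(
        loglik=loglik(y, ybar, factors), prior=rdp_value(x, p), beta=p.beta
    )


def full_grad(
    x: ImageVolume,
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    p: PriorParams,
) -> ImageVolume:
    """Gradient of the full MAP objective Psi."""
    gl = loglik_grad(x, y, geom, factors)
    gr = rdp_grad(x, p)
    return x.with_values(gl.values - p.beta * gr.values)
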