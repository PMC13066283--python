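"""Affine Poisson acquisition model with a matched projector/adjoint pair.

The forward model for expected counts is

    ybar(x) = m * (A x + a)

with ``A`` a 2-D parallel-beam line-integral operator (exact voxel
intersection lengths, Siddon-style ray tracing), ``m`` multiplicative
factors (detector efficiency times attenuation) and ``a`` a strictly
positive additive background standing in for randoms and scatter.  The
operator is materialised once per geometry as a sparse matrix so that the
adjoint is the transpose of the identical footprint — the sensitivity-image
and preconditioner algebra used by the solvers is then self-consistent by
construction.  3-D volumes are projected plane by plane with the same
in-plane operator.

Bins with ``m = 0`` model "virtual crystal" bins that can never record a
count; every downstream likelihood expression excludes them before
dividing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .grids import ImageVolume
from .phantoms import PhantomScene

__all__ = [
    "ProjectorGeometry",
    "ProjectionData",
    "AcquisitionFactors",
    "SubsetScheme",
    "default_geometry",
    "system_matrix",
    "forward_project",
    "back_project",
    "predict",
    "sample_counts",
    "make_subsets",
    "sensitivity_images",
    "subset_forward",
    "subset_back",
    "simulate_acquisition",
    "SimulatedAcquisition",
]


@dataclass(frozen=True)
class ProjectorGeometry:
    """Parallel-beam sinogram geometry bound to a reconstruction grid.

    View angles are evenly spaced over [0, pi); radial bins are centred on
    the grid origin with pitch ``radial_spacing`` mm.  ``n_planes`` is None
    for a purely 2-D study, otherwise the number of trans-axial planes.
    """

    image_shape: tuple[int, int]
    voxel_size: tuple[float, float]
    n_views: int
    n_radial: int
    radial_spacing: float
    n_planes: int | None = None
    plane_spacing: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_shape", tuple(int(n) for n in self.image_shape))
        object.__setattr__(
            self, "voxel_size", tuple(float(v) for v in self.voxel_size)
        )
        if self.n_views < 1 or self.n_radial < 1:
            raise ValueError("n_views and n_radial must be >= 1")
        if self.radial_spacing <= 0:
            raise ValueError("radial_spacing must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")

    @property
    def angles(self) -> np.ndarray:
        """Strictly increasing view angles in radians over [0, pi)."""
        return np.linspace(0.0, np.pi, self.n_views, endpoint=False)

    @property
    def radial_offsets(self) -> np.ndarray:
        """Signed radial bin centres in mm."""
        return (
            np.arange(self.n_radial) - (self.n_radial - 1) / 2.0
        ) * self.radial_spacing

    @property
    def sinogram_shape(self) -> tuple[int, ...]:
        if self.n_planes is None:
            return (self.n_views, self.n_radial)
        return (self.n_planes, self.n_views, self.n_radial)


@dataclass(frozen=True)
class ProjectionData:
    """Sinogram-shaped data: counts y, expectations ybar, or factors."""

    values: np.ndarray
    geom: ProjectorGeometry

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", arr)
        if arr.shape != self.geom.sinogram_shape:
            raise ValueError(
                f"projection data shape {arr.shape} != geometry "
                f"{self.geom.sinogram_shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("projection values must be finite")

    def with_values(self, values: np.ndarray) -> "ProjectionData":
        return ProjectionData(values, self.geom)


@dataclass(frozen=True)
class AcquisitionFactors:
    """Multiplicative factors m (>= 0) and additive background a.

    ``a`` must be strictly positive wherever ``m > 0``; bins with ``m = 0``
    are virtual-crystal bins and are excluded from all likelihood terms.
    """

    m: ProjectionData
    a: ProjectionData

    def __post_init__(self) -> None:
        if self.m.geom != self.a.geom:
            raise ValueError("m and a must share the geometry")
        if np.any(self.m.values < 0):
            raise ValueError("multiplicative factors must be >= 0")
        live = self.m.values > 0
        if np.any(self.a.values[live] <= 0):
            raise ValueError("additive background must be > 0 at live bins")

    @property
    def live(self) -> np.ndarray:
        """Boolean mask of bins that can record counts (m > 0)."""
        return self.m.values > 0


@dataclass(frozen=True)
class SubsetScheme:
    """Ordered partition of view indices into disjoint angular subsets."""

    subsets: tuple[tuple[int, ...], ...]
    n_views: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for s in self.subsets:
            if len(s) == 0:
                raise ValueError("subsets must be nonempty")
            if seen.intersection(s):
                raise ValueError("subsets must be pairwise disjoint")
            seen.update(s)
        if seen != set(range(self.n_views)):
            raise ValueError("subsets must cover every view exactly once")

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


def make_subsets(n_views: int, n_subsets: int) -> SubsetScheme:
    """Maximally interleaved angular subsets: subset j = views == j (mod n).

    ``n_subsets`` must divide ``n_views`` so all subsets are equal-sized.
    """
    if not (1 <= n_subsets <= n_views):
        raise ValueError("need 1 <= n_subsets <= n_views")
    if n_views % n_subsets:
        raise ValueError(f"n_subsets={n_subsets} does not divide n_views={n_views}")
    subs = tuple(
        tuple(range(j, n_views, n_subsets)) for j in range(n_subsets)
    )
    return SubsetScheme(subsets=subs, n_views=n_views)


# ---------------------------------------------------------------------------
# system matrix (Siddon ray tracing)

_MATRIX_CACHE: dict[ProjectorGeometry, sparse.csr_matrix] = {}
_SUBSET_CACHE: dict[tuple[ProjectorGeometry, tuple[int, ...]], sparse.csr_matrix] = {}


def _trace_ray(
    p1: np.ndarray,
    p2: np.ndarray,
    x0: float,
    y0: float,
    vx: float,
    vy: float,
    nx: int,
    ny: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact voxel intersection lengths (mm) of the segment p1 -> p2.

    Returns flat voxel indices (row-major over (nx, ny)) and lengths.
    """
    d = p2 - p1
    ray_len = float(np.hypot(d[0], d[1]))
    alphas = [np.array([0.0, 1.0])]
    amin, amax = 0.0, 1.0
    for axis, (o, v, n) in enumerate(((x0, vx, nx), (y0, vy, ny))):
        if abs(d[axis]) > 1e-12 * ray_len:
            a = (o + v * np.arange(n + 1) - p1[axis]) / d[axis]
            lo, hi = min(a[0], a[-1]), max(a[0], a[-1])
            amin, amax = max(amin, lo), min(amax, hi)
            alphas.append(a)
        else:
            # ray parallel to this axis: must lie inside the slab
            if not (o <= p1[axis] <= o + v * n):
                return np.empty(0, dtype=np.int64), np.empty(0)
    if amax <= amin:
        return np.empty(0, dtype=np.int64), np.empty(0)
    a = np.concatenate(alphas)
    a = a[(a >= amin) & (a <= amax)]
    a = np.unique(np.concatenate((a, [amin, amax])))
    if a.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)
    seg = np.diff(a) * ray_len
    mids = 0.5 * (a[1:] + a[:-1])
    px = p1[0] + mids * d[0]
    py = p1[1] + mids * d[1]
    ix = np.floor((px - x0) / vx).astype(np.int64)
    iy = np.floor((py - y0) / vy).astype(np.int64)
    ok = (seg > 1e-12) & (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    return ix[ok] * ny + iy[ok], seg[ok]


def system_matrix(geom: ProjectorGeometry) -> sparse.csr_matrix:
    """Sparse line-integral operator of shape (n_views*n_radial, nx*ny).

    Built once per geometry and cached; the adjoint used throughout the
    package is the transpose of this same matrix.
    """
    cached = _MATRIX_CACHE.get(geom)
    if cached is not None:
        return cached
    nx, ny = geom.image_shape
    vx, vy = geom.voxel_size
    x0, y0 = -nx * vx / 2.0, -ny * vy / 2.0
    half_len = float(np.hypot(nx * vx, ny * vy))
    rows, cols, vals = [], [], []
    offsets = geom.radial_offsets
    for iv, th in enumerate(geom.angles):
        nvec = np.array([np.cos(th), np.sin(th)])
        dvec = np.array([-np.sin(th), np.cos(th)])
        for ir, r in enumerate(offsets):
            p1 = r * nvec - half_len * dvec
            p2 = r * nvec + half_len * dvec
            idx, seg = _trace_ray(p1, p2, x0, y0, vx, vy, nx, ny)
            if idx.size:
                rows.append(np.full(idx.size, iv * geom.n_radial + ir))
                cols.append(idx)
                vals.append(seg)
    if rows:
        mat = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(geom.n_views * geom.n_radial, nx * ny),
        ).tocsr()
    else:
        mat = sparse.csr_matrix((geom.n_views * geom.n_radial, nx * ny))
    _MATRIX_CACHE[geom] = mat
    return mat


def _subset_matrix(geom: ProjectorGeometry, views: tuple[int, ...]) -> sparse.csr_matrix:
    key = (geom, views)
    cached = _SUBSET_CACHE.get(key)
    if cached is not None:
        return cached
    a = system_matrix(geom)
    rows = (
        np.asarray(views)[:, None] * geom.n_radial + np.arange(geom.n_radial)
    ).ravel()
    sub = a[rows]
    _SUBSET_CACHE[key] = sub
    return sub


def _image_voxel_size(geom: ProjectorGeometry) -> tuple[float, ...]:
    if geom.n_planes is None:
        return geom.voxel_size
    return geom.voxel_size + (geom.plane_spacing or geom.voxel_size[0],)


def _check_grid(x: ImageVolume, geom: ProjectorGeometry) -> None:
    if x.shape[:2] != geom.image_shape or x.voxel_size[:2] != geom.voxel_size:
        raise ValueError(
            f"image grid {x.shape}/{x.voxel_size} does not match geometry "
            f"{geom.image_shape}/{geom.voxel_size}"
        )
    nz = x.shape[2] if x.ndim == 3 else None
    if nz != geom.n_planes:
        raise ValueError(
            f"image has {nz} planes but geometry declares {geom.n_planes}"
        )


def _apply(mat: sparse.csr_matrix, x: ImageVolume, out_shape: tuple[int, ...]) -> np.ndarray:
    if x.ndim == 2:
        return (mat @ x.values.ravel()).reshape(out_shape)
    out = np.empty((x.shape[2],) + out_shape)
    for p in range(x.shape[2]):
        out[p] = (mat @ x.values[:, :, p].ravel()).reshape(out_shape)
    return out


def _apply_T(
    mat: sparse.csr_matrix, g: np.ndarray, geom: ProjectorGeometry
) -> np.ndarray:
    nx, ny = geom.image_shape
    if geom.n_planes is None:
        return (mat.T @ g.ravel()).reshape(nx, ny)
    out = np.empty((nx, ny, geom.n_planes))
    for p in range(geom.n_planes):
        out[:, :, p] = (mat.T @ g[p].ravel()).reshape(nx, ny)
    return out


def forward_project(x: ImageVolume, geom: ProjectorGeometry) -> ProjectionData:
    """Line integrals of ``x`` along every (view, radial) ray, in activity*mm."""
    _check_grid(x, geom)
    vals = _apply(system_matrix(geom), x, (geom.n_views, geom.n_radial))
    return ProjectionData(vals, geom)


def back_project(g: ProjectionData, geom: ProjectorGeometry) -> ImageVolume:
    """Exact adjoint of :func:`forward_project` (transpose of the footprint)."""
    if g.geom != geom:
        raise ValueError("projection data does not match geometry")
    vals = _apply_T(system_matrix(geom), g.values, geom)
    return ImageVolume(vals, _image_voxel_size(geom))


def subset_forward(x: ImageVolume, geom: ProjectorGeometry, views: tuple[int, ...]) -> np.ndarray:
    """Forward projection restricted to the given views; shape (..., len(views), n_radial)."""
    _check_grid(x, geom)
    return _apply(_subset_matrix(geom, views), x, (len(views), geom.n_radial))


def subset_back(
    vals: np.ndarray, geom: ProjectorGeometry, views: tuple[int, ...]
) -> ImageVolume:
    """Adjoint of :func:`subset_forward` for the given views."""
    mat = _subset_matrix(geom, views)
    nx, ny = geom.image_shape
    if geom.n_planes is None:
        out = (mat.T @ np.asarray(vals, dtype=np.float64).ravel()).reshape(nx, ny)
    else:
        out = np.empty((nx, ny, geom.n_planes))
        for p in range(geom.n_planes):
            out[:, :, p] = (
                mat.T @ np.asarray(vals[p], dtype=np.float64).ravel()
            ).reshape(nx, ny)
    return ImageVolume(out, _image_voxel_size(geom))


def predict(
    x: ImageVolume, geom: ProjectorGeometry, factors: AcquisitionFactors
) -> ProjectionData:
    """Expected counts ybar = m * (A x + a); exactly zero at virtual bins."""
    if np.any(x.values < 0):
        raise ValueError("image must be non-negative for prediction")
    ax = forward_project(x, geom).values
    return ProjectionData(factors.m.values * (ax + factors.a.values), geom)


def sample_counts(ybar: ProjectionData, seed: int) -> ProjectionData:
    """Independent Poisson counts with mean ``ybar``; deterministic in seed."""
    if np.any(ybar.values < 0):
        raise ValueError("Poisson means must be >= 0")
    rng = np.random.default_rng(seed)
    return ybar.with_values(rng.poisson(ybar.values).astype(np.float64))


def sensitivity_images(
    geom: ProjectorGeometry, factors: AcquisitionFactors, scheme: SubsetScheme
) -> tuple[list[ImageVolume], ImageVolume]:
    """Per-subset sensitivity images A_s^T m_s and their average S."""
    per_subset = []
    for views in scheme.subsets:
        m_s = factors.m.values[..., list(views), :]
        per_subset.append(subset_back(m_s, geom, views))
    avg = sum(img.values for img in per_subset) / scheme.n_subsets
    return per_subset, per_subset[0].with_values(avg)


# ---------------------------------------------------------------------------
# simulation helpers


def default_geometry(
    scene: PhantomScene, n_views: int | None = None, n_radial: int | None = None
) -> ProjectorGeometry:
    """A geometry that comfortably covers the phantom's field of view.

    Radial pitch equals the in-plane voxel pitch; the radial extent covers
    the grid diagonal; an odd bin count keeps a central (offset-zero) ray.
    """
    dims = scene.activity.shape
    vs = scene.activity.voxel_size
    if n_views is None:
        n_views = dims[0]
    if n_radial is None:
        n_radial = 2 * int(np.ceil(0.75 * max(dims[0], dims[1]))) + 1
    return ProjectorGeometry(
        image_shape=(dims[0], dims[1]),
        voxel_size=(vs[0], vs[1]),
        n_views=n_views,
        n_radial=n_radial,
        radial_spacing=vs[0],
        n_planes=dims[2] if len(dims) == 3 else None,
        plane_spacing=vs[2] if len(dims) == 3 else None,
    )


@dataclass(frozen=True)
class SimulatedAcquisition:
    """Scaled ground truth, factors and one Poisson realisation."""

    x_true: ImageVolume
    geom: ProjectorGeometry
    factors: AcquisitionFactors
    ybar: ProjectionData
    counts: ProjectionData
    scale: float


def simulate_acquisition(
    scene: PhantomScene,
    geom: ProjectorGeometry | None = None,
    counts_target: float = 1e6,
    background_fraction: float = 0.2,
    efficiency: float = 1.0,
    dead_fraction: float = 0.01,
    seed: int = 0,
) -> SimulatedAcquisition:
    """Simulate one noisy acquisition of a phantom scene.

    The activity is scaled so the total expected true coincidences equal
    ``counts_target``; attenuation enters the multiplicative factors as
    exp(-A mu) times a constant efficiency; the additive background is a
    constant strictly positive sinogram whose expected contribution is
    ``background_fraction`` of the trues.  ``dead_fraction`` of the bins
    (chosen deterministically from ``seed``) get m = 0 to emulate
    virtual-crystal bins.
    """
    if geom is None:
        geom = default_geometry(scene)
    rng = np.random.default_rng(seed)
    mu_line = forward_project(scene.mu, geom).values
    m = efficiency * np.exp(-mu_line)
    if dead_fraction > 0:
        n_bins = m.size
        n_dead = int(round(dead_fraction * n_bins))
        if n_dead:
            dead = rng.choice(n_bins, size=n_dead, replace=False)
            m.ravel()[dead] = 0.0
    ax = forward_project(scene.activity, geom).values
    trues_unit = float(np.sum(m * ax))
    if trues_unit <= 0:
        raise ValueError("phantom produces no detectable counts")
    scale = counts_target / trues_unit
    x_true = scene.activity.with_values(scene.activity.values * scale)
    m_sum = float(np.sum(m))
    a_val = background_fraction * counts_target / m_sum if m_sum > 0 else 1.0
    a = np.full(geom.sinogram_shape, max(a_val, 1e-12))
    factors = AcquisitionFactors(
        m=ProjectionData(m, geom), a=ProjectionData(a, geom)
    )
    ybar = predict(x_true, geom, factors)
    counts = sample_counts(ybar, seed=int(rng.integers(0, 2**31 - 1)))
    return SimulatedAcquisition(
        x_true=x_true, geom=geom, factors=factors, ybar=ybar, counts=counts, scale=scale
    )
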