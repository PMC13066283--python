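"""Synthetic digital phantoms and the VOI masks the scoring protocol needs.

Each generated scene bundles a ground-truth activity image, a water-like
attenuation map and a :class:`VoiSet`: the object support mask (the mask M
of the non-negativity constraint set), a marginally eroded whole-object VOI
W, a uniform-activity background VOI B, and one target VOI per insert or
matter region.  The geometry mimics the structure of image-quality phantoms
used on clinical scanners (NEMA-IQ-like sphere inserts, Hoffman-like
interleaved grey/white matter bands) without any anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ImageVolume

__all__ = ["VoiSet", "PhantomScene", "generate_phantom", "erode_mask"]

# linear attenuation of water at 511 keV, 1/mm
MU_WATER = 0.0096

_BOX = {2: np.ones((3, 3), dtype=bool), 3: np.ones((3, 3, 3), dtype=bool)}


@dataclass(frozen=True)
class VoiSet:
    """Binary region masks used by the convergence metrics.

    ``object_mask`` is the support mask M; ``whole_eroded`` (W) is M eroded
    by a configurable margin; ``background`` (B) is a uniform-activity
    region used as the metric normaliser; ``targets`` maps VOI names to
    masks of individual hot/cold regions.
    """

    object_mask: np.ndarray
    whole_eroded: np.ndarray
    background: np.ndarray
    targets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.object_mask.shape
        for name, m in self.items():
            if m.dtype != bool:
                raise ValueError(f"VOI {name!r} must be boolean")
            if m.shape != shape:
                raise ValueError(f"VOI {name!r} shape {m.shape} != {shape}")
        if np.any(self.whole_eroded & ~self.object_mask):
            raise ValueError("whole_eroded must be a subset of object_mask")
        if np.any(self.background & ~self.whole_eroded):
            raise ValueError("background must be a subset of whole_eroded")
        if not self.background.any():
            raise ValueError("background VOI is empty")
        names = list(self.targets)
        for i, a in enumerate(names):
            if np.any(self.targets[a] & ~self.object_mask):
                raise ValueError(f"target {a!r} leaves the object mask")
            for b in names[i + 1 :]:
                if np.any(self.targets[a] & self.targets[b]):
                    raise ValueError(f"targets {a!r} and {b!r} overlap")

    def items(self):
        yield "object", self.object_mask
        yield "whole_eroded", self.whole_eroded
        yield "background", self.background
        yield from self.targets.items()


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth activity, attenuation and VOIs for one synthetic study."""

    activity: ImageVolume
    mu: ImageVolume
    vois: VoiSet
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.activity.same_grid(self.mu):
            raise ValueError("activity and mu must share the grid")
        if self.vois.object_mask.shape != self.activity.shape:
            raise ValueError("VOIs must share the phantom grid")
        if np.any(self.activity.values < 0) or np.any(self.mu.values < 0):
            raise ValueError("activity and mu must be non-negative")
        if np.any(self.activity.values[~self.vois.object_mask] != 0):
            raise ValueError("activity must vanish outside the object mask")


def erode_mask(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Erode a boolean mask with the full 3^ndim box structuring element.

    Out-of-bounds voxels count as background, so the object shrinks at the
    image border as well.  ``iterations=0`` returns the mask unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0 or not mask.any():
        return mask.copy()
    return ndimage.binary_erosion(
        mask, structure=_BOX[mask.ndim], iterations=iterations, border_value=0
    )


def _dilate(mask: np.ndarray, iterations: int) -> np.ndarray:
    if iterations == 0 or mask.ndim not in (2, 3):
        return mask.copy()
    return ndimage.binary_dilation(
        mask, structure=_BOX[mask.ndim], iterations=iterations
    )


def _index_grids(dims: tuple[int, ...]) -> list[np.ndarray]:
    """Centred voxel-index coordinates, one broadcastable array per axis."""
    axes = [np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in dims]
    return list(np.meshgrid(*axes, indexing="ij"))


def _inplane_disc(
    grids: list[np.ndarray], centre: tuple[float, float], radius: float
) -> np.ndarray:
    """Disc (2-D) or ball (3-D, centred on the mid plane) in voxel units."""
    d2 = (grids[0] - centre[0]) ** 2 + (grids[1] - centre[1]) ** 2
    if len(grids) == 3:
        d2 = d2 + grids[2] ** 2
    return d2 < radius**2


def _ellipse(grids: list[np.ndarray], a: float, b: float) -> np.ndarray:
    """Elliptic support, extruded along z in 3-D (elliptic cylinder)."""
    return (grids[0] / a) ** 2 + (grids[1] / b) ** 2 < 1.0


def generate_phantom(
    kind: str,
    dims: tuple[int, ...] = (64, 64),
    voxel_size: tuple[float, ...] | None = None,
    contrast: float = 4.0,
    seed: int = 0,
    erosion_iterations: int = 1,
) -> PhantomScene:
    """Build a deterministic synthetic phantom scene.

    Parameters
    ----------
    kind
        ``"nema_like"`` — warm ellipse at activity 1.0 with 4–6 disc/sphere
        inserts at activity ``contrast`` on a ring; ``"hoffman_like"`` —
        interleaved high (``contrast``) / low (1.0) bands inside an ellipse;
        ``"constant_disc"`` — a uniform centred disc at activity
        ``contrast``.
    dims, voxel_size
        Grid shape (2-D or 3-D, every axis >= 16) and mm voxel pitch
        (default 2 mm isotropic).
    contrast
        Hot-region activity relative to the warm background (must be > 0).
    seed
        Jitters insert positions / band phase by at most one voxel; two
        calls with identical arguments produce bit-identical scenes.
    erosion_iterations
        Margin (in voxels) of the eroded whole-object VOI W.
    """
    dims = tuple(int(n) for n in dims)
    if len(dims) not in (2, 3):
        raise ValueError("dims must be 2-D or 3-D")
    if min(dims) < 16:
        raise ValueError(f"every grid axis must be >= 16, got {dims}")
    if contrast <= 0:
        raise ValueError("contrast must be > 0")
    if voxel_size is None:
        voxel_size = (2.0,) * len(dims)

    rng = np.random.default_rng(seed)
    grids = _index_grids(dims)
    nx, ny = dims[0], dims[1]
    span = min(nx, ny)

    activity = np.zeros(dims)
    targets: dict[str, np.ndarray] = {}

    if kind == "constant_disc":
        obj = _inplane_disc_cyl(grids, (0.0, 0.0), 0.40 * span)
        activity[obj] = contrast
        tgt = _inplane_disc(grids, (0.0, 0.0), 0.10 * span)
        targets["centre"] = tgt
        avoid = _dilate(tgt, 1)
        # the disc is uniform throughout, so the background only needs
        # clearance from the boundary and the target VOI
        bg_margin = max(2, erosion_iterations + 1)
        mu = np.where(obj, MU_WATER, 0.0)
    elif kind == "nema_like":
        a, b = 0.44 * nx, 0.38 * ny
        obj = _ellipse(grids, a, b)
        activity[obj] = 1.0
        n_slots = 6 if span >= 48 else 4
        fractions = (0.085, 0.07, 0.06, 0.05, 0.042, 0.035)[:n_slots]
        rho = 0.55 * min(a, b)
        inserts = []
        for i, f in enumerate(fractions):
            r = f * span
            if r < 1.5:
                continue
            phi = 2.0 * np.pi * i / n_slots
            jitter = rng.integers(-1, 2, size=2)
            centre = (rho * np.cos(phi) + jitter[0], rho * np.sin(phi) + jitter[1])
            disc = _inplane_disc(grids, centre, r) & obj
            inserts.append((f"insert_{i + 1}", disc))
        if len(inserts) < 4:
            raise ValueError(f"grid {dims} too small to place >= 4 inserts")
        union = np.zeros(dims, dtype=bool)
        for name, disc in inserts:
            if np.any(disc & union):
                raise ValueError("insert placement overlap (grid too small)")
            activity[disc] = contrast
            targets[name] = disc
            union |= disc
        avoid = _dilate(union, 2)
        mu = np.where(obj, MU_WATER, 0.0)
    elif kind == "hoffman_like":
        a, b = 0.44 * nx, 0.40 * ny
        obj = _ellipse(grids, a, b)
        band = max(2, round(0.08 * nx))
        phase = int(rng.integers(-1, 2))
        xi = np.arange(nx) + phase
        high_cols = ((xi // band) % 2 == 0)
        # stripes live in an inner ellipse; a uniform warm rim surrounds them
        inner = _ellipse(grids, 0.58 * a, 0.58 * b)
        high = high_cols[(slice(None),) + (None,) * (len(dims) - 1)] & inner
        activity[obj] = 1.0
        activity[high] = contrast
        # one target patch inside a high band, one inside a low band
        r_t = max(1.5, 0.4 * band)
        x_high = _band_centre(nx, band, phase, want_high=True)
        x_low = _band_centre(nx, band, phase, want_high=False)
        targets["matter_high"] = _inplane_disc(grids, (x_high, 0.0), r_t) & inner
        targets["matter_low"] = _inplane_disc(grids, (x_low, 0.0), r_t) & inner
        # the uniform rim hosts the background; margin of one voxel from the
        # striped core and two from the object boundary
        avoid = _dilate(inner, 1)
        bg_margin = max(2, erosion_iterations + 1)
        mu = np.where(obj, MU_WATER, 0.0)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    if kind == "nema_like":
        bg_margin = max(3, erosion_iterations + 2)
    whole = erode_mask(obj, erosion_iterations)
    background = erode_mask(obj, bg_margin) & ~avoid
    if not background.any():
        raise ValueError(f"grid {dims} too small for a valid background VOI")
    for name, t in targets.items():
        if not t.any():
            raise ValueError(f"grid {dims} too small for target VOI {name!r}")

    vois = VoiSet(
        object_mask=obj, whole_eroded=whole, background=background, targets=targets
    )
    meta = {
        "kind": kind,
        "seed": int(seed),
        "contrast": float(contrast),
        "dims": dims,
        "voxel_size": tuple(float(v) for v in voxel_size),
    }
    return PhantomScene(
        activity=ImageVolume(activity, voxel_size),
        mu=ImageVolume(mu, voxel_size),
        vois=vois,
        meta=meta,
    )


def _inplane_disc_cyl(
    grids: list[np.ndarray], centre: tuple[float, float], radius: float
) -> np.ndarray:
    """In-plane disc extruded along z (a rod in 3-D)."""
    d2 = (grids[0] - centre[0]) ** 2 + (grids[1] - centre[1]) ** 2
    return d2 < radius**2


def _band_centre(nx: int, band: int, phase: int, want_high: bool) -> float:
    """Centred x-coordinate of the band of requested parity nearest centre."""
    centre_idx = (nx - 1) / 2.0
    best, best_d = None, np.inf
    for k in range((nx + 2 * band) // band + 2):
        lo = k * band - phase
        hi = lo + band - 1
        if hi < 0 or lo >= nx:
            continue
        is_high = (k % 2) == 0
        if is_high != want_high:
            continue
        mid = (max(lo, 0) + min(hi, nx - 1)) / 2.0
        d = abs(mid - centre_idx)
        if d < best_d:
            best, best_d = mid, d
    assert best is not None
    return best - centre_idx
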