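"""Interfile-lite readers and writers.

A deliberately small, documented dialect of the Interfile convention used
in emission tomography: a plain-text ``key := value`` header file plus a
raw little/big-endian binary payload in a sibling data file.  Images use
``.hv`` (header) / ``.v`` (data); projection data use ``.hs`` / ``.s``
and carry the sinogram geometry in extra keys.  Full STIR-dialect
compatibility is not promised; unknown keys are ignored with a logged
warning so that slightly richer headers still load.

Recognised keys (images):
    name of data file, number format (float / signed integer),
    number of bytes per pixel (4 / 8), imagedata byte order
    (LITTLEENDIAN / BIGENDIAN), number of dimensions,
    matrix size [i], scaling factor (mm/pixel) [i],
    data offset in bytes, imaging modality.

Projection headers add:
    number of views, number of radial bins, radial bin spacing (mm),
    number of planes, plane spacing (mm),
    image matrix size [i], image scaling factor (mm/pixel) [i].
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np

from .acquisition import ProjectionData, ProjectorGeometry
from .grids import ImageVolume

__all__ = ["write_image", "read_image", "write_projdata", "read_projdata"]

log = logging.getLogger("petbench.interfile")

_MAGIC = "!INTERFILE"
_END = "!END OF INTERFILE"

_IMAGE_KEYS = {
    "name of data file",
    "number format",
    "number of bytes per pixel",
    "imagedata byte order",
    "number of dimensions",
    "data offset in bytes",
    "imaging modality",
}
_PROJ_KEYS = _IMAGE_KEYS | {
    "number of views",
    "number of radial bins",
    "radial bin spacing (mm)",
    "number of planes",
    "plane spacing (mm)",
}


def _dtype(number_format: str, nbytes: int, byte_order: str) -> np.dtype:
    if number_format == "float":
        base = {4: "f4", 8: "f8"}.get(nbytes)
    elif number_format == "signed integer":
        base = {4: "i4", 8: "i8"}.get(nbytes)
    else:
        raise ValueError(f"unsupported number format {number_format!r}")
    if base is None:
        raise ValueError(f"unsupported bytes per pixel {nbytes}")
    order = {"LITTLEENDIAN": "<", "BIGENDIAN": ">"}.get(byte_order.upper())
    if order is None:
        raise ValueError(f"unsupported byte order {byte_order!r}")
    return np.dtype(order + base)


def _write_header(path: Path, pairs: list[tuple[str, str]]) -> None:
    lines = [f"{_MAGIC} :="]
    lines += [f"{k} := {v}" for k, v in pairs]
    lines.append(f"{_END} :=")
    path.write_text("\n".join(lines) + "\n")


def _parse_header(path: Path, known: set[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(_MAGIC) or line.startswith(_END):
            continue
        if ":=" not in line:
            raise ValueError(f"{path}: malformed header line {raw!r}")
        key, _, val = line.partition(":=")
        key = key.strip().lstrip("!").strip()
        val = val.strip()
        if key not in known and not key.startswith(("matrix size", "scaling factor", "image matrix size", "image scaling factor")):
            log.warning("%s: ignoring unknown header key %r", path, key)
            continue
        out[key] = val
    return out


def _axis_values(header: dict[str, str], stem: str, ndim: int, cast) -> list:
    vals = []
    for i in range(1, ndim + 1):
        key = f"{stem} [{i}]"
        if key not in header:
            raise ValueError(f"missing header key {key!r}")
        vals.append(cast(header[key]))
    return vals


def _read_payload(
    header: dict[str, str], header_path: Path, n_expected: int
) -> np.ndarray:
    for key in ("name of data file", "number format", "number of bytes per pixel",
                "imagedata byte order", "data offset in bytes"):
        if key not in header:
            raise ValueError(f"{header_path}: missing header key {key!r}")
    nbytes = int(header["number of bytes per pixel"])
    dtype = _dtype(header["number format"], nbytes, header["imagedata byte order"])
    offset = int(header["data offset in bytes"])
    data_path = header_path.parent / header["name of data file"]
    declared = n_expected * nbytes
    actual = os.path.getsize(data_path) - offset
    if actual != declared:
        raise ValueError(
            f"{data_path}: payload is {actual} bytes but header declares "
            f"{declared} bytes"
        )
    with open(data_path, "rb") as fh:
        fh.seek(offset)
        return np.frombuffer(fh.read(declared), dtype=dtype).astype(np.float64)


def write_image(img: ImageVolume, path: str | Path) -> Path:
    """Write an image as ``<path>.hv`` header + ``<path>.v`` raw float64.

    ``path`` may carry the ``.hv`` suffix or none.  Returns the header path;
    ``read_image`` of the result is bit-identical in values, dims and voxel
    sizes.
    """
    path = Path(path)
    if path.suffix == ".hv":
        path = path.with_suffix("")
    header_path = path.with_suffix(".hv")
    data_path = path.with_suffix(".v")
    data_path.write_bytes(img.values.astype("<f8").tobytes())
    pairs = [
        ("name of data file", data_path.name),
        ("number format", "float"),
        ("number of bytes per pixel", "8"),
        ("imagedata byte order", "LITTLEENDIAN"),
        ("imaging modality", "PT"),
        ("number of dimensions", str(img.ndim)),
    ]
    for i, (n, v) in enumerate(zip(img.shape, img.voxel_size), start=1):
        pairs.append((f"matrix size [{i}]", str(n)))
        pairs.append((f"scaling factor (mm/pixel) [{i}]", repr(float(v))))
    pairs.append(("data offset in bytes", "0"))
    _write_header(header_path, pairs)
    return header_path


def read_image(path: str | Path) -> ImageVolume:
    """Read an Interfile-lite image written by :func:`write_image`."""
    header_path = Path(path)
    if header_path.suffix != ".hv":
        header_path = header_path.with_suffix(".hv")
    header = _parse_header(header_path, _IMAGE_KEYS)
    if "number of dimensions" not in header:
        raise ValueError(f"{header_path}: missing 'number of dimensions'")
    ndim = int(header["number of dimensions"])
    shape = tuple(_axis_values(header, "matrix size", ndim, int))
    voxel = tuple(_axis_values(header, "scaling factor (mm/pixel)", ndim, float))
    flat = _read_payload(header, header_path, int(np.prod(shape)))
    return ImageVolume(flat.reshape(shape), voxel)


def write_projdata(pd_: ProjectionData, path: str | Path) -> Path:
    """Write projection data as ``<path>.hs`` header + ``<path>.s`` raw float64."""
    path = Path(path)
    if path.suffix == ".hs":
        path = path.with_suffix("")
    header_path = path.with_suffix(".hs")
    data_path = path.with_suffix(".s")
    data_path.write_bytes(pd_.values.astype("<f8").tobytes())
    g = pd_.geom
    pairs = [
        ("name of data file", data_path.name),
        ("number format", "float"),
        ("number of bytes per pixel", "8"),
        ("imagedata byte order", "LITTLEENDIAN"),
        ("imaging modality", "PT"),
        ("number of dimensions", str(len(pd_.values.shape))),
        ("number of views", str(g.n_views)),
        ("number of radial bins", str(g.n_radial)),
        ("radial bin spacing (mm)", repr(float(g.radial_spacing))),
    ]
    if g.n_planes is not None:
        pairs.append(("number of planes", str(g.n_planes)))
        if g.plane_spacing is not None:
            pairs.append(("plane spacing (mm)", repr(float(g.plane_spacing))))
    for i, (n, v) in enumerate(zip(g.image_shape, g.voxel_size), start=1):
        pairs.append((f"image matrix size [{i}]", str(n)))
        pairs.append((f"image scaling factor (mm/pixel) [{i}]", repr(float(v))))
    pairs.append(("data offset in bytes", "0"))
    _write_header(header_path, pairs)
    return header_path


def read_projdata(path: str | Path, expect_counts: bool = False) -> ProjectionData:
    """Read Interfile-lite projection data; geometry comes from the header.

    With ``expect_counts=True`` non-integral values trigger a validation
    warning (count data should be integers).
    """
    header_path = Path(path)
    if header_path.suffix != ".hs":
        header_path = header_path.with_suffix(".hs")
    header = _parse_header(header_path, _PROJ_KEYS)
    for key in ("number of views", "number of radial bins", "radial bin spacing (mm)"):
        if key not in header:
            raise ValueError(f"{header_path}: missing geometry key {key!r}")
    n_views = int(header["number of views"])
    n_radial = int(header["number of radial bins"])
    n_planes = int(header["number of planes"]) if "number of planes" in header else None
    plane_spacing = (
        float(header["plane spacing (mm)"]) if "plane spacing (mm)" in header else None
    )
    shape2 = tuple(_axis_values(header, "image matrix size", 2, int))
    voxel2 = tuple(_axis_values(header, "image scaling factor (mm/pixel)", 2, float))
    geom = ProjectorGeometry(
        image_shape=shape2,
        voxel_size=voxel2,
        n_views=n_views,
        n_radial=n_radial,
        radial_spacing=float(header["radial bin spacing (mm)"]),
        n_planes=n_planes,
        plane_spacing=plane_spacing,
    )
    ndim = int(header.get("number of dimensions", "2"))
    if ndim != len(geom.sinogram_shape):
        raise ValueError(
            f"{header_path}: declared {ndim} dimensions but geometry implies "
            f"{len(geom.sinogram_shape)}"
        )
    flat = _read_payload(header, header_path, int(np.prod(geom.sinogram_shape)))
    values = flat.reshape(geom.sinogram_shape)
    if expect_counts and not np.allclose(values, np.round(values)):
        log.warning("%s: count data contains non-integral values", header_path)
    return ProjectionData(values, geom)
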