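"""Reading and writing SBF image stacks, label volumes and instance volumes.

On-disk interchange format is multipage TIFF, one page per z slice
(``z`` = milling direction, pages in acquisition order).  A directory of
same-sized single-page TIFF/PNG slices, lexicographically ordered, is
accepted on read for fixtures.  Voxel spacing is *not* stored in TIFF tags
— FIB-SEM TIFFs rarely carry reliable z spacing — but travels in an
optional JSON sidecar (``<stem>.meta.json``) or is supplied by the caller.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from sbfseg.volumes import (
    CLASS_MAP,
    CellInstanceVolume,
    LabelVolume,
    RawVolume,
    VoxelSpacing,
)

_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


def _read_pages(path: Path) -> np.ndarray:
    """Return a (z, y, x) array from a multipage TIFF or a slice directory."""
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG slices in directory {path}")
        slices = []
        for f in files:
            page = iio.imread(f) if f.suffix.lower() == ".png" else tifffile.imread(f)
            page = np.asarray(page)
            if page.ndim != 2:
                raise ValueError(f"slice {f.name} is not single-channel 2D "
                                 f"(shape {page.shape})")
            if slices and page.shape != slices[0].shape:
                raise ValueError(
                    f"inconsistent slice dimensions: {f.name} has {page.shape}, "
                    f"expected {slices[0].shape}"
                )
            slices.append(page)
        return np.stack(slices, axis=0)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a stack of 2D pages, got shape {data.shape}")
    return data


def read_stack(path: str | Path, spacing: VoxelSpacing) -> RawVolume:
    """Read an intensity stack as a :class:`RawVolume`.

    8-bit data is preserved bit-exact.  Inputs deeper than 8 bits are
    rejected: rescaling is an irreversible choice the caller must make
    explicitly.
    """
    data = _read_pages(Path(path))
    if data.dtype != np.uint8:
        raise ValueError(
            f"unsupported bit depth {data.dtype}; >8-bit input must be "
            "explicitly rescaled by the caller"
        )
    return RawVolume(data=data, spacing=spacing, normalized=False)


def read_labels(path: str | Path) -> LabelVolume:
    """Read a six-class label stack."""
    return LabelVolume(data=_read_pages(Path(path)).astype(np.int64))


def read_instances(path: str | Path) -> CellInstanceVolume:
    """Read a per-cell instance stack."""
    return CellInstanceVolume(data=_read_pages(Path(path)).astype(np.int64))


def write_stack(
    volume: RawVolume | LabelVolume | CellInstanceVolume,
    path: str | Path,
    sidecar: bool = False,
) -> None:
    """Write a volume as a multipage TIFF, one page per z slice.

    Intensity volumes are written uint8 (normalized volumes are rescaled
    back to 0..255 losslessly only if the caller denormalizes first — a
    normalized volume is rejected to avoid silent quantization).  Label and
    instance volumes are written as integer pages (uint8, or uint16 when
    instance ids exceed 255).
    """
    path = Path(path)
    if isinstance(volume, RawVolume):
        if volume.normalized:
            raise ValueError("refusing to quantize a normalized volume; "
                             "write the 8-bit volume instead")
        pages = volume.data
    elif isinstance(volume, LabelVolume):
        pages = volume.data.astype(np.uint8)
    elif isinstance(volume, CellInstanceVolume):
        dtype = np.uint8 if volume.data.max() <= 255 else np.uint16
        pages = volume.data.astype(dtype)
    else:
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    if pages.size == 0:
        raise ValueError("refusing to write an empty volume")
    path.parent.mkdir(parents=True, exist_ok=True)
    # grayscale pages always; never let a 3-slice stack become RGB planes
    tifffile.imwrite(path, pages, photometric="minisblack")
    if sidecar:
        meta: dict = {"axes": "zyx", "shape": list(pages.shape)}
        if isinstance(volume, RawVolume):
            meta["spacing_nm"] = {"dz": volume.spacing.dz,
                                  "dy": volume.spacing.dy,
                                  "dx": volume.spacing.dx}
        if isinstance(volume, LabelVolume):
            meta["class_map"] = {str(k): v for k, v in CLASS_MAP.items()}
        sidecar_path = path.with_suffix(path.suffix + ".meta.json")
        sidecar_path.write_text(json.dumps(meta, indent=2))
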