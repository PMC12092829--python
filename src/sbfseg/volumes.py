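"""Core volume containers shared by every pipeline stage.

All 3D grids are indexed ``(z, y, x)`` with 0-based indices; axis 0 (z) is
the milling/acquisition direction of the serial block-face stack.  No
operation in the package silently transposes axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed six-class taxonomy used for every label volume.
CLASS_MAP: dict[int, str] = {
    0: "background",
    1: "cytoplasm",
    2: "plastid",
    3: "mitochondrion",
    4: "peroxisome",
    5: "nucleus",
}

N_CLASSES = len(CLASS_MAP)


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical edge lengths of one voxel in nanometres, ``(dz, dy, dx)``."""

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        for name in ("dz", "dy", "dx"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"spacing {name} must be a positive real, got {v}")

    @property
    def is_isotropic(self) -> bool:
        return self.dz == self.dy == self.dx

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)


def _require_3d(data: np.ndarray, what: str) -> None:
    if not isinstance(data, np.ndarray) or data.ndim != 3:
        raise ValueError(f"{what} data must be a 3D array, got shape "
                         f"{getattr(data, 'shape', None)}")
    if data.size == 0:
        raise ValueError(f"{what} data must be nonempty")


@dataclass
class RawVolume:
    """A 3D scalar intensity grid (the SBF image) plus voxel spacing.

    ``data`` is either 8-bit integers in 0..255 (``normalized=False``) or
    floating-point values in [0, 1] (``normalized=True``).
    """

    data: np.ndarray
    spacing: VoxelSpacing
    normalized: bool = False

    def __post_init__(self) -> None:
        _require_3d(self.data, "RawVolume")
        if self.normalized:
            if not np.issubdtype(self.data.dtype, np.floating):
                raise ValueError("normalized volumes must be floating point")
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < 0.0 or hi > 1.0:
                raise ValueError(f"normalized intensities outside [0,1]: [{lo},{hi}]")
        else:
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("un-normalized volumes must be 8-bit integer")
            if self.data.dtype != np.uint8:
                lo, hi = int(self.data.min()), int(self.data.max())
                if lo < 0 or hi > 255:
                    raise ValueError(
                        ">8-bit input must be explicitly rescaled by the caller"
                    )
                self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype_float(self) -> np.ndarray:
        """Intensities as float32 on the native scale (no rescaling)."""
        return self.data.astype(np.float32)


@dataclass
class LabelVolume:
    """A 3D integer grid over the six-class taxonomy."""

    data: np.ndarray
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_MAP))

    def __post_init__(self) -> None:
        _require_3d(self.data, "LabelVolume")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        values = np.unique(self.data)
        if values.min() < 0 or values.max() >= N_CLASSES:
            raise ValueError(f"label values must lie in 0..{N_CLASSES - 1}, "
                             f"got {values.tolist()}")
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def value_set(self) -> set[int]:
        return set(int(v) for v in np.unique(self.data))


@dataclass
class CellInstanceVolume:
    """Per-cell instance identifiers: 0 = background, 1..K = cells."""

    data: np.ndarray

    def __post_init__(self) -> None:
        _require_3d(self.data, "CellInstanceVolume")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("instance data must be integer")
        ids = np.unique(self.data)
        if ids.min() < 0:
            raise ValueError("instance ids must be non-negative")
        positive = ids[ids > 0]
        expected = np.arange(1, positive.size + 1)
        if positive.size and not np.array_equal(positive, expected):
            raise ValueError(
                f"instance ids must form a contiguous range 1..K, got {positive.tolist()}"
            )
        self.data = np.ascontiguousarray(self.data, dtype=np.int32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_instances(self) -> int:
        return int(self.data.max())
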