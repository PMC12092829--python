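"""Preprocessing chain and tri-axial reslicing.

The chain mirrors how serial block-face stacks are prepared for slice-wise
deep learning: (1) nearest-neighbor resampling to isotropic voxels, (2) a
2D bilateral filter per acquired section, (3) nearest-neighbor resizing to
a cube of fixed side, (4) normalization of 8-bit intensities to [0, 1].
Nearest-neighbor is used for *every* geometric operation so that intensity
and label volumes go through the identical operator and label classes are
never blended.

Reslicing cuts an isotropic cube into 2D sections perpendicular to any of
the three axes; it is a pure re-indexing (no interpolation) and is used
both for training-set augmentation and for multi-directional inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sbfseg.volumes import LabelVolume, RawVolume, VoxelSpacing

AXES = ("z", "y", "x")


# ---------------------------------------------------------------------------
# nearest-neighbor index mapping

def _nn_indices(n_out: int, n_in: int) -> np.ndarray:
    """Output index i -> input index floor(i * n_in / n_out)."""
    return np.minimum((np.arange(n_out) * n_in) // n_out, n_in - 1).astype(np.intp)


def _resample_nn(data: np.ndarray, new_shape: tuple[int, int, int]) -> np.ndarray:
    iz = _nn_indices(new_shape[0], data.shape[0])
    iy = _nn_indices(new_shape[1], data.shape[1])
    ix = _nn_indices(new_shape[2], data.shape[2])
    return data[np.ix_(iz, iy, ix)]


def correct_anisotropy(volume: RawVolume) -> RawVolume:
    """Resample to cubic voxels at the finest of the three spacings.

    Nearest-neighbor interpolation creates no new intensity values.
    Isotropic input is returned unchanged.
    """
    sp = volume.spacing
    if sp.is_isotropic:
        return volume
    target = min(sp.as_tuple())
    new_shape = tuple(
        int(round(n * d / target)) for n, d in zip(volume.shape, sp.as_tuple())
    )
    data = _resample_nn(volume.data, new_shape)
    return RawVolume(data=data, spacing=VoxelSpacing(target, target, target),
                     normalized=volume.normalized)


def correct_anisotropy_labels(labels: LabelVolume, spacing: VoxelSpacing) -> LabelVolume:
    """Apply the identical resampling operator to a label volume."""
    if spacing.is_isotropic:
        return labels
    target = min(spacing.as_tuple())
    new_shape = tuple(
        int(round(n * d / target)) for n, d in zip(labels.shape, spacing.as_tuple())
    )
    return LabelVolume(data=_resample_nn(labels.data, new_shape))


def resize_to_cube(volume: RawVolume, side: int) -> RawVolume:
    """Nearest-neighbor resize so all three extents equal ``side``."""
    if side < 2:
        raise ValueError(f"side must be >= 2, got {side}")
    if volume.shape == (side, side, side):
        return volume
    data = _resample_nn(volume.data, (side, side, side))
    sp = volume.spacing
    # physical extent is preserved; per-axis spacing rescales accordingly
    new_sp = VoxelSpacing(*(d * n / side for d, n in zip(sp.as_tuple(), volume.shape)))
    return RawVolume(data=data, spacing=new_sp, normalized=volume.normalized)


def resize_labels(labels: LabelVolume, side: int) -> LabelVolume:
    """Resize labels with the same nearest-neighbor operator (no blending)."""
    if side < 2:
        raise ValueError(f"side must be >= 2, got {side}")
    if labels.shape == (side, side, side):
        return labels
    return LabelVolume(data=_resample_nn(labels.data, (side, side, side)))


# ---------------------------------------------------------------------------
# bilateral filter

def denoise_bilateral(
    volume: RawVolume,
    sigma_spatial: float = 2.0,
    sigma_range: float | None = None,
) -> RawVolume:
    """Edge-preserving bilateral filter applied slice-wise along z.

    Each output pixel is a weight-normalized average over a square window
    (radius ``ceil(3 * sigma_spatial)``) with Gaussian spatial weights and
    Gaussian range (intensity-difference) weights.  Weights are
    renormalized over the in-image part of the window, so borders are not
    darkened.  ``sigma_range`` defaults to 10% of the intensity range of
    the data type (25.5 for 8-bit, 0.1 for normalized volumes).

    The output range is contained in the input range; a constant volume is
    returned unchanged.
    """
    if sigma_spatial <= 0:
        raise ValueError(f"sigma_spatial must be positive, got {sigma_spatial}")
    if sigma_range is None:
        sigma_range = 0.1 * (1.0 if volume.normalized else 255.0)
    if sigma_range <= 0:
        raise ValueError(f"sigma_range must be positive, got {sigma_range}")

    img = volume.data.astype(np.float64)
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    r = int(np.ceil(3.0 * sigma_spatial))
    inv2ss = 1.0 / (2.0 * sigma_spatial**2)
    inv2sr = 1.0 / (2.0 * sigma_range**2)
    nz, ny, nx = img.shape
    for dy in range(-r, r + 1):
        ys_lo, ys_hi = max(dy, 0), min(ny + dy, ny)      # shifted source rows
        yt_lo, yt_hi = max(-dy, 0), min(ny - dy, ny)     # target rows
        for dx in range(-r, r + 1):
            w_s = np.exp(-(dy * dy + dx * dx) * inv2ss)
            xs_lo, xs_hi = max(dx, 0), min(nx + dx, nx)
            xt_lo, xt_hi = max(-dx, 0), min(nx - dx, nx)
            src = img[:, ys_lo:ys_hi, xs_lo:xs_hi]
            tgt = img[:, yt_lo:yt_hi, xt_lo:xt_hi]
            w = w_s * np.exp(-((src - tgt) ** 2) * inv2sr)
            num[:, yt_lo:yt_hi, xt_lo:xt_hi] += w * src
            den[:, yt_lo:yt_hi, xt_lo:xt_hi] += w
    out = num / den
    if volume.normalized:
        data = out.astype(volume.data.dtype)
    else:
        data = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return RawVolume(data=data, spacing=volume.spacing, normalized=volume.normalized)


def normalize(volume: RawVolume) -> RawVolume:
    """Divide 8-bit intensities by 255, yielding values in [0, 1]."""
    if volume.normalized:
        raise ValueError("volume is already normalized")
    return RawVolume(data=(volume.data.astype(np.float32) / np.float32(255.0)),
                     spacing=volume.spacing, normalized=True)


# ---------------------------------------------------------------------------
# reslicing

@dataclass
class SliceBatch:
    """An ordered stack of 2D sections cut perpendicular to one axis."""

    slices: np.ndarray  # (n, H, W)
    axis: str           # one of "z", "y", "x"
    source_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n, H, W) array")
        n_expected = self.source_shape[AXES.index(self.axis)]
        if self.slices.shape[0] != n_expected:
            raise ValueError(
                f"slice count {self.slices.shape[0]} does not match source "
                f"extent {n_expected} along axis {self.axis}"
            )

    def __len__(self) -> int:
        return self.slices.shape[0]


def reslice(volume: RawVolume | LabelVolume, axis: str) -> SliceBatch:
    """Cut the volume into 2D sections perpendicular to ``axis``.

    Pure re-indexing: section ``i`` along ``y`` is ``data[:, i, :]`` and so
    on.  Raw volumes must be isotropic first — reslicing an anisotropic
    stack would produce geometrically distorted sections.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    if isinstance(volume, RawVolume) and not volume.spacing.is_isotropic:
        raise ValueError("cannot reslice an anisotropic volume; "
                         "run correct_anisotropy first")
    data = volume.data
    k = AXES.index(axis)
    slices = np.ascontiguousarray(np.moveaxis(data, k, 0))
    return SliceBatch(slices=slices, axis=axis, source_shape=data.shape)


def unreslice(batch: SliceBatch) -> np.ndarray:
    """Reassemble a slice batch into its source (z, y, x) array, exactly."""
    k = AXES.index(batch.axis)
    data = np.ascontiguousarray(np.moveaxis(batch.slices, 0, k))
    if data.shape != batch.source_shape:
        raise ValueError(f"reassembled shape {data.shape} does not match "
                         f"source shape {batch.source_shape}")
    return data


def augment_training_set(
    volumes: list[tuple[RawVolume, LabelVolume]],
) -> list[tuple[SliceBatch, SliceBatch]]:
    """Tri-axial augmentation: paired intensity/label sections from all axes.

    For each cube-shaped volume this emits three batch pairs (one per axis),
    i.e. ``3 * side`` paired sections per volume.
    """
    out: list[tuple[SliceBatch, SliceBatch]] = []
    for raw, lab in volumes:
        if raw.shape != lab.shape:
            raise ValueError(
                f"intensity shape {raw.shape} != label shape {lab.shape}"
            )
        for axis in AXES:
            out.append((reslice(raw, axis), reslice(lab, axis)))
    return out


def preprocess_volume(
    volume: RawVolume,
    side: int = 256,
    sigma_spatial: float = 2.0,
    sigma_range: float | None = None,
) -> RawVolume:
    """Full chain: anisotropy correction, bilateral, cube resize, normalize."""
    if side < 16:
        raise ValueError(f"side must be >= 16 for the full chain, got {side}")
    v = correct_anisotropy(volume)
    v = denoise_bilateral(v, sigma_spatial=sigma_spatial, sigma_range=sigma_range)
    v = resize_to_cube(v, side)
    return normalize(v)


def preprocess_labels(labels: LabelVolume, spacing: VoxelSpacing, side: int = 256) -> LabelVolume:
    """Geometric part of the chain for labels (never filtered or blended)."""
    lab = correct_anisotropy_labels(labels, spacing)
    return resize_labels(lab, side)
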