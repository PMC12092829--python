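"""Multi-directional inference, highest-probability fusion, label denoising.

A trained scanning U-Net sees only 2D sections, so its errors depend on
the cutting direction.  Running inference along all three axes yields
three voxel-aligned probability volumes; the fused label at a voxel is the
class holding the single largest of the 3 x n_classes probabilities.  A
categorical mode filter (the label-space analogue of a median filter)
removes speckle noise afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from sbfseg.model import ScanningUNet, predict_slices
from sbfseg.preprocess import AXES, reslice
from sbfseg.volumes import LabelVolume, RawVolume, N_CLASSES


@dataclass
class ProbabilityVolume:
    """Per-class probabilities on the (z, y, x) grid: shape (C, Z, Y, X)."""

    probs: np.ndarray
    axis: str  # inference direction that produced it

    def __post_init__(self) -> None:
        if self.probs.ndim != 4:
            raise ValueError("probs must have shape (n_classes, Z, Y, X)")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-4):
            raise ValueError("per-voxel class probabilities must sum to 1")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.probs.shape


def infer_direction(network: ScanningUNet, volume: RawVolume, axis: str,
                    batch_size: int = 8) -> ProbabilityVolume:
    """Slice along ``axis``, predict each section, reassemble probabilities.

    The output is always on the original (z, y, x) grid, so the three
    directional volumes are voxel-aligned and can be fused directly.
    """
    batch = reslice(volume, axis)
    pred = predict_slices(network, batch, batch_size=batch_size)  # (n, C, H, W)
    # move the class axis out, then undo the reslice on the spatial axes
    k = AXES.index(axis)
    probs = np.moveaxis(np.moveaxis(pred, 1, 0), 1, k + 1)
    return ProbabilityVolume(probs=np.ascontiguousarray(probs), axis=axis)


def fuse_directions(p_z: ProbabilityVolume, p_y: ProbabilityVolume,
                    p_x: ProbabilityVolume) -> LabelVolume:
    """Per-voxel global argmax over the 3 x n_classes probabilities.

    The selected class is the one holding the single largest probability
    across directions.  Exact ties break to the lowest class index first,
    then to axis order z, y, x.
    """
    vols = (p_z, p_y, p_x)
    if not (p_z.shape == p_y.shape == p_x.shape):
        raise ValueError("directional probability volumes differ in shape")
    # order (class, axis) so np.argmax's first-max rule = our tie-break
    stacked = np.stack([v.probs for v in vols], axis=1)  # (C, 3, Z, Y, X)
    c = stacked.shape[0]
    flat = stacked.reshape(c * 3, *stacked.shape[2:])
    labels = (np.argmax(flat, axis=0) // 3).astype(np.uint8)
    return LabelVolume(data=labels)


def direction_disagreement(p_z: ProbabilityVolume, p_y: ProbabilityVolume,
                           p_x: ProbabilityVolume) -> int:
    """Number of voxels where the three per-direction argmax classes differ."""
    args = [v.probs.argmax(axis=0) for v in (p_z, p_y, p_x)]
    agree = (args[0] == args[1]) & (args[1] == args[2])
    return int((~agree).sum())


def denoise_labels(labels: LabelVolume, radius: int = 1) -> LabelVolume:
    """Neighborhood-mode filter on categorical labels.

    For each voxel, count the labels in its (2r+1)^3 cube (clipped at the
    volume border) and take the majority.  Ties keep the center voxel's
    label when it is among the modes, else the lowest class index.  A
    constant volume is unchanged.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    data = labels.data
    size = 2 * radius + 1
    counts = np.empty((N_CLASSES,) + data.shape, dtype=np.int32)
    footprint = np.ones((size, size, size), dtype=np.int32)
    for c in range(N_CLASSES):
        counts[c] = ndimage.correlate((data == c).astype(np.int32), footprint,
                                      mode="constant", cval=0)
    best = counts.max(axis=0)
    winner = counts.argmax(axis=0).astype(np.uint8)  # lowest index on ties
    center_count = np.take_along_axis(counts, data[None].astype(np.intp), axis=0)[0]
    keep_center = center_count == best
    out = np.where(keep_center, data, winner)
    return LabelVolume(data=out.astype(np.uint8))


def predict_volume(network: ScanningUNet, volume: RawVolume,
                   directions: int = 3, denoise_radius: int | None = 1,
                   batch_size: int = 8) -> LabelVolume:
    """Full inference: 1 or 3 directions, fusion, optional mode denoising."""
    if directions == 1:
        pv = infer_direction(network, volume, "z", batch_size=batch_size)
        labels = LabelVolume(data=pv.probs.argmax(axis=0).astype(np.uint8))
    elif directions == 3:
        pz, py, px = (infer_direction(network, volume, ax, batch_size=batch_size)
                      for ax in AXES)
        labels = fuse_directions(pz, py, px)
    else:
        raise ValueError("directions must be 1 or 3")
    if denoise_radius:
        labels = denoise_labels(labels, radius=denoise_radius)
    return labels
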