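"""Carving individual cells out of multi-cell volumes.

The stages mirror the published workflow: a per-section foreground masker
separates cells from background (a pluggable interface, so a promptable
2D model such as SAM can be adapted in; the default is a classical global
Otsu threshold with morphological cleanup), a 3D watershed on the negated
Euclidean distance transform splits the foreground into per-cell
instances, and each instance is cropped — with a margin, neighbors blanked
to background intensity — into a single-cell volume ready for the
segmentation network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from sbfseg.volumes import CellInstanceVolume, RawVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: A 2D masker maps one section to a boolean foreground mask of equal shape.
SectionMasker = Callable[[np.ndarray], np.ndarray]


@dataclass
class ForegroundMask:
    """Boolean cell-vs-background grid aligned with the scene volume."""

    mask: np.ndarray
    provenance: str  # "threshold" or "external-masker"

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 3:
            raise ValueError("mask must be a 3D boolean array")


@dataclass
class CellCrop:
    """A single-cell volume cut from a scene."""

    volume: RawVolume
    instance_id: int
    bounding_box: tuple[int, int, int, int, int, int]  # z0,y0,x0,z1,y1,x1
    margin: int
    instance_mask: np.ndarray  # this instance's voxels within the box


def mask_foreground(volume: RawVolume,
                    masker: SectionMasker | None = None) -> ForegroundMask:
    """Per-z-section foreground masking.

    The default masker thresholds at the global Otsu level of the volume,
    then applies a morphological opening (removing speckle) and fills 2D
    holes (dark organelles inside a cell remain cell).  A volume with no
    intensity contrast yields an empty mask.  An external masker is any
    callable mapping a 2D section to a same-shaped boolean mask.
    """
    data = volume.data
    if masker is not None:
        sections = []
        for z in range(data.shape[0]):
            m = np.asarray(masker(data[z]))
            if m.shape != data[z].shape or m.dtype != bool:
                raise ValueError(
                    f"masker returned shape {m.shape} dtype {m.dtype}; "
                    f"expected boolean {data[z].shape}"
                )
            sections.append(m)
        return ForegroundMask(mask=np.stack(sections), provenance="external-masker")

    if data.min() == data.max():  # flat field: no bimodality, nothing to find
        return ForegroundMask(mask=np.zeros(data.shape, dtype=bool),
                              provenance="threshold")
    thr = threshold_otsu(data)
    mask = np.empty(data.shape, dtype=bool)
    for z in range(data.shape[0]):
        m = data[z] > thr
        m = ndimage.binary_opening(m, structure=np.ones((3, 3), bool))
        m = ndimage.binary_fill_holes(m)
        mask[z] = m
    return ForegroundMask(mask=mask, provenance="threshold")


def watershed_cells(mask: ForegroundMask,
                    min_seed_distance: int = 18) -> CellInstanceVolume:
    """3D watershed instance separation on the distance transform.

    Seeds are local maxima of the Euclidean distance transform separated
    by at least ``min_seed_distance`` voxels (at least one seed per
    connected foreground component); the watershed floods the negated
    distance transform restricted to the mask with 26-connectivity.  The
    instance count equals the seed count; an empty mask yields zero
    instances (not an error).
    """
    m = mask.mask
    if not m.any():
        return CellInstanceVolume(data=np.zeros(m.shape, dtype=np.int32))
    comp, _n = ndimage.label(m, structure=_CONN26)
    dist = ndimage.distance_transform_edt(m)
    coords = peak_local_max(dist, min_distance=min_seed_distance,
                            labels=comp, exclude_border=False)
    # peak_local_max's maximum-filter test keeps equal-height peaks closer
    # than min_distance (plateaus); enforce the separation explicitly with
    # greedy highest-first suppression, independently per component.
    markers = np.zeros(m.shape, dtype=np.int32)
    i = 0
    for c_id in np.unique(comp[tuple(coords.T)]) if coords.size else []:
        cc = coords[comp[tuple(coords.T)] == c_id]
        order = np.lexsort(cc.T[::-1])  # deterministic tie order
        cc = cc[order]
        heights = dist[tuple(cc.T)]
        cc = cc[np.argsort(-heights, kind="stable")]
        accepted: list[np.ndarray] = []
        for p in cc:
            if all(np.linalg.norm(p - q) >= min_seed_distance for q in accepted):
                accepted.append(p)
        for p in accepted:
            i += 1
            markers[tuple(p)] = i
    labels = watershed(-dist, markers=markers, mask=m, connectivity=_CONN26)
    return CellInstanceVolume(data=labels.astype(np.int32))


def crop_cells(volume: RawVolume, instances: CellInstanceVolume,
               margin: int = 2) -> list[CellCrop]:
    """One crop per instance, margin-dilated box, neighbors blanked.

    Voxels belonging to other instances inside the box are replaced by the
    scene's background intensity (median over background voxels) so each
    crop centrally contains exactly its own cell.
    """
    if margin < 0:
        raise ValueError(f"margin must be nonnegative, got {margin}")
    if volume.shape != instances.shape:
        raise ValueError(f"volume shape {volume.shape} != instance shape "
                         f"{instances.shape}")
    k = instances.n_instances
    if k == 0:
        return []
    bg = instances.data == 0
    bg_value = (np.median(volume.data[bg]) if bg.any() else 0)
    bg_value = np.asarray(bg_value).astype(volume.data.dtype)

    crops = []
    slices = ndimage.find_objects(instances.data)
    for inst_id, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        lo = [max(s.start - margin, 0) for s in sl]
        hi = [min(s.stop + margin, n) for s, n in zip(sl, volume.shape)]
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        data = volume.data[box].copy()
        inst_box = instances.data[box]
        data[(inst_box != 0) & (inst_box != inst_id)] = bg_value
        crops.append(CellCrop(
            volume=RawVolume(data=data, spacing=volume.spacing,
                             normalized=volume.normalized),
            instance_id=inst_id,
            bounding_box=(lo[0], lo[1], lo[2], hi[0], hi[1], hi[2]),
            margin=margin,
            instance_mask=inst_box == inst_id,
        ))
    return crops


def extract_pipeline(
    scene: RawVolume,
    masker: SectionMasker | None = None,
    min_seed_distance: int = 18,
    margin: int = 2,
) -> tuple[list[CellCrop], CellInstanceVolume, dict]:
    """mask_foreground -> watershed_cells -> crop_cells, plus a manifest."""
    fg = mask_foreground(scene, masker=masker)
    instances = watershed_cells(fg, min_seed_distance=min_seed_distance)
    crops = crop_cells(scene, instances, margin=margin)
    manifest = {
        "masker": fg.provenance,
        "min_seed_distance": min_seed_distance,
        "margin": margin,
        "n_instances": instances.n_instances,
        "bounding_boxes": [list(c.bounding_box) for c in crops],
    }
    return crops, instances, manifest
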