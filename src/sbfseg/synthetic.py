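"""Synthetic phantom cells and multi-cell scenes with ground-truth labels.

Real serial block-face volumes of *C. merolae* are not publicly deposited,
so training, fusion, evaluation and extraction are exercised on phantoms
that emulate the structure of that data:

* a roughly ellipsoidal cell that pinches into a dumbbell as the division
  stage advances (five stages; two daughter lobes by stage 5);
* one organelle of each type (plastid, mitochondrion, peroxisome, nucleus)
  inside the cytoplasm, duplicated — one copy per daughter lobe — in the
  late stages, mirroring the equal partitioning of organelles to daughters;
* class-dependent brightness with overlapping ranges: mitochondrion and
  nucleus means sit deliberately close to the background mean, as in the
  real images, while the plastid is distinctly bright;
* additive Gaussian voxel noise, optional slice-wise gain jitter, and an
  anisotropy degradation operator so preprocessing can be exercised.

All randomness flows through the spec seeds; no global RNG state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from sbfseg.volumes import CellInstanceVolume, LabelVolume, RawVolume, VoxelSpacing

#: Default per-class target volume fractions within the cell.
DEFAULT_FRACTIONS: dict[int, float] = {2: 0.22, 3: 0.05, 4: 0.015, 5: 0.07}

#: Default class mean brightness (0..255).  Mitochondrion (45) and nucleus
#: (55) overlap the background (30 +/- noise); plastid (200) is distinct.
DEFAULT_MEANS: dict[int, float] = {0: 30.0, 1: 105.0, 2: 200.0,
                                   3: 45.0, 4: 70.0, 5: 55.0}

DEFAULT_SDS: dict[int, float] = {c: 8.0 for c in range(6)}

#: Reduced fractions for small cells (radius < ~12 voxels), where the
#: defaults leave too little cytoplasm for feasible organelle placement.
SMALL_CELL_FRACTIONS: dict[int, float] = {2: 0.14, 3: 0.03, 4: 0.01, 5: 0.045}


def fractions_for_cube(cube_side: int) -> dict[int, float]:
    """Organelle volume fractions appropriate to the cube size."""
    return dict(DEFAULT_FRACTIONS if cube_side >= 48 else SMALL_CELL_FRACTIONS)

_PLACEMENT_ORDER = (2, 5, 3, 4)  # largest organelle first


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cell."""

    stage: int = 1
    cube_side: int = 64
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(1.0, 1.0, 1.0))
    cell_radius: float | None = None  # voxels; default 0.24 * cube_side
    organelle_fractions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS))
    intensity_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MEANS))
    intensity_sds: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    constriction: float | None = None  # default (stage - 1) / 4
    slice_gain_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3, 4, 5):
            raise ValueError(f"stage must be in 1..5, got {self.stage}")
        if self.cube_side < 16:
            raise ValueError(f"cube_side must be >= 16, got {self.cube_side}")
        fracs = self.organelle_fractions
        if any(f < 0 for f in fracs.values()):
            raise ValueError("organelle fractions must be nonnegative")
        if sum(fracs.values()) >= 1.0:
            raise ValueError("organelle fractions must sum to < 1 "
                             "(remainder is cytoplasm)")
        if self.constriction is not None and not 0.0 <= self.constriction <= 1.0:
            raise ValueError("constriction must lie in [0, 1]")

    @property
    def radius(self) -> float:
        return self.cell_radius if self.cell_radius is not None else 0.24 * self.cube_side

    @property
    def pinch(self) -> float:
        """Dumbbell pinch in [0, 1]; 0 at stage 1, 1 at stage 5."""
        if self.constriction is not None:
            return self.constriction
        return (self.stage - 1) / 4.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a multi-cell scene."""

    n_cells: int
    volume_shape: tuple[int, int, int] = (96, 96, 96)
    min_gap: int = 4
    phantoms: tuple[PhantomSpec, ...] | None = None
    max_attempts_per_cell: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.min_gap < 0:
            raise ValueError("min_gap must be nonnegative")
        if self.phantoms is not None and len(self.phantoms) != self.n_cells:
            raise ValueError("phantoms must have one spec per cell")


def _lobe_geometry(spec: PhantomSpec) -> tuple[float, float]:
    """Return (half-separation of lobe centers, lobe radius) in voxels."""
    c = spec.pinch
    r = spec.radius
    return 0.95 * c * r, r * (1.0 - 0.1 * c)


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2) <= 1.0


def _axis_factors(rng: np.random.Generator, spread: float = 0.18) -> np.ndarray:
    f = rng.uniform(1.0 - spread, 1.0 + spread, size=3)
    return f / np.prod(f) ** (1.0 / 3.0)  # volume-preserving


def generate_phantom(spec: PhantomSpec) -> tuple[RawVolume, LabelVolume]:
    """Generate one phantom cell: intensities and voxel-wise ground truth.

    The cell is the union of two ellipsoids whose center separation grows
    with the pinch parameter: coincident at stage 1 (single ellipsoid),
    nearly split dumbbell at stage 5.  Division is along x.  Each organelle
    class forms exactly one connected component at stages 1-3 and two
    mirrored components (one per daughter lobe) at stages 4-5.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.cube_side
    shape = (side, side, side)
    center = np.array([side / 2.0] * 3)

    sep, r_lobe = _lobe_geometry(spec)
    lobe_factors = _axis_factors(rng, spread=0.12)
    semi = r_lobe * lobe_factors
    # cytokinesis is never complete: cap the separation so the two lobes
    # always overlap in a pinched neck and the cell mask stays connected
    sep = min(sep, 0.95 * semi[2])
    half_extent_x = sep + semi[2]
    if half_extent_x + 1.0 > side / 2.0 or max(semi) + 1.0 > side / 2.0:
        raise ValueError(
            f"cell does not fit in the cube: radius {spec.radius:.1f}, "
            f"pinch {spec.pinch:.2f}, cube_side {side}"
        )

    # division axis is x = axis 2
    c0 = center.copy(); c0[2] -= sep
    c1 = center.copy(); c1[2] += sep
    cell = _ellipsoid_mask(shape, c0, semi) | _ellipsoid_mask(shape, c1, semi)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[cell] = 1  # cytoplasm

    # organelles must stay inside the cell behind a thin cytoplasm rim
    rim = 2 if spec.radius >= 12 else 1
    core = ndimage.binary_erosion(cell, iterations=rim)
    occupied = np.zeros(shape, dtype=bool)
    cell_volume = float(cell.sum())
    two_copies = spec.stage >= 4
    lobe_centers = (c0, c1) if two_copies else (0.5 * (c0 + c1),)

    for cls in _PLACEMENT_ORDER:
        frac = spec.organelle_fractions.get(cls, 0.0)
        if frac <= 0.0:
            continue
        target = frac * cell_volume / len(lobe_centers)
        re = (3.0 * target / (4.0 * np.pi)) ** (1.0 / 3.0)
        factors = _axis_factors(rng)
        first_center: np.ndarray | None = None
        for i_copy, lobe_c in enumerate(lobe_centers):
            scale = 1.0
            for attempt in range(150):
                o_semi = np.maximum(re * scale * factors, 1.2)
                if i_copy == 1 and first_center is not None and attempt < 20:
                    # mirror the first daughter copy through the cell center;
                    # fall back to free placement in the lobe if blocked
                    o_center = (2.0 * center - first_center
                                + rng.uniform(-1.0, 1.0, size=3) * (1 + 0.2 * attempt))
                else:
                    spread = min(0.45 + 0.004 * attempt, 0.75)
                    o_center = lobe_c + rng.uniform(-spread, spread, size=3) * semi
                cand = _ellipsoid_mask(shape, o_center, o_semi)
                # full 3^3 dilation keeps distinct organelles out of 26-adjacency
                blocked = (ndimage.binary_dilation(occupied, structure=np.ones((3, 3, 3), bool))
                           if occupied.any() else occupied)
                if cand.any() and not (cand & ~core).any() and not (cand & blocked).any():
                    labels[cand] = cls
                    occupied |= cand
                    if i_copy == 0:
                        first_center = o_center
                    break
                scale *= 0.97
            else:
                raise RuntimeError(
                    f"failed to place organelle class {cls} (stage {spec.stage}, "
                    f"seed {spec.seed}); fractions too large for this geometry"
                )

    means = np.array([spec.intensity_means.get(c, 0.0) for c in range(6)])
    sds = np.array([spec.intensity_sds.get(c, 0.0) for c in range(6)])
    img = means[labels] + rng.normal(0.0, 1.0, size=shape) * sds[labels]
    if spec.slice_gain_jitter > 0:
        gain = 1.0 + rng.normal(0.0, spec.slice_gain_jitter, size=side)
        img *= gain[:, None, None]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return (RawVolume(data=img, spacing=spec.spacing, normalized=False),
            LabelVolume(data=labels))


def default_scene_phantoms(spec: SceneSpec) -> tuple[PhantomSpec, ...]:
    """Per-cell specs for a scene: small cells, stages cycling 1..5."""
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_cells)
    return tuple(
        PhantomSpec(stage=(i % 5) + 1, cube_side=36, cell_radius=8.0,
                    organelle_fractions=dict(SMALL_CELL_FRACTIONS),
                    seed=int(seeds[i]))
        for i in range(spec.n_cells)
    )


def generate_scene(spec: SceneSpec) -> tuple[RawVolume, CellInstanceVolume, LabelVolume]:
    """Generate a multi-cell scene with instance and class ground truth.

    Cells are placed by rejection sampling on bounding spheres so that any
    two cells are separated by at least ``min_gap`` background voxels.
    Raises :class:`RuntimeError` naming the parameters if the placement
    budget is exhausted.
    """
    rng = np.random.default_rng(spec.seed ^ 0x5CE9E)
    phantoms = spec.phantoms if spec.phantoms is not None else default_scene_phantoms(spec)
    shape = spec.volume_shape

    radii = []
    for ph in phantoms:
        sep, r_lobe = _lobe_geometry(ph)
        radii.append(sep + r_lobe * 1.12 + 1.0)  # bounding-sphere radius

    centers: list[np.ndarray] = []
    for i, (ph, R) in enumerate(zip(phantoms, radii)):
        margin = max(R + 1.0, ph.cube_side / 2.0 + 1.0)  # paste cube must fit too
        lo = np.array([margin] * 3)
        hi = np.array(shape, dtype=float) - margin
        if np.any(hi <= lo):
            raise RuntimeError(
                f"cell {i} (radius {R:.1f}) cannot fit in scene shape {shape}"
            )
        for _attempt in range(spec.max_attempts_per_cell):
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - cj) >= R + Rj + spec.min_gap
                   for cj, Rj in zip(centers, radii)):
                centers.append(c)
                break
        else:
            raise RuntimeError(
                f"placement budget exhausted: n_cells={spec.n_cells}, "
                f"volume_shape={shape}, min_gap={spec.min_gap}, "
                f"max_attempts_per_cell={spec.max_attempts_per_cell}"
            )

    bg_mean = DEFAULT_MEANS[0]
    bg_sd = DEFAULT_SDS[0]
    img = np.clip(np.rint(bg_mean + rng.normal(0.0, bg_sd, size=shape)),
                  0, 255).astype(np.uint8)
    labels = np.zeros(shape, dtype=np.uint8)
    instances = np.zeros(shape, dtype=np.int32)

    for k, (ph, c) in enumerate(zip(phantoms, centers), start=1):
        raw_k, lab_k = generate_phantom(ph)
        half = ph.cube_side // 2
        origin = np.rint(c).astype(int) - half
        sl = tuple(slice(o, o + ph.cube_side) for o in origin)
        cell_vox = lab_k.data > 0
        img[sl][cell_vox] = raw_k.data[cell_vox]
        labels[sl][cell_vox] = lab_k.data[cell_vox]
        instances[sl][cell_vox] = k

    spacing = phantoms[0].spacing
    return (RawVolume(data=img, spacing=spacing, normalized=False),
            CellInstanceVolume(data=instances),
            LabelVolume(data=labels))


def degrade_anisotropic(volume: RawVolume, factor: int) -> RawVolume:
    """Keep every ``factor``-th z slice, multiplying dz accordingly.

    Simulates the coarser milling-direction resolution of FIB-SEM stacks so
    anisotropy correction can be exercised on phantoms.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 2:
        raise ValueError(f"factor must be an integer >= 2, got {factor}")
    nz = volume.shape[0]
    if nz % factor != 0:
        raise ValueError(f"z extent {nz} not divisible by factor {factor}")
    sp = volume.spacing
    return RawVolume(
        data=volume.data[::factor].copy(),
        spacing=VoxelSpacing(sp.dz * factor, sp.dy, sp.dx),
        normalized=volume.normalized,
    )


def stage_series(base: PhantomSpec, seed: int) -> list[PhantomSpec]:
    """One phantom spec per division stage, seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    return [replace(base, stage=s, seed=int(seeds[s - 1])) for s in (1, 2, 3, 4, 5)]
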