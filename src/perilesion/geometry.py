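"""Perilesional expansion rings, lesioned tracts and side classification.

Expansion distances default to 2, 4, 6, 8 and 10 mm — multiples of the
2 mm acquisition voxel.  Rings are by default *disjoint concentric shells*
defined on the Euclidean distance transform of the lesion (voxel-center to
nearest lesion-voxel-center distance, per-axis spacing aware): the ring at
distance d_i contains the voxels with distance in (d_{i-1}, d_i].  A
cumulative mode (each expansion includes all closer voxels) is available
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .registry import TractRegistry

__all__ = [
    "LesionTractGeometry", "expansion_rings", "lesioned_tracts",
    "classify_sides", "lesion_volume", "overlap_map", "lesion_compartments",
    "DEFAULT_DISTANCES", "build_geometry",
]

DEFAULT_DISTANCES = (2.0, 4.0, 6.0, 8.0, 10.0)


def expansion_rings(lesion, voxel_size_mm, distances=DEFAULT_DISTANCES,
                    cumulative: bool = False) -> dict:
    """Concentric expansion masks around a lesion.

    Parameters
    ----------
    lesion : bool array
        Non-empty lesion mask.
    voxel_size_mm : float or (3,) sequence
        Per-axis voxel spacing (anisotropic grids supported).
    distances : increasing sequence of mm distances
    cumulative : bool
        If True, each mask contains *all* voxels within its distance
        (still excluding the lesion) rather than only its shell.

    Returns ``{distance: bool mask}``; masks are clipped to the grid,
    pairwise disjoint (shell mode) and disjoint from the lesion.
    """
    lesion = np.asarray(lesion).astype(bool)
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    distances = [float(d) for d in distances]
    if any(b <= a for a, b in zip(distances, distances[1:])) or distances[0] <= 0:
        raise ValueError("distances must be positive and strictly increasing")
    sampling = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    dist = distance_transform_edt(~lesion, sampling=sampling)
    rings = {}
    prev = 0.0
    for d in distances:
        if cumulative:
            rings[d] = (~lesion) & (dist <= d + 1e-9)
        else:
            rings[d] = (dist > prev + 1e-9) & (dist <= d + 1e-9)
        prev = d
    return rings


def lesioned_tracts(lesion, tract_masks: dict) -> set:
    """Names of tracts whose mask overlaps the lesion by >= 1 voxel."""
    lesion = np.asarray(lesion).astype(bool)
    out = set()
    for name, mask in tract_masks.items():
        mask = np.asarray(mask).astype(bool)
        if mask.shape != lesion.shape:
            raise ValueError(f"tract mask {name!r} grid does not match lesion grid")
        if (mask & lesion).any():
            out.add(name)
    return out


def lesion_compartments(lesion, affine, midline_world_x: float | None = None,
                        tentorium_world_z: float | None = None) -> dict:
    """Which (hemisphere, region) compartments contain lesion voxels.

    The midline defaults to the world-x median of the grid, and with no
    tentorium plane the whole grid counts as supratentorial (the phantom
    default).  Returns ``{(hemisphere, region): bool}`` over
    left/right x supratentorial/infratentorial.
    """
    lesion = np.asarray(lesion).astype(bool)
    idx = np.argwhere(lesion)
    out = {(h, r): False for h in ("left", "right")
           for r in ("supratentorial", "infratentorial")}
    if idx.size == 0:
        return out
    world = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
    if midline_world_x is None:
        shape = lesion.shape
        corners = np.array([[0, 0, 0], [s - 1 for s in shape]])
        wc = (affine[:3, :3] @ corners.T).T + affine[:3, 3]
        midline_world_x = float(wc[:, 0].mean())
    right = world[:, 0] >= midline_world_x
    if tentorium_world_z is None:
        infra = np.zeros(len(world), dtype=bool)
    else:
        infra = world[:, 2] < tentorium_world_z
    out[("right", "supratentorial")] = bool(np.any(right & ~infra))
    out[("left", "supratentorial")] = bool(np.any(~right & ~infra))
    out[("right", "infratentorial")] = bool(np.any(right & infra))
    out[("left", "infratentorial")] = bool(np.any(~right & infra))
    return out


def classify_sides(compartments: dict, registry: TractRegistry) -> dict:
    """Label every non-excluded tract as affected or unaffected.

    A lateralized tract is affected iff its own hemisphere-and-region
    compartment contains lesion; the infratentorial region counts as
    contralateral to supratentorial lesions and vice versa.  Bilateral or
    mixed lesions mark every lesion-containing compartment affected.
    Commissural/midline tracts (corpus callosum segments and kin) are
    assigned to the affected family.
    """
    labels = {}
    for name in registry.included:
        hemi = registry.hemisphere(name)
        region = registry.region(name)
        if hemi == "commissural":
            labels[name] = "affected"
        else:
            labels[name] = ("affected" if compartments.get((hemi, region), False)
                            else "unaffected")
    return labels


def lesion_volume(lesion, voxel_size_mm) -> float:
    """Lesion volume in mL (voxel count x voxel volume)."""
    sampling = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    voxel_mm3 = float(np.prod(sampling))
    return float(np.count_nonzero(np.asarray(lesion) > 0) * voxel_mm3 / 1000.0)


def overlap_map(lesions) -> np.ndarray:
    """Voxelwise count of lesions covering each voxel (shared grid)."""
    lesions = [np.asarray(m).astype(bool) for m in lesions]
    if not lesions:
        raise ValueError("no lesion masks given")
    shape = lesions[0].shape
    if any(m.shape != shape for m in lesions):
        raise ValueError("lesion masks are not on one grid")
    return np.sum(np.stack(lesions, axis=0), axis=0).astype(int)


@dataclass
class LesionTractGeometry:
    """Lesion, rings, tracts and side labels for one patient."""

    lesion_mask: np.ndarray
    ring_masks: dict                 # distance (mm) -> bool grid
    tract_masks: dict                # name -> bool grid
    lesioned_tracts: set
    side_labels: dict                # name -> affected | unaffected
    lesion_volume_mL: float
    voxel_size_mm: np.ndarray = field(default=None)
    cumulative: bool = False

    def __post_init__(self):
        shape = self.lesion_mask.shape
        les = self.lesion_mask.astype(bool)
        union = np.zeros(shape, dtype=int)
        for d, m in self.ring_masks.items():
            if (m & les).any():
                raise ValueError(f"ring at {d} mm overlaps the lesion")
            union += m.astype(int)
        if not self.cumulative and np.any(union > 1):
            raise ValueError("rings are not pairwise disjoint")
        for name in self.lesioned_tracts:
            if not (self.tract_masks[name].astype(bool) & les).any():
                raise ValueError(f"{name!r} marked lesioned but does not "
                                 "intersect the lesion")


def build_geometry(lesion, tract_masks: dict, registry: TractRegistry,
                   affine, distances=DEFAULT_DISTANCES,
                   cumulative: bool = False,
                   tentorium_world_z: float | None = None) -> LesionTractGeometry:
    """Assemble the full geometry for one patient."""
    voxel_size = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    rings = expansion_rings(lesion, voxel_size, distances, cumulative=cumulative)
    tracts = {n: np.asarray(m).astype(bool) for n, m in tract_masks.items()}
    lt = lesioned_tracts(lesion, tracts)
    comp = lesion_compartments(lesion, affine, tentorium_world_z=tentorium_world_z)
    labels = classify_sides(comp, registry)
    vol = lesion_volume(lesion, voxel_size)
    return LesionTractGeometry(np.asarray(lesion).astype(bool), rings, tracts,
                               lt, labels, vol, voxel_size, cumulative=cumulative)
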