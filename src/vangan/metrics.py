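"""Segmentation metrics and skeleton-based vascular descriptors.

Voxelwise metrics (F1, IoU, sensitivity, specificity) follow the standard
confusion-matrix formulas.  Vascular topology is measured on the medial-axis
skeleton of a binary mask: the skeleton voxels form a graph (26-adjacency,
with redundant diagonal chords pruned so that digitally-thin curves map to
simple paths), from which connected components (Betti-0), independent loops
(Betti-1 = E - V + C) and geometric summaries (diameters from the Euclidean
distance transform, network volume, surface density, connectivity) are
derived.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from ._thinning import thin as _thin
from .vessel_synth import BinaryMask3D

__all__ = ["ConfusionCounts", "SkeletonGraph", "VascularDescriptors",
           "confusion", "seg_metrics", "skeletonize", "betti_numbers",
           "descriptors"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _mask_values(m) -> np.ndarray:
    if isinstance(m, BinaryMask3D):
        return m.values
    arr = np.asarray(m)
    return (arr > 0).astype(np.uint8)


def confusion(pred, truth) -> ConfusionCounts:
    p, t = _mask_values(pred), _mask_values(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p, t = p.astype(bool), t.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)))


def seg_metrics(c: ConfusionCounts) -> Dict[str, float]:
    """F1, IoU, sensitivity, specificity from confusion counts.

    Degenerate conventions: with both masks empty F1 = IoU = 1; sensitivity
    is reported as 1 when there are no positives in the truth; specificity
    as 1 when there are no negatives.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    pos_pred, pos_true = tp + fp, tp + fn
    precision = tp / pos_pred if pos_pred else 1.0
    sensitivity = tp / pos_true if pos_true else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    if pos_pred == 0 and pos_true == 0:
        f1 = 1.0
        iou = 1.0
    else:
        f1 = (2 * precision * sensitivity / (precision + sensitivity)
              if precision + sensitivity > 0 else 0.0)
        iou = tp / (tp + fp + fn)
    return {"f1": f1, "iou": iou, "sensitivity": sensitivity,
            "specificity": specificity, "precision": precision}


@dataclass
class SkeletonGraph:
    """Voxel skeleton graph: node coordinates, local radii (um), edges."""
    coords: np.ndarray               # (M, 3) int voxel coordinates
    radii_um: np.ndarray             # (M,) local radius from the EDT
    edges: List[Tuple[int, int]]
    voxel_size_um: float = 20.0

    @property
    def n_nodes(self) -> int:
        return len(self.radii_um)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


_OFFSETS = [(i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) > (0, 0, 0)]  # 13 positive-lexicographic offsets
_ALL_NEIGHBOURS = [(i, j, k)
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]


def _rank(offset: Tuple[int, int, int]) -> int:
    return sum(1 for v in offset if v != 0)


def skeletonize(mask) -> SkeletonGraph:
    """Medial-axis thinning plus graph extraction.

    Edges connect 26-adjacent skeleton voxels; a diagonal edge is dropped
    when a strictly lower-rank two-step path through a common neighbour
    exists (it is a chord of a triangle and carries no topological
    information for a thin skeleton).  Node radii are the Euclidean
    distance-transform values at skeleton voxels times the voxel size.
    """
    voxel_size = mask.voxel_size_um if isinstance(mask, BinaryMask3D) else 20.0
    values = _mask_values(mask)
    if not values.any():
        return SkeletonGraph(np.zeros((0, 3), int), np.zeros(0), [],
                             voxel_size)
    skel = _thin(values)
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    edt = ndimage.distance_transform_edt(values)
    radii = np.maximum(edt[skel], 0.5) * voxel_size
    voxels = set(index)
    edges: List[Tuple[int, int]] = []
    for c in coords:
        cu = tuple(c)
        for off in _OFFSETS:
            cv = (cu[0] + off[0], cu[1] + off[1], cu[2] + off[2])
            if cv not in voxels:
                continue
            r = _rank(off)
            if r > 1 and _has_shortcut(cu, cv, r, voxels):
                continue
            edges.append((index[cu], index[cv]))
    return SkeletonGraph(coords, radii, edges, voxel_size)


def _has_shortcut(u: Tuple[int, int, int], v: Tuple[int, int, int],
                  rank_uv: int, voxels: set) -> bool:
    """True if u and v share a neighbour reachable by strictly lower-rank
    steps from both (making edge (u, v) a redundant triangle chord)."""
    for off in _ALL_NEIGHBOURS:
        w = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
        if w == v or w not in voxels:
            continue
        r_uw = _rank(off)
        dv = (w[0] - v[0], w[1] - v[1], w[2] - v[2])
        if max(abs(d) for d in dv) > 1:
            continue
        r_wv = _rank(dv)
        if r_uw < rank_uv and r_wv < rank_uv:
            return True
    return False


def betti_numbers(sk: SkeletonGraph) -> Tuple[int, int]:
    """(Betti-0, Betti-1) of the skeleton graph via union-find."""
    n = sk.n_nodes
    if n == 0:
        return 0, 0
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in sk.edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    components = len({find(i) for i in range(n)})
    cycles = sk.n_edges - n + components
    return components, cycles


def _surface_area_mm2(values: np.ndarray, voxel_size_um: float) -> float:
    """Exposed-face counting: every foreground voxel face adjacent to
    background (or the volume boundary) contributes one face area."""
    faces = 0
    fg = values.astype(bool)
    for axis in range(3):
        shifted = np.zeros_like(fg)
        sl_to = [slice(None)] * 3
        sl_from = [slice(None)] * 3
        sl_to[axis] = slice(1, None)
        sl_from[axis] = slice(None, -1)
        shifted[tuple(sl_to)] = fg[tuple(sl_from)]
        faces += int(np.count_nonzero(fg & ~shifted))
        shifted = np.zeros_like(fg)
        shifted[tuple(sl_from)] = fg[tuple(sl_to)]
        faces += int(np.count_nonzero(fg & ~shifted))
    face_area_mm2 = (voxel_size_um / 1000.0) ** 2
    return faces * face_area_mm2


@dataclass
class VascularDescriptors:
    diameter_sd_um: float
    network_volume_mm3: float
    surface_density_per_mm: float
    cc_density_per_mm3: float
    loop_density_per_mm3: float
    connectivity_pct: float


def descriptors(sk: SkeletonGraph, mask, tissue_volume_mm3: float
                ) -> VascularDescriptors:
    """Skeleton/mask summary statistics normalised by tissue volume.

    Betti-0 and Betti-1 densities come from the skeleton graph; network
    volume and connectivity from 26-connected components of the mask;
    surface density from exposed voxel faces.
    """
    if tissue_volume_mm3 <= 0:
        raise ValueError("tissue volume must be > 0")
    values = _mask_values(mask)
    voxel_size = mask.voxel_size_um if isinstance(mask, BinaryMask3D) \
        else sk.voxel_size_um
    if sk.n_nodes == 0 or not values.any():
        return VascularDescriptors(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    b0, b1 = betti_numbers(sk)
    voxel_mm3 = (voxel_size / 1000.0) ** 3
    network_volume = float(values.sum()) * voxel_mm3
    labels, n_comp = ndimage.label(values, structure=np.ones((3, 3, 3)))
    comp_volumes = np.bincount(labels.ravel())[1:]
    connectivity = 100.0 * comp_volumes.max() / comp_volumes.sum()
    return VascularDescriptors(
        diameter_sd_um=float(np.std(2.0 * sk.radii_um)),
        network_volume_mm3=network_volume,
        surface_density_per_mm=_surface_area_mm2(values, voxel_size)
        / tissue_volume_mm3,
        cc_density_per_mm3=b0 / tissue_volume_mm3,
        loop_density_per_mm3=b1 / tissue_volume_mm3,
        connectivity_pct=float(connectivity))
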