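"""Stochastic L-system synthesis of 3-D branching vascular networks.

A stochastic string-rewriting grammar (a "V-System") generates branching
instructions; a 3-D turtle interprets them into a geometric graph of
centreline nodes with radii; the graph is rasterised into a binary
segmentation mask by capsule (cylinder + hemispherical caps) coverage of
voxel centres.  These masks form the segmentation domain of the unpaired
training set.

The default grammar (axiom ``F``, rule ``F -> F[+F][-F]``, branch angles
~ N(40deg, 10deg), per-branch length ratio 0.8 and radius ratio 0.75)
reproduces the qualitative phenotype of mesoscopic vascular trees --
branching order, diameter taper, tortuosity -- while every parameter stays
configurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = ["LSystemSpec", "VesselGraph", "BinaryMask3D", "VesselParseError",
           "derive_string", "string_to_graph", "voxelize", "generate_dataset",
           "DEFAULT_RULES"]

TURTLE_ALPHABET = frozenset("F+-&^\\/[]")

DEFAULT_RULES: Dict[str, List[Tuple[str, float]]] = {
    "F": [("F[+F][-F]", 1.0)],
}


class VesselParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at index {position})")
        self.position = position


@dataclass
class LSystemSpec:
    """Parameters of the stochastic vascular grammar and its turtle.

    Angles are in degrees as ``(mean, sd)`` pairs; lengths/radii in microns.
    ``length_ratio`` and ``radius_ratio`` scale step length and vessel radius
    each time a branch is entered.  ``shrink_prob`` halves the branch radius
    ratio (abnormally thin daughter vessels); ``aneurysm_prob`` locally
    doubles a node radius (focal dilation).
    """
    axiom: str = "F"
    rules: Dict[str, List[Tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_RULES.items()})
    iterations: int = 6
    step_length_um: float = 400.0
    length_ratio: float = 0.8
    initial_radius_um: float = 100.0
    radius_ratio: float = 0.75
    branch_angle_deg: Tuple[float, float] = (40.0, 10.0)
    tortuosity_angle_deg: Tuple[float, float] = (0.0, 5.0)
    shrink_prob: float = 0.05
    aneurysm_prob: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.iterations <= 12:
            raise ValueError("iterations must be in [0, 12]")
        for name in ("step_length_um", "initial_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("length_ratio", "radius_ratio"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("shrink_prob", "aneurysm_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for sym, prods in self.rules.items():
            total = sum(p for _, p in prods)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"rule probabilities for {sym!r} sum to {total}, not 1")


@dataclass
class VesselGraph:
    """Geometric centreline graph: node positions (um), radii (um), edges."""
    positions: np.ndarray            # (N, 3) float
    radii: np.ndarray                # (N,) float > 0
    edges: List[Tuple[int, int]]
    root: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        n = len(self.radii)
        if len(self.positions) != n:
            raise ValueError("positions and radii length mismatch")
        if n and np.any(self.radii <= 0):
            raise ValueError("all radii must be > 0")
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("edge references an unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.radii)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class BinaryMask3D:
    """Voxel grid of {0,1} vessel labels with isotropic spacing, (X, Y, Z)."""
    values: np.ndarray
    voxel_size_um: float = 20.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("mask must be a non-empty 3-D grid")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be > 0")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def foreground_fraction(self) -> float:
        return float(self.values.mean())


# -- string derivation ------------------------------------------------------

def derive_string(spec: LSystemSpec, max_length: int = 500_000) -> str:
    """Apply the stochastic production rules ``iterations`` times to the
    axiom; deterministic for a given ``spec.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    s = spec.axiom
    prods = {sym: ([p for p, _ in alts], np.array([w for _, w in alts]))
             for sym, alts in spec.rules.items()}
    for _ in range(spec.iterations):
        parts: List[str] = []
        length = 0
        for ch in s:
            if ch in prods:
                options, weights = prods[ch]
                chosen = options[rng.choice(len(options), p=weights)]
            elif ch in TURTLE_ALPHABET:
                chosen = ch
            else:
                raise ValueError(
                    f"symbol {ch!r} has no production rule and is not a "
                    f"turtle terminal")
            parts.append(chosen)
            length += len(chosen)
            if length > max_length:
                raise ValueError(
                    f"derived string exceeds the {max_length}-symbol cap")
        s = "".join(parts)
    return s


# -- turtle interpretation --------------------------------------------------

def _rot(axis: np.ndarray, theta_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def string_to_graph(s: str, spec: LSystemSpec,
                    origin: Sequence[float] = (0.0, 0.0, 0.0),
                    frame: np.ndarray | None = None,
                    rng: np.random.Generator | None = None) -> VesselGraph:
    """3-D turtle interpretation of an instruction string.

    ``F`` advances one step (emitting a node and an edge); ``+``/``-`` yaw,
    ``&``/``^`` pitch and ``\\``/``/`` roll the orthonormal turtle frame by a
    branch angle sampled from ``spec.branch_angle_deg``; ``[``/``]`` push and
    pop turtle state, scaling radius and step length on branch entry; each
    step applies a small random tortuosity rotation.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    # frame columns: heading, left, up
    M = np.eye(3) if frame is None else np.asarray(frame, dtype=float).copy()
    pos = np.asarray(origin, dtype=float).copy()
    radius = float(spec.initial_radius_um)
    step = float(spec.step_length_um)
    b_mean, b_sd = spec.branch_angle_deg
    t_mean, t_sd = spec.tortuosity_angle_deg

    positions = [pos.copy()]
    radii = [radius]
    edges: List[Tuple[int, int]] = []
    current = 0
    stack: List[tuple] = []

    def branch_angle(sign: float) -> float:
        return np.deg2rad(sign * rng.normal(b_mean, b_sd))

    for i, ch in enumerate(s):
        if ch == "F":
            if t_sd > 0 or t_mean != 0:
                # tortuosity: bend heading by a small random angle about a
                # random axis perpendicular to it
                roll = rng.uniform(0.0, 2 * np.pi)
                bend = np.deg2rad(rng.normal(t_mean, t_sd))
                axis = np.cos(roll) * M[:, 1] + np.sin(roll) * M[:, 2]
                R = _rot(axis, bend)
                M = R @ M
            pos = pos + step * M[:, 0]
            node_radius = radius
            if spec.aneurysm_prob > 0 and rng.random() < spec.aneurysm_prob:
                node_radius = radius * 2.0
            positions.append(pos.copy())
            radii.append(node_radius)
            edges.append((current, len(radii) - 1))
            current = len(radii) - 1
        elif ch in "+-":
            M = M @ _rot(np.array([0.0, 0.0, 1.0]),
                         branch_angle(+1.0 if ch == "+" else -1.0))
        elif ch in "&^":
            M = M @ _rot(np.array([0.0, 1.0, 0.0]),
                         branch_angle(+1.0 if ch == "&" else -1.0))
        elif ch in "\\/":
            M = M @ _rot(np.array([1.0, 0.0, 0.0]),
                         branch_angle(+1.0 if ch == "\\" else -1.0))
        elif ch == "[":
            stack.append((pos.copy(), M.copy(), radius, step, current))
            ratio = spec.radius_ratio
            if spec.shrink_prob > 0 and rng.random() < spec.shrink_prob:
                ratio *= 0.5
            radius *= ratio
            step *= spec.length_ratio
        elif ch == "]":
            if not stack:
                raise VesselParseError("unmatched ']'", i)
            pos, M, radius, step, current = stack.pop()
        else:
            raise VesselParseError(f"unknown turtle symbol {ch!r}", i)
    if stack:
        raise VesselParseError("unclosed '['", len(s))
    return VesselGraph(np.array(positions), np.array(radii), edges)


# -- voxelization -----------------------------------------------------------

def voxelize(graph: VesselGraph, shape: Tuple[int, int, int] = (512, 512, 140),
             voxel_size_um: float = 20.0) -> BinaryMask3D:
    """Rasterise a vessel graph into a binary mask.

    Each edge is a capsule with linearly interpolated radius; a voxel is
    foreground iff its centre (at ``(i + 0.5) * voxel_size``) lies inside any
    capsule.  Geometry outside the grid is clipped.
    """
    if voxel_size_um <= 0:
        raise ValueError("voxel size must be > 0")
    vs = float(voxel_size_um)
    mask = np.zeros(shape, dtype=np.uint8)
    if graph.n_nodes == 0:
        return BinaryMask3D(mask, vs)
    pos = graph.positions
    rad = graph.radii
    for i, j in graph.edges:
        p1, p2 = pos[i], pos[j]
        r1, r2 = rad[i], rad[j]
        rmax = max(r1, r2)
        lo = np.minimum(p1, p2) - rmax
        hi = np.maximum(p1, p2) + rmax
        i0 = np.maximum(np.floor(lo / vs - 0.5).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / vs + 0.5).astype(int) + 1,
                        np.array(shape))
        if np.any(i0 >= i1):
            continue
        ax = (np.arange(i0[0], i1[0]) + 0.5) * vs
        ay = (np.arange(i0[1], i1[1]) + 0.5) * vs
        az = (np.arange(i0[2], i1[2]) + 0.5) * vs
        dx = (ax - p1[0])[:, None, None]
        dy = (ay - p1[1])[None, :, None]
        dz = (az - p1[2])[None, None, :]
        u = p2 - p1
        seg_len2 = float(u @ u)
        if seg_len2 == 0.0:
            t = np.zeros(np.broadcast_shapes(dx.shape, dy.shape, dz.shape))
        else:
            t = (dx * u[0] + dy * u[1] + dz * u[2]) / seg_len2
            t = np.clip(t, 0.0, 1.0)
        qx = dx - t * u[0]
        qy = dy - t * u[1]
        qz = dz - t * u[2]
        dist2 = qx * qx + qy * qy + qz * qz
        r_t = r1 + (r2 - r1) * t
        sub = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        sub |= (dist2 <= r_t * r_t)
    return BinaryMask3D(mask, vs)


# -- dataset generation -----------------------------------------------------

def generate_dataset(n: int, spec: LSystemSpec | None = None, seed: int = 0,
                     shape: Tuple[int, int, int] = (512, 512, 140),
                     voxel_size_um: float = 20.0,
                     iteration_range: Tuple[int, int] = (5, 8),
                     max_attempts: int = 20) -> List[BinaryMask3D]:
    """Generate ``n`` reproducible masks; each is regenerated (with a fresh
    substream) until it contains at least one foreground voxel.

    Branching order is sampled uniformly from ``iteration_range`` per mask
    and the tree root/orientation is randomised inside the grid.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    spec = spec or LSystemSpec()
    extent = np.array(shape) * voxel_size_um
    masks: List[BinaryMask3D] = []
    for index in range(n):
        for attempt in range(max_attempts):
            ss = np.random.SeedSequence((seed, index, attempt))
            rng = np.random.default_rng(ss)
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            iters = int(rng.integers(iteration_range[0],
                                     iteration_range[1] + 1))
            spec_i = replace(spec, seed=sub_seed, iterations=iters)
            s = derive_string(spec_i)
            origin = np.array([
                rng.uniform(0.1, 0.3) * extent[0],
                rng.uniform(0.3, 0.7) * extent[1],
                rng.uniform(0.3, 0.7) * extent[2]])
            yaw = rng.uniform(0.0, 2 * np.pi)
            pitch = np.deg2rad(rng.normal(0.0, 10.0))
            M = _rot(np.array([0.0, 0.0, 1.0]), yaw) \
                @ _rot(np.array([0.0, 1.0, 0.0]), pitch)
            graph = string_to_graph(s, spec_i, origin=origin, frame=M)
            mask = voxelize(graph, shape=shape, voxel_size_um=voxel_size_um)
            if mask.values.any():
                masks.append(mask)
                break
        else:
            raise RuntimeError(
                f"failed to generate a non-empty mask for index {index}")
    return masks
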