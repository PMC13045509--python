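"""Centerline extraction: skeletonization, branch pruning, arc length.

The vessel mask of each cMPR slice is thinned to a one-pixel-wide skeleton
(Zhang-Suen-class topological thinning), side branches are pruned by
keeping the maximum-weight geodesic between skeleton endpoints on the
8-connectivity pixel graph (axial steps weigh 1, diagonal steps sqrt(2)),
and the surviving path is parameterized by cumulative arc length. Each
path point carries a normal/stenotic label taken from the nearest labelled
mask pixel in its 3x3 neighbourhood (ties favour stenotic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from skimage.morphology import thin

from .config import logger

__all__ = [
    "SkeletonPath",
    "EmptySkeletonError",
    "skeletonize_mask",
    "prune_to_main_path",
    "arc_length",
    "label_path_points",
    "extract_centerline",
]

SQRT2 = math.sqrt(2.0)

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class EmptySkeletonError(ValueError):
    """Raised when a slice has no vessel pixels to skeletonize."""


@dataclass
class SkeletonPath:
    """Ordered centerline pixel chain with arc-length parameterization.

    ``points`` is an (n, 2) integer array of (row, col); consecutive points
    are 8-neighbours. ``s_mm`` is strictly increasing cumulative arc length
    with ``s_mm[0] == 0``. ``point_label`` is 0 (normal) or 1 (stenotic) per
    point.
    """

    points: np.ndarray
    s_mm: np.ndarray
    point_label: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64)
        self.s_mm = np.asarray(self.s_mm, dtype=np.float64)
        self.point_label = np.asarray(self.point_label, dtype=np.uint8)
        n = len(self.points)
        if not (len(self.s_mm) == len(self.point_label) == n):
            raise ValueError("points, s_mm and point_label must have equal length")
        if n > 1:
            steps = np.abs(np.diff(self.points, axis=0))
            if steps.max() > 1:
                raise ValueError("consecutive path points must be 8-neighbors")
            if not np.all(np.diff(self.s_mm) > 0):
                raise ValueError("s_mm must be strictly increasing")
        if n >= 1 and self.s_mm[0] != 0.0:
            raise ValueError("s_mm must start at 0")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_length_mm(self) -> float:
        return float(self.s_mm[-1]) if len(self) else 0.0


def skeletonize_mask(
    mask_slice: np.ndarray, labels_as_vessel: FrozenSet[int] = frozenset({1, 2})
) -> np.ndarray:
    """Thin the vessel region of one slice to a one-pixel-wide skeleton.

    Returns a boolean array; the skeleton is a subset of the vessel pixels
    and contains no 2x2 all-skeleton block. Raises
    :class:`EmptySkeletonError` when the slice has no vessel pixels.
    """
    binary = np.isin(np.asarray(mask_slice), list(labels_as_vessel))
    if not binary.any():
        raise EmptySkeletonError("slice contains no vessel pixels")
    return _remove_square_blocks(thin(binary))


_NBH = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def _n_components(cells: List[Tuple[int, int]], max_dist: int) -> int:
    """Connected components among neighbourhood offsets; adjacency is
    Chebyshev distance 1 (max_dist=1, 8-connectivity) or Manhattan distance
    1 (max_dist=0, 4-connectivity)."""
    parent = {cell: cell for cell in cells}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            dr, dc = abs(a[0] - b[0]), abs(a[1] - b[1])
            adj = max(dr, dc) == 1 if max_dist else dr + dc == 1
            if adj:
                parent[find(a)] = find(b)
    return len({find(cell) for cell in cells})


def _is_simple(skel: np.ndarray, r: int, c: int) -> bool:
    """Simple-point test for (8, 4) connectivity: deleting the pixel
    preserves topology iff its foreground neighbours form one 8-connected
    component and the background 4-neighbours belong to one 4-connected
    background component of the neighbourhood."""
    H, W = skel.shape

    def val(d):
        rr, cc = r + d[0], c + d[1]
        return bool(skel[rr, cc]) if 0 <= rr < H and 0 <= cc < W else False

    fg = [d for d in _NBH if val(d)]
    if not fg or _n_components(fg, max_dist=1) != 1:
        return False
    bg = [d for d in _NBH if not val(d)]
    bg4_center = [d for d in bg if abs(d[0]) + abs(d[1]) == 1]
    if not bg4_center:
        return False
    # count 4-connected bg components that touch a 4-neighbour of the center
    parent = {cell: cell for cell in bg}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(bg):
        for b in bg[i + 1:]:
            if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1:
                parent[find(a)] = find(b)
    touching = {find(d) for d in bg4_center}
    return len(touching) == 1


def _remove_square_blocks(skel: np.ndarray) -> np.ndarray:
    """Delete simple pixels until no 2x2 window is fully skeletal.

    Thinning algorithms of the two-subiteration family can leave a 2x2
    block at branch junctions; this deterministic cleanup restores the
    one-pixel-wide guarantee without changing topology.
    """
    skel = np.asarray(skel, dtype=bool).copy()
    changed = True
    while changed:
        changed = False
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        for r, c in np.argwhere(blocks):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if skel[rr, cc] and _is_simple(skel, rr, cc):
                    skel[rr, cc] = False
                    changed = True
                    break
    return skel


def _skeleton_graph(skeleton: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skeleton)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(pixels)
    for (r, c) in pixels:
        for dr, dc in _NEIGHBORS8:
            nb = (r + dr, c + dc)
            if nb in pixels and nb > (r, c):
                g.add_edge((r, c), nb, weight=1.0 if dr == 0 or dc == 0 else SQRT2)
    return g


def _path_weight(path: Sequence[Tuple[int, int]]) -> float:
    w = 0.0
    for a, b in zip(path[:-1], path[1:]):
        w += 1.0 if a[0] == b[0] or a[1] == b[1] else SQRT2
    return w


def prune_to_main_path(skeleton: np.ndarray) -> np.ndarray:
    """Prune side branches: keep the longest geodesic between endpoints.

    The skeleton pixels form an 8-connectivity graph with unit/sqrt(2) edge
    weights; the retained path is the maximum-weight shortest path between
    two degree-1 pixels (the weighted graph diameter restricted to
    endpoints). Off-path pixels are discarded. Equal-weight ties break on
    lexicographic endpoint coordinates. Returns an ordered (n, 2) array,
    oriented proximal to distal (endpoint nearer the left image border
    first).
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    n_px = int(skeleton.sum())
    if n_px == 0:
        raise EmptySkeletonError("empty skeleton")
    if n_px == 1:
        r, c = np.argwhere(skeleton)[0]
        return np.array([[r, c]], dtype=np.int64)

    g = _skeleton_graph(skeleton)
    if g.number_of_edges() >= g.number_of_nodes():
        logger.warning("skeleton contains a cycle; geodesic pruning keeps a simple path")
    endpoints = sorted(n for n in g.nodes if g.degree(n) == 1)
    if not endpoints:
        # pure cycle: anchor at the lexicographically smallest pixel
        endpoints = [min(g.nodes)]

    best: Optional[List[Tuple[int, int]]] = None
    best_key: Tuple[float, Tuple[int, int], Tuple[int, int]] = (-1.0, (0, 0), (0, 0))
    for src in endpoints:
        dist, paths = nx.single_source_dijkstra(g, src, weight="weight")
        targets = endpoints if len(endpoints) > 1 else list(g.nodes)
        for dst in targets:
            if dst == src or dst not in dist:
                continue
            # tie-break deterministically on (weight, -endpoints) so larger
            # weight wins, then lexicographically smaller endpoint pair
            key = (dist[dst], tuple(np.negative(src)), tuple(np.negative(dst)))
            if best is None or key > best_key:
                best, best_key = paths[dst], key
    if best is None:  # disconnected single components handled above; safeguard
        best = [min(g.nodes)]

    # orient proximal (left image border) -> distal; ties on row
    if (best[0][1], best[0][0]) > (best[-1][1], best[-1][0]):
        best = best[::-1]
    return np.asarray(best, dtype=np.int64)


def arc_length(points: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Cumulative arc length along an 8-connected pixel path, in mm.

    Axial steps contribute ``spacing_mm``; diagonal steps
    ``spacing_mm * sqrt(2)``.
    """
    points = np.asarray(points, dtype=np.int64)
    if len(points) == 0:
        return np.zeros(0)
    steps = np.abs(np.diff(points, axis=0))
    if len(steps) and (steps.max() > 1 or steps.sum(axis=1).min() == 0):
        raise ValueError("consecutive points must be distinct 8-neighbors")
    lengths = np.where(steps.sum(axis=1) == 2, SQRT2, 1.0) * spacing_mm
    return np.concatenate([[0.0], np.cumsum(lengths)])


def label_path_points(points: np.ndarray, mask_slice: np.ndarray) -> np.ndarray:
    """Per-point normal(0)/stenotic(1) labels from the aligned mask.

    A point is stenotic iff the nearest labelled mask pixel within its 3x3
    neighbourhood has label 2; equidistant ties favour stenotic. (A skeleton
    point lies on the vessel, so normally its own mask value decides.)
    """
    mask_slice = np.asarray(mask_slice)
    H, W = mask_slice.shape
    labels = np.zeros(len(points), dtype=np.uint8)
    for i, (r, c) in enumerate(np.asarray(points, dtype=np.int64)):
        best_dist, stenotic = np.inf, False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < H and 0 <= cc < W):
                    continue
                val = mask_slice[rr, cc]
                if val == 0:
                    continue
                d = dr * dr + dc * dc
                if d < best_dist:
                    best_dist, stenotic = d, val == 2
                elif d == best_dist and val == 2:
                    stenotic = True
        labels[i] = 1 if stenotic else 0
    return labels


def extract_centerline(
    mask_slice: np.ndarray, spacing_mm: float
) -> SkeletonPath:
    """Full per-slice centerline: skeletonize, prune, parameterize, label."""
    skel = skeletonize_mask(mask_slice)
    points = prune_to_main_path(skel)
    s_mm = arc_length(points, spacing_mm)
    labels = label_path_points(points, mask_slice)
    return SkeletonPath(points=points, s_mm=s_mm, point_label=labels, spacing_mm=spacing_mm)
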