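"""Thinning of single-root masks to one-pixel-wide medial curves.

The default thinning method is K3M, an iterative border-marking scheme: each
iteration marks the current border pixels (3x3 neighbourhood weight in the
border lookup set) and then runs five deletion phases that remove marked
pixels having 3, 3-4, 3-5, 3-6 and 3-7 "sticking" foreground neighbours
respectively, testing the 8-neighbourhood weight against per-phase lookup
sets; iterations repeat to a fixpoint and a final pass sequentially removes
remaining 8-simple pixels (endpoints protected) so the residue is strictly
one pixel wide.  Deletions are applied sequentially in row-major order so
results are bit-stable.

Neighbour weights (clockwise from north)::

    128   1   2
     64   p   4
     32  16   8

A ``fallback`` method (scikit-image's thinning plus the same final
unitary-width pass) satisfies identical postconditions and serves as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from rootgrain.instance_postprocess import InstanceMask

__all__ = [
    "CyclicSkeletonError",
    "MultiComponentError",
    "Polyline",
    "Skeleton",
    "prune_spurs",
    "thin",
    "to_polyline",
]

# neighbour offsets as (dy, dx), clockwise from north, with weights 1..128
_OFFSETS = (
    (-1, 0, 1),
    (-1, 1, 2),
    (0, 1, 4),
    (1, 1, 8),
    (1, 0, 16),
    (1, -1, 32),
    (0, -1, 64),
    (-1, -1, 128),
)

# K3M lookup sets: border pixels (A0) and deletable configurations for the
# phases removing pixels with 3, 3-4, 3-5, 3-6 and 3-7 sticking neighbours.
_A0 = frozenset({
    3, 6, 7, 12, 14, 15, 24, 28, 30, 31, 48, 56, 60, 62, 63, 96, 112, 120,
    124, 126, 127, 129, 131, 135, 143, 159, 191, 192, 193, 195, 199, 207,
    223, 224, 225, 227, 231, 239, 240, 241, 243, 247, 248, 249, 251, 252,
    253, 254,
})
_A1 = frozenset({7, 14, 28, 56, 112, 131, 193, 224})
_A2 = frozenset({
    7, 14, 15, 28, 30, 56, 60, 112, 120, 131, 135, 193, 195, 224, 225, 240,
})
_A3 = frozenset({
    7, 14, 15, 28, 30, 31, 56, 60, 62, 112, 120, 124, 131, 135, 143, 193,
    195, 199, 224, 225, 227, 240, 241, 248,
})
_A4 = frozenset({
    7, 14, 15, 28, 30, 31, 56, 60, 62, 63, 112, 120, 124, 126, 131, 135,
    143, 159, 193, 195, 199, 207, 224, 225, 227, 231, 240, 241, 243, 248,
    249, 252,
})
_A5 = frozenset({
    7, 14, 15, 28, 30, 31, 56, 60, 62, 63, 112, 120, 124, 126, 131, 135,
    143, 159, 191, 193, 195, 199, 207, 224, 225, 227, 231, 239, 240, 241,
    243, 248, 249, 251, 252, 254,
})
_PHASES = (_A1, _A2, _A3, _A4, _A5)


def _build_simple_table() -> np.ndarray:
    """Deletability lookup for the final unitary-width pass.

    A pixel is deletable when it is 8-simple (Hilditch crossing number 1,
    so its removal preserves connectivity and holes) and has at least two
    foreground neighbours (endpoints are never eaten).  Indexed by the
    neighbourhood weight.
    """
    # map weight bits to the circular order E, NE, N, NW, W, SW, S, SE
    order_bits = (4, 2, 1, 128, 64, 32, 16, 8)
    table = np.zeros(256, dtype=bool)
    for w in range(256):
        x = [(w & b) != 0 for b in order_bits]
        xb = [0 if v else 1 for v in x]
        n_c = 0
        for k in (0, 2, 4, 6):  # E, N, W, S positions
            n_c += xb[k] - xb[k] * xb[(k + 1) % 8] * xb[(k + 2) % 8]
        table[w] = n_c == 1 and sum(x) >= 2
    return table


_SIMPLE_DELETE = _build_simple_table()

_KERNEL = np.array(
    [[128, 1, 2], [64, 0, 4], [32, 16, 8]], dtype=np.uint16
)


class MultiComponentError(ValueError):
    """Mask has several connected components; run instance post-processing
    (largest-component selection) before thinning."""


class CyclicSkeletonError(ValueError):
    """Skeleton is a closed loop with no endpoints to anchor a polyline."""


@dataclass
class Skeleton:
    """One-pixel-wide medial curve stored as a boolean grid.

    ``pixels`` yields ``(x, y)`` coordinates (x = column, y = row, top-left
    origin).  Endpoints have exactly one skeleton 8-neighbour; branchpoints
    have three or more.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pixels(self) -> set[tuple[int, int]]:
        ys, xs = np.nonzero(self.mask)
        return {(int(x), int(y)) for x, y in zip(xs, ys)}

    def neighbor_counts(self) -> np.ndarray:
        """Number of skeleton 8-neighbours at every skeleton pixel (0 elsewhere)."""
        m = self.mask.astype(np.uint8)
        counts = ndimage.convolve(m, np.ones((3, 3), np.uint8), mode="constant") - m
        counts[~self.mask] = 0
        return counts

    @property
    def endpoints(self) -> set[tuple[int, int]]:
        counts = self.neighbor_counts()
        ys, xs = np.nonzero(self.mask & (counts == 1))
        return {(int(x), int(y)) for x, y in zip(xs, ys)}

    @property
    def branchpoints(self) -> set[tuple[int, int]]:
        counts = self.neighbor_counts()
        ys, xs = np.nonzero(self.mask & (counts >= 3))
        return {(int(x), int(y)) for x, y in zip(xs, ys)}

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Polyline:
    """Ordered endpoint-to-endpoint pixel path along a skeleton."""

    points: list[tuple[int, int]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


def _neighbor_weight(grid: np.ndarray, y: int, x: int) -> int:
    """3x3 neighbourhood weight of pixel (y, x) on a padded grid."""
    w = 0
    for dy, dx, weight in _OFFSETS:
        if grid[y + dy, x + dx]:
            w += weight
    return w


def _unitary_width_pass(grid: np.ndarray) -> None:
    """Sequentially delete redundant 8-simple pixels until strict unit width.

    Operates in place on a 1-px padded boolean grid; endpoints are
    protected, connectivity and holes are preserved, and afterwards no
    pixel is removable without breaking the curve (in particular no 2x2
    square and no thick staircase corner survives).
    """
    changed = True
    while changed:
        changed = False
        ys, xs = np.nonzero(grid)
        for y, x in zip(ys, xs):
            if not grid[y, x]:
                continue
            if _SIMPLE_DELETE[_neighbor_weight(grid, y, x)]:
                grid[y, x] = False
                changed = True


def _k3m(grid: np.ndarray) -> None:
    """K3M thinning in place on a 1-px padded boolean grid."""
    while True:
        deleted = False
        # phase 0: mark current border pixels
        weights = ndimage.convolve(
            grid.astype(np.uint16), _KERNEL, mode="constant"
        )
        border = grid & np.isin(weights, list(_A0))
        marked = list(zip(*np.nonzero(border)))
        for phase_set in _PHASES:
            for y, x in marked:
                if not grid[y, x]:
                    continue
                if _neighbor_weight(grid, y, x) in phase_set:
                    grid[y, x] = False
                    deleted = True
        if not deleted:
            break
    _unitary_width_pass(grid)


def thin(mask: InstanceMask | np.ndarray, method: str = "k3m") -> Skeleton:
    """Thin a single-object mask to a one-pixel-wide, 8-connected skeleton.

    Postconditions (any method): the skeleton contains no 2x2 foreground
    square, is a subset of the input foreground, and has the same number of
    connected components (and holes) as the input.

    Parameters
    ----------
    mask : single-component instance mask (or raw boolean array).  An empty
        mask yields an empty skeleton.
    method : ``"k3m"`` (default) or ``"fallback"`` (scikit-image thinning
        plus the same unitary-width pass).
    """
    pixels = mask.pixels if isinstance(mask, InstanceMask) else np.asarray(mask)
    pixels = pixels.astype(bool)
    if not pixels.any():
        return Skeleton(np.zeros_like(pixels, dtype=bool))
    _, n = ndimage.label(pixels, structure=np.ones((3, 3), bool))
    if n > 1:
        raise MultiComponentError(
            f"mask has {n} connected components; apply largest_component "
            "from rootgrain.instance_postprocess first"
        )
    if method == "k3m":
        grid = np.pad(pixels, 1)
        _k3m(grid)
        out = grid[1:-1, 1:-1]
    elif method == "fallback":
        out = _sk_skeletonize(pixels)
        grid = np.pad(out, 1)
        _unitary_width_pass(grid)
        out = grid[1:-1, 1:-1]
    else:
        raise ValueError(f"unknown thinning method '{method}'")
    return Skeleton(out)


def prune_spurs(skel: Skeleton, min_branch_px: int = 10) -> Skeleton:
    """Remove short side branches (noise spurs) from a thinned skeleton.

    Every branch running from a branchpoint to an endpoint in fewer than
    ``min_branch_px`` pixels is deleted; the scan repeats until no such
    branch remains, so cascaded spurs vanish too.  The main path (a branch
    ending at another endpoint rather than a branchpoint) is never removed.
    """
    if min_branch_px <= 0:
        return Skeleton(skel.mask.copy())
    grid = skel.mask.copy()
    h, w = grid.shape

    def neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        x, y = p
        return [
            (x + dx, y + dy)
            for dy, dx, _ in _OFFSETS
            if 0 <= y + dy < h and 0 <= x + dx < w and grid[y + dy, x + dx]
        ]

    def spur_from(start: tuple[int, int]) -> list[tuple[int, int]] | None:
        """Path from an endpoint up to (excluding) the first junction, or
        None if the walk ends at another endpoint / exceeds the threshold."""
        path = [start]
        prev: tuple[int, int] | None = None
        cur = start
        while len(path) <= min_branch_px:
            nxt = [q for q in neighbors(cur) if q != prev]
            if not nxt:
                return None  # simple open chain: the main path itself
            if len(nxt) > 1:  # cur is the junction
                path.pop()
                return path if 0 < len(path) < min_branch_px else None
            if len(neighbors(nxt[0])) >= 3:  # next pixel is the junction
                return path if len(path) < min_branch_px else None
            prev, cur = cur, nxt[0]
            path.append(cur)
        return None

    while True:
        endpoints = sorted(Skeleton(grid).endpoints, key=lambda p: (p[1], p[0]))
        spurs = [s for s in (spur_from(e) for e in endpoints) if s]
        if not spurs:
            return Skeleton(grid)
        # remove one spur at a time, shortest first (start order breaks
        # ties), so the junction state is never stale
        shortest = min(spurs, key=lambda s: (len(s), s[0][1], s[0][0]))
        for x, y in shortest:
            grid[y, x] = False
        # junction residue (e.g. a triangle clique) is dissolved before the
        # next scan so endpoint/branch classification stays consistent
        padded = np.pad(grid, 1)
        _unitary_width_pass(padded)
        grid = padded[1:-1, 1:-1]


def _skeleton_graph(skel: Skeleton) -> nx.Graph:
    g = nx.Graph()
    pts = skel.pixels
    g.add_nodes_from(pts)
    for x, y in pts:
        for dy, dx, _ in _OFFSETS:
            q = (x + dx, y + dy)
            if q in pts:
                weight = 1.0 if dx == 0 or dy == 0 else float(np.sqrt(2.0))
                g.add_edge((x, y), q, weight=weight)
    return g


def to_polyline(skel: Skeleton) -> Polyline:
    """Order a skeleton into its longest endpoint-to-endpoint pixel path.

    Residual side branches (if any survive pruning) are ignored: the path
    returned is the longest geodesic between two endpoints, with axial steps
    weighing 1 and diagonal steps sqrt(2).  A single-pixel skeleton yields a
    one-point polyline.

    Raises
    ------
    ValueError : empty skeleton.
    CyclicSkeletonError : skeleton is a closed loop (no endpoints).
    """
    if skel.n_pixels == 0:
        raise ValueError("cannot order an empty skeleton")
    if skel.n_pixels == 1:
        return Polyline(sorted(skel.pixels))
    endpoints = sorted(skel.endpoints, key=lambda p: (p[1], p[0]))
    g = _skeleton_graph(skel)
    if not endpoints:
        raise CyclicSkeletonError(
            "skeleton has no endpoints (closed loop); cannot order a polyline"
        )
    if len(endpoints) == 1:
        # degenerate tip (e.g. a loop with a tail): pair the sole endpoint
        # with the farthest reachable node, deterministically
        start = endpoints[0]
        dist = nx.single_source_dijkstra_path_length(g, start, weight="weight")
        far = max(dist, key=lambda n: (dist[n], -n[1], -n[0]))
        endpoints = [start, far]
    best: tuple[float, tuple, tuple] | None = None
    for src in endpoints:
        dist, paths = nx.single_source_dijkstra(g, src, weight="weight")
        for dst in endpoints:
            if dst == src or dst not in dist:
                continue
            key = (dist[dst], src, dst)
            if best is None or key[0] > best[0] + 1e-12:
                best = (key[0], src, dst)
                best_path = paths[dst]
    if best is None:  # endpoints in different components cannot happen post-thin
        raise CyclicSkeletonError("no endpoint-to-endpoint path found")
    path = [(int(x), int(y)) for x, y in best_path]
    # geodesics cut corners diagonally; reinstate the skeleton's own corner
    # pixel between two diagonal steps so the full curve is traversed
    pts = skel.pixels
    visited = set(path)
    out = [path[0]]
    for p, q in zip(path, path[1:]):
        if p[0] != q[0] and p[1] != q[1]:
            for corner in ((p[0], q[1]), (q[0], p[1])):
                if corner in pts and corner not in visited:
                    out.append(corner)
                    visited.add(corner)
                    break
        out.append(q)
    return Polyline(out)
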