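"""The Live Wire engine.

The image is an 8-connected weighted directed graph: each pixel is a node with
links to its 8 neighbors, weighted by a local cost that is low along object
boundaries. From a user-placed seed, Dijkstra's algorithm computes the optimal
spanning tree of the image; the boundary segment to any free point is then the
reverse walk through the predecessor pointers. A closed contour is assembled
from an ordered list of clicks (each consecutive pair contributing one optimal
segment, the last click closing back to the first) and rasterized to a binary
mask for evaluation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_core import ValidationError

#: Fixed neighbor-offset order: N, NE, E, SE, S, SW, W, NW as (drow, dcol).
OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)

#: Euclidean length of each neighbor offset (1 for axial, sqrt(2) diagonal).
OFFSET_LENGTHS: np.ndarray = np.array(
    [np.hypot(dr, dc) for dr, dc in OFFSETS]
)


@dataclass(frozen=True)
class LinkCostGraph:
    """Per-pixel directed 8-neighbor link costs.

    ``link_costs`` has shape ``(rows, cols, 8)``; slot ``k`` holds the cost of
    the link from pixel ``p`` to ``p + OFFSETS[k]``.  Links leaving the image
    are marked absent with ``+inf``.
    """

    link_costs: np.ndarray

    def __post_init__(self) -> None:
        lc = np.asarray(self.link_costs, dtype=np.float64)
        if lc.ndim != 3 or lc.shape[2] != 8:
            raise ValidationError("link_costs must have shape (rows, cols, 8)")
        finite = lc[np.isfinite(lc)]
        if finite.size and finite.min() < 0:
            raise ValidationError("link costs must be non-negative")
        object.__setattr__(self, "link_costs", lc)

    @property
    def shape(self) -> tuple[int, int]:
        return self.link_costs.shape[:2]

    @classmethod
    def from_costs(cls, link_costs: np.ndarray) -> "LinkCostGraph":
        """Build a graph, masking out-of-image links with ``+inf``."""
        lc = np.array(link_costs, dtype=np.float64)
        rows, cols = lc.shape[:2]
        for k, (dr, dc) in enumerate(OFFSETS):
            if dr == -1:
                lc[0, :, k] = np.inf
            if dr == 1:
                lc[rows - 1, :, k] = np.inf
            if dc == -1:
                lc[:, 0, k] = np.inf
            if dc == 1:
                lc[:, cols - 1, k] = np.inf
        return cls(lc)

    @classmethod
    def uniform(cls, shape: tuple[int, int], axial: float = 1.0,
                diagonal: float | None = None) -> "LinkCostGraph":
        """Graph with one cost per axial link and one per diagonal link."""
        if diagonal is None:
            diagonal = axial * np.sqrt(2.0)
        lc = np.empty(shape + (8,))
        for k, (dr, dc) in enumerate(OFFSETS):
            lc[:, :, k] = axial if (dr == 0 or dc == 0) else diagonal
        return cls.from_costs(lc)


@dataclass(frozen=True)
class PathTree:
    """Optimal spanning tree from one seed: predecessors and path costs."""

    seed: tuple[int, int]
    parent: np.ndarray          # (rows, cols, 2) int; (-1,-1) at the seed
    cumulative_cost: np.ndarray  # (rows, cols) float

    @property
    def shape(self) -> tuple[int, int]:
        return self.cumulative_cost.shape


@dataclass(frozen=True)
class ClosedContour:
    """Ordered closed pixel chain plus the per-click-pair segments."""

    vertices: list[tuple[int, int]]
    segments: list[list[tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.vertices
        if len(v) < 2 or v[0] != v[-1]:
            raise ValidationError("contour must be closed (first == last)")
        for a, b in zip(v, v[1:]):
            if max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1:
                raise ValidationError(
                    f"contour vertices {a} and {b} are not 8-adjacent"
                )


def _check_inside(point: tuple[int, int], shape: tuple[int, int],
                  what: str) -> None:
    r, c = point
    if not (0 <= r < shape[0] and 0 <= c < shape[1]):
        raise ValidationError(f"{what} {point} outside image {shape}")


def dijkstra_tree(graph: LinkCostGraph, seed: tuple[int, int]) -> PathTree:
    """Single-source shortest paths over the pixel graph.

    Ties between equal cumulative costs are broken FIFO (first inserted,
    first extracted) so results are deterministic across platforms.
    """
    rows, cols = graph.shape
    _check_inside(seed, graph.shape, "seed")
    lc = graph.link_costs
    dist = np.full((rows, cols), np.inf)
    parent = np.full((rows, cols, 2), -1, dtype=np.int64)
    done = np.zeros((rows, cols), dtype=bool)
    sr, sc = int(seed[0]), int(seed[1])
    dist[sr, sc] = 0.0
    counter = 0
    heap: list[tuple[float, int, int, int]] = [(0.0, counter, sr, sc)]
    while heap:
        d, _, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        for k, (dr, dc) in enumerate(OFFSETS):
            w = lc[r, c, k]
            if not np.isfinite(w):
                continue
            nr, nc = r + dr, c + dc
            if done[nr, nc]:
                continue
            nd = d + w
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                parent[nr, nc] = (r, c)
                counter += 1
                heapq.heappush(heap, (nd, counter, nr, nc))
    return PathTree(seed=(sr, sc), parent=parent, cumulative_cost=dist)


def trace_path(tree: PathTree, free_point: tuple[int, int]
               ) -> list[tuple[int, int]]:
    """Walk predecessors from ``free_point`` to the seed; return seed-first."""
    _check_inside(free_point, tree.shape, "free point")
    r, c = int(free_point[0]), int(free_point[1])
    if not np.isfinite(tree.cumulative_cost[r, c]):
        raise ValidationError(f"free point {free_point} unreachable from seed")
    path = [(r, c)]
    while (r, c) != tree.seed:
        r, c = (int(x) for x in tree.parent[r, c])
        path.append((r, c))
    path.reverse()
    return path


def segment_with_clicks(graph: LinkCostGraph,
                        clicks: list[tuple[int, int]]) -> ClosedContour:
    """Assemble a closed contour from ordered boundary clicks.

    Each consecutive click pair (including last back to first) contributes the
    optimal path from the earlier click to the later one; junction pixels are
    de-duplicated so the chain visits each click once.
    """
    if len(clicks) < 3:
        raise ValidationError(f"need at least 3 clicks, got {len(clicks)}")
    clicks = [(int(r), int(c)) for r, c in clicks]
    for p in clicks:
        _check_inside(p, graph.shape, "click")
    segments: list[list[tuple[int, int]]] = []
    vertices: list[tuple[int, int]] = []
    pairs = list(zip(clicks, clicks[1:] + clicks[:1]))
    for i, (a, b) in enumerate(pairs):
        tree = dijkstra_tree(graph, a)
        seg = trace_path(tree, b)
        segments.append(seg)
        vertices.extend(seg if i == 0 else seg[1:])
    return ClosedContour(vertices=vertices, segments=segments)


def contour_to_mask(contour: ClosedContour,
                    shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed contour to a filled binary mask.

    The traced boundary pixels themselves count as inside.  Interior filling
    floods the 4-connected background from the border, which cannot leak
    through an 8-connected closed chain.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for r, c in contour.vertices:
        _check_inside((r, c), shape, "contour vertex")
        mask[r, c] = 1
    filled = ndimage.binary_fill_holes(mask)
    return filled.astype(np.uint8)
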