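"""AOI schemes: semantic lead rectangles and the data-driven uniform grid.

The grid scheme is bottom-up: fixation points are clustered with DBSCAN, a
neighborhood scale is selected from the knee of the k-distance curve, and a
uniform grid whose cell side equals that scale tiles the canvas. The lead
scheme maps fixations onto researcher-defined lead rectangles, with a
dedicated label for fixations landing in no lead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .dataset import Rect, Scanpath, StimulusLayout
from .errors import ArgumentError

logger = logging.getLogger(__name__)

NOISE = -1
OUTSIDE_LABEL = "outside"


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid anchored at the canvas origin; edge cells truncated."""

    cell_side: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_side <= 0:
            raise ArgumentError("cell_side must be positive")

    @classmethod
    def for_canvas(cls, width: float, height: float, cell_side: float) -> "GridSpec":
        return cls(
            cell_side=cell_side,
            n_cols=max(1, math.ceil(width / cell_side)),
            n_rows=max(1, math.ceil(height / cell_side)),
        )

    def cell_name(self, row: int, col: int) -> str:
        return f"r{row:02d}c{col:02d}"

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        col = min(int(x // self.cell_side), self.n_cols - 1)
        row = min(int(y // self.cell_side), self.n_rows - 1)
        return row, col


@dataclass(frozen=True)
class AOISet:
    """A named segmentation of the stimulus plane.

    ``scheme`` is ``"lead"`` (researcher rectangles plus an outside label) or
    ``"grid"`` (uniform cells tiling the whole canvas). ``assign`` maps a
    point to exactly one label; for the grid scheme the mapping is total.
    """

    scheme: str
    width: float
    height: float
    regions: Mapping[str, Rect] = field(default_factory=dict)
    outside_label: str | None = None
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        if self.scheme not in {"lead", "grid"}:
            raise ArgumentError(f"unknown AOI scheme {self.scheme!r}")
        if self.scheme == "grid" and self.grid is None:
            raise ArgumentError("grid scheme requires a GridSpec")

    @property
    def labels(self) -> tuple[str, ...]:
        """All labels in deterministic order (grid: row-major)."""
        if self.scheme == "grid":
            g = self.grid
            return tuple(
                g.cell_name(r, c) for r in range(g.n_rows) for c in range(g.n_cols)
            )
        names = tuple(self.regions)
        if self.outside_label is not None:
            names = names + (self.outside_label,)
        return names

    def assign(self, x: float, y: float) -> str:
        if self.scheme == "grid":
            row, col = self.grid.cell_of(x, y)
            return self.grid.cell_name(row, col)
        for name, rect in self.regions.items():
            if rect.contains(x, y):
                return name
        if self.outside_label is None:
            raise ArgumentError(
                f"point ({x}, {y}) falls in no region and no outside label is set"
            )
        return self.outside_label

    def to_rows(self) -> list[dict[str, float | str]]:
        """Region table (name, x0, y0, x1, y1) for CSV export."""
        if self.scheme == "grid":
            g = self.grid
            rows = []
            for r in range(g.n_rows):
                for c in range(g.n_cols):
                    rows.append(
                        {
                            "name": g.cell_name(r, c),
                            "x0": c * g.cell_side,
                            "y0": r * g.cell_side,
                            "x1": min((c + 1) * g.cell_side, self.width),
                            "y1": min((r + 1) * g.cell_side, self.height),
                        }
                    )
            return rows
        return [
            {"name": n, "x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}
            for n, r in self.regions.items()
        ]

    def region_rect(self, label: str) -> Rect:
        """Bounding rectangle of a label (grid cells truncated at the canvas)."""
        if self.scheme == "grid":
            g = self.grid
            if not (label.startswith("r") and "c" in label):
                raise ArgumentError(f"not a grid cell label: {label!r}")
            r, c = (int(part) for part in label[1:].split("c"))
            return Rect(
                c * g.cell_side,
                r * g.cell_side,
                min((c + 1) * g.cell_side, self.width),
                min((r + 1) * g.cell_side, self.height),
            )
        if label in self.regions:
            return self.regions[label]
        raise ArgumentError(f"unknown region label {label!r}")


def lead_aois(layout: StimulusLayout, outside_label: str = OUTSIDE_LABEL) -> AOISet:
    """Top-down AOI scheme: the layout's lead rectangles plus an outside label."""
    return AOISet(
        scheme="lead",
        width=layout.width,
        height=layout.height,
        regions=dict(layout.lead_regions),
        outside_label=outside_label,
    )


@dataclass(frozen=True)
class ClusterResult:
    """DBSCAN output on a fixation point cloud.

    ``labels[i]`` is the cluster id of input point ``i`` (``NOISE`` = -1).
    ``optimal_diameter`` is the density scale carried forward to the grid:
    by default the eps used, optionally the mean within-cluster diameter.
    """

    labels: np.ndarray
    eps: float
    min_pts: int
    cluster_diameters: tuple[float, ...]
    optimal_diameter: float

    def __post_init__(self) -> None:
        if self.optimal_diameter <= 0:
            raise ArgumentError("optimal_diameter must be positive")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_diameters)

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))


def _scan_order(pts: np.ndarray) -> np.ndarray:
    # deterministic order: (x, y, input index); lexsort's last key is primary
    n = len(pts)
    return np.lexsort((np.arange(n), pts[:, 1], pts[:, 0]))


def dbscan_cluster(
    points: Sequence[tuple[float, float]] | np.ndarray,
    eps: float,
    min_pts: int,
    diameter_rule: str = "eps",
) -> ClusterResult:
    """Density-based clustering with deterministic border-point resolution.

    A point is *core* when its closed eps-ball holds at least ``min_pts``
    points (itself included). Clusters are the connected components of core
    points under eps-adjacency; a non-core point adjacent to a core point is
    a border point assigned to the cluster of its first core neighbor in scan
    order (points sorted by ``(x, y, input index)``); remaining points are
    noise. Cluster ids are numbered by first member in scan order, so the
    result is independent of input order up to that fixed rule.

    ``diameter_rule`` selects ``optimal_diameter``: ``"eps"`` (the eps used)
    or ``"mean_cluster_diameter"`` (mean of per-cluster maximal pairwise
    distances over clusters with >= 2 points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ArgumentError("points must be a non-empty (n, 2) array")
    if eps <= 0:
        raise ArgumentError(f"eps must be positive, got {eps}")
    if min_pts < 1:
        raise ArgumentError(f"min_pts must be >= 1, got {min_pts}")
    n = len(pts)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, eps)  # closed ball, includes self
    is_core = np.array([len(nb) >= min_pts for nb in neighbors])
    order = _scan_order(pts)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    labels = np.full(n, NOISE, dtype=int)
    next_id = 0
    # connected components of core points, seeded in scan order
    for i in order:
        if not is_core[i] or labels[i] != NOISE:
            continue
        cid = next_id
        next_id += 1
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if is_core[k] and labels[k] == NOISE:
                    labels[k] = cid
                    stack.append(k)
    # border points: first core neighbor in scan order decides
    for i in range(n):
        if is_core[i]:
            continue
        core_nb = [k for k in neighbors[i] if is_core[k]]
        if core_nb:
            winner = min(core_nb, key=lambda k: rank[k])
            labels[i] = labels[winner]

    diameters = []
    for cid in range(next_id):
        members = pts[labels == cid]
        diameters.append(float(pdist(members).max()) if len(members) > 1 else 0.0)

    if diameter_rule == "eps":
        optimal = float(eps)
    elif diameter_rule == "mean_cluster_diameter":
        positive = [d for d in diameters if d > 0]
        optimal = float(np.mean(positive)) if positive else float(eps)
    else:
        raise ArgumentError(f"unknown diameter_rule {diameter_rule!r}")
    return ClusterResult(
        labels=labels,
        eps=float(eps),
        min_pts=int(min_pts),
        cluster_diameters=tuple(diameters),
        optimal_diameter=optimal,
    )


def k_distances(points: np.ndarray, min_pts: int) -> np.ndarray:
    """Sorted (ascending) distances to each point's ``min_pts``-th nearest
    neighbor, the point itself excluded."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < min_pts + 1:
        raise ArgumentError(
            f"need at least min_pts + 1 = {min_pts + 1} points, got {len(pts)}"
        )
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=min_pts + 1)
    return np.sort(dist[:, -1])


def select_epsilon(
    points: Sequence[tuple[float, float]] | np.ndarray, min_pts: int = 5
) -> float:
    """Neighborhood radius from the knee of the k-distance curve.

    The sorted ``min_pts``-nearest-neighbor distance curve is rescaled to the
    unit square and the knee is the point of maximal distance below the chord
    joining its endpoints (a discrete maximum-curvature rule). Flat curves
    have no knee; any plateau value is returned. Deterministic for fixed
    input; all-duplicate point sets carry no scale and raise.
    """
    d = k_distances(points, min_pts)
    if d[-1] <= 0:
        raise ArgumentError("k-distance curve is identically zero (duplicate points)")
    n = len(d)
    x = np.linspace(0.0, 1.0, n)
    span = d[-1] - d[0]
    if span <= 0:
        return float(d[0])  # flat curve: every value sits on the plateau
    y = (d - d[0]) / span
    # signed distance below the chord y = x; knee = most extreme sag
    sag = x - y
    idx = int(np.argmax(sag))
    value = float(d[idx])
    if value <= 0:
        positive = d[d > 0]
        value = float(positive[0])
    return value


def derive_grid(
    layout: StimulusLayout,
    cluster: ClusterResult | float,
) -> AOISet:
    """Uniform grid AOI set whose cell side is the cluster's optimal diameter.

    Accepts either a :class:`ClusterResult` or a raw cell side in pixels. The
    grid is anchored at the canvas origin; edge cells are truncated at the
    canvas; a diameter larger than the canvas degenerates to a single cell
    (logged).
    """
    side = cluster.optimal_diameter if isinstance(cluster, ClusterResult) else float(cluster)
    if side <= 0:
        raise ArgumentError("cell side must be positive")
    if side > max(layout.width, layout.height):
        logger.warning(
            "grid cell side %.1f exceeds canvas %sx%s; single-cell grid",
            side, layout.width, layout.height,
        )
    spec = GridSpec.for_canvas(layout.width, layout.height, side)
    return AOISet(
        scheme="grid", width=layout.width, height=layout.height, grid=spec
    )


def assign_fixations(scanpath: Scanpath, aois: AOISet) -> list[str]:
    """One AOI label per fixation, in fixation order."""
    return [aois.assign(fx.x, fx.y) for fx in scanpath.fixations]
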