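"""Shared builders for the test suite."""

from __future__ import annotations

import numpy as np

from gazeflow.aoi import AOISet, derive_grid
from gazeflow.dataset import (
    Condition,
    Fixation,
    OrderGroup,
    Rect,
    Scanpath,
    StimulusLayout,
    StudyDataset,
)


def scanpath_from_points(
    points,
    pid: str = "p1",
    sid: str = "s1",
    cond: Condition = Condition.HISTORY,
    duration: float = 100.0,
) -> Scanpath:
    fixations = tuple(
        Fixation(
            participant_id=pid,
            stimulus_id=sid,
            condition=cond,
            index=i + 1,
            x=float(x),
            y=float(y),
            duration=duration,
            onset=i * (duration + 20.0),
        )
        for i, (x, y) in enumerate(points)
    )
    return Scanpath(pid, sid, cond, fixations)


def small_grid_layout(width: float = 100.0, height: float = 100.0) -> StimulusLayout:
    return StimulusLayout("s1", width, height, {})


def grid_aois(cell_side: float = 10.0, width: float = 100.0,
              height: float = 100.0) -> AOISet:
    return derive_grid(small_grid_layout(width, height), cell_side)


def scanpath_in_cells(
    cells,
    aois: AOISet,
    pid: str = "p1",
    sid: str = "s1",
    cond: Condition = Condition.HISTORY,
) -> Scanpath:
    """Scanpath visiting the centers of the named AOI cells, in order."""
    points = [aois.region_rect(label).center for label in cells]
    return scanpath_from_points(points, pid=pid, sid=sid, cond=cond)


def dataset_from_scanpaths(scanpaths, responses=None) -> StudyDataset:
    pids = sorted({sp.participant_id for sp in scanpaths})
    order_groups = {
        pid: (OrderGroup.HISTORY_FIRST if i % 2 == 0 else OrderGroup.HISTORY_LAST)
        for i, pid in enumerate(pids)
    }
    return StudyDataset(
        scanpaths=tuple(scanpaths),
        responses=dict(responses or {}),
        order_groups=order_groups,
    )


def two_lead_layout() -> StimulusLayout:
    """200x100 canvas split into two 100x100 lead rectangles."""
    return StimulusLayout(
        "s1",
        200.0,
        100.0,
        {"left": Rect(0, 0, 100, 100), "right": Rect(100, 0, 200, 100)},
    )


def random_points(rng: np.random.Generator, n: int, scale: float = 100.0) -> np.ndarray:
    return rng.random((n, 2)) * scale
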