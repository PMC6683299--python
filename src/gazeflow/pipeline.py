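"""End-to-end orchestration: segmentation -> transitions -> permutation tests
-> accuracy and fixation-metric statistics, from one config, deterministically
seeded per (stimulus, scheme, comparison) cell.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clinical
from .aoi import AOISet, dbscan_cluster, derive_grid, lead_aois, select_epsilon
from .dataset import Condition, OrderGroup, StudyDataset
from .errors import GazeflowError
from .io import write_table
from .permutation import GroupAssignment, permutation_test

logger = logging.getLogger(__name__)

PERMUTATION_COLUMNS = [
    "stimulus", "scheme", "comparison", "n1", "n2",
    "M", "SD", "d", "Hd", "p", "n_perm", "seed",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs.

    ``comparisons`` entries: ``"order"`` (history-first vs history-last
    participants) and/or ``"accuracy"`` (post hoc correct vs incorrect per
    stimulus, in ``accuracy_condition``).
    """

    schemes: tuple[str, ...] = ("lead", "grid")
    comparisons: tuple[str, ...] = ("order", "accuracy")
    n_permutations: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    min_pts: int = 5
    diameter_rule: str = "eps"
    accuracy_condition: Condition = Condition.HISTORY
    output_dir: Path | None = None
    per_stimulus_grid: bool = True

    def __post_init__(self) -> None:
        if not self.schemes or not self.comparisons:
            raise ValueError("need at least one scheme and one comparison")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for s in self.schemes:
            if s not in {"lead", "grid"}:
                raise ValueError(f"unknown scheme {s!r}")
        for c in self.comparisons:
            if c not in {"order", "accuracy"}:
                raise ValueError(f"unknown comparison {c!r}")


@dataclass
class AnalysisResult:
    """Result bundle: per-comparison permutation rows, clinical tables, log."""

    permutation_table: pd.DataFrame
    mcnemar_table: pd.DataFrame | None
    wilcoxon_table: pd.DataFrame
    aoi_tables: Mapping[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def cell_seed(master_seed: int, stimulus: str, scheme: str, comparison: str) -> int:
    """Stable per-cell seed independent of execution order."""
    tag = f"{master_seed}|{stimulus}|{scheme}|{comparison}".encode()
    return zlib.crc32(tag)


def order_group_assignment(dataset: StudyDataset) -> GroupAssignment:
    """Group 1 = history-first participants, group 2 = history-last."""
    return GroupAssignment(
        {
            pid: (1 if og is OrderGroup.HISTORY_FIRST else 2)
            for pid, og in dataset.order_groups.items()
        }
    )


def grid_for_stimulus(
    dataset: StudyDataset,
    layout,
    stimulus_id: str | None,
    min_pts: int = 5,
    diameter_rule: str = "eps",
) -> AOISet:
    """Bottom-up grid: pool the stimulus's fixation points across all
    participants and conditions, select eps at the k-distance knee, run
    DBSCAN, and tile the canvas with the resulting optimal diameter."""
    points = np.array(
        [
            (fx.x, fx.y)
            for sp in dataset.select(stimulus_id=stimulus_id)
            for fx in sp.fixations
        ]
    )
    eps = select_epsilon(points, min_pts=min_pts)
    cluster = dbscan_cluster(points, eps, min_pts, diameter_rule=diameter_rule)
    return derive_grid(layout, cluster)


def run_full_analysis(
    dataset: StudyDataset,
    layout,
    config: RunConfig,
    answer_key: clinical.AnswerKey | None = None,
) -> AnalysisResult:
    """Run every (stimulus, scheme, comparison) cell plus the accuracy and
    fixation-metric tables. A failing cell is logged and skipped; remaining
    cells still run. Writes CSVs when ``config.output_dir`` is set."""
    log: list[str] = []
    stimuli = dataset.stimuli()
    records = None
    if answer_key is not None and dataset.responses:
        records = clinical.score_dataset(dataset, answer_key)
    elif "accuracy" in config.comparisons:
        log.append("accuracy comparison requested but no answer key/responses; skipped")

    aoi_sets: dict[tuple[str, str], AOISet] = {}
    shared_grid: AOISet | None = None
    if "grid" in config.schemes and not config.per_stimulus_grid:
        shared_grid = grid_for_stimulus(
            dataset, layout, None, config.min_pts, config.diameter_rule
        )
    for sid in stimuli:
        if "lead" in config.schemes:
            aoi_sets[(sid, "lead")] = lead_aois(layout)
        if "grid" in config.schemes:
            if shared_grid is not None:
                aoi_sets[(sid, "grid")] = shared_grid
            else:
                try:
                    aoi_sets[(sid, "grid")] = grid_for_stimulus(
                        dataset, layout, sid, config.min_pts, config.diameter_rule
                    )
                except GazeflowError as exc:
                    log.append(f"grid derivation failed for {sid}: {exc}")

    rows = []
    for sid in stimuli:
        for scheme in config.schemes:
            aois = aoi_sets.get((sid, scheme))
            if aois is None:
                continue
            for comparison in config.comparisons:
                try:
                    if comparison == "order":
                        groups = order_group_assignment(dataset)
                        condition = None
                    else:
                        if records is None:
                            continue
                        groups = clinical.accuracy_split(
                            records, sid, config.accuracy_condition
                        )
                        condition = config.accuracy_condition
                    result = permutation_test(
                        dataset,
                        groups,
                        aois,
                        stimulus_id=sid,
                        n_perm=config.n_permutations,
                        seed=cell_seed(config.seed, sid, scheme, comparison),
                        condition=condition,
                    )
                except GazeflowError as exc:
                    msg = f"cell ({sid}, {scheme}, {comparison}) failed: {exc}"
                    log.append(msg)
                    logger.warning(msg)
                    continue
                row = result.to_row()
                row["comparison"] = comparison
                rows.append({c: row[c] for c in PERMUTATION_COLUMNS})
    permutation_table = pd.DataFrame(rows, columns=PERMUTATION_COLUMNS)

    mcnemar_table = None
    if records is not None:
        mcnemar_table = clinical.mcnemar_table_per_stimulus(records, stimuli)
    wilcoxon_table = clinical.wilcoxon_table_per_stimulus(dataset, stimuli)

    result = AnalysisResult(
        permutation_table=permutation_table,
        mcnemar_table=mcnemar_table,
        wilcoxon_table=wilcoxon_table,
        aoi_tables={
            key: pd.DataFrame(aois.to_rows()) for key, aois in aoi_sets.items()
        },
        log=log,
    )
    if config.output_dir is not None:
        _write_outputs(result, config.output_dir)
    return result


def _write_outputs(result: AnalysisResult, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_table(
        result.permutation_table, out_dir / "permutation_results.csv",
        columns=PERMUTATION_COLUMNS,
    )
    if result.mcnemar_table is not None:
        write_table(result.mcnemar_table, out_dir / "accuracy_mcnemar.csv")
    write_table(result.wilcoxon_table, out_dir / "fixation_wilcoxon.csv")
    (out_dir / "run_log.txt").write_text(
        "".join(line + "\n" for line in result.log)
    )


def calibration_study(
    make_scenario,
    analyze,
    magnitudes: Sequence[float],
    n_replicates: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rejection-rate curve over perturbation magnitudes.

    ``make_scenario(magnitude, replicate)`` returns a scenario;
    ``analyze(scenario)`` returns a p-value. Generic so tests and the CLI can
    share the loop.
    """
    rows = []
    for mag in magnitudes:
        rejections = 0
        for rep in range(n_replicates):
            p = analyze(make_scenario(mag, rep))
            if p <= alpha:
                rejections += 1
        rows.append(
            {
                "magnitude": mag,
                "n_replicates": n_replicates,
                "rejection_rate": rejections / n_replicates,
            }
        )
    return pd.DataFrame(rows)
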