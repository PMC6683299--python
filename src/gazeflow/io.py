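"""Reading and writing fixation tables, layouts, answer keys, result tables.

The fixation-table dialect (delimiter, column names, decimal mark) is
config-driven; the default matches a tab-separated export with columns
``participant, stimulus, condition, fix_index, x, y, duration_ms, onset_ms``
plus an ``order_group`` column carrying the counterbalancing arm.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .dataset import (
    Condition,
    Fixation,
    OrderGroup,
    Rect,
    Scanpath,
    StimulusLayout,
    StudyDataset,
)
from .errors import FormatError, IntegrityError, LayoutValidationError

logger = logging.getLogger(__name__)

#: canonical internal field -> default column header
_DEFAULT_COLUMNS = {
    "participant": "participant",
    "stimulus": "stimulus",
    "condition": "condition",
    "order_group": "order_group",
    "fix_index": "fix_index",
    "x": "x",
    "y": "y",
    "duration_ms": "duration_ms",
    "onset_ms": "onset_ms",
}


@dataclass(frozen=True)
class TableDialect:
    """How a fixation export is laid out on disk."""

    delimiter: str = "\t"
    decimal: str = "."
    columns: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_COLUMNS))

    def with_delimiter(self, delimiter: str) -> "TableDialect":
        return replace(self, delimiter=delimiter)


DEFAULT_DIALECT = TableDialect()


def read_fixation_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    layouts: Mapping[str, StimulusLayout] | None = None,
    out_of_bounds: str = "drop",
    responses: Mapping[tuple[str, str, Condition], str] | None = None,
) -> StudyDataset:
    """Parse a delimited fixation export into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path : path
        Delimited text file with one fixation per row.
    dialect : TableDialect
        Column naming, delimiter and decimal mark.
    layouts : mapping, optional
        Per-stimulus layouts used to validate coordinates. Without layouts no
        bounds check is performed.
    out_of_bounds : {"drop", "clamp", "keep"}
        Handling of fixations outside the stimulus canvas; dropped rows are
        counted and logged.
    responses : mapping, optional
        Per-trial free-text interpretations keyed by
        ``(participant, stimulus, condition)``.
    """
    path = Path(path)
    if out_of_bounds not in {"drop", "clamp", "keep"}:
        raise ValueError(f"unknown out_of_bounds policy {out_of_bounds!r}")
    df = pd.read_csv(
        path, sep=dialect.delimiter, decimal=dialect.decimal, dtype=str,
        keep_default_na=False, engine="python",
    )
    cols = dialect.columns
    for fld in ("participant", "stimulus", "condition", "fix_index", "x", "y",
                "duration_ms", "onset_ms"):
        if cols[fld] not in df.columns:
            raise FormatError(f"missing required column {cols[fld]!r} in {path}")
    has_order = cols["order_group"] in df.columns
    if not has_order:
        raise FormatError(
            f"missing order-group column {cols['order_group']!r} in {path}; "
            "every participant needs a counterbalancing label"
        )

    order_groups: dict[str, OrderGroup] = {}
    trials: dict[tuple[str, str, Condition], list[Fixation]] = {}
    n_dropped = 0
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        pid = str(rec[cols["participant"]])
        sid = str(rec[cols["stimulus"]])
        try:
            cond = Condition(rec[cols["condition"]])
        except ValueError as exc:
            raise FormatError(f"unknown condition {rec[cols['condition']]!r}") from exc
        try:
            og = OrderGroup(rec[cols["order_group"]])
        except ValueError as exc:
            raise FormatError(
                f"unknown order group {rec[cols['order_group']]!r}"
            ) from exc
        if pid in order_groups and order_groups[pid] is not og:
            raise IntegrityError(f"participant {pid!r} appears in two order groups")
        order_groups[pid] = og
        x = float(rec[cols["x"]])
        y = float(rec[cols["y"]])
        if layouts is not None and sid in layouts:
            lay = layouts[sid]
            if not lay.in_bounds(x, y):
                if out_of_bounds == "drop":
                    n_dropped += 1
                    continue
                if out_of_bounds == "clamp":
                    eps = 1e-9
                    x = min(max(x, 0.0), lay.width - eps)
                    y = min(max(y, 0.0), lay.height - eps)
        fx = Fixation(
            participant_id=pid,
            stimulus_id=sid,
            condition=cond,
            index=int(rec[cols["fix_index"]]),
            x=x,
            y=y,
            duration=float(rec[cols["duration_ms"]]),
            onset=float(rec[cols["onset_ms"]]),
        )
        trials.setdefault(fx.trial_key, []).append(fx)

    if n_dropped:
        logger.info("dropped %d out-of-bounds fixation rows from %s", n_dropped, path)

    scanpaths = []
    for key in trials:
        fxs = trials[key]
        indices = [fx.index for fx in fxs]
        if len(set(indices)) != len(indices):
            raise IntegrityError(f"duplicate fixation index in trial {key}")
        scanpaths.append(Scanpath(key[0], key[1], key[2], tuple(fxs)))
    return StudyDataset(
        scanpaths=tuple(scanpaths),
        responses=dict(responses or {}),
        order_groups=order_groups,
    )


def dataset_to_rows(dataset: StudyDataset) -> list[dict[str, Any]]:
    """Flatten a dataset to one dict per fixation, in the default dialect."""
    rows = []
    for sp in dataset.scanpaths:
        og = dataset.order_groups[sp.participant_id]
        for fx in sp.fixations:
            rows.append(
                {
                    "participant": fx.participant_id,
                    "stimulus": fx.stimulus_id,
                    "condition": fx.condition.value,
                    "order_group": og.value,
                    "fix_index": fx.index,
                    "x": fx.x,
                    "y": fx.y,
                    "duration_ms": fx.duration,
                    "onset_ms": fx.onset,
                }
            )
    return rows


def write_dataset(
    dataset: StudyDataset,
    fixations_path: str | Path,
    responses_path: str | Path | None = None,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write a dataset in the given dialect; losslessly round-trips."""
    write_table(dataset_to_rows(dataset), fixations_path, delimiter=dialect.delimiter)
    if responses_path is not None:
        rows = [
            {
                "participant": pid,
                "stimulus": sid,
                "condition": cond.value,
                "response": text,
            }
            for (pid, sid, cond), text in sorted(
                dataset.responses.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
            )
        ]
        write_table(
            rows,
            responses_path,
            columns=["participant", "stimulus", "condition", "response"],
            delimiter=dialect.delimiter,
        )


def read_responses(
    path: str | Path, delimiter: str = "\t"
) -> dict[tuple[str, str, Condition], str]:
    """Read a per-trial response table (participant, stimulus, condition, response)."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     engine="python")
    for col in ("participant", "stimulus", "condition", "response"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    out: dict[tuple[str, str, Condition], str] = {}
    for row in df.itertuples(index=False):
        key = (str(row.participant), str(row.stimulus), Condition(row.condition))
        if key in out:
            raise IntegrityError(f"duplicate response for trial {key}")
        out[key] = str(row.response)
    return out


def write_table(
    rows: Sequence[Mapping[str, Any]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write tabular rows as delimited text with a header row.

    Column order is deterministic: explicit ``columns`` if given, else the key
    order of the first row (all rows must share one schema). Floats are
    serialized with ``repr`` semantics so values round-trip exactly.
    """
    if isinstance(rows, pd.DataFrame):
        cols = list(columns) if columns is not None else list(rows.columns)
        records = rows.to_dict(orient="records")
    else:
        records = list(rows)
        if columns is not None:
            cols = list(columns)
        elif records:
            cols = list(records[0].keys())
        else:
            cols = []
    for rec in records:
        if set(rec.keys()) != set(cols):
            raise FormatError(
                f"row schema {sorted(rec.keys())} does not match columns {sorted(cols)}"
            )
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for rec in records:
            writer.writerow([_serialize(rec[c]) for c in cols])


def _serialize(value: Any) -> str:
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (Condition, OrderGroup)):
        return value.value
    return str(value)


def read_layout(path: str | Path) -> StimulusLayout:
    """Read a stimulus layout from a YAML file.

    Expected structure::

        stimulus_id: ecg1
        width: 1280
        height: 1024
        leads:
          I: [40, 80, 320, 310]
          ...

    Overlapping lead rectangles are allowed but logged; a region outside the
    canvas raises :class:`LayoutValidationError`. An empty lead list is valid
    but flagged in the log.
    """
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"layout file {path} is not a mapping")
    for key in ("stimulus_id", "width", "height"):
        if key not in doc:
            raise FormatError(f"layout file {path} missing key {key!r}")
    leads_doc = doc.get("leads") or {}
    regions: dict[str, Rect] = {}
    for name, box in leads_doc.items():
        if len(box) != 4:
            raise FormatError(f"region {name!r} must have 4 numbers, got {box!r}")
        x0, y0, x1, y1 = (float(v) for v in box)
        if min(x0, y0, x1, y1) < 0:
            raise LayoutValidationError(f"region {name!r} has negative coordinates")
        regions[str(name)] = Rect(x0, y0, x1, y1)
    layout = StimulusLayout(
        stimulus_id=str(doc["stimulus_id"]),
        width=float(doc["width"]),
        height=float(doc["height"]),
        lead_regions=regions,
    )
    overlaps = layout.overlapping_pairs()
    if overlaps:
        logger.warning("layout %s has overlapping leads: %s", path, overlaps)
    if not regions:
        logger.warning("layout %s defines no lead regions", path)
    return layout


def write_layout(layout: StimulusLayout, path: str | Path) -> None:
    doc = {
        "stimulus_id": layout.stimulus_id,
        "width": layout.width,
        "height": layout.height,
        "leads": {
            name: [r.x0, r.y0, r.x1, r.y1]
            for name, r in layout.lead_regions.items()
        },
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_answer_key(path: str | Path) -> dict[str, dict[str, Any]]:
    """Read an answer key YAML: ``stimulus -> {canonical: str, accepted: [str]}``."""
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"answer key {path} is not a mapping")
    out: dict[str, dict[str, Any]] = {}
    for sid, entry in doc.items():
        if isinstance(entry, str):
            entry = {"canonical": entry, "accepted": [entry]}
        if "canonical" not in entry:
            raise FormatError(f"answer key entry {sid!r} lacks a canonical term")
        out[str(sid)] = {
            "canonical": str(entry["canonical"]),
            "accepted": [str(t) for t in entry.get("accepted", [])],
        }
    return out
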