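"""Accuracy scoring and conventional repeated-measures statistics.

Responses are scored by exact-set membership against an answer key after
case folding and whitespace normalization (auditability over fuzziness).
Per-stimulus accuracy differences use McNemar's continuity-corrected
chi-squared test; fixation count and mean duration use the Wilcoxon
signed-rank test (exact for small tie-free samples, normal approximation
with continuity correction otherwise); family-wise error is controlled with
a Bonferroni-divided alpha.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Condition, StudyDataset
from .errors import ArgumentError, UndefinedTestError
from .permutation import GroupAssignment

_WS = re.compile(r"\s+")
_PUNCT_EDGE = re.compile(r"^[\W_]+|[\W_]+$")


def normalize_term(text: str) -> str:
    """Case-folded, whitespace-collapsed, edge-punctuation-stripped form."""
    text = _PUNCT_EDGE.sub("", text.strip())
    return _WS.sub(" ", text).casefold()


@dataclass(frozen=True)
class AnswerKeyEntry:
    """Canonical diagnosis plus accepted synonyms/acronyms for one stimulus."""

    canonical: str
    accepted: frozenset[str]

    @classmethod
    def from_terms(cls, canonical: str, accepted: Sequence[str] = ()) -> "AnswerKeyEntry":
        terms = {normalize_term(canonical)}
        terms.update(normalize_term(t) for t in accepted)
        terms.discard("")
        return cls(canonical=canonical, accepted=frozenset(terms))


class AnswerKey:
    """Per-stimulus accepted-answer sets."""

    def __init__(self, entries: Mapping[str, AnswerKeyEntry]):
        self.entries = dict(entries)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Mapping[str, object]]) -> "AnswerKey":
        return cls(
            {
                sid: AnswerKeyEntry.from_terms(
                    str(entry["canonical"]), [str(t) for t in entry.get("accepted", [])]
                )
                for sid, entry in doc.items()
            }
        )

    def __getitem__(self, stimulus_id: str) -> AnswerKeyEntry:
        return self.entries[stimulus_id]

    def __contains__(self, stimulus_id: str) -> bool:
        return stimulus_id in self.entries


def score_response(response: str, key: AnswerKeyEntry) -> bool:
    """True iff the normalized response is in the accepted set.

    Umbrella terms not listed in the key score incorrect; the empty response
    scores incorrect.
    """
    return normalize_term(response) in key.accepted


@dataclass(frozen=True)
class AccuracyRecord:
    participant_id: str
    stimulus_id: str
    condition: Condition
    response: str
    correct: bool


def score_dataset(dataset: StudyDataset, key: AnswerKey) -> list[AccuracyRecord]:
    """Score every recorded response against the answer key."""
    records = []
    for (pid, sid, cond), text in sorted(
        dataset.responses.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
    ):
        if sid not in key:
            raise ArgumentError(f"no answer key entry for stimulus {sid!r}")
        records.append(
            AccuracyRecord(pid, sid, cond, text, score_response(text, key[sid]))
        )
    return records


@dataclass(frozen=True)
class PairedBinaryTable:
    """2x2 paired-outcome table: a = correct in both conditions, b = correct
    only in condition 1, c = correct only in condition 2, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ArgumentError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def paired_binary_table(
    records: Sequence[AccuracyRecord],
    stimulus_id: str,
    condition1: Condition = Condition.HISTORY,
    condition2: Condition = Condition.NO_HISTORY,
) -> PairedBinaryTable:
    """Cross-tabulate correctness across the two conditions for participants
    observed in both."""
    by_participant: dict[str, dict[Condition, bool]] = {}
    for rec in records:
        if rec.stimulus_id == stimulus_id:
            by_participant.setdefault(rec.participant_id, {})[rec.condition] = rec.correct
    a = b = c = d = 0
    for conds in by_participant.values():
        if condition1 not in conds or condition2 not in conds:
            continue
        c1, c2 = conds[condition1], conds[condition2]
        if c1 and c2:
            a += 1
        elif c1:
            b += 1
        elif c2:
            c += 1
        else:
            d += 1
    return PairedBinaryTable(a, b, c, d)


def mcnemar_test(table: PairedBinaryTable) -> tuple[float, float]:
    """Continuity-corrected McNemar chi-squared test on 1 degree of freedom.

    ``chi2 = (max(0, |b - c| - 1))^2 / (b + c)``; the upper-tail chi-square
    p-value is returned alongside. Undefined when no discordant pairs exist.
    """
    b, c = table.b, table.c
    if b + c == 0:
        raise UndefinedTestError("McNemar test undefined with zero discordant pairs")
    chi2 = max(0.0, abs(b - c) - 1.0) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Returns ``(V, p)`` where V is the sum of ranks of positive differences
    (zero differences dropped, mid-ranks for ties). The two-sided p-value is
    exact via sign-pattern enumeration for n <= 25 without ties among |d|,
    and a continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ArgumentError("paired samples must have equal length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(nonzero))
    v = float(ranks[nonzero > 0].sum())
    n = len(nonzero)
    has_ties = len(np.unique(np.abs(nonzero))) != n
    if n <= 25 and not has_ties:
        res = stats.wilcoxon(nonzero, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        res = stats.wilcoxon(
            nonzero, alternative="two-sided", method="approx", correction=True
        )
        p = float(res.pvalue)
    return v, p


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise threshold: alpha divided by the number of tests."""
    if m < 1:
        raise ArgumentError("number of tests must be >= 1")
    return alpha / m


def accuracy_split(
    records: Sequence[AccuracyRecord],
    stimulus_id: str,
    condition: Condition,
) -> GroupAssignment:
    """Post hoc correct (1) vs incorrect (2) grouping for one trial cell."""
    assignment: dict[str, int] = {}
    for rec in records:
        if rec.stimulus_id == stimulus_id and rec.condition == condition:
            assignment[rec.participant_id] = 1 if rec.correct else 2
    return GroupAssignment(assignment)


def participant_accuracy(records: Sequence[AccuracyRecord]) -> pd.DataFrame:
    """Per-participant percentage correct, overall and per condition."""
    rows = [
        {
            "participant": r.participant_id,
            "condition": r.condition.value,
            "correct": int(r.correct),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    overall = df.groupby("participant")["correct"].mean() * 100.0
    per_cond = (
        df.groupby(["participant", "condition"])["correct"].mean().unstack() * 100.0
    )
    out = per_cond.copy()
    out["overall"] = overall
    return out.reset_index()


def fixation_metrics(dataset: StudyDataset) -> pd.DataFrame:
    """Fixation count and mean fixation duration per trial."""
    rows = []
    for sp in dataset.scanpaths:
        durations = [fx.duration for fx in sp.fixations]
        rows.append(
            {
                "participant": sp.participant_id,
                "stimulus": sp.stimulus_id,
                "condition": sp.condition.value,
                "fixation_count": len(sp),
                "mean_fixation_duration": float(np.mean(durations)),
            }
        )
    return pd.DataFrame(rows)


def paired_metric(
    metrics: pd.DataFrame,
    stimulus_id: str,
    metric: str,
    condition1: Condition = Condition.HISTORY,
    condition2: Condition = Condition.NO_HISTORY,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant paired metric arrays (condition1, condition2) for one
    stimulus; participants lacking either condition are omitted."""
    sub = metrics[metrics["stimulus"] == stimulus_id]
    wide = sub.pivot(index="participant", columns="condition", values=metric)
    wide = wide.dropna(subset=[condition1.value, condition2.value])
    return (
        wide[condition1.value].to_numpy(dtype=float),
        wide[condition2.value].to_numpy(dtype=float),
    )


def mcnemar_table_per_stimulus(
    records: Sequence[AccuracyRecord], stimuli: Sequence[str]
) -> pd.DataFrame:
    """Per-stimulus accuracy comparison between conditions (chi2, p)."""
    rows = []
    for sid in stimuli:
        table = paired_binary_table(records, sid)
        try:
            chi2, p = mcnemar_test(table)
        except UndefinedTestError:
            chi2, p = math.nan, math.nan
        rows.append(
            {
                "stimulus": sid,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_table_per_stimulus(
    dataset: StudyDataset, stimuli: Sequence[str]
) -> pd.DataFrame:
    """Per-stimulus paired Wilcoxon tests on fixation count and duration."""
    metrics = fixation_metrics(dataset)
    rows = []
    for sid in stimuli:
        row: dict[str, object] = {"stimulus": sid}
        for metric, prefix in (
            ("fixation_count", "count"),
            ("mean_fixation_duration", "duration"),
        ):
            x, y = paired_metric(metrics, sid, metric)
            try:
                v, p = wilcoxon_signed_rank(x, y)
            except UndefinedTestError:
                v, p = math.nan, math.nan
            row[f"{prefix}_V"] = v
            row[f"{prefix}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)
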