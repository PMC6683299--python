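"""Transition counts, Markov chains, flat transition distributions, Hellinger.

A transition is a consecutive fixation pair within one trial; sequences never
bridge trials. Self-transitions (staying within an AOI) are counted like any
other. The distribution compared between groups is, by default, the joint
distribution over directed AOI pairs: the count matrix normalized by its
grand total and flattened row-major over a shared support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ArgumentError, IntegrityError

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class TransitionCountMatrix:
    """Directed AOI-to-AOI transition counts pooled over sequences."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (k, k) non-negative integers
    n_sequences: int
    n_transitions: int

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise IntegrityError("counts must be square over the label support")
        if (self.counts < 0).any():
            raise IntegrityError("counts must be non-negative")
        if int(self.counts.sum()) != self.n_transitions:
            raise IntegrityError("n_transitions does not match the count total")


@dataclass(frozen=True)
class MarkovChain:
    """Row-stochastic transition probabilities; zero-count rows stay zero."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    zero_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.matrix.shape != (k, k):
            raise IntegrityError("matrix must be square over the label support")
        sums = self.matrix.sum(axis=1)
        for i, label in enumerate(self.labels):
            if label in self.zero_rows:
                if sums[i] != 0:
                    raise IntegrityError(f"flagged zero row {label!r} has mass")
            elif not math.isclose(sums[i], 1.0, abs_tol=1e-9):
                raise IntegrityError(f"row {label!r} sums to {sums[i]}, not 1")

    @property
    def k(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TransitionDistribution:
    """Probabilities over an ordered support of directed (from, to) AOI pairs."""

    support: tuple[tuple[str, str], ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.probabilities) != len(self.support):
            raise IntegrityError("probability vector does not match support size")
        if (self.probabilities < 0).any():
            raise IntegrityError("probabilities must be non-negative")
        if not math.isclose(float(self.probabilities.sum()), 1.0, abs_tol=1e-9):
            raise IntegrityError(
                f"probabilities sum to {self.probabilities.sum()}, not 1"
            )

    @property
    def k(self) -> int:
        return len(self.support)


def count_transitions(
    sequences: Iterable[Sequence[str]], labels: Sequence[str]
) -> TransitionCountMatrix:
    """Pool directed consecutive-pair counts over the given label sequences.

    Every sequence contributes ``len - 1`` transitions; a single-label
    sequence contributes none. Labels outside the support raise.
    """
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise ArgumentError("support labels must be unique")
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    n_seq = 0
    for seq in sequences:
        if len(seq) < 1:
            raise ArgumentError("sequences must be non-empty")
        n_seq += 1
        try:
            idx = [index[lab] for lab in seq]
        except KeyError as exc:
            raise IntegrityError(f"label {exc.args[0]!r} outside support") from exc
        for a, b in zip(idx, idx[1:]):
            counts[a, b] += 1
    return TransitionCountMatrix(
        labels=labels,
        counts=counts,
        n_sequences=n_seq,
        n_transitions=int(counts.sum()),
    )


def to_markov(counts: TransitionCountMatrix) -> MarkovChain:
    """Row-normalize counts into a Markov chain; zero rows are flagged."""
    if counts.n_transitions == 0:
        raise ArgumentError("cannot build a Markov chain from zero transitions")
    row_sums = counts.counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(row_sums > 0, counts.counts / row_sums, 0.0)
    zero_rows = tuple(
        lab for lab, s in zip(counts.labels, row_sums[:, 0]) if s == 0
    )
    return MarkovChain(labels=counts.labels, matrix=matrix, zero_rows=zero_rows)


def flat_support(labels: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Row-major ordering of all directed pairs over a label set."""
    return tuple((a, b) for a in labels for b in labels)


def to_distribution(counts: TransitionCountMatrix) -> TransitionDistribution:
    """Grand-total-normalized flattening of the count matrix (the joint
    distribution over directed AOI pairs)."""
    if counts.n_transitions == 0:
        raise ArgumentError("cannot normalize zero transitions")
    probs = (counts.counts / counts.n_transitions).ravel()
    return TransitionDistribution(
        support=flat_support(counts.labels), probabilities=probs
    )


def hellinger(P: TransitionDistribution, Q: TransitionDistribution) -> float:
    """Hellinger distance between two distributions on an identical support.

    ``H = (1/sqrt(2)) * sqrt(sum_i (sqrt(p_i) - sqrt(q_i))^2)``, in [0, 1];
    0 iff the distributions coincide, 1 iff their supports are disjoint.
    """
    if P.support != Q.support:
        raise ArgumentError("distributions must share an identical support order")
    return hellinger_from_probs(P.probabilities, Q.probabilities)


def hellinger_from_probs(p: np.ndarray, q: np.ndarray) -> float:
    """Fast path of :func:`hellinger` on aligned probability vectors."""
    if p.shape != q.shape:
        raise ArgumentError("probability vectors must have equal length")
    # exact boundary cases: identical vectors and disjoint supports
    if np.array_equal(p, q):
        return 0.0
    if not np.any((p > 0) & (q > 0)):
        return 1.0
    diff = np.sqrt(p) - np.sqrt(q)
    h = math.sqrt(float(np.dot(diff, diff))) / SQRT2
    return min(max(h, 0.0), 1.0)


def rowwise_hellinger(a: MarkovChain, b: MarkovChain) -> float:
    """Alternative comparison mode: mean Hellinger distance across rows.

    Rows with no outgoing mass in either chain are skipped; a row empty in
    exactly one chain counts as maximally distant from any distribution's
    square-root embedding restricted to observed mass (H computed on the raw
    vectors, with the zero row contributing sqrt(sum q)/sqrt(2)).
    """
    if a.labels != b.labels:
        raise ArgumentError("chains must share an identical label support")
    distances = []
    for i in range(a.k):
        pa, pb = a.matrix[i], b.matrix[i]
        if pa.sum() == 0 and pb.sum() == 0:
            continue
        diff = np.sqrt(pa) - np.sqrt(pb)
        distances.append(math.sqrt(float(np.dot(diff, diff))) / SQRT2)
    if not distances:
        raise ArgumentError("no comparable rows between the chains")
    return float(np.mean(distances))


def normalized_by_max(counts: TransitionCountMatrix) -> np.ndarray:
    """Count matrix scaled by its maximum entry, for heat-map rendering."""
    peak = counts.counts.max()
    if peak == 0:
        return counts.counts.astype(float)
    return counts.counts / peak
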