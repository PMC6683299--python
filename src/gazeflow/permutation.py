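"""Group-difference inference: observed Hellinger distance and its
participant-shuffling permutation null.

Each participant contributes a pooled transition-count vector over the
directed-pair support of the AOI scheme; a group's distribution is the
grand-total-normalized sum of its members' vectors. The null reassigns
participants uniformly at random into groups of the original sizes.
Internally the support is compressed to pairs observed at least once across
the compared participants — absent pairs carry zero mass in both groups and
cannot change the distance.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .aoi import AOISet, assign_fixations
from .dataset import Condition, StudyDataset
from .errors import ArgumentError, InferenceError
from .transitions import hellinger_from_probs


@dataclass(frozen=True)
class GroupAssignment:
    """Disjoint two-group labeling of participants (group ids 1 and 2)."""

    assignment: Mapping[str, int]

    def __post_init__(self) -> None:
        values = set(self.assignment.values())
        if not values <= {1, 2}:
            raise ArgumentError(f"group ids must be 1 or 2, got {sorted(values)}")
        if 1 not in values or 2 not in values:
            raise ArgumentError("both groups must be non-empty")

    def group(self, gid: int) -> tuple[str, ...]:
        return tuple(sorted(p for p, g in self.assignment.items() if g == gid))

    @property
    def n1(self) -> int:
        return len(self.group(1))

    @property
    def n2(self) -> int:
        return len(self.group(2))

    @property
    def participants(self) -> tuple[str, ...]:
        return self.group(1) + self.group(2)


@dataclass(frozen=True)
class PermutationResult:
    """Observed distance plus permutation-null summaries.

    ``d`` is the null-standardized deviation ``(observed - M) / SD`` and the
    p-value follows the add-one rule
    ``(1 + #{null >= observed}) / (1 + n_permutations)``, so it is never 0.
    """

    stimulus_id: str | None
    scheme: str
    observed_hd: float
    null_mean: float
    null_sd: float
    d: float
    p_value: float
    n_permutations: int
    seed: int
    n1: int
    n2: int

    def to_row(self) -> dict[str, object]:
        return {
            "stimulus": self.stimulus_id if self.stimulus_id is not None else "all",
            "scheme": self.scheme,
            "n1": self.n1,
            "n2": self.n2,
            "M": self.null_mean,
            "SD": self.null_sd,
            "d": self.d,
            "Hd": self.observed_hd,
            "p": self.p_value,
            "n_perm": self.n_permutations,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TransitionProfile:
    """Per-participant transition-count vectors on a shared compressed support."""

    participants: tuple[str, ...]
    support: tuple[tuple[str, str], ...]
    matrix: np.ndarray  # (n_participants, len(support)) float counts

    @classmethod
    def build(
        cls,
        dataset: StudyDataset,
        aois: AOISet,
        participants: Sequence[str],
        stimulus_id: str | None = None,
        condition: Condition | None = None,
        include_outside: bool = True,
    ) -> "TransitionProfile":
        """Count each participant's directed AOI pairs on the selected trials.

        ``stimulus_id=None`` pools every stimulus (sequences still never
        bridge trials); ``condition=None`` pools both conditions. With
        ``include_outside=False`` the lead scheme's outside label is removed
        from sequences before pairing (transitions through it vanish).
        """
        participants = tuple(participants)
        per_participant: list[Counter] = []
        for pid in participants:
            counter: Counter = Counter()
            for sp in dataset.select(
                stimulus_id=stimulus_id, condition=condition, participant_id=pid
            ):
                seq = assign_fixations(sp, aois)
                if not include_outside and aois.outside_label is not None:
                    seq = [lab for lab in seq if lab != aois.outside_label]
                for pair in zip(seq, seq[1:]):
                    counter[pair] += 1
            per_participant.append(counter)
        observed = sorted({pair for c in per_participant for pair in c})
        index = {pair: i for i, pair in enumerate(observed)}
        matrix = np.zeros((len(participants), len(observed)))
        for row, counter in enumerate(per_participant):
            for pair, n in counter.items():
                matrix[row, index[pair]] = n
        return cls(
            participants=participants, support=tuple(observed), matrix=matrix
        )

    def indices_of(self, pids: Sequence[str]) -> np.ndarray:
        pos = {p: i for i, p in enumerate(self.participants)}
        return np.array([pos[p] for p in pids], dtype=int)


def _group_distance(matrix: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    c1 = matrix[idx1].sum(axis=0)
    c2 = matrix[idx2].sum(axis=0)
    t1, t2 = c1.sum(), c2.sum()
    if t1 == 0 or t2 == 0:
        gid = 1 if t1 == 0 else 2
        raise InferenceError(f"group {gid} contributes zero transitions")
    return hellinger_from_probs(c1 / t1, c2 / t2)


def observed_distance(
    dataset: StudyDataset,
    groups: GroupAssignment,
    aois: AOISet,
    stimulus_id: str | None = None,
    condition: Condition | None = None,
    profile: TransitionProfile | None = None,
) -> float:
    """Hellinger distance between the two groups' pooled joint transition
    distributions on their shared support."""
    if profile is None:
        profile = TransitionProfile.build(
            dataset, aois, groups.participants, stimulus_id, condition
        )
    if profile.matrix.shape[1] == 0:
        raise InferenceError("no transitions observed in either group")
    return _group_distance(
        profile.matrix,
        profile.indices_of(groups.group(1)),
        profile.indices_of(groups.group(2)),
    )


def permutation_null(
    dataset: StudyDataset,
    groups: GroupAssignment,
    aois: AOISet,
    stimulus_id: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    condition: Condition | None = None,
    profile: TransitionProfile | None = None,
) -> np.ndarray:
    """Null distribution of the distance under uniformly random reassignment
    of participants into groups of sizes (n1, n2). Reproducible per seed."""
    if n_perm < 1:
        raise ArgumentError("n_perm must be >= 1")
    if profile is None:
        profile = TransitionProfile.build(
            dataset, aois, groups.participants, stimulus_id, condition
        )
    n, n1 = len(profile.participants), groups.n1
    if math.comb(n, n1) < 2:
        raise InferenceError(
            f"fewer than 2 distinct reassignments for sizes ({n1}, {n - n1})"
        )
    if profile.matrix.shape[1] == 0:
        raise InferenceError("no transitions observed in either group")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = _group_distance(profile.matrix, perm[:n1], perm[n1:])
    return null


def permutation_test(
    dataset: StudyDataset,
    groups: GroupAssignment,
    aois: AOISet,
    stimulus_id: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    condition: Condition | None = None,
) -> PermutationResult:
    """Observed distance, null summaries (M, SD), standardized deviation d,
    and add-one empirical p-value for one (stimulus, scheme) comparison."""
    profile = TransitionProfile.build(
        dataset, aois, groups.participants, stimulus_id, condition
    )
    observed = observed_distance(
        dataset, groups, aois, stimulus_id, condition, profile=profile
    )
    null = permutation_null(
        dataset, groups, aois, stimulus_id, n_perm, seed, condition, profile=profile
    )
    m = float(null.mean())
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    if sd > 0:
        d = (observed - m) / sd
    else:
        d = 0.0 if math.isclose(observed, m, abs_tol=1e-12) else math.inf
    p = (1 + int(np.sum(null >= observed - 1e-12))) / (1 + n_perm)
    return PermutationResult(
        stimulus_id=stimulus_id,
        scheme=aois.scheme,
        observed_hd=observed,
        null_mean=m,
        null_sd=sd,
        d=d,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        n1=groups.n1,
        n2=groups.n2,
    )
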