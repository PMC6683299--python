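"""Synthetic study generator.

Produces full datasets with the statistical structure the analysis assumes:
per-group Markov transition chains over AOIs, within-AOI coordinate scatter
(truncated Gaussian around the cell center), log-normal fixation durations,
counterbalanced order groups, and Bernoulli correctness of responses.
Everything is driven by one seeded generator, so a scenario plus a seed is
bitwise-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .aoi import AOISet, lead_aois
from .dataset import (
    Condition,
    Fixation,
    OrderGroup,
    Rect,
    Scanpath,
    StimulusLayout,
    StudyDataset,
)
from .errors import ArgumentError, GenerationError
from .transitions import MarkovChain

_SACCADE_GAP_MS = 20.0


@dataclass(frozen=True)
class FixationCountModel:
    """Distribution of fixations per trial. ``negbinom`` uses a
    mean/dispersion parameterization; draws are floored at 2 so every trial
    carries at least one transition."""

    kind: str = "negbinom"
    mean: float = 30.0
    dispersion: float = 8.0

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return max(2, int(self.mean))
        if self.kind == "negbinom":
            r = self.dispersion
            p = r / (r + self.mean)
            return max(2, int(rng.negative_binomial(r, p)))
        raise ArgumentError(f"unknown fixation count model {self.kind!r}")


@dataclass(frozen=True)
class DurationModel:
    """Log-normal fixation durations in milliseconds (positive, right-skewed)."""

    meanlog: float = 5.3  # median ~200 ms
    sdlog: float = 0.4

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.meanlog, self.sdlog, size=n)


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of a synthetic study."""

    layout: StimulusLayout
    gen_aois: AOISet
    group_chains: Mapping[OrderGroup, MarkovChain]
    stimuli: tuple[str, ...]
    n_participants: int
    answers: Mapping[str, str]
    accuracy: Mapping[OrderGroup, float]
    fixation_count: FixationCountModel = field(default_factory=FixationCountModel)
    duration: DurationModel = field(default_factory=DurationModel)
    scatter_sd: float = 25.0
    start_probs: Mapping[OrderGroup, np.ndarray] | None = None
    leaky_scatter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ArgumentError("need at least 2 participants")
        if not self.stimuli:
            raise ArgumentError("need at least one stimulus")
        for og, p in self.accuracy.items():
            if not 0.0 <= p <= 1.0:
                raise ArgumentError(f"accuracy for {og} must be in [0, 1], got {p}")
        for og, chain in self.group_chains.items():
            if tuple(chain.labels) != tuple(self.gen_aois.labels):
                raise ArgumentError(
                    f"chain for {og} is not defined over the generation AOI labels"
                )

    def with_seed(self, seed: int) -> "SimulationScenario":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedStudy:
    dataset: StudyDataset
    ground_truth: SimulationScenario


def _start_vector(
    scenario_start: Mapping[OrderGroup, np.ndarray] | None,
    group: OrderGroup,
    k: int,
) -> np.ndarray:
    if scenario_start is not None and group in scenario_start:
        start = np.asarray(scenario_start[group], dtype=float)
        if len(start) != k or not np.isclose(start.sum(), 1.0):
            raise ArgumentError("start distribution must be a length-k simplex point")
        return start
    return np.full(k, 1.0 / k)


def _sample_state_sequence(
    chain: MarkovChain, start: np.ndarray, n_fix: int, rng: np.random.Generator
) -> np.ndarray:
    start_cum = np.cumsum(start)
    row_cum = np.cumsum(chain.matrix, axis=1)
    row_ok = chain.matrix.sum(axis=1) > 0
    u = rng.random(n_fix)
    states = np.empty(n_fix, dtype=int)
    s = int(np.searchsorted(start_cum, u[0], side="right"))
    states[0] = s
    for t in range(1, n_fix):
        if not row_ok[s]:
            raise GenerationError(
                f"chain state {chain.labels[s]!r} has no outgoing mass but "
                f"{n_fix - t} more fixations were requested"
            )
        s = int(np.searchsorted(row_cum[s], u[t], side="right"))
        s = min(s, chain.k - 1)  # guard against cumsum rounding at 1.0
        states[t] = s
    return states


def _scatter_in_rect(
    rect: Rect,
    n: int,
    sd: float,
    rng: np.random.Generator,
    leaky: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian scatter around the rectangle center, truncated to the
    half-open rectangle by resampling (clamped after 50 rounds). With
    ``leaky=True`` the raw Gaussian is returned untruncated."""
    cx, cy = rect.center
    x = cx + sd * rng.standard_normal(n)
    y = cy + sd * rng.standard_normal(n)
    if leaky:
        return x, y
    for _ in range(50):
        bad = (x < rect.x0) | (x >= rect.x1) | (y < rect.y0) | (y >= rect.y1)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return x, y
        x[bad] = cx + sd * rng.standard_normal(n_bad)
        y[bad] = cy + sd * rng.standard_normal(n_bad)
    eps = 1e-9
    np.clip(x, rect.x0, rect.x1 - eps, out=x)
    np.clip(y, rect.y0, rect.y1 - eps, out=y)
    return x, y


def simulate_scanpath(
    chain: MarkovChain,
    start: np.ndarray,
    n_fix: int,
    aois: AOISet,
    scatter_sd: float,
    duration_model: DurationModel,
    rng: np.random.Generator,
    participant_id: str = "p01",
    stimulus_id: str = "s01",
    condition: Condition = Condition.HISTORY,
    leaky_scatter: bool = False,
) -> Scanpath:
    """Sample one trial: an AOI state sequence from the chain, coordinates
    inside each state's region, and log-normal durations."""
    if n_fix < 1:
        raise ArgumentError("n_fix must be >= 1")
    states = _sample_state_sequence(chain, start, n_fix, rng)
    labels = aois.labels
    durations = duration_model.sample(rng, n_fix)
    onsets = np.concatenate(
        ([0.0], np.cumsum(durations[:-1] + _SACCADE_GAP_MS))
    )
    xs = np.empty(n_fix)
    ys = np.empty(n_fix)
    for s in np.unique(states):
        mask = states == s
        rect = aois.region_rect(labels[s])
        xs[mask], ys[mask] = _scatter_in_rect(
            rect, int(mask.sum()), scatter_sd, rng, leaky=leaky_scatter
        )
    fixations = tuple(
        Fixation(
            participant_id=participant_id,
            stimulus_id=stimulus_id,
            condition=condition,
            index=i + 1,
            x=float(xs[i]),
            y=float(ys[i]),
            duration=float(durations[i]),
            onset=float(onsets[i]),
        )
        for i in range(n_fix)
    )
    return Scanpath(participant_id, stimulus_id, condition, fixations)


def simulate_study(scenario: SimulationScenario) -> SimulatedStudy:
    """Generate the full trial grid: every participant sees every stimulus in
    both conditions; order groups alternate by participant index."""
    rng = np.random.default_rng(scenario.seed)
    k = len(scenario.gen_aois.labels)
    participants = [f"p{i + 1:02d}" for i in range(scenario.n_participants)]
    order_groups = {
        pid: (OrderGroup.HISTORY_FIRST if i % 2 == 0 else OrderGroup.HISTORY_LAST)
        for i, pid in enumerate(participants)
    }
    scanpaths: list[Scanpath] = []
    responses: dict[tuple[str, str, Condition], str] = {}
    for pid in participants:
        og = order_groups[pid]
        chain = scenario.group_chains[og]
        start = _start_vector(scenario.start_probs, og, k)
        p_correct = scenario.accuracy.get(og, 0.5)
        for sid in scenario.stimuli:
            for cond in (Condition.HISTORY, Condition.NO_HISTORY):
                n_fix = scenario.fixation_count.sample(rng)
                scanpaths.append(
                    simulate_scanpath(
                        chain,
                        start,
                        n_fix,
                        scenario.gen_aois,
                        scenario.scatter_sd,
                        scenario.duration,
                        rng,
                        participant_id=pid,
                        stimulus_id=sid,
                        condition=cond,
                        leaky_scatter=scenario.leaky_scatter,
                    )
                )
                correct = rng.random() < p_correct
                responses[(pid, sid, cond)] = (
                    scenario.answers[sid] if correct else "uncertain"
                )
    dataset = StudyDataset(
        scanpaths=tuple(scanpaths),
        responses=responses,
        order_groups=order_groups,
    )
    return SimulatedStudy(dataset=dataset, ground_truth=scenario)


def perturb_chain(
    chain: MarkovChain,
    magnitude: float,
    alternative: MarkovChain | None = None,
) -> MarkovChain:
    """Mix each row toward an alternative row: ``(1 - m) * row + m * alt``.

    Magnitude 0 returns the input chain; magnitude 1 returns the alternative
    exactly. The default alternative shifts each row one column to the right
    (cyclically), which differs from any non-shift-invariant chain.
    """
    if not 0.0 <= magnitude <= 1.0:
        raise ArgumentError("magnitude must be in [0, 1]")
    alt = (
        alternative.matrix
        if alternative is not None
        else np.roll(chain.matrix, 1, axis=1)
    )
    if alternative is not None and alternative.labels != chain.labels:
        raise ArgumentError("alternative chain must share the label support")
    mixed = (1.0 - magnitude) * chain.matrix + magnitude * alt
    row_sums = mixed.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        mixed = np.where(row_sums > 0, mixed / row_sums, 0.0)
    zero_rows = tuple(
        lab for lab, s in zip(chain.labels, mixed.sum(axis=1)) if s == 0
    )
    return MarkovChain(labels=chain.labels, matrix=mixed, zero_rows=zero_rows)


def random_chain(
    labels: Sequence[str],
    rng: np.random.Generator,
    concentration: float = 1.0,
) -> MarkovChain:
    """Row-stochastic chain with Dirichlet rows (shared concentration)."""
    k = len(labels)
    matrix = rng.dirichlet(np.full(k, concentration), size=k)
    return MarkovChain(labels=tuple(labels), matrix=matrix)


# ---------------------------------------------------------------------------
# default study scenario: 12-lead layout, 9 stimuli, 31 participants

STIMULUS_IDS = (
    "anterolateral_stemi",
    "inferolateral_stemi",
    "high_lateral_stemi",
    "anterior_stemi",
    "inferior_stemi_af",
    "rbbb",
    "atrial_fibrillation",
    "lateral_stemi",
    "lbbb",
)

DEFAULT_ANSWERS: dict[str, str] = {
    "anterolateral_stemi": "anterolateral stemi",
    "inferolateral_stemi": "inferolateral stemi",
    "high_lateral_stemi": "high lateral stemi",
    "anterior_stemi": "anterior stemi",
    "inferior_stemi_af": "inferior stemi with af",
    "rbbb": "rbbb",
    "atrial_fibrillation": "atrial fibrillation",
    "lateral_stemi": "lateral stemi",
    "lbbb": "lbbb",
}

_LEAD_NAMES = (
    "I", "aVR", "V1", "V4",
    "II", "aVL", "V2", "V5",
    "III", "aVF", "V3", "V6",
)


def default_layout(stimulus_id: str = "ecg") -> StimulusLayout:
    """A 1280x1024 canvas with 12 lead rectangles in the conventional
    4-column, 3-row print arrangement plus a rhythm strip."""
    width, height = 1280.0, 1024.0
    margin, gap = 40.0, 8.0
    cols, rows = 4, 3
    cell_w = (width - 2 * margin - (cols - 1) * gap) / cols
    strip_h = 160.0
    cell_h = (height - 2 * margin - strip_h - rows * gap) / rows
    regions: dict[str, Rect] = {}
    for i, name in enumerate(_LEAD_NAMES):
        r, c = divmod(i, cols)
        x0 = margin + c * (cell_w + gap)
        y0 = margin + r * (cell_h + gap)
        regions[name] = Rect(x0, y0, x0 + cell_w, y0 + cell_h)
    y0 = margin + rows * (cell_h + gap)
    regions["rhythm"] = Rect(margin, y0, width - margin, y0 + strip_h)
    return StimulusLayout(
        stimulus_id=stimulus_id, width=width, height=height, lead_regions=regions
    )


def default_scenario(
    seed: int = 0,
    n_participants: int = 31,
    mean_fixations: float = 30.0,
    group_difference: float = 0.3,
) -> SimulationScenario:
    """The bundled study scenario: 31 participants x 9 stimuli x 2 conditions
    with counterbalanced order groups and group chains over the lead AOIs
    that differ by ``group_difference`` (0 makes the groups exchangeable)."""
    layout = default_layout()
    gen_aois = lead_aois(layout, outside_label=None)
    rng = np.random.default_rng(seed)
    base = random_chain(gen_aois.labels, rng, concentration=0.6)
    other = perturb_chain(base, group_difference)
    return SimulationScenario(
        layout=layout,
        gen_aois=gen_aois,
        group_chains={
            OrderGroup.HISTORY_FIRST: base,
            OrderGroup.HISTORY_LAST: other,
        },
        stimuli=STIMULUS_IDS,
        n_participants=n_participants,
        answers=dict(DEFAULT_ANSWERS),
        accuracy={OrderGroup.HISTORY_FIRST: 0.7, OrderGroup.HISTORY_LAST: 0.6},
        fixation_count=FixationCountModel(mean=mean_fixations),
        scatter_sd=60.0,
        seed=seed,
    )
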