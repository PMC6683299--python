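"""Simulation designs shared by the calibration, power and granularity
acceptance tests: 14 + 14 participants, 9 stimuli x 2 conditions, ~20
fixations per trial."""

from __future__ import annotations

import numpy as np

from gazeflow.aoi import derive_grid, lead_aois
from gazeflow.dataset import OrderGroup, Rect, StimulusLayout
from gazeflow.permutation import permutation_test
from gazeflow.pipeline import order_group_assignment
from gazeflow.simulate import (
    FixationCountModel,
    SimulationScenario,
    default_scenario,
    random_chain,
    simulate_study,
)
from gazeflow.transitions import MarkovChain

N_PARTICIPANTS = 28  # 14 per order group
MEAN_FIXATIONS = 20.0


def calibration_scenario(seed: int, magnitude: float = 0.0) -> SimulationScenario:
    """Both groups' chains differ by ``magnitude`` (0: exchangeable null)."""
    return default_scenario(
        seed=seed,
        n_participants=N_PARTICIPANTS,
        mean_fixations=MEAN_FIXATIONS,
        group_difference=magnitude,
    )


def calibration_p_value(scenario: SimulationScenario, n_perm: int,
                        seed: int, aois=None) -> float:
    study = simulate_study(scenario)
    groups = order_group_assignment(study.dataset)
    result = permutation_test(
        study.dataset, groups, aois if aois is not None else scenario.gen_aois,
        stimulus_id=None, n_perm=n_perm, seed=seed,
    )
    return result.p_value


def rejection_rate(magnitude: float, n_replicates: int, n_perm: int,
                   seed_base: int, alpha: float = 0.05) -> float:
    rejections = 0
    for rep in range(n_replicates):
        p = calibration_p_value(
            calibration_scenario(seed_base + rep, magnitude), n_perm, rep
        )
        rejections += p <= alpha
    return rejections / n_replicates


# -- granularity design ------------------------------------------------------
# Two 100x100 leads over a 200x100 canvas, each containing four 50-px grid
# cells. Group 2's chain is group 1's with the cells permuted *within* each
# lead, so the lead-aggregated transition process is identical in
# distribution while the grid-level joint differs.

GRAN_LAYOUT = StimulusLayout(
    "s", 200.0, 100.0,
    {"left": Rect(0, 0, 100, 100), "right": Rect(100, 0, 200, 100)},
)
GRAN_GRID = derive_grid(GRAN_LAYOUT, 50.0)  # 2 rows x 4 cols
GRAN_LEADS = lead_aois(GRAN_LAYOUT)


def _within_lead_permutation() -> list[int]:
    """Index permutation swapping the two cell columns inside each lead."""
    labels = GRAN_GRID.labels
    mapped = []
    for label in labels:
        r, c = (int(part) for part in label[1:].split("c"))
        c2 = c + 1 if c % 2 == 0 else c - 1
        mapped.append(labels.index(f"r{r:02d}c{c2:02d}"))
    return mapped


def granularity_scenario(seed: int, chain_seed: int = 7,
                         differ: bool = True) -> SimulationScenario:
    rng = np.random.default_rng(chain_seed)
    base = random_chain(GRAN_GRID.labels, rng, concentration=0.3)
    idx = _within_lead_permutation()
    permuted = MarkovChain(
        GRAN_GRID.labels, base.matrix[np.ix_(idx, idx)]
    )
    stimuli = tuple(f"s{i}" for i in range(9))
    return SimulationScenario(
        layout=GRAN_LAYOUT,
        gen_aois=GRAN_GRID,
        group_chains={
            OrderGroup.HISTORY_FIRST: base,
            OrderGroup.HISTORY_LAST: permuted if differ else base,
        },
        stimuli=stimuli,
        n_participants=N_PARTICIPANTS,
        answers={s: "x" for s in stimuli},
        accuracy={OrderGroup.HISTORY_FIRST: 0.7, OrderGroup.HISTORY_LAST: 0.7},
        fixation_count=FixationCountModel(mean=MEAN_FIXATIONS),
        scatter_sd=15.0,
        seed=seed,
    )
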