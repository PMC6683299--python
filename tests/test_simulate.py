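import numpy as np
import pytest

from gazeflow.aoi import assign_fixations
from gazeflow.dataset import Condition, OrderGroup
from gazeflow.errors import ArgumentError, GenerationError
from gazeflow.io import read_fixation_table, read_responses, write_dataset
from gazeflow.simulate import (
    DurationModel,
    FixationCountModel,
    default_scenario,
    perturb_chain,
    random_chain,
    simulate_scanpath,
    simulate_study,
)
from gazeflow.transitions import MarkovChain, count_transitions, to_distribution
from gazeflow.transitions import hellinger_from_probs
from helpers import grid_aois

AOIS = grid_aois(cell_side=50.0)  # labels r00c00 r00c01 r01c00 r01c01
LABELS = AOIS.labels
DUR = DurationModel()


def delta_start(k, i):
    v = np.zeros(k)
    v[i] = 1.0
    return v


class TestSimulateScanpath:
    def test_identity_chain_absorbs(self, rng):
        chain = MarkovChain(LABELS, np.eye(4))
        sp = simulate_scanpath(chain, delta_start(4, 0), 20, AOIS, 5.0, DUR, rng)
        assert assign_fixations(sp, AOIS) == ["r00c00"] * 20

    def test_single_fixation(self, rng):
        chain = MarkovChain(LABELS, np.eye(4))
        sp = simulate_scanpath(chain, delta_start(4, 2), 1, AOIS, 5.0, DUR, rng)
        assert len(sp) == 1

    def test_zero_row_state_raises_when_more_requested(self, rng):
        m = np.zeros((4, 4))
        m[0, 1] = 1.0  # state 1 has no outgoing mass
        chain = MarkovChain(LABELS, m, zero_rows=LABELS[1:])
        with pytest.raises(GenerationError):
            simulate_scanpath(chain, delta_start(4, 0), 10, AOIS, 5.0, DUR, rng)

    def test_uniform_two_state_empirical_distribution(self):
        rng = np.random.default_rng(99)
        labels = LABELS[:2]
        aois = AOIS  # only first two cells used
        chain = MarkovChain(LABELS, np.full((4, 4), 0.25))
        sp = simulate_scanpath(chain, np.full(4, 0.25), 10_000, AOIS, 5.0,
                               DUR, rng)
        seq = assign_fixations(sp, AOIS)
        dist = to_distribution(count_transitions([seq], LABELS))
        tv = 0.5 * np.abs(dist.probabilities - 1.0 / 16).sum()
        assert tv < 0.02

    def test_durations_positive_and_onsets_increase(self, rng):
        chain = MarkovChain(LABELS, np.full((4, 4), 0.25))
        sp = simulate_scanpath(chain, np.full(4, 0.25), 50, AOIS, 5.0, DUR, rng)
        durations = [fx.duration for fx in sp.fixations]
        onsets = [fx.onset for fx in sp.fixations]
        assert min(durations) > 0
        assert all(b > a for a, b in zip(onsets, onsets[1:]))

    def test_truncated_scatter_stays_in_generating_cell(self, rng):
        chain = MarkovChain(LABELS, np.eye(4))
        sp = simulate_scanpath(chain, delta_start(4, 3), 200, AOIS, 100.0,
                               DUR, rng)
        assert set(assign_fixations(sp, AOIS)) == {"r01c01"}


class TestSimulateStudy:
    def test_default_trial_grid(self):
        study = simulate_study(default_scenario(seed=0, n_participants=31,
                                                mean_fixations=4.0))
        ds = study.dataset
        assert len(ds.participants()) == 31
        assert len(ds.stimuli()) == 9
        assert len(ds.scanpaths) == 31 * 9 * 2
        for pid in ds.participants():
            for sid in ds.stimuli():
                for cond in Condition:
                    assert len(ds.select(sid, cond, pid)) == 1

    def test_counterbalancing_alternates(self):
        study = simulate_study(default_scenario(seed=0, n_participants=6,
                                                mean_fixations=3.0))
        ogs = [study.dataset.order_groups[p]
               for p in sorted(study.dataset.order_groups)]
        assert ogs == [OrderGroup.HISTORY_FIRST, OrderGroup.HISTORY_LAST] * 3

    def test_same_seed_identical(self):
        sc = default_scenario(seed=21, n_participants=4, mean_fixations=5.0)
        assert simulate_study(sc).dataset == simulate_study(sc).dataset

    def test_different_seed_differs(self):
        a = simulate_study(default_scenario(seed=1, n_participants=4,
                                            mean_fixations=5.0)).dataset
        b = simulate_study(default_scenario(seed=2, n_participants=4,
                                            mean_fixations=5.0)).dataset
        assert a != b

    def test_extreme_accuracy_models(self):
        import dataclasses

        sc = default_scenario(seed=5, n_participants=4, mean_fixations=3.0)
        sc = dataclasses.replace(sc, accuracy={OrderGroup.HISTORY_FIRST: 1.0,
                                               OrderGroup.HISTORY_LAST: 0.0})
        study = simulate_study(sc)
        ds = study.dataset
        for (pid, sid, cond), text in ds.responses.items():
            if ds.order_groups[pid] is OrderGroup.HISTORY_FIRST:
                assert text == sc.answers[sid]
            else:
                assert text != sc.answers[sid]

    def test_round_trips_through_io(self, tmp_path):
        study = simulate_study(default_scenario(seed=9, n_participants=3,
                                                mean_fixations=6.0))
        write_dataset(study.dataset, tmp_path / "f.tsv", tmp_path / "r.tsv")
        back = read_fixation_table(
            tmp_path / "f.tsv", responses=read_responses(tmp_path / "r.tsv")
        )
        assert back == study.dataset


class TestPerturbChain:
    def test_magnitude_zero_is_identity(self, rng):
        chain = random_chain(LABELS, rng)
        out = perturb_chain(chain, 0.0)
        np.testing.assert_allclose(out.matrix, chain.matrix)

    def test_magnitude_one_is_alternative(self, rng):
        chain = random_chain(LABELS, rng)
        out = perturb_chain(chain, 1.0)
        np.testing.assert_allclose(out.matrix, np.roll(chain.matrix, 1, axis=1))

    def test_rows_remain_stochastic(self, rng):
        chain = random_chain(LABELS, rng)
        for mag in (0.1, 0.5, 0.9):
            out = perturb_chain(chain, mag)
            np.testing.assert_allclose(out.matrix.sum(axis=1), 1.0)

    def test_invalid_magnitude(self, rng):
        with pytest.raises(ArgumentError):
            perturb_chain(random_chain(LABELS, rng), 1.5)

    def test_joint_distance_nondecreasing_in_magnitude(self):
        # direct computation on large simulated samples, fixed seed
        rng = np.random.default_rng(7)
        base = random_chain(LABELS, rng, concentration=0.5)
        start = np.full(4, 0.25)
        dur = DurationModel()

        def empirical_joint(chain, seed):
            r = np.random.default_rng(seed)
            sp = simulate_scanpath(chain, start, 20_000, AOIS, 5.0, dur, r)
            seq = assign_fixations(sp, AOIS)
            return to_distribution(count_transitions([seq], LABELS)).probabilities

        ref = empirical_joint(base, 1)
        distances = [
            hellinger_from_probs(ref, empirical_joint(perturb_chain(base, m), 2))
            for m in (0.0, 0.25, 0.5, 1.0)
        ]
        slack = 0.01  # sampling noise tolerance
        assert all(b >= a - slack for a, b in zip(distances, distances[1:]))
        assert distances[-1] > distances[0]


class TestParameterRecovery:
    def test_empirical_joint_converges_to_chain_joint(self):
        rng = np.random.default_rng(3)
        chain = random_chain(LABELS, rng, concentration=1.0)
        # stationary distribution from the leading left eigenvector
        w, v = np.linalg.eig(chain.matrix.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        pi = pi / pi.sum()
        joint = (pi[:, None] * chain.matrix).ravel()
        tvs = []
        for n in (100, 1_000, 10_000):
            r = np.random.default_rng(17)
            sp = simulate_scanpath(chain, pi, n + 1, AOIS, 5.0, DUR, r)
            seq = assign_fixations(sp, AOIS)
            emp = to_distribution(count_transitions([seq], LABELS)).probabilities
            tvs.append(0.5 * np.abs(emp - joint).sum())
        assert tvs[2] < tvs[0]  # shrinks with sample size
        assert tvs[2] < 0.02


def test_fixation_count_models(rng):
    assert FixationCountModel(kind="fixed", mean=7).sample(rng) == 7
    draws = [FixationCountModel(mean=20.0).sample(rng) for _ in range(500)]
    assert min(draws) >= 2
    assert abs(np.mean(draws) - 20.0) < 2.0
    with pytest.raises(ArgumentError):
        FixationCountModel(kind="poisson").sample(rng)
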