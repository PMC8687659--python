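"""Exploration/exploitation labelling, baselines, shares and initiators."""

import numpy as np
import pytest

from infoflow.encoding import ProjectedDistanceSeries
from infoflow.explore_exploit import (distance_to_baseline,
                                      exploration_proportion, initiation_test,
                                      label_segments, phase_leadership_share,
                                      select_baseline, transition_initiators)
from infoflow.io import mean_pair_trajectory
from infoflow.simulate import SimConfig, simulate_transmission_chain

from conftest import make_traj


def dseries(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return ProjectedDistanceSeries(d_en=values, u_hat=np.zeros((len(values), 2)),
                                   valid=np.asarray(valid, dtype=bool),
                                   sampling_period=0.2)


class TestDistanceToBaseline:
    def test_self_distance_zero(self):
        tr = make_traj(np.c_[np.arange(100) * 4.0, np.zeros(100)])
        assert np.allclose(distance_to_baseline(tr, tr), 0.0)

    def test_parallel_offset(self):
        base = make_traj(np.c_[np.arange(500) * 4.0, np.zeros(500)])
        focal = make_traj(np.c_[np.arange(500) * 4.0, np.full(500, 400.0)])
        d = distance_to_baseline(focal, base)
        assert np.allclose(d, 400.0, atol=0.5)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(0)
        base_xy = np.cumsum(rng.normal(size=(200, 2)), axis=0) * 10
        focal_xy = base_xy + rng.normal(size=(200, 2)) * 50
        d0 = distance_to_baseline(make_traj(focal_xy), make_traj(base_xy))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([1234.0, -987.0])
        d1 = distance_to_baseline(make_traj(focal_xy @ R.T + shift),
                                  make_traj(base_xy @ R.T + shift))
        assert np.allclose(d0, d1, atol=1e-6)


class TestSelectBaseline:
    def _flights(self, generations=3, releases=12):
        out = []
        for g in range(1, generations + 1):
            for r in range(1, releases + 1):
                out.append(make_traj(np.zeros((5, 2)), chain="c",
                                     generation=g, release=r))
        return out

    def test_model_a_previous_release(self):
        mapping, _ = select_baseline(self._flights(), "previous_release")
        assert mapping[("c", 2, 5)] == ("c", 2, 4)

    def test_model_a_generation_boundary(self):
        mapping, excluded = select_baseline(self._flights(), "previous_release")
        assert mapping[("c", 3, 1)] == ("c", 2, 12)
        assert ("c", 1, 1) in excluded

    def test_model_b_last_of_previous_generation(self):
        mapping, _ = select_baseline(self._flights(),
                                     "last_of_previous_generation")
        assert mapping[("c", 3, 7)] == ("c", 2, 12)
        # generation 1 falls back to model A
        assert mapping[("c", 1, 7)] == ("c", 1, 6)

    def test_every_generation_release_cell_follows_the_rule(self):
        flights = self._flights(4, 6)
        map_a, ex_a = select_baseline(flights, "previous_release")
        map_b, _ = select_baseline(flights, "last_of_previous_generation")
        for g in range(1, 5):
            for r in range(1, 7):
                if g == 1 and r == 1:
                    assert ("c", g, r) in ex_a
                    continue
                expect_a = ("c", g, r - 1) if r > 1 else ("c", g - 1, 6)
                assert map_a[("c", g, r)] == expect_a
                expect_b = ("c", g - 1, 6) if g > 1 else expect_a
                assert map_b[("c", g, r)] == expect_b

    def test_missing_baseline_excluded_with_reason(self):
        flights = [make_traj(np.zeros((5, 2)), chain="c", generation=2, release=3)]
        mapping, excluded = select_baseline(flights, "previous_release")
        assert mapping == {}
        assert "missing" in excluded[("c", 2, 3)]


class TestLabelling:
    def test_all_near_all_exploitation(self):
        lab = label_segments(np.zeros(100))
        assert lab.proportion_exploration() == 0.0

    def test_all_far_all_exploration(self):
        lab = label_segments(np.full(100, 400.0))
        assert lab.proportion_exploration() == 1.0

    def test_threshold_boundary_counts_as_exploitation(self):
        lab = label_segments(np.array([100.0, 300.0, 300.1]))
        assert lab.explore.tolist() == [False, False, True]

    def test_phase_runs(self):
        lab = label_segments(np.array([100, 350, 350, 100.0]))
        assert [p[0] for p in lab.phases()] == [False, True, False]

    def test_proportion_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 800, 1000)
        props = [label_segments(d, th).proportion_exploration()
                 for th in (100, 300, 500, 1e9)]
        assert all(b <= a for a, b in zip(props, props[1:]))
        assert props[-1] == 0.0


@pytest.fixture(scope="module")
def chain():
    cfg = SimConfig(n_steps=3600, p_explore=0.0002, seed=7,
                    explore_band=(400.0, 1000.0))
    return simulate_transmission_chain(cfg, n_generations=3, n_releases=12,
                                       chain_id="c1")


class TestOnSyntheticChains:
    def _labels(self, chain):
        focal = {}
        gts = {}
        for fl in chain:
            key = (fl.chain_id, fl.generation, fl.release)
            focal[key] = fl.solo if fl.is_solo else mean_pair_trajectory(fl.pair)
            gts[key] = fl.ground_truth
        mapping, _ = select_baseline(list(focal.values()), "previous_release")
        labels = {}
        for fk, bk in mapping.items():
            d = distance_to_baseline(focal[fk], focal[bk])
            labels[fk] = label_segments(d, flight_key=fk, baseline_ref=bk)
        return labels, gts

    def test_labels_recover_ground_truth_bouts(self, chain):
        labels, gts = self._labels(chain)
        inter = union = 0
        for fk, lab in labels.items():
            gt = gts[fk].explore_state
            inter += np.sum(lab.explore & gt)
            union += np.sum(lab.explore | gt)
        assert union > 0
        assert inter / union >= 0.8

    def test_exploration_elevated_early_in_paired_generations(self, chain):
        labels, _ = self._labels(chain)
        paired = {k: v for k, v in labels.items() if k[1] > 1}
        table = exploration_proportion(paired)
        early = table[table.release <= 6]["proportion_exploration"].mean()
        late = table[table.release > 6]["proportion_exploration"].mean()
        assert early > late


class TestPhaseShares:
    def test_always_front_full_share_in_both_phases(self):
        lab = label_segments(np.r_[np.zeros(50), np.full(50, 400.0)])
        d = dseries(np.full(100, 3.0))
        shares = phase_leadership_share(lab, d)
        assert shares["exploration"]["share_E"] == 1.0
        assert shares["exploitation"]["share_E"] == 1.0

    def test_absent_phase_missing_not_zero(self):
        lab = label_segments(np.zeros(100))
        shares = phase_leadership_share(lab, dseries(np.ones(100)))
        assert shares["exploration"]["share_E"] is None
        assert shares["exploration"]["n_samples"] == 0

    def test_designated_bout_leader_dominates_exploration(self):
        # N leads every exploration sample, phases split 50/50 otherwise
        rng = np.random.default_rng(9)
        dist = np.r_[np.zeros(500), np.full(500, 400.0)]
        d_en = np.where(np.arange(1000) >= 500, -5.0,
                        np.where(rng.random(1000) < 0.5, 5.0, -5.0))
        shares = phase_leadership_share(label_segments(dist), dseries(d_en))
        assert shares["exploration"]["share_N"] == 1.0
        assert shares["exploitation"]["share_N"] == pytest.approx(0.5, abs=0.1)


class TestTransitionInitiators:
    def test_front_bird_at_onset_is_initiator(self):
        lab = label_segments(np.r_[np.zeros(10), np.full(5, 400.0)])
        d = dseries(np.full(15, 3.0))
        assert transition_initiators(lab, d, "exploit_to_explore") == ["E"]

    def test_masked_onset_falls_back_to_preceding_sample(self):
        lab = label_segments(np.r_[np.zeros(10), np.full(5, 400.0)])
        valid = np.ones(15, dtype=bool)
        valid[10] = False
        d = dseries(np.r_[np.full(10, -2.0), np.full(5, 2.0)], valid=valid)
        assert transition_initiators(lab, d, "exploit_to_explore") == ["N"]

    def test_binomial_31_of_44_significant(self):
        rep = initiation_test(["N"] * 31 + ["E"] * 13, role="N")
        assert rep["n"] == 44
        assert rep["p"] < 0.01

    def test_even_split_p_one(self):
        rep = initiation_test(["N"] * 10 + ["E"] * 10)
        assert rep["p"] == 1.0

    def test_no_transitions_contribute_nothing(self):
        lab = label_segments(np.zeros(50))
        assert transition_initiators(lab, dseries(np.ones(50))) == []
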