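import itertools
import math

import numpy as np
import pytest

from erpconsensus.consensus import (coassociation, consensus_across_trials,
                                    consensus_within_trial, cspa, nmi,
                                    select_consensus)
from erpconsensus.datamodel import Labeling
from tests.conftest import make_labeling, planted_epoch


def hand_nmi(a, b):
    """Contingency-table NMI with arithmetic-mean normalisation (oracle)."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size

    def entropy(x):
        _, counts = np.unique(x, return_counts=True)
        p = counts / n
        return -np.sum(p * np.log(p))

    mi = 0.0
    for ai in np.unique(a):
        for bi in np.unique(b):
            nij = np.sum((a == ai) & (b == bi))
            if nij == 0:
                continue
            pij = nij / n
            mi += pij * math.log(pij / ((np.sum(a == ai) / n) *
                                        (np.sum(b == bi) / n)))
    denom = (entropy(a) + entropy(b)) / 2
    return mi / denom if denom > 0 else 0.0


class TestCoassociation:
    def test_identical_labelings_give_block_matrix(self):
        lab = make_labeling([1, 1, 2, 2, 3])
        S = coassociation([lab] * 4)
        expected = (lab.labels[:, None] == lab.labels[None, :]).astype(float)
        assert np.array_equal(S, expected)

    def test_single_labeling(self):
        lab = make_labeling([1, 2, 1])
        S = coassociation([lab])
        assert np.array_equal(S, np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1.0]]))

    def test_matches_pairwise_counting_oracle(self, rng):
        labs = [make_labeling(rng.integers(1, 4, size=12)) for _ in range(5)]
        S = coassociation(labs)
        for i, j in itertools.combinations(range(12), 2):
            frac = np.mean([l.labels[i] == l.labels[j] for l in labs])
            assert S[i, j] == pytest.approx(frac)
        assert np.allclose(np.diag(S), 1.0)
        assert np.allclose(S, S.T)
        assert S.min() >= 0 and S.max() <= 1

    def test_agreeing_labeling_never_decreases_pairs_together(self, rng):
        labs = [make_labeling(rng.integers(1, 4, size=10)) for _ in range(4)]
        S1 = coassociation(labs)
        agree = labs[0]
        S2 = coassociation(labs + [agree])
        together = agree.labels[:, None] == agree.labels[None, :]
        assert np.all(S2[together] >= S1[together] - 1e-12)


class TestCspa:
    def test_identical_inputs_recovered(self):
        lab = make_labeling([1, 1, 1, 2, 2, 3, 3, 3])
        out = cspa([lab] * 5, K=3)
        assert nmi(out, lab) == pytest.approx(1.0)

    def test_planted_blocks_with_label_noise(self, rng):
        truth = np.repeat([1, 2, 3], 20)
        labs = []
        for _ in range(15):
            noisy = truth.copy()
            flip = rng.random(60) < 0.10
            noisy[flip] = rng.integers(1, 4, size=flip.sum())
            labs.append(make_labeling(noisy))
        out = cspa(labs, K=3)
        assert nmi(out, make_labeling(truth)) >= 0.9

    def test_single_labeling_returned_as_is(self):
        lab = make_labeling([1, 1, 2, 2])
        assert nmi(cspa([lab], K=2), lab) == pytest.approx(1.0)

    def test_invariant_to_label_permutation_and_order(self, rng):
        labs = [make_labeling(rng.integers(1, 4, size=15)) for _ in range(6)]
        out1 = cspa(labs, K=3)
        permuted = []
        for l in labs:
            perm = rng.permutation(3) + 1
            permuted.append(Labeling(perm[l.labels - 1], 3))
        out2 = cspa(list(reversed(permuted)), K=3)
        assert nmi(out1, out2) == pytest.approx(1.0)

    def test_matches_exhaustive_partition_search_on_small_ensembles(self, rng):
        # all 2-cluster partitions of 7 points, scored by mean NMI to the
        # ensemble: on unambiguous ensembles CSPA must find the optimum
        truth = np.array([1, 1, 1, 1, 2, 2, 2])
        labs = [make_labeling(truth), make_labeling(truth),
                make_labeling([1, 1, 1, 2, 2, 2, 2])]
        out = cspa(labs, K=2)

        best_score, best_part = -1.0, None
        for bits in itertools.product([1, 2], repeat=6):
            part = np.array([1, *bits])
            if len(set(part)) < 2:
                continue
            score = np.mean([nmi(part, l.labels) for l in labs])
            if score > best_score:
                best_score, best_part = score, part
        assert nmi(out, make_labeling(best_part)) == pytest.approx(1.0)


class TestNmi:
    def test_relabeling_gives_one(self, rng):
        a = rng.integers(1, 5, size=30)
        perm = rng.permutation(4) + 1
        assert nmi(a, perm[a - 1]) == pytest.approx(1.0)

    def test_constant_labeling_gives_zero(self, rng):
        a = np.ones(20, dtype=int)
        b = rng.integers(1, 4, size=20)
        assert nmi(a, b) == 0.0
        assert nmi(a, a) == 0.0  # zero-entropy convention

    def test_six_point_example_matches_hand_computation(self):
        a = np.array([1, 1, 1, 2, 2, 2])
        b = np.array([1, 1, 2, 2, 2, 2])
        assert nmi(a, b) == pytest.approx(hand_nmi(a, b), abs=1e-12)

    def test_random_labelings_match_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(1, 4, size=25)
            b = rng.integers(1, 5, size=25)
            assert nmi(a, b) == pytest.approx(hand_nmi(a, b), abs=1e-9)


class TestSelectConsensus:
    def test_all_identical(self):
        lab = make_labeling([1, 1, 2, 2, 3, 3])
        out = select_consensus([lab] * 4, K=3)
        assert nmi(out, lab) == pytest.approx(1.0)

    def test_majority_beats_outlier(self, rng):
        major = make_labeling([1, 1, 1, 2, 2, 2, 3, 3, 3])
        outlier = make_labeling(rng.integers(1, 4, size=9))
        out = select_consensus([major] * 9 + [outlier], K=3)
        assert nmi(out, major) == pytest.approx(1.0)
        # exhaustive candidate scoring: no candidate beats the majority
        cands = [major] * 9 + [outlier]
        scores = [np.mean([nmi(c, l) for l in cands]) for c in cands]
        assert np.argmax(scores) < 9

    def test_idempotent_up_to_relabeling(self, rng):
        labs = [make_labeling(rng.integers(1, 4, size=20)) for _ in range(5)]
        out = select_consensus(labs, K=3)
        again = select_consensus(labs + [out], K=3)
        assert nmi(out, again) >= 0.99

    def test_single_input(self):
        lab = make_labeling([1, 2, 1, 2])
        assert select_consensus([lab]) is lab

    def test_two_disagreeing_inputs_tie_goes_to_cspa(self):
        a = make_labeling([1, 1, 1, 2, 2, 2])
        b = make_labeling([1, 1, 2, 2, 1, 1])
        out = select_consensus([a, b], K=2)
        reference = cspa([a, b], K=2)
        assert nmi(out, reference) == pytest.approx(1.0)


class TestTrialLevelConsensus:
    def test_clean_planted_data_any_method_subset(self):
        data, truth = planted_epoch(n_per_phase=25, n_phases=3, seed=9)
        for methods in (["KM"], ["KM", "HC", "GMM"], ["MKM", "KMD"]):
            lab = consensus_within_trial(data, methods, 3, master_seed=1)
            assert nmi(lab, make_labeling(truth)) == pytest.approx(1.0)

    def test_deterministic_under_master_seed(self):
        data, _ = planted_epoch(noise=1.0, seed=10)
        l1 = consensus_within_trial(data, ["KM", "GMM", "SOM"], 3, 7, ("t",))
        l2 = consensus_within_trial(data, ["KM", "GMM", "SOM"], 3, 7, ("t",))
        assert np.array_equal(l1.labels, l2.labels)

    def test_across_trials_identical(self):
        lab = make_labeling([1, 1, 2, 2, 3])
        out = consensus_across_trials([lab] * 7, K=3)
        assert nmi(out, lab) == pytest.approx(1.0)

    def test_across_trials_jittered_boundaries(self, rng):
        # 3-segment structure with boundaries jittered by up to 3 samples
        outs = []
        for _ in range(20):
            b1 = 20 + rng.integers(-3, 4)
            b2 = 40 + rng.integers(-3, 4)
            labels = np.r_[np.ones(b1), 2 * np.ones(b2 - b1), 3 * np.ones(60 - b2)]
            outs.append(make_labeling(labels.astype(int)))
        cons = consensus_across_trials(outs, K=3)
        # consensus boundaries lie within the jitter span of the medians
        changes = np.flatnonzero(np.diff(cons.labels)) + 1
        assert len(changes) == 2
        assert abs(changes[0] - 20) <= 3 and abs(changes[1] - 40) <= 3

    def test_noise_trial_does_not_dominate(self, rng):
        structure = make_labeling(np.repeat([1, 2, 3], 20))
        noise = make_labeling(rng.integers(1, 4, size=60))
        cons = consensus_across_trials([structure] * 20 + [noise], K=3)
        assert nmi(cons, structure) >= nmi(noise, structure)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            consensus_across_trials([], K=3)
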