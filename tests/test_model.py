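"""Event grid, trajectory and likelihood core: oracles and invariances."""

import numpy as np
import pytest

from scipy.stats import norm

from zsustain.model import (
    EventGrid,
    EventSequence,
    NoiseModel,
    SubtypeModel,
    mixture_loglik,
    stage_likelihood_vector,
    stage_posteriors,
    subject_loglik,
    subject_logliks,
    trajectory_matrix,
    trajectory_value,
)

from conftest import enumerate_valid_orderings


class TestEventGrid:
    def test_event_count_and_order(self):
        g = EventGrid.create(["a", "b"], thresholds=((1.0, 2.0), (1.5,)), z_max=(3.0, 3.0))
        assert g.n_events == 3
        assert g.events == [(0, 0), (0, 1), (1, 0)]

    @pytest.mark.parametrize(
        "thresholds,z_max",
        [(((2.0, 1.0),), (3.0,)), (((1.0, 2.0),), (1.5,)), (((),), (3.0,))],
    )
    def test_invalid_grids_rejected(self, thresholds, z_max):
        with pytest.raises(ValueError):
            EventGrid(biomarkers=("a",), thresholds=thresholds, z_max=z_max)

    def test_sequence_must_respect_threshold_order(self):
        g = EventGrid.create(["a"], thresholds=(1.0, 2.0), z_max=3.0)
        with pytest.raises(ValueError):
            EventSequence([1, 0], g)  # z=2 event before z=1 event


class TestTrajectory:
    def test_zero_at_stage_zero_everywhere(self):
        g = EventGrid.create(["a", "b"], thresholds=(1.0, 2.0), z_max=4.0)
        seq = EventSequence([0, 2, 1, 3], g)
        assert np.all(trajectory_matrix(seq, g)[0] == 0.0)

    def test_hand_interpolated_value(self):
        # biomarker a: one event (z=1) at position 2 of N=4, z_max 3
        # value at t=3: 1 + (3-1)*(3-2)/(4-2) = 2
        g = EventGrid.create(["a", "b"], thresholds=((1.0,), (1.0, 2.0, 3.0)), z_max=(3.0, 5.0))
        seq = EventSequence([1, 0, 2, 3], g)
        assert trajectory_value(seq, g, 0, 3) == pytest.approx(2.0)

    def test_cap_rule_when_last_event_at_final_stage(self):
        # biomarker a's only event at position N: trajectory caps at its threshold
        g = EventGrid.create(["a", "b"], thresholds=((1.0,), (1.0, 2.0, 3.0)), z_max=(3.0, 5.0))
        seq = EventSequence([1, 2, 3, 0], g)
        assert trajectory_value(seq, g, 0, g.n_events) == pytest.approx(1.0)

    def test_monotone_in_stage(self):
        g = EventGrid.create(["a", "b", "c"], thresholds=(1.0, 2.5), z_max=4.0)
        rng = np.random.default_rng(0)
        for order in [next(enumerate_valid_orderings(g)) for _ in range(1)]:
            seq = EventSequence(order, g)
            tm = trajectory_matrix(seq, g)
            assert np.all(np.diff(tm, axis=0) >= -1e-12)

    def test_stage_out_of_range_rejected(self):
        g = EventGrid.create(["a"], thresholds=(1.0,), z_max=2.0)
        seq = EventSequence([0], g)
        with pytest.raises(ValueError):
            trajectory_value(seq, g, 0, 2)


class TestStageLikelihood:
    def test_argmax_at_generating_stage(self):
        g = EventGrid.create(["a", "b"], thresholds=(1.0, 2.0), z_max=4.0)
        seq = EventSequence([0, 2, 1, 3], g)
        noise = NoiseModel.default(2, 0.01)
        tm = trajectory_matrix(seq, g)
        for k in range(g.n_events + 1):
            vec = stage_likelihood_vector(tm[k], seq, g, noise)
            assert np.argmax(vec) == k

    def test_flat_limit_for_huge_noise(self):
        g = EventGrid.create(["a"], thresholds=(1.0, 2.0), z_max=4.0)
        seq = EventSequence([0, 1], g)
        vec = stage_likelihood_vector(np.array([1.3]), seq, g, NoiseModel.default(1, 1e4))
        assert np.ptp(vec / vec.max()) < 1e-6

    def test_two_biomarker_arithmetic_oracle(self):
        # 2 biomarkers, 1 threshold each, x = (1, 0): hand-computed Normal products
        g = EventGrid.create(["a", "b"], thresholds=(1.0,), z_max=(1.0, 1.0))
        seq = EventSequence([0, 1], g)  # a's event first
        x = np.array([1.0, 0.0])
        # linear anchors: a through (0,0),(1,1),(2,1); b through (0,0),(2,1)
        # so trajectories across stages 0..2 are a: (0,1,1); b: (0,0.5,1)
        expected = np.array(
            [
                norm.pdf(1.0, 0, 1) * norm.pdf(0.0, 0, 1),
                norm.pdf(1.0, 1, 1) * norm.pdf(0.0, 0.5, 1),
                norm.pdf(1.0, 1, 1) * norm.pdf(0.0, 1, 1),
            ]
        )
        got = stage_likelihood_vector(x, seq, g, NoiseModel.default(2))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        g = EventGrid.create(["a", "b"], thresholds=(1.0,), z_max=2.0)
        seq = EventSequence([0, 1], g)
        with pytest.raises(ValueError):
            stage_likelihood_vector(np.array([1.0]), seq, g, NoiseModel.default(2))


class TestSubjectLoglik:
    def test_closed_form_single_event(self):
        # N=1, x=0, sigma=1, threshold 1, z_max 1: log(0.5*(phi(0)+phi(1)))
        g = EventGrid.create(["a"], thresholds=(1.0,), z_max=1.0)
        seq = EventSequence([0], g)
        got = subject_loglik(np.array([0.0]), seq, g, NoiseModel.default(1))
        expected = np.log(0.5 * (norm.pdf(0.0) + norm.pdf(1.0)))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_stage_posterior_normalizes(self):
        g = EventGrid.create(["a", "b", "c"], thresholds=(1.0, 2.0), z_max=3.0)
        seq = EventSequence(next(enumerate_valid_orderings(g)), g)
        rng = np.random.default_rng(3)
        X = rng.normal(0, 2, (20, 3))
        post = stage_posteriors(X, seq, g, NoiseModel.default(3))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_extreme_values_stay_finite(self):
        g = EventGrid.create(["a"], thresholds=(1.0,), z_max=2.0)
        seq = EventSequence([0], g)
        ll = subject_loglik(np.array([1e4]), seq, g, NoiseModel.default(1))
        assert np.isfinite(ll)

    def test_relabeling_biomarkers_preserves_loglik(self):
        g = EventGrid.create(["a", "b", "c"], thresholds=(1.0, 2.0), z_max=4.0)
        order = next(enumerate_valid_orderings(g))
        seq = EventSequence(order, g)
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1.5, (10, 3))
        # permute biomarkers consistently: swap a <-> c
        perm = [2, 1, 0]
        g2 = EventGrid.create(
            [g.biomarkers[i] for i in perm],
            thresholds=[g.thresholds[i] for i in perm],
            z_max=[g.z_max[i] for i in perm],
        )
        bio, th_idx, _ = g.event_arrays()
        lookup2 = {e: k for k, e in enumerate(g2.events)}
        order2 = [lookup2[(perm.index(bio[e]), th_idx[e])] for e in order]
        seq2 = EventSequence(order2, g2)
        noise = NoiseModel.default(3)
        ll1 = subject_logliks(X, seq, g, noise)
        ll2 = subject_logliks(X[:, perm], seq2, g2, noise)
        assert ll1 == pytest.approx(ll2, abs=1e-10)


class TestMixture:
    def _model(self, fractions):
        g = EventGrid.create(["a", "b"], thresholds=(1.0, 2.0), z_max=4.0)
        s1 = EventSequence([0, 2, 1, 3], g)
        s2 = EventSequence([2, 0, 3, 1], g)
        return SubtypeModel(
            grid=g, sequences=[s1, s2], fractions=np.array(fractions), noise=NoiseModel.default(2)
        )

    def test_single_subtype_equals_sum_of_subject_logliks(self):
        m = self._model([1.0, 0.0])
        m1 = SubtypeModel(
            grid=m.grid, sequences=[m.sequences[0]], fractions=np.array([1.0]), noise=m.noise
        )
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (15, 2))
        expect = float(subject_logliks(X, m.sequences[0], m.grid, m.noise).sum())
        assert mixture_loglik(X, m1) == pytest.approx(expect, abs=1e-10)
        # degenerate fractions (1, 0) reduce to the same value regardless of S_2
        assert mixture_loglik(X, m) == pytest.approx(expect, abs=1e-10)

    def test_matches_brute_force_exponential_sum(self):
        m = self._model([0.3, 0.7])
        rng = np.random.default_rng(13)
        X = rng.normal(0, 1, (2, 2))
        total = 0.0
        for x in X:
            lik = sum(
                f * np.exp(subject_loglik(x, s, m.grid, m.noise))
                for f, s in zip(m.fractions, m.sequences)
            )
            total += np.log(lik)
        assert mixture_loglik(X, m) == pytest.approx(total, abs=1e-9)

    def test_subtype_permutation_invariance(self):
        m = self._model([0.3, 0.7])
        m_perm = SubtypeModel(
            grid=m.grid,
            sequences=[m.sequences[1], m.sequences[0]],
            fractions=np.array([0.7, 0.3]),
            noise=m.noise,
        )
        rng = np.random.default_rng(17)
        X = rng.normal(0, 1, (8, 2))
        assert mixture_loglik(X, m) == pytest.approx(mixture_loglik(X, m_perm), abs=1e-10)

    def test_unnormalized_fractions_rejected(self):
        with pytest.raises(ValueError):
            self._model([0.5, 0.6])

    def test_serialization_roundtrip(self, tmp_path):
        m = self._model([0.3, 0.7])
        path = tmp_path / "model.json"
        m.save(path)
        m2 = SubtypeModel.load(path)
        assert [s.order.tolist() for s in m2.sequences] == [s.order.tolist() for s in m.sequences]
        assert np.allclose(m2.fractions, m.fractions)
        assert m2.grid.biomarkers == m.grid.biomarkers


def test_noise_free_data_identifies_true_sequence_exhaustively():
    """Over all valid orderings of a small grid, the generating one maximizes loglik."""
    g = EventGrid.create(["a", "b"], thresholds=((1.0, 2.0), (1.5,)), z_max=(3.0, 3.0))
    true = EventSequence([0, 2, 1], g)
    tm = trajectory_matrix(true, g)
    X = tm[np.arange(g.n_events + 1)]  # one noise-free subject per stage
    noise = NoiseModel.default(2, 0.3)
    lls = {}
    for order in enumerate_valid_orderings(g):
        seq = EventSequence(order, g)
        lls[tuple(order)] = float(subject_logliks(X, seq, g, noise).sum())
    assert max(lls, key=lls.get) == tuple(true.order)
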