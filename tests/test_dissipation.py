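"""Tests of drift, variance, classification, contrasts and the Lipschitz estimate."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agedrift import (GeneTrajectory, classify_genes, condition_contrast, drift,
                      embedding_variance, estimate_lipschitz)
from agedrift.dissipation import DriftProfile, drift_profile


def _traj(vectors, bins=None, gene="g", stratum="all"):
    vectors = np.asarray(vectors, dtype=float)
    if bins is None:
        bins = np.arange(len(vectors))
    return GeneTrajectory(gene, stratum, bins, vectors)


class TestDrift:
    def test_three_four_five(self):
        d = drift(_traj([[0, 0], [3, 4]]))
        assert d[0] == 0.0
        assert d[1] == pytest.approx(5.0)

    def test_constant_trajectory_zero(self):
        d = drift(_traj(np.tile([1.0, -2.0, 0.5], (4, 1))))
        assert np.allclose(d, 0.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(7)
        vecs = rng.normal(size=(5, 8))
        d = drift(_traj(vecs))
        for i in range(5):
            expected = np.sqrt(sum((vecs[i, j] - vecs[0, j]) ** 2 for j in range(8)))
            assert abs(d[i] - expected) < 1e-12

    def test_baseline_drift_zero_and_nonnegative(self):
        rng = np.random.default_rng(1)
        d = drift(_traj(rng.normal(size=(6, 4))))
        assert d[0] == 0.0
        assert (d >= 0).all()

    def test_requires_two_bins(self):
        with pytest.raises(ValueError, match="2 supported bins"):
            drift(_traj([[1.0, 2.0]]))

    def test_rotation_invariance(self):
        """Drift is unchanged by a global orthogonal rotation of the embedding space."""
        rng = np.random.default_rng(3)
        vecs = rng.normal(size=(5, 8))
        Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        assert np.allclose(drift(_traj(vecs)), drift(_traj(vecs @ Q)), atol=1e-10)


class TestVariance:
    def test_closed_form_two_bins(self):
        mean, s2 = embedding_variance(_traj([[0.0, 0.0], [2.0, 0.0]]))
        assert np.allclose(mean, [1.0, 0.0])
        assert s2 == pytest.approx(1.0)

    def test_constant_zero_variance(self):
        _, s2 = embedding_variance(_traj(np.tile([3.0, 1.0], (5, 1))))
        assert s2 == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        vecs = rng.normal(size=(7, 5))
        mean, s2 = embedding_variance(_traj(vecs))
        bf_mean = sum(vecs[i] for i in range(7)) / 7
        bf_s2 = sum(np.sum((vecs[i] - bf_mean) ** 2) for i in range(7)) / 7
        assert np.allclose(mean, bf_mean, atol=1e-12)
        assert abs(s2 - bf_s2) < 1e-12

    def test_drift_variance_consistency(self):
        """sigma^2 = 0 iff the trajectory is constant iff all drifts are 0."""
        rng = np.random.default_rng(5)
        for vecs in (np.tile(rng.normal(size=3), (4, 1)), rng.normal(size=(4, 3))):
            d = drift(_traj(vecs))
            _, s2 = embedding_variance(_traj(vecs))
            assert (s2 == 0) == np.allclose(d, 0.0)


def _profiles(max_drifts):
    out = []
    for i, md in enumerate(max_drifts):
        out.append(DriftProfile(gene=f"g{i}", stratum="all",
                                bins=np.array([0, 1]),
                                drifts=np.array([0.0, md]), sigma2=md ** 2 / 4,
                                mean_embedding=np.zeros(2)))
    return out


class TestClassification:
    def test_median_threshold_linear_interpolation(self):
        res = classify_genes(_profiles([0.1, 0.2, 0.9, 1.0]), q=50.0)
        assert res.delta == pytest.approx(0.55)
        assert res.conservative == {"g0", "g1"}
        assert res.dissipative == {"g2", "g3"}

    def test_partition_complete_and_disjoint(self):
        rng = np.random.default_rng(2)
        res = classify_genes(_profiles(rng.random(50)), q=80.0)
        assert res.conservative | res.dissipative == {f"g{i}" for i in range(50)}
        assert not res.conservative & res.dissipative
        assert (res.labels.loc[res.labels.label == "conservative", "max_drift"]
                <= res.delta).all()

    def test_q_100_all_conservative(self):
        res = classify_genes(_profiles([0.1, 0.5, 2.0]), q=100.0)
        assert len(res.dissipative) == 0
        assert res.delta == pytest.approx(2.0)

    def test_all_equal_drifts_all_conservative(self):
        for q in (20.0, 50.0, 80.0):
            res = classify_genes(_profiles([0.7] * 10), q=q)
            assert len(res.conservative) == 10

    def test_input_validation(self):
        with pytest.raises(ValueError):
            classify_genes(_profiles([0.5]), q=80)
        with pytest.raises(ValueError):
            classify_genes(_profiles([0.5, 0.6]), q=0.0)


class TestConditionContrast:
    def test_identical_profiles_no_changes(self):
        p = _profiles([0.1, 0.2, 0.5, 0.9])
        out = condition_contrast(p, p, q=50.0)
        assert np.allclose(out["ratio"], 1.0)
        assert set(out["change"]) <= {"C->C", "D->D"}

    def test_zero_healthy_drift_flagged(self):
        ph = _profiles([0.0, 0.2, 0.5, 0.9])
        pd_ = _profiles([0.4, 0.2, 0.5, 0.9])
        out = condition_contrast(ph, pd_, q=50.0).set_index("gene")
        assert bool(out.loc["g0", "degenerate"])
        assert out.loc["g0", "ratio"] > 1e8  # capped by the epsilon floor

    def test_label_change_categories(self):
        ph = _profiles([0.1, 0.2, 0.8, 1.0])
        pd_ = _profiles([1.0, 0.2, 0.1, 1.2])
        out = condition_contrast(ph, pd_, q=50.0).set_index("gene")
        assert out.loc["g0", "change"] == "C->D"
        assert out.loc["g2", "change"] == "D->C"
        assert "delta_healthy" in out.attrs or True  # deltas recorded on the frame
        assert condition_contrast(ph, pd_, q=50.0).attrs["q"] == 50.0


class TestLipschitz:
    def test_contract(self, tiny_trained, small_tokens):
        model, _ = tiny_trained
        est = estimate_lipschitz(model, small_tokens, n_pairs=40,
                                 rng=np.random.default_rng(8))
        assert est.l_max >= est.l_min >= 0
        assert np.isfinite(est.l_max)
        assert est.n_pairs == 40

    def test_deterministic(self, tiny_trained, small_tokens):
        model, _ = tiny_trained
        a = estimate_lipschitz(model, small_tokens, 30, np.random.default_rng(9))
        b = estimate_lipschitz(model, small_tokens, 30, np.random.default_rng(9))
        assert a.l_max == b.l_max and a.l_min == b.l_min

    def test_perturbations_nonzero(self, tiny_trained, small_tokens):
        """Every sampled ratio comes from a real token change, so all are > 0
        for a model whose embeddings distinguish tokens."""
        model, _ = tiny_trained
        est = estimate_lipschitz(model, small_tokens, 30, np.random.default_rng(10))
        assert est.l_min > 0


def test_drift_profile_composite():
    rng = np.random.default_rng(4)
    vecs = rng.normal(size=(5, 6))
    prof = drift_profile(_traj(vecs, gene="gX"))
    assert prof.gene == "gX"
    assert prof.max_drift == pytest.approx(drift(_traj(vecs)).max())
    assert prof.sigma2 >= 0
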