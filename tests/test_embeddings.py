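"""Tests of trajectory aggregation and cosine-similarity analyses."""

import numpy as np
import pandas as pd
import pytest

from agedrift import (GeneTrajectory, age_token_trajectory, cosine_similarity,
                      gene_age_embeddings, gene_age_similarity_trajectory,
                      token_similarity_ranking)
from agedrift.embeddings import binned_position_means, select_stratum
from agedrift.mlm import contextual_embeddings
from agedrift.tokenizer import N_META_POSITIONS


class TestCosine:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0), (0, 1), 0.0),
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 1), (1, 0), 1 / np.sqrt(2)),
            ((1, 0), (-1, 0), -1.0),
        ],
    )
    def test_closed_forms(self, u, v, expected):
        assert cosine_similarity(np.array(u), np.array(v)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestTrajectories:
    def test_identical_cells_give_their_vector(self, tiny_trained, small_tokens,
                                               small_study):
        """Mean over identical token sequences equals a single cell's embedding."""
        model, _ = tiny_trained
        tokens = np.repeat(small_tokens[:1], 5, axis=0)
        bins = np.zeros(5, dtype=int)
        trajs = gene_age_embeddings(model, tokens, bins, small_study.gene_ids,
                                    min_cells=5)
        single = contextual_embeddings(model, small_tokens[0])
        g0 = trajs[small_study.gene_ids[0]]
        assert g0.bins.tolist() == [0]
        assert np.allclose(g0.vectors[0], single[N_META_POSITIONS], atol=1e-5)

    def test_min_cells_enforced(self, tiny_trained, small_tokens, small_study):
        model, _ = tiny_trained
        bins = small_study.cell_meta["age_bin"].to_numpy()[:30]
        with pytest.raises(ValueError, match="min_cells"):
            gene_age_embeddings(model, small_tokens[:30], bins,
                                small_study.gene_ids, min_cells=10**6)

    def test_cell_order_invariance(self, tiny_trained, small_tokens, small_study):
        model, _ = tiny_trained
        bins = small_study.cell_meta["age_bin"].to_numpy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(bins))
        a = gene_age_embeddings(model, small_tokens, bins, small_study.gene_ids,
                                min_cells=5)
        b = gene_age_embeddings(model, small_tokens[perm], bins[perm],
                                small_study.gene_ids, min_cells=5)
        g = small_study.gene_ids[3]
        assert np.allclose(a[g].vectors, b[g].vectors, atol=1e-4)

    def test_unsupported_bins_absent_not_zero(self, tiny_trained, small_tokens,
                                              small_study):
        model, _ = tiny_trained
        bins = small_study.cell_meta["age_bin"].to_numpy()
        counts = np.bincount(bins)
        thresh = int(counts.max())  # only the largest bin survives
        trajs = gene_age_embeddings(model, small_tokens, bins,
                                    small_study.gene_ids, min_cells=thresh)
        g = trajs[small_study.gene_ids[0]]
        assert g.n_bins == (counts >= thresh).sum()

    def test_mean_norm_bounded_by_max_cell_norm(self, tiny_trained, small_tokens,
                                                small_study):
        model, _ = tiny_trained
        bins = small_study.cell_meta["age_bin"].to_numpy()
        sel = bins == 0
        emb = contextual_embeddings(model, small_tokens[sel])
        trajs = gene_age_embeddings(model, small_tokens[sel], bins[sel],
                                    small_study.gene_ids, min_cells=2)
        for g_idx in (0, 5):
            tr = trajs[small_study.gene_ids[g_idx]]
            cell_norms = np.linalg.norm(emb[:, N_META_POSITIONS + g_idx, :], axis=1)
            assert np.linalg.norm(tr.vectors[0]) <= cell_norms.max() + 1e-6

    def test_age_trajectory_uses_position_zero(self, tiny_trained, small_tokens,
                                               small_study):
        model, _ = tiny_trained
        bins = small_study.cell_meta["age_bin"].to_numpy()
        pre = binned_position_means(model, small_tokens, bins)
        ages = age_token_trajectory(model, small_tokens, bins, min_cells=5,
                                    _precomputed=pre)
        assert np.allclose(ages.vectors, pre[1][pre[2] >= 5][:, 0, :])


class TestSimilarity:
    def test_ranking_scores_in_range_and_sorted(self, tiny_trained):
        model, _ = tiny_trained
        for cat in ("tissue", "cell_type"):
            df = token_similarity_ranking(model, cat)
            assert df["score"].between(-1, 1).all()
            assert (df["score"].diff().dropna() <= 1e-12).all()
            assert df["rank"].tolist() == list(range(1, len(df) + 1))

    def test_tied_scores_stable_by_token_id(self, tiny_trained, small_vocab):
        model, _ = tiny_trained
        # force both tissue embeddings identical -> tie broken by token id
        ids = small_vocab.tissue_token_ids
        model.net.params.data["tok_emb"][ids[1]] = \
            model.net.params.data["tok_emb"][ids[0]]
        df = token_similarity_ranking(model, "tissue")
        assert df["token_id"].tolist() == sorted(df["token_id"].tolist())
        model.net.params.data["tok_emb"][ids[1]] += 0.01  # restore non-tie

    def test_unknown_category_rejected(self, tiny_trained):
        with pytest.raises(ValueError):
            token_similarity_ranking(tiny_trained[0], "organ")


class TestGeneAgeCurve:
    def test_identical_trajectories_curve_one(self):
        vecs = np.tile(np.array([1.0, 2.0, 0.5]), (4, 1))
        tr = GeneTrajectory("g", "all", np.arange(4), vecs)
        ages = GeneTrajectory("<age>", "all", np.arange(4), vecs)
        curve = gene_age_similarity_trajectory(tr, ages)
        assert np.allclose(curve["cosine"], 1.0)

    def test_orthogonal_curve_zero(self):
        tr = GeneTrajectory("g", "all", np.arange(3),
                            np.tile([1.0, 0.0], (3, 1)))
        ages = GeneTrajectory("<age>", "all", np.arange(3),
                              np.tile([0.0, 1.0], (3, 1)))
        curve = gene_age_similarity_trajectory(tr, ages)
        assert np.allclose(curve["cosine"], 0.0)

    def test_restricted_to_common_bins(self):
        tr = GeneTrajectory("g", "all", np.array([0, 1, 2]),
                            np.ones((3, 2)))
        ages = GeneTrajectory("<age>", "all", np.array([1, 2, 3]),
                              np.ones((3, 2)))
        curve = gene_age_similarity_trajectory(tr, ages)
        assert curve["age_bin"].tolist() == [1, 2]


def test_stratum_selector(small_study):
    meta = small_study.cell_meta
    sel_h = select_stratum(meta, disease=0)
    sel_d = select_stratum(meta, disease=1)
    assert not (sel_h & sel_d).any()
    assert (sel_h | sel_d).all()
    sel_t0 = select_stratum(meta, tissue=0, disease=1)
    assert (meta.loc[sel_t0, "tissue"] == 0).all()
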