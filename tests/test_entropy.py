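"""Tests of masked-token Shannon entropy and its age/disease aggregation."""

import numpy as np
import pandas as pd
import pytest

from agedrift import entropy_by_age, masked_entropy_profile, token_entropy
from agedrift.entropy import reconstruction_entropy_profile


class TestTokenEntropy:
    def test_uniform_is_ln_k(self):
        assert token_entropy(np.full(4, 0.25)) == pytest.approx(np.log(4))

    def test_one_hot_is_zero(self):
        d = np.zeros(8)
        d[3] = 1.0
        assert token_entropy(d) == 0.0

    def test_direct_summation_example(self):
        p = np.array([0.5, 0.25, 0.25])
        expected = -sum(x * np.log(x) for x in p)  # 1.0397...
        assert token_entropy(p) == pytest.approx(expected)
        assert token_entropy(p) == pytest.approx(1.0397, abs=1e-4)

    def test_bits_option(self):
        assert token_entropy(np.full(8, 0.125), base="bits") == pytest.approx(3.0)

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            token_entropy(np.array([0.5, 0.6]))
        with pytest.raises(ValueError, match="non-negative"):
            token_entropy(np.array([1.5, -0.5]))

    @pytest.mark.parametrize("n", [2, 5, 30])
    def test_bounds(self, n):
        rng = np.random.default_rng(n)
        p = rng.dirichlet(np.ones(n))
        assert 0.0 <= token_entropy(p) <= np.log(n) + 1e-12


class TestProfile:
    def test_zero_genes_per_cell_empty(self, tiny_trained, small_tokens, small_study):
        model, _ = tiny_trained
        out = masked_entropy_profile(model, small_tokens[:5],
                                     small_study.cell_meta.iloc[:5],
                                     np.random.default_rng(0), genes_per_cell=0)
        assert len(out) == 0

    def test_too_many_positions_rejected(self, tiny_trained, small_tokens,
                                         small_study):
        model, _ = tiny_trained
        with pytest.raises(ValueError, match="exceeds"):
            masked_entropy_profile(model, small_tokens[:2],
                                   small_study.cell_meta.iloc[:2],
                                   np.random.default_rng(0), genes_per_cell=10**4)

    def test_records_bounded_and_deterministic(self, tiny_trained, small_tokens,
                                               small_study, small_vocab):
        model, _ = tiny_trained
        args = (model, small_tokens[:10], small_study.cell_meta.iloc[:10])
        a = masked_entropy_profile(*args, np.random.default_rng(1), genes_per_cell=4)
        b = masked_entropy_profile(*args, np.random.default_rng(1), genes_per_cell=4)
        assert len(a) == 40
        assert a["H_nats"].between(0, np.log(small_vocab.k)).all()
        pd.testing.assert_frame_equal(a, b)

    def test_age_conditioning_masks_age(self, tiny_trained, small_tokens,
                                        small_study):
        """Unconditioned scoring must differ from age-conditioned scoring."""
        model, _ = tiny_trained
        args = (model, small_tokens[:20], small_study.cell_meta.iloc[:20])
        with_age = masked_entropy_profile(*args, np.random.default_rng(2),
                                          genes_per_cell=6, condition_on_age=True)
        without = masked_entropy_profile(*args, np.random.default_rng(2),
                                         genes_per_cell=6, condition_on_age=False)
        assert not np.allclose(with_age["H_nats"], without["H_nats"])

    def test_metadata_target(self, tiny_trained, small_tokens, small_study,
                             small_vocab):
        model, _ = tiny_trained
        out = masked_entropy_profile(model, small_tokens[:6],
                                     small_study.cell_meta.iloc[:6],
                                     np.random.default_rng(3), target="tissue")
        assert (out["position"] == 1).all()
        assert out["H_nats"].between(0, np.log(small_vocab.k)).all()

    def test_category_restriction_smaller_support(self, tiny_trained, small_tokens,
                                                  small_study, small_vocab):
        model, _ = tiny_trained
        out = masked_entropy_profile(model, small_tokens[:6],
                                     small_study.cell_meta.iloc[:6],
                                     np.random.default_rng(4), target="tissue",
                                     restrict_to_category=True)
        assert out["H_nats"].between(0, np.log(small_vocab.n_tissues)).all()


class TestReconstructionProfile:
    def test_records_per_draw_and_bounds(self, tiny_trained, small_tokens,
                                         small_study, small_vocab):
        model, _ = tiny_trained
        n_genes = small_tokens.shape[1] - 4
        out = reconstruction_entropy_profile(
            model, small_tokens[:6], small_study.cell_meta.iloc[:6],
            np.random.default_rng(0), n_draws=2)
        assert len(out) == 2 * 6 * round(0.85 * n_genes)
        assert out["H_nats"].between(0, np.log(small_vocab.k)).all()
        assert (out["position"] >= 4).all()

    def test_deterministic_and_age_flag(self, tiny_trained, small_tokens,
                                        small_study):
        model, _ = tiny_trained
        args = (model, small_tokens[:5], small_study.cell_meta.iloc[:5])
        a = reconstruction_entropy_profile(*args, np.random.default_rng(3))
        b = reconstruction_entropy_profile(*args, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)
        c = reconstruction_entropy_profile(*args, np.random.default_rng(3),
                                           condition_on_age=False)
        assert not np.allclose(a["H_nats"], c["H_nats"])


class TestByAge:
    def _records(self, h_values, bins, disease=None):
        n = len(h_values)
        return pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n)],
            "position": 5, "target_category": "genes",
            "H_nats": h_values, "age_bin": bins,
            "tissue": 0, "disease": disease if disease is not None else 0,
            "conditioned_on_age": True,
        })

    def test_constant_records_spearman_not_applicable(self):
        table = entropy_by_age(self._records([1.0] * 9, [0, 0, 0, 1, 1, 1, 2, 2, 2]))
        assert table.attrs["spearman"][0] is None
        assert np.allclose(table["mean"], 1.0)

    def test_linear_increase_rho_one(self):
        bins = np.repeat(np.arange(5), 3)
        table = entropy_by_age(self._records(bins * 0.1 + 1.0, bins))
        assert table.attrs["spearman"][0] == pytest.approx(1.0)

    def test_disease_split_keys(self):
        bins = np.repeat(np.arange(3), 4)
        dz = np.tile([0, 1], 6)
        table = entropy_by_age(self._records(np.linspace(1, 2, 12), bins, dz))
        assert set(map(tuple, table[["age_bin", "disease"]].to_numpy())) == {
            (b, d) for b in range(3) for d in (0, 1)
        }

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy_by_age(self._records([], []))
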