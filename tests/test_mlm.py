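"""Tests of the transformer MLM: gradients, training contract, prediction contract."""

import numpy as np
import pytest

from agedrift import (ModelConfig, contextual_embeddings, init_model, load_model,
                      predict_masked, save_model, token_embedding, train)
from agedrift.nn import Adam, Transformer, cross_entropy_grads, softmax
from agedrift.tokenizer import AGE_POS, N_META_POSITIONS, mask_batch


def test_invalid_head_split_rejected():
    with pytest.raises(ValueError):
        ModelConfig(d=30, n_heads=4)
    with pytest.raises(ValueError):
        Transformer(k=10, seq_len=8, d=30, n_layers=1, n_heads=4, d_ff=16)


def test_seeded_init_reproducible(small_vocab, small_tokens, tiny_model_config):
    a = init_model(small_vocab, small_tokens.shape[1], tiny_model_config)
    b = init_model(small_vocab, small_tokens.shape[1], tiny_model_config)
    assert a.net.params.allclose(b.net.params, rtol=0, atol=0)


def test_untrained_predictions_near_uniform(small_vocab, small_tokens,
                                            tiny_model_config):
    """With near-zero init logits, masked-token entropy is close to ln k."""
    model = init_model(small_vocab, small_tokens.shape[1], tiny_model_config)
    mask = np.zeros(small_tokens.shape[1], bool)
    mask[N_META_POSITIONS + 2] = True
    toks = small_tokens[0].copy()
    toks[mask] = small_vocab.mask_id
    [(pos, dist)] = predict_masked(model, toks, mask)
    h = -np.sum(dist * np.log(dist))
    assert abs(h - np.log(small_vocab.k)) < 0.05


def test_gradients_match_finite_differences(monkeypatch):
    """Backprop agrees with central finite differences on a tiny model."""
    import agedrift.nn as nn_mod

    monkeypatch.setattr(nn_mod, "DTYPE", np.float64)  # full precision for the check
    rng = np.random.default_rng(0)
    net = Transformer(k=9, seq_len=6, d=8, n_layers=2, n_heads=2, d_ff=12, seed=5)
    tokens = rng.integers(0, 9, size=(3, 6))
    targets = rng.integers(0, 9, size=(3, 6))
    mask = rng.random((3, 6)) < 0.5
    mask[0, 0] = True  # ensure at least one masked position
    _, grads = net.loss_and_grads(tokens, targets, mask, train=False)
    eps = 1e-5
    for name in ["tok_emb", "pos_emb", "l0.q.W", "l0.kk.W", "l0.v.W", "l0.o.W",
                 "l1.ff1.W", "l1.ff2.b", "l0.ln1.g", "l1.ln2.b", "head.W", "head.b"]:
        p = net.params.data[name]
        flat_idx = [0, p.size // 2, p.size - 1]
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = net.loss_and_grads(tokens, targets, mask, train=False)
            p[idx] = orig - eps
            lm, _ = net.loss_and_grads(tokens, targets, mask, train=False)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[name][idx]
            assert num == pytest.approx(ana, rel=2e-3, abs=1e-7), (name, idx)


def test_zero_epochs_identity(small_vocab, small_tokens, tiny_model_config):
    import dataclasses

    cfg = dataclasses.replace(tiny_model_config, epochs=0)
    model = init_model(small_vocab, small_tokens.shape[1], cfg)
    before = model.net.params.copy()
    model, trace = train(model, small_tokens, cfg)
    assert model.net.params.allclose(before, rtol=0, atol=0)
    assert len(trace) == 0


def test_training_beats_uniform_baseline(tiny_trained, small_vocab):
    """Held-out masked-token cross-entropy drops below the ln k uniform baseline."""
    _, trace = tiny_trained
    assert trace["val_loss"].iloc[-1] < np.log(small_vocab.k)
    assert trace["train_loss"].iloc[-1] < trace["train_loss"].iloc[0]


def test_training_deterministic(small_vocab, small_tokens, tiny_model_config):
    runs = []
    for _ in range(2):
        model = init_model(small_vocab, small_tokens.shape[1], tiny_model_config)
        _, trace = train(model, small_tokens, tiny_model_config)
        runs.append(trace["train_loss"].iloc[-1])
    assert abs(runs[0] - runs[1]) < 1e-6


def test_contextual_embeddings_contract(tiny_trained, small_tokens):
    model, _ = tiny_trained
    emb = contextual_embeddings(model, small_tokens[0])
    assert emb.shape == (small_tokens.shape[1], model.d)
    assert np.isfinite(emb).all()
    # identical cells give identical matrices
    emb2 = contextual_embeddings(model, small_tokens[0])
    assert np.allclose(emb, emb2)


def test_age_token_changes_gene_embeddings(tiny_trained, small_tokens, small_vocab):
    """Contextual gene vectors respond to the age context, not just their own token."""
    model, _ = tiny_trained
    seq = small_tokens[0].copy()
    other_age = (seq[AGE_POS] - small_vocab.age_offset + 1) % small_vocab.n_age_bins
    seq2 = seq.copy()
    seq2[AGE_POS] = small_vocab.age_token(other_age)
    e1 = contextual_embeddings(model, seq)[N_META_POSITIONS:]
    e2 = contextual_embeddings(model, seq2)[N_META_POSITIONS:]
    assert np.linalg.norm(e1 - e2, axis=1).max() > 0


def test_predict_masked_distributions_normalized(tiny_trained, small_tokens,
                                                 small_vocab):
    model, _ = tiny_trained
    rng = np.random.default_rng(5)
    mb = mask_batch(small_tokens[:1], small_vocab, rng)
    out = predict_masked(model, mb.tokens[0], mb.mask[0])
    assert len(out) == mb.mask[0].sum()
    for pos, dist in out:
        assert dist.shape == (small_vocab.k,)
        assert (dist >= 0).all()
        assert abs(dist.sum() - 1.0) < 1e-6


def test_predict_masked_empty(tiny_trained, small_tokens):
    model, _ = tiny_trained
    assert predict_masked(model, small_tokens[0],
                          np.zeros(small_tokens.shape[1], bool)) == []


def test_token_embedding_contract(tiny_trained, small_vocab):
    model, _ = tiny_trained
    v = token_embedding(model, 0)
    assert v.shape == (model.d,)
    assert np.allclose(v, model.net.params.data["tok_emb"][0])
    with pytest.raises(ValueError):
        token_embedding(model, small_vocab.k)


def test_divergence_aborts(small_vocab, small_tokens):
    """A non-finite loss aborts training with a diagnostic."""
    cfg = ModelConfig(d=16, n_layers=1, n_heads=2, d_ff=32, epochs=1,
                      batch_size=32, seed=0)
    model = init_model(small_vocab, small_tokens.shape[1], cfg)
    model.net.params.data["head.b"][:] = np.nan
    with pytest.raises(RuntimeError, match="diverged"):
        train(model, small_tokens, cfg)


def test_checkpoint_round_trip(tmp_path, tiny_trained, small_tokens):
    model, _ = tiny_trained
    save_model(model, tmp_path / "ckpt")
    back = load_model(tmp_path / "ckpt")
    assert back.net.params.allclose(model.net.params, rtol=0, atol=0)
    assert np.allclose(contextual_embeddings(back, small_tokens[0]),
                       contextual_embeddings(model, small_tokens[0]))


def test_missing_checkpoint_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_model(tmp_path / "nope")


def test_cross_entropy_uniform_loss():
    logits = np.zeros((2, 3, 7))
    targets = np.ones((2, 3), dtype=int)
    mask = np.ones((2, 3), bool)
    loss, dl = cross_entropy_grads(logits, targets, mask)
    assert loss == pytest.approx(np.log(7))
    assert dl.shape == logits.shape
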