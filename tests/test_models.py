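"""Forward-pass contracts: an independent scalar evaluation of the gate,
convolution and attention formulas is the oracle for every architecture."""

import math

import numpy as np
import pytest

import doctriage as dt
from doctriage.features import FeaturizedDocument, Vocabulary
from doctriage.nn import autodiff as ad
from doctriage.nn.checkpoint import (
    load_checkpoint,
    load_ppi_module,
    save_checkpoint,
    save_ppi_module,
)
from doctriage.nn.models import Arch, ModelConfig, PpiMode, PpiModule, PredictionRecord, TriageModel

# ---------------------------------------------------------------------------
# scalar (pure-Python) evaluation helpers — the independent route


def _mv(x, W):
    return [sum(x[i] * W[i][j] for i in range(len(x))) for j in range(len(W[0]))]


def _vadd(*vs):
    return [sum(t) for t in zip(*vs)]


def _sig(v):
    return [1.0 / (1.0 + math.exp(-a)) for a in v]


def _vtanh(v):
    return [math.tanh(a) for a in v]


def _emul(a, b):
    return [x * y for x, y in zip(a, b)]


def _relu(v):
    return [max(0.0, a) for a in v]


def _softmax2(v):
    m = max(v)
    e = [math.exp(a - m) for a in v]
    z = sum(e)
    return [a / z for a in e]


def _lstm_params(p):
    return {k: getattr(p, k).data.tolist() for k in
            ("W_i", "U_i", "b_i", "W_f", "U_f", "b_f", "W_c", "U_c", "b_c",
             "W_o", "U_o", "V_o", "b_o")}


def _scalar_lstm(xs, P, reverse=False):
    H = len(P["b_i"])
    h, c = [0.0] * H, [0.0] * H
    out = {}
    order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    for t in order:
        x = xs[t]
        i = _sig(_vadd(_mv(x, P["W_i"]), _mv(h, P["U_i"]), P["b_i"]))
        f = _sig(_vadd(_mv(x, P["W_f"]), _mv(h, P["U_f"]), P["b_f"]))
        g = _vtanh(_vadd(_mv(x, P["W_c"]), _mv(h, P["U_c"]), P["b_c"]))
        c = _vadd(_emul(f, c), _emul(i, g))
        o = _sig(_vadd(_mv(x, P["W_o"]), _mv(h, P["U_o"]), _mv(c, P["V_o"]), P["b_o"]))
        h = _emul(o, _vtanh(c))
        out[t] = h
    return [out[t] for t in range(len(xs))]


def _scalar_conv(xs, P):
    W, b, k = P.W.data.tolist(), P.b.data.tolist(), P.k
    dim = len(xs[0])
    left = (k - 1) // 2
    zero = [0.0] * dim
    padded = [zero] * left + xs + [zero] * (k - 1 - left)
    out = []
    for t in range(len(xs)):
        window = [v for step in padded[t : t + k] for v in step]
        out.append(_relu(_vadd(_mv(window, W), b)))
    return out


def _scalar_maxpool(steps):
    return [max(col) for col in zip(*steps)]


def _embed(model, ids):
    return [model.word_emb.data[i].tolist() for i in ids]


def _scalar_forward(model: TriageModel, ids, sentences=None):
    """Pure-Python forward of a single unpadded document."""
    c = model.config
    if c.arch is Arch.HIELSTM:
        P = _lstm_params(model.lstm)
        svecs = [
            _scalar_maxpool(_scalar_lstm(_embed(model, sent), P))
            for sent in sentences
        ]
        sf = _scalar_lstm(svecs, _lstm_params(model.sent_fwd))
        sb = _scalar_lstm(svecs, _lstm_params(model.sent_bwd), reverse=True)
        rep = sf[-1] + sb[0]
    else:
        xs = _embed(model, ids)
        if c.arch is Arch.LSTM:
            rep = _scalar_maxpool(_scalar_lstm(xs, _lstm_params(model.lstm)))
        elif c.arch is Arch.CNN:
            pooled = _scalar_maxpool(_scalar_conv(_scalar_conv(xs, model.conv1), model.conv2))
            rep = _vtanh(_vadd(_mv(pooled, model.W_fc.data.tolist()), model.b_fc.data.tolist()))
        elif c.arch is Arch.LSTM_CNN:
            hf = _scalar_lstm(xs, _lstm_params(model.lstm))
            hb = _scalar_lstm(xs, _lstm_params(model.lstm_bwd), reverse=True)
            ys = [_vtanh(f + b) for f, b in zip(hf, hb)]
            pooled = _scalar_maxpool(_scalar_conv(ys, model.conv1))
            rep = _vtanh(_vadd(_mv(pooled, model.W_fc.data.tolist()), model.b_fc.data.tolist()))
        elif c.arch is Arch.RCNN:
            hf = _scalar_lstm(xs, _lstm_params(model.lstm))
            hb = _scalar_lstm(xs, _lstm_params(model.lstm_bwd), reverse=True)
            zero = [0.0] * c.hidden
            ys = []
            for t in range(len(xs)):
                left = hf[t - 1] if t > 0 else zero
                right = hb[t + 1] if t + 1 < len(xs) else zero
                ys.append(_vtanh(left + xs[t] + right))
            rep = _scalar_maxpool(ys)
    logits = _vadd(_mv(rep, model.W_cls.data.tolist()), model.b_cls.data.tolist())
    return rep, _softmax2(logits)


def _vocab(n=8) -> Vocabulary:
    return Vocabulary.from_tokens([f"tok{i}" for i in range(n)])


def _cfg(arch, seed=0):
    return ModelConfig(arch=arch, hidden=3, filters=3, fc_dim=3, word_dim=4, seed=seed)


@pytest.mark.parametrize("arch", list(Arch))
def test_forward_matches_scalar_oracle(arch):
    model = TriageModel(_cfg(arch, seed=13), _vocab())
    ids = [2, 5, 3]
    sentences = [[2, 5], [3]]
    fdoc = FeaturizedDocument(
        "d", [[2, 5], [3]] if arch is Arch.HIELSTM else [ids], label=1
    )
    rep, logits = model.forward([fdoc])
    probs = ad.softmax(logits.data)[0]
    rep_exp, probs_exp = _scalar_forward(model, ids, sentences)
    np.testing.assert_allclose(rep.data[0], rep_exp, atol=1e-10)
    np.testing.assert_allclose(probs, probs_exp, atol=1e-10)


def test_ppi_module_matches_scalar_oracle():
    module = PpiModule(_vocab(), word_dim=4, hidden=3, fc_dims=(3, 2), seed=21)
    ids = [1, 4, 6]
    fdoc = FeaturizedDocument("d", [ids], label=0)
    rep, logits, alpha = module.forward([fdoc])
    # scalar route: BiLSTM, attention (u = tanh(Wh+b), softmax, weighted sum)
    xs = [module.embedding.data[i].tolist() for i in ids]
    hf = _scalar_lstm(xs, _lstm_params(module.fwd))
    hb = _scalar_lstm(xs, _lstm_params(module.bwd), reverse=True)
    hs = [f + b for f, b in zip(hf, hb)]
    Wa, ba = module.attn.W.data.tolist(), module.attn.b.data.tolist()
    us = [math.tanh(_mv(h, Wa)[0] + ba[0]) for h in hs]
    z = sum(math.exp(u) for u in us)
    alphas = [math.exp(u) / z for u in us]
    v = [sum(a * h[j] for a, h in zip(alphas, hs)) for j in range(len(hs[0]))]
    a1 = _vtanh(_vadd(_mv(v, module.W_fc1.data.tolist()), module.b_fc1.data.tolist()))
    rep_exp = _vtanh(_vadd(_mv(a1, module.W_fc2.data.tolist()), module.b_fc2.data.tolist()))
    probs_exp = _softmax2(_vadd(_mv(rep_exp, module.W_cls.data.tolist()), module.b_cls.data.tolist()))
    np.testing.assert_allclose(alpha[0], alphas, atol=1e-10)
    np.testing.assert_allclose(rep.data[0], rep_exp, atol=1e-10)
    np.testing.assert_allclose(ad.softmax(logits.data)[0], probs_exp, atol=1e-10)
    assert alpha.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("arch", list(Arch))
def test_softmax_normalization_random_draws(arch):
    rng = np.random.default_rng(99)
    for draw in range(5):
        model = TriageModel(_cfg(arch, seed=1000 + draw), _vocab())
        n_tok = int(rng.integers(1, 6))
        ids = rng.integers(2, 10, size=n_tok).tolist()
        fdoc = FeaturizedDocument("d", [ids[:1], ids[1:]] if arch is Arch.HIELSTM and n_tok > 1 else [ids])
        _, logits = model.forward([fdoc])
        probs = ad.softmax(logits.data)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


@pytest.mark.parametrize("arch", list(Arch))
def test_pad_invariance_via_batching(arch):
    """Batching a short document with a longer one (which forces padding)
    must not change the short document's output."""
    model = TriageModel(_cfg(arch, seed=5), _vocab())
    short = FeaturizedDocument("s", [[2, 3], [4]])
    long = FeaturizedDocument("l", [[5, 6, 7, 2], [3, 4, 5], [6, 7]])
    _, logits_alone = model.forward([short])
    _, logits_batched = model.forward([short, long])
    np.testing.assert_allclose(logits_alone.data[0], logits_batched.data[0], atol=1e-10)


def test_rcnn_zero_lstm_params_gives_context_free_window():
    model = TriageModel(_cfg(Arch.RCNN, seed=1), _vocab())
    for name, t in model.own_parameters().items():
        if name.startswith(("lstm", "lstm_bwd")):
            t.data[...] = 0.0
    ids = [2, 4, 6]
    fdoc = FeaturizedDocument("d", [ids])
    rep, _ = model.forward([fdoc])
    H, D = model.config.hidden, model.config.word_dim
    # w_t = [0; x_t; 0]  =>  pooled rep = [0 block, max tanh(x), 0 block]
    xs = np.array([model.word_emb.data[i] for i in ids])
    np.testing.assert_allclose(rep.data[0][:H], 0.0, atol=1e-12)
    np.testing.assert_allclose(rep.data[0][H + D :], 0.0, atol=1e-12)
    np.testing.assert_allclose(rep.data[0][H : H + D], np.tanh(xs).max(axis=0), atol=1e-12)


def test_single_token_lstm_composes_unit_operations():
    """One-token document through the LSTM model == lstm_step then the
    softmax classifier applied to h_1."""
    from doctriage.nn.layers import lstm_step

    model = TriageModel(_cfg(Arch.LSTM, seed=3), _vocab())
    fdoc = FeaturizedDocument("d", [[4]])
    _, logits = model.forward([fdoc])
    x = ad.constant(model.word_emb.data[[4]])
    zeros = ad.constant(np.zeros((1, model.config.hidden)))
    h1, _ = lstm_step(x, zeros, zeros, model.lstm)
    logits_exp = h1.data @ model.W_cls.data + model.b_cls.data
    np.testing.assert_allclose(logits.data, logits_exp, atol=1e-12)


def test_empty_document_rejected():
    model = TriageModel(_cfg(Arch.LSTM), _vocab())
    with pytest.raises(ValueError):
        model.forward([FeaturizedDocument("d", [])])


def test_prediction_record_contracts():
    assert PredictionRecord("d", 0.3, 0.7).decision == 1
    assert PredictionRecord("d", 0.5, 0.5).decision == 0  # tie -> negative
    with pytest.raises(ValueError):
        PredictionRecord("d", 0.5, 0.6)


class TestFusion:
    def _fused(self, mode=PpiMode.STATIC, arch=Arch.LSTM):
        ppi = PpiModule(_vocab(), word_dim=4, hidden=3, fc_dims=(3, 2), seed=7)
        ppi.strip_classifier()
        cfg = ModelConfig(arch=arch, hidden=3, filters=3, fc_dim=3, word_dim=4,
                          ppi_mode=mode, seed=2)
        return TriageModel(cfg, _vocab(), ppi_module=ppi)

    def test_fused_dimension_additive(self):
        model = self._fused()
        fdoc = FeaturizedDocument("d", [[2, 3]])
        rep, _ = model.forward([fdoc], [fdoc])
        assert rep.data.shape[1] == model.rep_dim + model.ppi.rep_dim

    def test_static_excludes_ppi_from_trainable(self):
        model = self._fused(PpiMode.STATIC)
        assert not any(k.startswith("ppi.") for k in model.trainable_parameters())

    def test_tuned_includes_ppi_in_trainable(self):
        model = self._fused(PpiMode.TUNED)
        assert any(k.startswith("ppi.") for k in model.trainable_parameters())

    def test_stripped_module_rep_equals_prestrip_penultimate(self):
        ppi = PpiModule(_vocab(), word_dim=4, hidden=3, fc_dims=(3, 2), seed=8)
        fdoc = FeaturizedDocument("d", [[2, 5, 3]])
        rep_before, logits, _ = ppi.forward([fdoc])
        ppi.strip_classifier()
        rep_after, logits_after, _ = ppi.forward([fdoc])
        assert logits is not None and logits_after is None
        np.testing.assert_array_equal(rep_before.data, rep_after.data)
        assert not any(k.startswith("W_cls") for k in ppi.parameters())


class TestCheckpoint:
    def test_model_round_trip_bit_exact(self, tmp_path):
        model = TriageModel(_cfg(Arch.LSTM_CNN, seed=4), _vocab())
        path = tmp_path / "m.json"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        for (ka, ta), (kb, tb) in zip(
            sorted(model.parameters().items()), sorted(loaded.parameters().items())
        ):
            assert ka == kb
            np.testing.assert_array_equal(ta.data, tb.data)
        fdoc = FeaturizedDocument("d", [[2, 3, 4]])
        _, la = model.forward([fdoc])
        _, lb = loaded.forward([fdoc])
        np.testing.assert_array_equal(la.data, lb.data)

    def test_fused_round_trip(self, tmp_path):
        ppi = PpiModule(_vocab(), word_dim=4, hidden=3, fc_dims=(3, 2), seed=9)
        ppi.strip_classifier()
        cfg = ModelConfig(arch=Arch.LSTM, hidden=3, word_dim=4, ppi_mode=PpiMode.TUNED, seed=1)
        model = TriageModel(cfg, _vocab(), ppi_module=ppi)
        path = tmp_path / "m.json"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.ppi is not None and loaded.ppi.stripped
        fdoc = FeaturizedDocument("d", [[2, 3]])
        _, la = model.forward([fdoc], [fdoc])
        _, lb = loaded.forward([fdoc], [fdoc])
        np.testing.assert_array_equal(la.data, lb.data)

    def test_ppi_module_round_trip(self, tmp_path):
        ppi = PpiModule(_vocab(), word_dim=4, hidden=3, fc_dims=(3, 2), seed=10)
        path = tmp_path / "p.json"
        save_ppi_module(ppi, path)
        loaded = load_ppi_module(path)
        fdoc = FeaturizedDocument("d", [[5, 6]])
        ra, la, _ = ppi.forward([fdoc])
        rb, lb, _ = loaded.forward([fdoc])
        np.testing.assert_array_equal(ra.data, rb.data)
        np.testing.assert_array_equal(la.data, lb.data)
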