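"""The five document encoders, the attention-BiLSTM auxiliary module and
representation fusion.

Every model maps a batch of featurized documents to a fixed-length
document representation and two-class logits.  The representation is the
vector entering the classification layer; when an auxiliary pre-trained
module is attached, the classifier sees the concatenation of the model's
own representation and the module's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ..corpus_io import Document
from ..features import (
    PAD_ID,
    EmbeddingTable,
    FeaturizedDocument,
    Vocabulary,
    featurize,
)
from . import autodiff as ad
from .autodiff import Tensor
from .layers import (
    AttentionParams,
    ConvParams,
    LSTMParams,
    affine,
    attention_pool,
    conv_layer,
    init_attention,
    init_conv,
    init_lstm,
    init_matrix,
    lstm_sequence,
    mask_steps,
    max_pool_time,
)

__all__ = [
    "Arch",
    "PpiMode",
    "OptimizerKind",
    "ModelConfig",
    "PredictionRecord",
    "PpiModule",
    "TriageModel",
]


class Arch(Enum):
    LSTM = "lstm"
    CNN = "cnn"
    LSTM_CNN = "lstm_cnn"
    RCNN = "rcnn"
    HIELSTM = "hielstm"


class PpiMode(Enum):
    NONE = "none"
    STATIC = "static"
    TUNED = "tuned"


class OptimizerKind(Enum):
    RMSPROP = "rmsprop"
    ADADELTA = "adadelta"


@dataclass
class ModelConfig:
    arch: Arch = Arch.LSTM
    hidden: int = 64
    filters: int = 64
    fc_dim: int = 32
    k: int = 3
    word_dim: int = 50
    pos_dim: int = 5
    ner_dim: int = 5
    use_pos: bool = False
    use_ner: bool = False
    ppi_mode: PpiMode = PpiMode.NONE
    optimizer: OptimizerKind | None = None  # None -> Adadelta iff CNN, else RMSprop
    learning_rate: float | None = None
    max_epochs: int = 10
    patience: int = 3
    batch_size: int = 32
    clip_norm: float = 5.0
    seed: int = 0

    def resolved_optimizer(self) -> OptimizerKind:
        if self.optimizer is not None:
            return self.optimizer
        return OptimizerKind.ADADELTA if self.arch is Arch.CNN else OptimizerKind.RMSPROP

    @property
    def input_dim(self) -> int:
        return (
            self.word_dim
            + (self.pos_dim if self.use_pos else 0)
            + (self.ner_dim if self.use_ner else 0)
        )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["arch"] = self.arch.value
        d["ppi_mode"] = self.ppi_mode.value
        d["optimizer"] = None if self.optimizer is None else self.optimizer.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["arch"] = Arch(d["arch"])
        d["ppi_mode"] = PpiMode(d["ppi_mode"])
        if d.get("optimizer") is not None:
            d["optimizer"] = OptimizerKind(d["optimizer"])
        return cls(**d)


@dataclass
class PredictionRecord:
    """Per-document class probabilities and the hard decision."""

    doc_id: str
    p_neg: float
    p_pos: float
    decision: int = field(default=-1)

    def __post_init__(self) -> None:
        if abs(self.p_neg + self.p_pos - 1.0) > 1e-6:
            raise ValueError("class probabilities must sum to 1")
        if self.decision == -1:
            # exact tie goes to the negative class
            self.decision = 1 if self.p_pos > self.p_neg else 0


# ---------------------------------------------------------------------------
# batching helpers


def _flat_batch(fdocs: list[FeaturizedDocument]) -> tuple[np.ndarray, ...]:
    """Pad flat token streams to (B, T) id arrays plus a validity mask."""
    flat = [d.flat_word_ids() for d in fdocs]
    if any(len(f) == 0 for f in flat):
        raise ValueError("cannot encode an empty document")
    T = max(len(f) for f in flat)
    B = len(fdocs)
    word = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T))
    pos = np.zeros((B, T), dtype=np.int64)
    ner = np.zeros((B, T), dtype=np.int64)
    for i, d in enumerate(fdocs):
        ids = flat[i]
        word[i, : len(ids)] = ids
        mask[i, : len(ids)] = 1.0
        if d.pos_ids is not None:
            p = [x for s in d.pos_ids for x in s]
            pos[i, : len(p)] = p
        if d.ner_ids is not None:
            nn_ = [x for s in d.ner_ids for x in s]
            ner[i, : len(nn_)] = nn_
    return word, pos, ner, mask


def _hier_batch(fdocs: list[FeaturizedDocument]) -> tuple[np.ndarray, ...]:
    """Pad to (B, S, L) id arrays with token and sentence masks."""
    if any(len(d.word_ids) == 0 for d in fdocs):
        raise ValueError("hierarchical encoder requires at least one sentence")
    B = len(fdocs)
    S = max(len(d.word_ids) for d in fdocs)
    L = max(max(len(s) for s in d.word_ids) for d in fdocs)
    word = np.zeros((B, S, L), dtype=np.int64)
    pos = np.zeros((B, S, L), dtype=np.int64)
    ner = np.zeros((B, S, L), dtype=np.int64)
    tok_mask = np.zeros((B, S, L))
    sent_mask = np.zeros((B, S))
    for i, d in enumerate(fdocs):
        for j, sent in enumerate(d.word_ids):
            if not sent:
                continue
            word[i, j, : len(sent)] = sent
            tok_mask[i, j, : len(sent)] = 1.0
            sent_mask[i, j] = 1.0
            if d.pos_ids is not None:
                pos[i, j, : len(sent)] = d.pos_ids[j]
            if d.ner_ids is not None:
                ner[i, j, : len(sent)] = d.ner_ids[j]
    return word, pos, ner, tok_mask, sent_mask


# ---------------------------------------------------------------------------
# the auxiliary (PPI) module


class PpiModule:
    """Attention-based BiLSTM document classifier over word features only.

    After pre-training on the auxiliary corpus the classification layer
    is stripped; what remains produces the auxiliary representation that
    gets concatenated to a target model's own representation.
    """

    def __init__(
        self,
        vocab: Vocabulary,
        word_dim: int = 50,
        hidden: int = 32,
        fc_dims: tuple[int, int] = (32, 16),
        seed: int = 0,
        word_vectors: EmbeddingTable | None = None,
    ):
        self.vocab = vocab
        self.word_dim = word_dim
        self.hidden = hidden
        self.fc_dims = fc_dims
        rng = np.random.default_rng(seed)
        if word_vectors is not None:
            if word_vectors.dim != word_dim:
                raise ValueError("word vector dim mismatch")
            emb = word_vectors.vectors.copy()
        else:
            emb = rng.uniform(-0.05, 0.05, size=(len(vocab), word_dim))
        emb[PAD_ID] = 0.0
        self.embedding = ad.tensor(emb, requires_grad=True)
        self.fwd = init_lstm(rng, word_dim, hidden)
        self.bwd = init_lstm(rng, word_dim, hidden)
        self.attn = init_attention(rng, 2 * hidden)
        self.W_fc1 = init_matrix(rng, 2 * hidden, fc_dims[0])
        self.b_fc1 = ad.tensor(np.zeros(fc_dims[0]), requires_grad=True)
        self.W_fc2 = init_matrix(rng, fc_dims[0], fc_dims[1])
        self.b_fc2 = ad.tensor(np.zeros(fc_dims[1]), requires_grad=True)
        self.W_cls: Tensor | None = init_matrix(rng, fc_dims[1], 2)
        self.b_cls: Tensor | None = ad.tensor(np.zeros(2), requires_grad=True)
        self.stripped = False

    @property
    def rep_dim(self) -> int:
        return self.fc_dims[1]

    def parameters(self) -> dict[str, Tensor]:
        params = {"embedding": self.embedding}
        params.update(self.fwd.named("fwd"))
        params.update(self.bwd.named("bwd"))
        params.update(self.attn.named("attn"))
        params.update({"W_fc1": self.W_fc1, "b_fc1": self.b_fc1,
                       "W_fc2": self.W_fc2, "b_fc2": self.b_fc2})
        if not self.stripped:
            assert self.W_cls is not None and self.b_cls is not None
            params.update({"W_cls": self.W_cls, "b_cls": self.b_cls})
        return params

    def embedding_names(self) -> set[str]:
        return {"embedding"}

    def featurize_many(self, docs: list[Document]) -> list[FeaturizedDocument]:
        return [featurize(d, self.vocab) for d in docs]

    def forward(
        self, fdocs: list[FeaturizedDocument]
    ) -> tuple[Tensor, Tensor | None, np.ndarray]:
        """Returns (representation, logits or None if stripped, attention)."""
        word, _, _, mask = _flat_batch(fdocs)
        xs = [ad.gather_rows(self.embedding, word[:, t]) for t in range(word.shape[1])]
        hf = lstm_sequence(xs, mask, self.fwd)
        hb = lstm_sequence(xs, mask, self.bwd, reverse=True)
        hs = [ad.concat([f, b], axis=1) for f, b in zip(hf, hb)]
        v, alpha = attention_pool(hs, mask, self.attn)
        a1 = ad.tanh(affine(v, self.W_fc1, self.b_fc1))
        rep = ad.tanh(affine(a1, self.W_fc2, self.b_fc2))
        logits = None
        if not self.stripped:
            assert self.W_cls is not None and self.b_cls is not None
            logits = affine(rep, self.W_cls, self.b_cls)
        return rep, logits, alpha

    def strip_classifier(self) -> "PpiModule":
        """Drop the final classification layer (in place)."""
        self.W_cls = None
        self.b_cls = None
        self.stripped = True
        return self

    def predict(self, docs: list[Document], batch_size: int = 64) -> list[PredictionRecord]:
        if self.stripped:
            raise ValueError("classifier layer has been stripped")
        out: list[PredictionRecord] = []
        fdocs = self.featurize_many(docs)
        for i in range(0, len(fdocs), batch_size):
            chunk = fdocs[i : i + batch_size]
            _, logits, _ = self.forward(chunk)
            assert logits is not None
            probs = ad.softmax(logits.data)
            for d, p in zip(chunk, probs):
                out.append(PredictionRecord(d.doc_id, float(p[0]), float(p[1])))
        return out


# ---------------------------------------------------------------------------
# the five target architectures


class TriageModel:
    """One of the five document classifiers, optionally fused with a
    pre-trained auxiliary module (static or tuned)."""

    def __init__(
        self,
        config: ModelConfig,
        vocab: Vocabulary,
        pos_vocab: Vocabulary | None = None,
        ner_vocab: Vocabulary | None = None,
        word_vectors: EmbeddingTable | None = None,
        ppi_module: PpiModule | None = None,
    ):
        if config.ppi_mode is not PpiMode.NONE and ppi_module is None:
            raise ValueError("ppi_mode set but no ppi_module given")
        if config.ppi_mode is PpiMode.NONE and ppi_module is not None:
            raise ValueError("ppi_module given but ppi_mode is NONE")
        self.config = config
        self.vocab = vocab
        self.pos_vocab = pos_vocab
        self.ner_vocab = ner_vocab
        self.ppi = ppi_module
        rng = np.random.default_rng(config.seed)
        c = config

        emb = rng.uniform(-0.05, 0.05, size=(len(vocab), c.word_dim))
        if word_vectors is not None:
            if word_vectors.dim != c.word_dim:
                raise ValueError("word vector dim mismatch")
            emb = word_vectors.vectors.copy()
        emb[PAD_ID] = 0.0
        self.word_emb = ad.tensor(emb, requires_grad=True)
        self.pos_emb: Tensor | None = None
        self.ner_emb: Tensor | None = None
        if c.use_pos:
            if pos_vocab is None:
                raise ValueError("use_pos requires pos_vocab")
            pe = rng.uniform(-0.05, 0.05, size=(len(pos_vocab), c.pos_dim))
            pe[PAD_ID] = 0.0
            self.pos_emb = ad.tensor(pe, requires_grad=True)
        if c.use_ner:
            if ner_vocab is None:
                raise ValueError("use_ner requires ner_vocab")
            ne = rng.uniform(-0.05, 0.05, size=(len(ner_vocab), c.ner_dim))
            ne[PAD_ID] = 0.0
            self.ner_emb = ad.tensor(ne, requires_grad=True)

        d_in = c.input_dim
        self.lstm: LSTMParams | None = None
        self.lstm_bwd: LSTMParams | None = None
        self.conv1: ConvParams | None = None
        self.conv2: ConvParams | None = None
        self.W_fc: Tensor | None = None
        self.b_fc: Tensor | None = None
        self.sent_fwd: LSTMParams | None = None
        self.sent_bwd: LSTMParams | None = None

        if c.arch is Arch.LSTM:
            self.lstm = init_lstm(rng, d_in, c.hidden)
            rep_dim = c.hidden
        elif c.arch is Arch.CNN:
            self.conv1 = init_conv(rng, d_in, c.filters, c.k)
            self.conv2 = init_conv(rng, c.filters, c.filters, c.k)
            self.W_fc = init_matrix(rng, c.filters, c.fc_dim)
            self.b_fc = ad.tensor(np.zeros(c.fc_dim), requires_grad=True)
            rep_dim = c.fc_dim
        elif c.arch is Arch.LSTM_CNN:
            self.lstm = init_lstm(rng, d_in, c.hidden)
            self.lstm_bwd = init_lstm(rng, d_in, c.hidden)
            self.conv1 = init_conv(rng, 2 * c.hidden, c.filters, c.k)
            self.W_fc = init_matrix(rng, c.filters, c.fc_dim)
            self.b_fc = ad.tensor(np.zeros(c.fc_dim), requires_grad=True)
            rep_dim = c.fc_dim
        elif c.arch is Arch.RCNN:
            self.lstm = init_lstm(rng, d_in, c.hidden)
            self.lstm_bwd = init_lstm(rng, d_in, c.hidden)
            rep_dim = 2 * c.hidden + d_in
        elif c.arch is Arch.HIELSTM:
            self.lstm = init_lstm(rng, d_in, c.hidden)  # word encoder
            self.sent_fwd = init_lstm(rng, c.hidden, c.hidden)
            self.sent_bwd = init_lstm(rng, c.hidden, c.hidden)
            rep_dim = 2 * c.hidden
        else:  # pragma: no cover
            raise ValueError(f"unknown architecture {c.arch}")

        self.rep_dim = rep_dim
        cls_dim = rep_dim + (self.ppi.rep_dim if self.ppi is not None else 0)
        self.W_cls = init_matrix(rng, cls_dim, 2)
        self.b_cls = ad.tensor(np.zeros(2), requires_grad=True)

    # -- parameter bookkeeping ------------------------------------------------

    def own_parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {"word_emb": self.word_emb}
        if self.pos_emb is not None:
            params["pos_emb"] = self.pos_emb
        if self.ner_emb is not None:
            params["ner_emb"] = self.ner_emb
        if self.lstm is not None:
            params.update(self.lstm.named("lstm"))
        if self.lstm_bwd is not None:
            params.update(self.lstm_bwd.named("lstm_bwd"))
        if self.conv1 is not None:
            params.update(self.conv1.named("conv1"))
        if self.conv2 is not None:
            params.update(self.conv2.named("conv2"))
        if self.W_fc is not None:
            assert self.b_fc is not None
            params.update({"W_fc": self.W_fc, "b_fc": self.b_fc})
        if self.sent_fwd is not None:
            params.update(self.sent_fwd.named("sent_fwd"))
        if self.sent_bwd is not None:
            params.update(self.sent_bwd.named("sent_bwd"))
        params.update({"W_cls": self.W_cls, "b_cls": self.b_cls})
        return params

    def parameters(self) -> dict[str, Tensor]:
        """All parameters, auxiliary module included (prefixed ppi.)."""
        params = self.own_parameters()
        if self.ppi is not None:
            params.update({f"ppi.{k}": v for k, v in self.ppi.parameters().items()})
        return params

    def trainable_parameters(self) -> dict[str, Tensor]:
        """Parameters the optimizer may update.  STATIC mode freezes the
        auxiliary module's parameters; TUNED leaves them trainable."""
        if self.ppi is not None and self.config.ppi_mode is PpiMode.STATIC:
            return self.own_parameters()
        return self.parameters()

    def embedding_names(self) -> set[str]:
        names = {"word_emb"}
        if self.pos_emb is not None:
            names.add("pos_emb")
        if self.ner_emb is not None:
            names.add("ner_emb")
        if self.ppi is not None:
            names |= {f"ppi.{n}" for n in self.ppi.embedding_names()}
        return names

    # -- featurization --------------------------------------------------------

    def featurize_many(self, docs: list[Document]) -> list[FeaturizedDocument]:
        return [
            featurize(
                d,
                self.vocab,
                pos_vocab=self.pos_vocab,
                ner_vocab=self.ner_vocab,
                use_pos=self.config.use_pos,
                use_ner=self.config.use_ner,
            )
            for d in docs
        ]

    # -- forward passes -------------------------------------------------------

    def _embed_flat(self, word, pos, ner, T: int) -> list[Tensor]:
        xs = []
        for t in range(T):
            parts = [ad.gather_rows(self.word_emb, word[:, t])]
            if self.pos_emb is not None:
                parts.append(ad.gather_rows(self.pos_emb, pos[:, t]))
            if self.ner_emb is not None:
                parts.append(ad.gather_rows(self.ner_emb, ner[:, t]))
            xs.append(parts[0] if len(parts) == 1 else ad.concat(parts, axis=1))
        return xs

    def _encode_flat(self, fdocs: list[FeaturizedDocument]) -> Tensor:
        c = self.config
        word, pos, ner, mask = _flat_batch(fdocs)
        xs = self._embed_flat(word, pos, ner, word.shape[1])
        if c.arch is Arch.LSTM:
            assert self.lstm is not None
            hs = lstm_sequence(xs, mask, self.lstm)
            return max_pool_time(hs, mask)
        if c.arch is Arch.CNN:
            assert self.conv1 is not None and self.conv2 is not None
            c1 = mask_steps(conv_layer(mask_steps(xs, mask), self.conv1), mask)
            cs = conv_layer(c1, self.conv2)
            pooled = max_pool_time(cs, mask)
            assert self.W_fc is not None and self.b_fc is not None
            return ad.tanh(affine(pooled, self.W_fc, self.b_fc))
        if c.arch is Arch.LSTM_CNN:
            assert self.lstm is not None and self.lstm_bwd is not None
            hf = lstm_sequence(xs, mask, self.lstm)
            hb = lstm_sequence(xs, mask, self.lstm_bwd, reverse=True)
            ys = [ad.tanh(ad.concat([f, b], axis=1)) for f, b in zip(hf, hb)]
            assert self.conv1 is not None
            cs = conv_layer(mask_steps(ys, mask), self.conv1)
            pooled = max_pool_time(cs, mask)
            assert self.W_fc is not None and self.b_fc is not None
            return ad.tanh(affine(pooled, self.W_fc, self.b_fc))
        if c.arch is Arch.RCNN:
            assert self.lstm is not None and self.lstm_bwd is not None
            hf = lstm_sequence(xs, mask, self.lstm)
            hb = lstm_sequence(xs, mask, self.lstm_bwd, reverse=True)
            B = word.shape[0]
            zero_h = ad.constant(np.zeros((B, c.hidden)))
            ys = []
            for t in range(len(xs)):
                left = hf[t - 1] if t > 0 else zero_h
                right = hb[t + 1] if t + 1 < len(xs) else zero_h
                ys.append(ad.tanh(ad.concat([left, xs[t], right], axis=1)))
            return max_pool_time(ys, mask)
        raise ValueError(f"{c.arch} is not a flat architecture")

    def _encode_hier(self, fdocs: list[FeaturizedDocument]) -> Tensor:
        c = self.config
        word, pos, ner, tok_mask, sent_mask = _hier_batch(fdocs)
        B, S, L = word.shape
        if not np.all(sent_mask.sum(axis=1) > 0):
            raise ValueError("hierarchical encoder requires at least one sentence")
        # word encoder over flattened (B*S, L) sentences
        word2 = word.reshape(B * S, L)
        pos2 = pos.reshape(B * S, L)
        ner2 = ner.reshape(B * S, L)
        tmask = tok_mask.reshape(B * S, L).copy()
        empty = tmask.sum(axis=1) == 0
        tmask[empty, 0] = 1.0  # placeholder; gated out by the sentence mask
        xs = self._embed_flat(word2, pos2, ner2, L)
        assert self.lstm is not None
        hs = lstm_sequence(xs, tmask, self.lstm)
        pooled = max_pool_time(hs, tmask)  # (B*S, H)
        # regroup into per-sentence steps; pooled rows are doc-major (i*S + j)
        sent_steps = []
        for j in range(S):
            idx = np.arange(B) * S + j
            sent_steps.append(ad.gather_rows(pooled, idx))
        assert self.sent_fwd is not None and self.sent_bwd is not None
        sf = lstm_sequence(sent_steps, sent_mask, self.sent_fwd)
        sb = lstm_sequence(sent_steps, sent_mask, self.sent_bwd, reverse=True)
        # final state of each direction (masked carry propagates the last
        # valid state to the ends)
        return ad.concat([sf[-1], sb[0]], axis=1)

    def forward(
        self,
        fdocs: list[FeaturizedDocument],
        ppi_fdocs: list[FeaturizedDocument] | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Returns (document representation, two-class logits)."""
        if not fdocs:
            raise ValueError("empty batch")
        if self.config.arch is Arch.HIELSTM:
            rep = self._encode_hier(fdocs)
        else:
            rep = self._encode_flat(fdocs)
        if self.ppi is not None:
            if ppi_fdocs is None:
                raise ValueError("fused model needs auxiliary featurizations")
            ppi_rep, _, _ = self.ppi.forward(ppi_fdocs)
            rep = ad.concat([rep, ppi_rep], axis=1)
        logits = affine(rep, self.W_cls, self.b_cls)
        return rep, logits

    def predict(self, docs: list[Document], batch_size: int | None = None) -> list[PredictionRecord]:
        bs = batch_size or self.config.batch_size
        fdocs = self.featurize_many(docs)
        ppi_fdocs = self.ppi.featurize_many(docs) if self.ppi is not None else None
        out: list[PredictionRecord] = []
        for i in range(0, len(fdocs), bs):
            chunk = fdocs[i : i + bs]
            pchunk = ppi_fdocs[i : i + bs] if ppi_fdocs is not None else None
            _, logits = self.forward(chunk, pchunk)
            probs = ad.softmax(logits.data)
            for d, p in zip(chunk, probs):
                out.append(PredictionRecord(d.doc_id, float(p[0]), float(p[1])))
        return out
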