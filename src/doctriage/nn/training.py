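"""Training loop: cross-entropy minimization with early stopping on dev F1.

RMSprop is the default optimizer for every architecture except the CNN,
which uses Adadelta.  After each epoch the dev-set F1 is recorded; when
it fails to improve for `patience` consecutive epochs training stops and
the parameters of the best epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..corpus_io import Label, LabeledCorpus
from ..evaluation import confusion, metrics
from ..features import PAD_ID, EmbeddingTable
from . import autodiff as ad
from .models import ModelConfig, OptimizerKind, PpiModule, TriageModel
from .optim import Adadelta, RMSprop, clip_gradients

__all__ = ["TrainHistory", "train", "pretrain_ppi", "dev_f1"]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    dev_f1: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based

    @property
    def epochs(self) -> int:
        return len(self.dev_f1)


def _labels_of(corpus: LabeledCorpus) -> np.ndarray:
    labels = []
    for d in corpus:
        if d.label is Label.UNKNOWN:
            raise ValueError(f"document {d.doc_id!r} is unlabeled")
        labels.append(d.label.value)
    return np.asarray(labels, dtype=np.int64)


def dev_f1(model, corpus: LabeledCorpus) -> float:
    """F1 (fraction in [0, 1]) of a model's decisions on a labeled corpus."""
    labels = _labels_of(corpus)
    preds = [r.decision for r in model.predict(list(corpus))]
    return metrics(confusion(preds, labels)).f1 / 100.0


def _make_optimizer(cfg: ModelConfig, params) -> RMSprop | Adadelta:
    kind = cfg.resolved_optimizer()
    if kind is OptimizerKind.RMSPROP:
        return RMSprop(params, lr=cfg.learning_rate if cfg.learning_rate else 1e-3)
    return Adadelta(params, lr=cfg.learning_rate if cfg.learning_rate else 1.0)


def train(
    model: TriageModel | PpiModule,
    train_corpus: LabeledCorpus,
    dev_corpus: LabeledCorpus,
    cfg: ModelConfig,
) -> TrainHistory:
    """Train in place; returns the per-epoch history.  Reproducible: all
    randomness (batch order) flows from cfg.seed."""
    if len(dev_corpus) == 0:
        raise ValueError("development set is empty")
    labels = _labels_of(train_corpus)
    docs = list(train_corpus)
    fdocs = model.featurize_many(docs)
    is_fused = isinstance(model, TriageModel) and model.ppi is not None
    ppi_fdocs = model.ppi.featurize_many(docs) if is_fused else None

    trainable = (
        model.trainable_parameters()
        if isinstance(model, TriageModel)
        else model.parameters()
    )
    all_params = model.parameters()
    emb_names = model.embedding_names()
    opt = _make_optimizer(cfg, trainable)
    rng = np.random.default_rng(cfg.seed)

    history = TrainHistory()
    best_f1 = -1.0
    best_snapshot: dict[str, np.ndarray] = {}
    bad_epochs = 0

    n = len(fdocs)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            chunk = [fdocs[i] for i in idx]
            if isinstance(model, TriageModel):
                pchunk = [ppi_fdocs[i] for i in idx] if ppi_fdocs is not None else None
                _, logits = model.forward(chunk, pchunk)
            else:
                _, logits, _ = model.forward(chunk)
                assert logits is not None
            loss, _ = ad.softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            ad.backward(loss)
            clip_gradients(trainable, cfg.clip_norm)
            opt.step()
            for name in emb_names:
                if name in trainable:
                    trainable[name].data[PAD_ID] = 0.0
            epoch_losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(epoch_losses)))
        f1 = dev_f1(model, dev_corpus)
        history.dev_f1.append(f1)
        if f1 > best_f1:
            best_f1 = f1
            history.best_epoch = epoch
            best_snapshot = {k: t.data.copy() for k, t in all_params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    for k, t in all_params.items():
        t.data[...] = best_snapshot[k]
    return history


def pretrain_ppi(
    ppi_corpus: LabeledCorpus,
    dev_fraction: float,
    cfg: ModelConfig,
    vocab=None,
    word_vectors: EmbeddingTable | None = None,
    fc_dims: tuple[int, int] | None = None,
) -> tuple[PpiModule, TrainHistory]:
    """Train the attention-BiLSTM auxiliary classifier, then strip its
    classification layer, leaving the representation producer."""
    from ..corpus_io import split_train_dev
    from ..features import build_vocab

    if vocab is None:
        vocab = build_vocab(ppi_corpus)
    module = PpiModule(
        vocab,
        word_dim=cfg.word_dim,
        hidden=cfg.hidden,
        fc_dims=fc_dims or (cfg.fc_dim, max(cfg.fc_dim // 2, 2)),
        seed=cfg.seed,
        word_vectors=word_vectors,
    )
    train_part, dev_part = split_train_dev(ppi_corpus, dev_fraction, cfg.seed)
    history = train(module, train_part, dev_part, cfg)
    module.strip_classifier()
    return module, history
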