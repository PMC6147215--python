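"""Self-describing JSON checkpoints: config, vocabularies and parameter
arrays, reloadable bit-exactly (JSON floats round-trip float64)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..features import Vocabulary
from .models import ModelConfig, PpiModule, TriageModel

__all__ = ["save_checkpoint", "load_checkpoint", "save_ppi_module", "load_ppi_module"]


def _params_out(params) -> dict:
    return {k: t.data.tolist() for k, t in params.items()}


def _params_in(model_params, stored: dict) -> None:
    for k, t in model_params.items():
        arr = np.asarray(stored[k], dtype=np.float64)
        if arr.shape != t.data.shape:
            raise ValueError(f"checkpoint shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
        t.data[...] = arr


def _vocab_out(vocab: Vocabulary | None):
    return None if vocab is None else vocab.id_to_token[2:]


def _vocab_in(tokens) -> Vocabulary | None:
    return None if tokens is None else Vocabulary.from_tokens(list(tokens))


def _ppi_out(module: PpiModule) -> dict:
    return {
        "vocab": _vocab_out(module.vocab),
        "word_dim": module.word_dim,
        "hidden": module.hidden,
        "fc_dims": list(module.fc_dims),
        "stripped": module.stripped,
        "params": _params_out(module.parameters()),
    }


def _ppi_in(obj: dict) -> PpiModule:
    module = PpiModule(
        _vocab_in(obj["vocab"]),
        word_dim=obj["word_dim"],
        hidden=obj["hidden"],
        fc_dims=tuple(obj["fc_dims"]),
    )
    if obj["stripped"]:
        module.strip_classifier()
    _params_in(module.parameters(), obj["params"])
    return module


def save_ppi_module(module: PpiModule, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"kind": "ppi_module", **_ppi_out(module)}))


def load_ppi_module(path: str | Path) -> PpiModule:
    obj = json.loads(Path(path).read_text())
    if obj.get("kind") != "ppi_module":
        raise ValueError(f"{path} is not an auxiliary-module checkpoint")
    return _ppi_in(obj)


def save_checkpoint(model: TriageModel, path: str | Path) -> None:
    obj = {
        "kind": "triage_model",
        "config": model.config.to_dict(),
        "vocab": _vocab_out(model.vocab),
        "pos_vocab": _vocab_out(model.pos_vocab),
        "ner_vocab": _vocab_out(model.ner_vocab),
        "params": _params_out(model.own_parameters()),
        "ppi": None if model.ppi is None else _ppi_out(model.ppi),
    }
    Path(path).write_text(json.dumps(obj))


def load_checkpoint(path: str | Path) -> TriageModel:
    obj = json.loads(Path(path).read_text())
    if obj.get("kind") != "triage_model":
        raise ValueError(f"{path} is not a model checkpoint")
    ppi = None if obj["ppi"] is None else _ppi_in(obj["ppi"])
    model = TriageModel(
        ModelConfig.from_dict(obj["config"]),
        _vocab_in(obj["vocab"]),
        pos_vocab=_vocab_in(obj["pos_vocab"]),
        ner_vocab=_vocab_in(obj["ner_vocab"]),
        ppi_module=ppi,
    )
    _params_in(model.own_parameters(), obj["params"])
    return model
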