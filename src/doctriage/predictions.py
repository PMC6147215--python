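"""Line-delimited prediction files: doc_id, p_neg, p_pos, decision."""

from __future__ import annotations

from pathlib import Path

from .nn.models import PredictionRecord

__all__ = ["write_predictions", "read_predictions"]

_HEADER = "doc_id\tp_neg\tp_pos\tdecision"


def write_predictions(records: list[PredictionRecord], path: str | Path) -> None:
    lines = [_HEADER]
    for r in records:
        lines.append(f"{r.doc_id}\t{r.p_neg!r}\t{r.p_pos!r}\t{r.decision}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != _HEADER:
        raise ValueError(f"{path} is not a prediction file")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"malformed prediction at line {lineno}")
        records.append(
            PredictionRecord(parts[0], float(parts[1]), float(parts[2]), int(parts[3]))
        )
    return records
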