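"""Reading and writing name-pair files and evaluation reports.

Pair files are UTF-8 delimited text (tab by default, comma accepted) with a
header row; ``source`` and ``target`` columns are resolved
case-insensitively, an optional ``label`` column carries the truth
(``1/0``, ``true/false``, ``yes/no``), and any extra columns are preserved
on round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluation import EvalMetrics, ScoredPair

__all__ = [
    "SchemaError",
    "PairRecord",
    "PairDataset",
    "read_pairs",
    "write_pairs",
    "write_metrics_tsv",
    "write_metrics_json",
]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


class SchemaError(ValueError):
    """A pair file does not match the expected schema."""


@dataclass(frozen=True)
class PairRecord:
    source: str
    target: str
    label: bool | None = None
    extras: dict = field(default_factory=dict)

    def as_tuple(self):
        if self.label is None:
            return (self.source, self.target)
        return (self.source, self.target, self.label)


@dataclass
class PairDataset:
    records: list[PairRecord]
    columns: list[str]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labeled(self) -> bool:
        return all(r.label is not None for r in self.records)


def _resolve_column(df: pd.DataFrame, name: str) -> str | None:
    for col in df.columns:
        if str(col).strip().lower() == name:
            return col
    return None


def _parse_label(raw: str, line_no: int) -> bool:
    token = str(raw).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise SchemaError(f"line {line_no}: unparseable label {raw!r}")


def read_pairs(path: "str | Path", delimiter: str = "\t") -> PairDataset:
    """Read a pair file; raises :class:`SchemaError` on schema problems."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except UnicodeDecodeError as exc:
        raise SchemaError(f"{path}: not valid UTF-8 ({exc})") from exc
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed rows ({exc})") from exc
    src_col = _resolve_column(df, "source")
    tgt_col = _resolve_column(df, "target")
    if src_col is None or tgt_col is None:
        missing = [n for n, c in (("source", src_col), ("target", tgt_col)) if c is None]
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    label_col = _resolve_column(df, "label")
    records = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        label = (
            _parse_label(row[label_col], line_no) if label_col is not None else None
        )
        extras = {
            str(c): row[c]
            for c in df.columns
            if c not in (src_col, tgt_col, label_col)
        }
        records.append(
            PairRecord(str(row[src_col]), str(row[tgt_col]), label, extras)
        )
    return PairDataset(records=records, columns=[str(c) for c in df.columns])


def write_pairs(
    dataset: "PairDataset | Sequence[PairRecord]",
    path: "str | Path",
    delimiter: str = "\t",
    extra_columns: "dict[str, Sequence] | None" = None,
) -> None:
    """Write records back out, preserving column order and any extras.

    ``extra_columns`` appends new columns (e.g. per-algorithm similarities)
    to the right of the existing ones.
    """
    records = dataset.records if isinstance(dataset, PairDataset) else list(dataset)
    if isinstance(dataset, PairDataset):
        columns = list(dataset.columns)
    else:
        columns = ["source", "target"]
        if any(r.label is not None for r in records):
            columns.append("label")
    data: dict[str, list] = {c: [] for c in columns}
    for r in records:
        for c in columns:
            lc = c.strip().lower()
            if lc == "source":
                data[c].append(r.source)
            elif lc == "target":
                data[c].append(r.target)
            elif lc == "label":
                data[c].append("" if r.label is None else str(int(r.label)))
            else:
                data[c].append(r.extras.get(c, ""))
    df = pd.DataFrame(data, columns=columns)
    if extra_columns:
        for name, values in extra_columns.items():
            df[name] = list(values)
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def _metrics_row(m: EvalMetrics) -> dict:
    return {
        "threshold": m.threshold,
        "tp": m.counts.tp,
        "fp": m.counts.fp,
        "fn": m.counts.fn,
        "tn": m.counts.tn,
        "precision": m.precision,
        "recall": m.recall,
        "f_measure": m.f_measure,
    }


def write_metrics_tsv(
    metrics: Sequence[EvalMetrics],
    path: "str | Path",
    header_info: "dict | None" = None,
) -> None:
    """Write a sweep report as TSV, with run parameters in # comment lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header_info or {}).items():
            fh.write(f"# {key}={value}\n")
        cols = ["threshold", "tp", "fp", "fn", "tn", "precision", "recall", "f_measure"]
        fh.write("\t".join(cols) + "\n")
        for m in metrics:
            row = _metrics_row(m)
            fh.write("\t".join(_format_cell(row[c]) for c in cols) + "\n")


def _format_cell(value) -> str:
    if isinstance(value, float):
        return f"{value:.6f}".rstrip("0").rstrip(".") if value else "0"
    return str(value)


def write_metrics_json(
    metrics: Sequence[EvalMetrics],
    path: "str | Path",
    header_info: "dict | None" = None,
) -> None:
    payload = {
        "run": header_info or {},
        "metrics": [_metrics_row(m) for m in metrics],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def scored_similarities(pairs: Sequence[ScoredPair]) -> list[float]:
    return [p.similarity for p in pairs]
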