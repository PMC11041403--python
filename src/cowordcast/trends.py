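"""Ranked trend tables: proportion of publications and percentage growth."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cooccurrence import CooccurrenceTensor
from .errors import ConfigurationError

__all__ = ["TrendRow", "TrendTable", "proportion_table", "growth_table", "difference_matrix"]


@dataclass(frozen=True)
class TrendRow:
    rank: int
    ai_term: str
    bio_term: str
    value: float  # percent
    past_count: float | None = None
    recent_count: float | None = None


@dataclass
class TrendTable:
    rows: list[TrendRow]
    metric: str  # "proportion" or "growth"
    threshold: float | None = None
    period: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.rank, r.ai_term, r.bio_term, self.metric, r.value, r.past_count, r.recent_count)
                for r in self.rows
            ],
            columns=["rank", "ai_term", "bio_term", "metric", "value", "past_count", "recent_count"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _rank_rows(cells, top_n: int):
    """Sort by value descending (term names break ties), assign 1-based ranks."""
    cells.sort(key=lambda c: (-c[2], c[0], c[1]))
    return [
        TrendRow(rank=k + 1, ai_term=ai, bio_term=bio, value=float(v), past_count=p, recent_count=r)
        for k, (ai, bio, v, p, r) in enumerate(cells[:top_n])
    ]


def proportion_table(
    tensor: CooccurrenceTensor,
    bins: Sequence[int],
    total_docs: Sequence[float],
    top_n: int = 20,
) -> TrendTable:
    """Share (%) of period documents mentioning both members of each pair.

    ``total_docs`` gives per-bin document totals aligned with ``bins``.
    Zero-count pairs are omitted (an all-zero tensor yields an empty table).
    """
    bins = list(bins)
    total_docs = np.asarray(list(total_docs), dtype=np.float64)
    if len(bins) != len(total_docs):
        raise ConfigurationError("bins and total_docs must align")
    if not bins:
        raise ConfigurationError("empty bin range")
    denom = float(total_docs.sum())
    if denom <= 0:
        raise ConfigurationError("total document count must be positive")
    summed = np.asarray(tensor.counts, dtype=np.float64)[bins].sum(axis=0)
    cells = []
    for i, ai in enumerate(tensor.ordering.ai_order):
        for j, bio in enumerate(tensor.ordering.bio_order):
            c = summed[i, j]
            if c > 0:
                cells.append((ai, bio, 100.0 * c / denom, None, float(c)))
    return TrendTable(
        rows=_rank_rows(cells, top_n),
        metric="proportion",
        period=f"bins {bins[0]}..{bins[-1]}",
    )


def growth_table(
    tensor: CooccurrenceTensor,
    past_bins: Sequence[int],
    recent_bins: Sequence[int],
    threshold: float = 10,
    top_n: int = 20,
) -> TrendTable:
    """Percentage growth 100 * (recent - past) / past per pair.

    Pairs whose past-period count falls below ``threshold`` are excluded —
    this is what keeps near-zero pairs from posting huge spurious growth.
    """
    past_bins, recent_bins = list(past_bins), list(recent_bins)
    if not past_bins or not recent_bins:
        raise ConfigurationError("past and recent bin ranges must be non-empty")
    if max(past_bins) >= min(recent_bins):
        raise ConfigurationError("past bins must all precede recent bins")
    if threshold < 1:
        raise ConfigurationError("threshold must be >= 1")
    counts = np.asarray(tensor.counts, dtype=np.float64)
    past = counts[past_bins].sum(axis=0)
    recent = counts[recent_bins].sum(axis=0)
    cells = []
    for i, ai in enumerate(tensor.ordering.ai_order):
        for j, bio in enumerate(tensor.ordering.bio_order):
            p = past[i, j]
            if p >= threshold:
                growth = 100.0 * (recent[i, j] - p) / p
                cells.append((ai, bio, growth, float(p), float(recent[i, j])))
    return TrendTable(
        rows=_rank_rows(cells, top_n),
        metric="growth",
        threshold=threshold,
        period=f"bins {past_bins[0]}..{past_bins[-1]} vs {recent_bins[0]}..{recent_bins[-1]}",
    )


def difference_matrix(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Elementwise predicted minus actual."""
    pred = np.asarray(pred, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if pred.shape != actual.shape:
        raise ConfigurationError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    return pred - actual
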