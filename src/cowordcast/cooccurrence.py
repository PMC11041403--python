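"""Semiannual co-occurrence tensor with clustering-ordered keyword axes."""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist

from .corpus_io import TokenizedDocument
from .embeddings import EmbeddingTable
from .errors import ConfigurationError, CowordcastError
from .vocab import KeywordSet

__all__ = [
    "TimeBinning",
    "AxisOrdering",
    "CooccurrenceTensor",
    "cluster_order",
    "order_axes",
    "count_tensor",
    "log_heat",
]


@dataclass(frozen=True)
class TimeBinning:
    """Tiling of [start, end] into fixed-length month bins (default semiannual)."""

    start: _dt.date
    end: _dt.date
    bin_months: int = 6

    def __post_init__(self):
        if self.bin_months < 1:
            raise ConfigurationError("bin_months must be >= 1")
        if self._month_index(self.end) < self._month_index(self.start):
            raise ConfigurationError(f"inverted span: {self.start} > {self.end}")
        span = self._month_index(self.end) - self._month_index(self.start) + 1
        if span % self.bin_months != 0:
            raise ConfigurationError(
                f"span of {span} months does not tile into {self.bin_months}-month bins"
            )

    def _month_index(self, d: _dt.date) -> int:
        return d.year * 12 + (d.month - 1)

    @property
    def n_bins(self) -> int:
        span = self._month_index(self.end) - self._month_index(self.start) + 1
        return span // self.bin_months

    def bin_of(self, d: _dt.date) -> int:
        idx = self._month_index(d) - self._month_index(self.start)
        if idx < 0 or idx >= self.n_bins * self.bin_months:
            raise CowordcastError(f"date {d} outside binning span")
        return idx // self.bin_months

    def bin_start(self, t: int) -> _dt.date:
        m = self._month_index(self.start) + t * self.bin_months
        return _dt.date(m // 12, m % 12 + 1, 1)

    def bin_label(self, t: int) -> str:
        s = self.bin_start(t)
        return f"{s.year}-{s.month:02d}"

    @classmethod
    def semiannual(cls, start_year: int = 2000, end_year: int = 2021) -> "TimeBinning":
        return cls(_dt.date(start_year, 1, 1), _dt.date(end_year, 12, 1), 6)


@dataclass
class AxisOrdering:
    """Dendrogram leaf orders for both keyword axes plus the merge histories."""

    ai_order: list[str]
    bio_order: list[str]
    ai_linkage: np.ndarray | None = None
    bio_linkage: np.ndarray | None = None

    def __post_init__(self):
        for name, order in (("ai_order", self.ai_order), ("bio_order", self.bio_order)):
            if len(set(order)) != len(order):
                raise ConfigurationError(f"{name} contains repeated terms")

    @property
    def ai_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.ai_order)}

    @property
    def bio_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.bio_order)}


def cluster_order(
    emb: EmbeddingTable,
    terms: Sequence[str],
    linkage: str = "average",
    optimal: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Order terms by agglomerative-clustering dendrogram leaf order.

    Cosine distance (1 - cosine) for average/complete linkage; ward uses
    Euclidean distance as it must.  `optimal=True` applies optimal leaf
    reordering on top of the canonical dendrogram order.
    """
    terms = list(terms)
    if len(terms) < 2:
        raise ConfigurationError("need at least 2 terms to cluster")
    if linkage not in ("average", "complete", "ward"):
        raise ConfigurationError(f"unknown linkage: {linkage!r}")
    mat = emb.matrix(terms)
    metric = "euclidean" if linkage == "ward" else "cosine"
    dists = pdist(mat, metric=metric)
    # cosine pdist can go slightly negative / nan on degenerate vectors
    dists = np.nan_to_num(np.maximum(dists, 0.0), nan=0.0)
    Z = scipy_linkage(dists, method=linkage)
    if optimal:
        Z = optimal_leaf_ordering(Z, dists)
    order = [terms[i] for i in leaves_list(Z)]
    return order, Z


def order_axes(
    emb: EmbeddingTable,
    keywords: KeywordSet,
    linkage: str = "average",
    optimal: bool = False,
) -> AxisOrdering:
    """Cluster each keyword axis independently and return both leaf orders."""
    ai_order, ai_Z = cluster_order(emb, keywords.ai_terms, linkage, optimal)
    bio_order, bio_Z = cluster_order(emb, keywords.bio_terms, linkage, optimal)
    return AxisOrdering(ai_order=ai_order, bio_order=bio_order, ai_linkage=ai_Z, bio_linkage=bio_Z)


@dataclass
class CooccurrenceTensor:
    """Integer counts indexed (time bin, AI keyword, BIO keyword)."""

    counts: np.ndarray
    binning: TimeBinning
    ordering: AxisOrdering

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ConfigurationError("counts must be a 3-D array (bin, ai, bio)")
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be nonnegative")
        T, A, B = self.counts.shape
        if A != len(self.ordering.ai_order) or B != len(self.ordering.bio_order):
            raise ConfigurationError("counts shape does not match axis orderings")
        if T != self.binning.n_bins:
            raise ConfigurationError("counts shape does not match binning")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def matrix(self, t: int) -> np.ndarray:
        return self.counts[t]

    # --- on-disk format: one TSV per bin + JSON sidecar ------------------
    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t in range(self.n_bins):
            self._write_matrix_tsv(outdir / f"bin_{t:03d}.tsv", self.counts[t])
        sidecar = {
            "start": self.binning.start.isoformat(),
            "end": self.binning.end.isoformat(),
            "bin_months": self.binning.bin_months,
            "ai_order": self.ordering.ai_order,
            "bio_order": self.ordering.bio_order,
            "ai_linkage": None
            if self.ordering.ai_linkage is None
            else np.asarray(self.ordering.ai_linkage).tolist(),
            "bio_linkage": None
            if self.ordering.bio_linkage is None
            else np.asarray(self.ordering.bio_linkage).tolist(),
        }
        (outdir / "tensor.json").write_text(json.dumps(sidecar, indent=1), encoding="utf-8")

    def _write_matrix_tsv(self, path: Path, mat: np.ndarray) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join([""] + self.ordering.bio_order) + "\n")
            for i, ai in enumerate(self.ordering.ai_order):
                fh.write("\t".join([ai] + [str(int(x)) for x in mat[i]]) + "\n")

    @classmethod
    def from_dir(cls, indir: str | Path) -> "CooccurrenceTensor":
        indir = Path(indir)
        meta = json.loads((indir / "tensor.json").read_text(encoding="utf-8"))
        binning = TimeBinning(
            _dt.date.fromisoformat(meta["start"]),
            _dt.date.fromisoformat(meta["end"]),
            meta["bin_months"],
        )
        ordering = AxisOrdering(
            ai_order=meta["ai_order"],
            bio_order=meta["bio_order"],
            ai_linkage=None if meta["ai_linkage"] is None else np.asarray(meta["ai_linkage"]),
            bio_linkage=None if meta["bio_linkage"] is None else np.asarray(meta["bio_linkage"]),
        )
        counts = np.zeros(
            (binning.n_bins, len(ordering.ai_order), len(ordering.bio_order)), dtype=np.int64
        )
        for t in range(binning.n_bins):
            lines = (indir / f"bin_{t:03d}.tsv").read_text(encoding="utf-8").splitlines()
            for i, line in enumerate(lines[1:]):
                counts[t, i] = [int(x) for x in line.split("\t")[1:]]
        return cls(counts=counts, binning=binning, ordering=ordering)


def count_tensor(
    docs: Iterable[TokenizedDocument],
    ordering: AxisOrdering,
    binning: TimeBinning,
) -> CooccurrenceTensor:
    """Count documents whose token set contains both keywords of each cell.

    Multiple mentions within one document count once; documents outside the
    binning span raise (filter first).
    """
    ai_idx = ordering.ai_index
    bio_idx = ordering.bio_index
    counts = np.zeros((binning.n_bins, len(ai_idx), len(bio_idx)), dtype=np.int64)
    for doc in docs:
        t = binning.bin_of(doc.date)
        toks = set(doc.tokens)
        ai_hits = [ai_idx[w] for w in toks if w in ai_idx]
        if not ai_hits:
            continue
        bio_hits = [bio_idx[w] for w in toks if w in bio_idx]
        for i in ai_hits:
            for j in bio_hits:
                counts[t, i, j] += 1
    return CooccurrenceTensor(counts=counts, binning=binning, ordering=ordering)


def log_heat(matrix: np.ndarray) -> np.ndarray:
    """Elementwise log10(1 + count) for heat display; zero maps to zero."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if np.any(matrix < 0):
        raise ConfigurationError("log_heat requires nonnegative counts")
    return np.log10(1.0 + matrix)
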