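"""Word vectors over the preprocessed corpus, plus similarity and 2-D projection.

The trainer builds a symmetric window co-occurrence matrix, applies positive
pointwise mutual information (PPMI), and factorizes it with a truncated SVD.
This is the classical count-based route to skip-gram-like vectors (PPMI-SVD
is an established equivalent formulation of skip-gram with negative
sampling); it is fully deterministic under a fixed seed, which the
prediction pipeline requires.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD

from .corpus_io import TokenizedDocument
from .errors import ConfigurationError, MissingEmbeddingError, UndefinedSimilarityError

__all__ = ["EmbeddingTable", "train_embeddings", "cosine", "project_2d"]


@dataclass
class EmbeddingTable:
    """Mapping term -> fixed-length real vector with training provenance."""

    dim: int
    vectors: dict[str, np.ndarray]
    window: int = 5
    seed: int = 0
    trained_on: str = ""

    def __post_init__(self):
        for term, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=np.float64)
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {term!r} has length {vec.shape}, expected ({self.dim},)")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite components in vector for {term!r}")
            self.vectors[term] = vec

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def __getitem__(self, term: str) -> np.ndarray:
        try:
            return self.vectors[term]
        except KeyError:
            raise MissingEmbeddingError([term]) from None

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def terms(self) -> list[str]:
        return list(self.vectors)

    def matrix(self, terms: Sequence[str]) -> np.ndarray:
        """Stack vectors for `terms` into an (n, dim) array; errors list offenders."""
        missing = [t for t in terms if t not in self.vectors]
        if missing:
            raise MissingEmbeddingError(missing)
        return np.vstack([self.vectors[t] for t in terms])

    # --- standard word2vec on-disk formats -------------------------------
    def save(self, path: str | Path, binary: bool = False) -> None:
        path = Path(path)
        if binary:
            with open(path, "wb") as fh:
                fh.write(f"{len(self.vectors)} {self.dim}\n".encode())
                for term, vec in self.vectors.items():
                    fh.write(term.encode("utf-8") + b" ")
                    fh.write(np.asarray(vec, dtype=np.float32).tobytes())
                    fh.write(b"\n")
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(f"{len(self.vectors)} {self.dim}\n")
                for term, vec in self.vectors.items():
                    comps = " ".join(repr(float(x)) for x in vec)
                    fh.write(f"{term} {comps}\n")

    @classmethod
    def load(cls, path: str | Path, binary: bool = False) -> "EmbeddingTable":
        path = Path(path)
        vectors: dict[str, np.ndarray] = {}
        if binary:
            with open(path, "rb") as fh:
                header = fh.readline().decode()
                n, dim = (int(x) for x in header.split())
                for _ in range(n):
                    term = bytearray()
                    while True:
                        ch = fh.read(1)
                        if ch == b" ":
                            break
                        term += ch
                    vec = np.frombuffer(fh.read(4 * dim), dtype=np.float32).astype(np.float64)
                    fh.read(1)  # trailing newline
                    vectors[term.decode("utf-8")] = vec
        else:
            with open(path, "r", encoding="utf-8") as fh:
                n, dim = (int(x) for x in fh.readline().split())
                for line in fh:
                    parts = line.rstrip("\n").split(" ")
                    vectors[parts[0]] = np.array([float(x) for x in parts[1 : dim + 1]])
        return cls(dim=dim, vectors=vectors)


def corpus_fingerprint(docs: Sequence[TokenizedDocument]) -> str:
    h = hashlib.sha256()
    for doc in docs:
        h.update(doc.doc_id.encode())
        h.update(" ".join(doc.tokens).encode())
    return h.hexdigest()[:16]


def train_embeddings(
    docs: Iterable[TokenizedDocument],
    dim: int = 300,
    window: int = 5,
    seed: int = 0,
    min_count: int = 5,
) -> EmbeddingTable:
    """Train PPMI-SVD word vectors on tokenized documents.

    Covers every token occurring at least ``min_count`` times.  Same seed,
    same corpus -> bitwise-identical table.
    """
    if dim < 2:
        raise ConfigurationError(f"embedding dim must be >= 2, got {dim}")
    docs = list(docs)
    if not docs:
        raise ConfigurationError("cannot train embeddings on an empty corpus")

    counts: Counter[str] = Counter()
    for doc in docs:
        counts.update(doc.tokens)
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ConfigurationError(f"no token reaches min_count={min_count}")
    index = {t: i for i, t in enumerate(vocab)}
    n = len(vocab)

    rows, cols, data = [], [], []
    pair_counts: Counter[tuple[int, int]] = Counter()
    for doc in docs:
        ids = [index[t] for t in doc.tokens if t in index]
        for pos, i in enumerate(ids):
            for j in ids[max(0, pos - window) : pos]:
                pair_counts[(i, j)] += 1
                pair_counts[(j, i)] += 1
    if not pair_counts:
        # degenerate corpus of single-token documents: fall back to identity-ish rows
        mat = sp.identity(n, format="csr")
    else:
        for (i, j), c in pair_counts.items():
            rows.append(i)
            cols.append(j)
            data.append(c)
        mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    total = mat.sum()
    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    col_sums = np.asarray(mat.sum(axis=0)).ravel()
    mat = mat.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log((mat.data * total) / (row_sums[mat.row] * col_sums[mat.col]))
    ppmi = np.maximum(pmi, 0.0)
    ppmi_mat = sp.csr_matrix((ppmi, (mat.row, mat.col)), shape=(n, n))

    k = min(dim, n - 1) if n > 1 else 1
    if k < 1:
        k = 1
    if n == 1:
        emb = np.ones((1, 1))
    else:
        svd = TruncatedSVD(n_components=k, random_state=seed, algorithm="randomized")
        u = svd.fit_transform(ppmi_mat)  # = U * Sigma
        # scale to U * sqrt(Sigma): symmetric factorization, standard for PPMI-SVD
        sigma = svd.singular_values_
        with np.errstate(divide="ignore", invalid="ignore"):
            emb = np.where(sigma > 0, u / np.sqrt(np.maximum(sigma, 1e-300)), 0.0)
    if emb.shape[1] < dim:
        emb = np.hstack([emb, np.zeros((n, dim - emb.shape[1]))])

    vectors = {t: emb[i].copy() for t, i in index.items()}
    return EmbeddingTable(
        dim=dim, vectors=vectors, window=window, seed=seed, trained_on=corpus_fingerprint(docs)
    )


def cosine(x: np.ndarray, y: np.ndarray) -> float:
    """cos(x, y) = x.y / (|x| |y|), in [-1, 1]."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def project_2d(
    emb: EmbeddingTable,
    terms: Sequence[str],
    seed: int = 0,
    perplexity: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Project term vectors to 2-D (t-SNE) for plotting. Deterministic per seed."""
    from sklearn.manifold import TSNE

    terms = list(terms)
    if len(terms) < 3:
        raise ConfigurationError("need at least 3 terms to project")
    mat = emb.matrix(terms)
    # degenerate case: all vectors (numerically) identical -> collapse to origin
    if np.allclose(mat, mat[0], atol=1e-12):
        return {t: (0.0, 0.0) for t in terms}
    if perplexity is None:
        perplexity = min(30.0, max(1.0, (len(terms) - 1) / 3.0))
    perplexity = min(perplexity, len(terms) - 1.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    coords = tsne.fit_transform(mat)
    return {t: (float(x), float(y)) for t, (x, y) in zip(terms, coords)}
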