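"""Keyword extraction and embedding-based domain assignment.

Candidate terms are ranked by document frequency and routed to the AI or
biomedical axis by comparing mean cosine similarity against two reference
lexicons (MeSH-style biomedical phrases, AI algorithm names).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import TokenizedDocument, tokenize_text
from .embeddings import EmbeddingTable, cosine
from .errors import ConfigurationError, UnclassifiableTermError

__all__ = [
    "ReferenceLexicon",
    "KeywordEntry",
    "KeywordSet",
    "count_frequencies",
    "classify_domain",
    "build_keyword_set",
]

AI = "AI"
BIO = "BIO"


@dataclass(frozen=True)
class ReferenceLexicon:
    """Two reference term sets, already in merged-token form."""

    bio_terms: frozenset[str]
    ai_terms: frozenset[str]

    def __post_init__(self):
        if not self.bio_terms or not self.ai_terms:
            raise ConfigurationError("reference lexicons must both be non-empty")

    @staticmethod
    def _phrase_to_token(phrase: str) -> str | None:
        toks = tokenize_text(phrase)
        if not toks:
            return None
        return "+".join(toks)

    @classmethod
    def from_phrases(cls, bio_phrases: Iterable[str], ai_phrases: Iterable[str]) -> "ReferenceLexicon":
        """Build a lexicon from raw phrases, applying the same merge rule as
        corpus preprocessing (multiword phrases become '+'-joined tokens)."""
        bio = {t for p in bio_phrases if (t := cls._phrase_to_token(p))}
        ai = {t for p in ai_phrases if (t := cls._phrase_to_token(p))}
        return cls(bio_terms=frozenset(bio), ai_terms=frozenset(ai))

    @classmethod
    def from_files(cls, bio_path: str | Path, ai_path: str | Path) -> "ReferenceLexicon":
        bio = Path(bio_path).read_text(encoding="utf-8").splitlines()
        ai = Path(ai_path).read_text(encoding="utf-8").splitlines()
        return cls.from_phrases([l for l in bio if l.strip()], [l for l in ai if l.strip()])


@dataclass(frozen=True)
class KeywordEntry:
    term: str
    frequency: int
    domain: str  # AI or BIO
    mean_sim_ai: float
    mean_sim_bio: float


@dataclass
class KeywordSet:
    """Ranked keywords per domain, frequency-descending."""

    entries: list[KeywordEntry]
    k_ai: int
    k_bio: int

    @property
    def ai_terms(self) -> list[str]:
        return [e.term for e in self.entries if e.domain == AI]

    @property
    def bio_terms(self) -> list[str]:
        return [e.term for e in self.entries if e.domain == BIO]

    def to_rows(self) -> list[tuple]:
        return [
            (e.term, e.frequency, e.domain, e.mean_sim_ai, e.mean_sim_bio) for e in self.entries
        ]


def count_frequencies(
    docs: Iterable[TokenizedDocument], candidates: set[str]
) -> dict[str, int]:
    """Document frequency: number of documents containing each candidate term."""
    if not candidates:
        raise ConfigurationError("candidate term set is empty")
    freqs = {t: 0 for t in candidates}
    for doc in docs:
        for term in set(doc.tokens) & candidates:
            freqs[term] += 1
    return freqs


def _mean_similarity(vec: np.ndarray, emb: EmbeddingTable, refs: Iterable[str]) -> float | None:
    """Mean cosine over embedded reference terms; None if all are out-of-vocabulary."""
    sims = [cosine(vec, emb[r]) for r in refs if r in emb]
    if not sims:
        return None
    return float(np.mean(sims))


def classify_domain(
    term: str, emb: EmbeddingTable, lex: ReferenceLexicon
) -> tuple[str, float, float]:
    """Assign AI or BIO by mean cosine similarity against the two lexicons.

    Returns (domain, mean_sim_ai, mean_sim_bio).  AI wins only on a strictly
    larger mean; ties go to BIO.  Out-of-vocabulary reference terms are
    dropped from the mean rather than scored zero.
    """
    if term not in emb:
        raise UnclassifiableTermError(f"term {term!r} has no embedding")
    vec = emb[term]
    sim_ai = _mean_similarity(vec, emb, sorted(lex.ai_terms))
    sim_bio = _mean_similarity(vec, emb, sorted(lex.bio_terms))
    if sim_ai is None or sim_bio is None:
        which = "AI" if sim_ai is None else "biomedical"
        raise ConfigurationError(f"{which} reference set is entirely out-of-vocabulary")
    domain = AI if sim_ai > sim_bio else BIO
    return domain, sim_ai, sim_bio


def build_keyword_set(
    freqs: Mapping[str, int],
    emb: EmbeddingTable,
    lex: ReferenceLexicon,
    k_ai: int,
    k_bio: int,
) -> KeywordSet:
    """Partition terms by domain and take the top-k by document frequency.

    Frequency ties are broken lexicographically; zero-frequency and
    unembeddable terms are dropped.  A domain with fewer than k classified
    terms returns everything available with a warning.
    """
    if k_ai < 1 or k_bio < 1:
        raise ConfigurationError("k_ai and k_bio must be >= 1")
    classified: dict[str, list[KeywordEntry]] = {AI: [], BIO: []}
    for term in sorted(freqs):
        if freqs[term] <= 0 or term not in emb:
            continue
        domain, s_ai, s_bio = classify_domain(term, emb, lex)
        classified[domain].append(
            KeywordEntry(term, int(freqs[term]), domain, s_ai, s_bio)
        )

    selected: list[KeywordEntry] = []
    for domain, k in ((AI, k_ai), (BIO, k_bio)):
        pool = sorted(classified[domain], key=lambda e: (-e.frequency, e.term))
        if len(pool) < k:
            warnings.warn(
                f"only {len(pool)} {domain} terms available, requested {k}", stacklevel=2
            )
        selected.extend(pool[:k])
    selected.sort(key=lambda e: (-e.frequency, e.term))
    return KeywordSet(entries=selected, k_ai=k_ai, k_bio=k_bio)
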