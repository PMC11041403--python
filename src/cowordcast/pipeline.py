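"""End-to-end pipeline driver and its configuration object."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cooccurrence import CooccurrenceTensor, TimeBinning, count_tensor, order_axes
from .corpus_io import filter_span, load_merge_list, preprocess, read_corpus
from .embeddings import train_embeddings
from .errors import ConfigurationError, CowordcastError
from .forecast import BACKENDS, WindowSpec, recurrent_forecast
from .trends import growth_table, proportion_table
from .vocab import ReferenceLexicon, build_keyword_set, count_frequencies

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    corpus: str
    corpus_format: str
    bio_lexicon: str
    ai_lexicon: str
    outdir: str
    merge_list: str | None = None
    k_ai: int = 50
    k_bio: int = 100
    start: str = "2000-01"
    end: str = "2021-12"
    bin_months: int = 6
    include_title: bool = False
    min_count: int = 5
    dim: int = 300
    window: int = 5
    linkage: str = "average"
    backend: str = "elastic_net"
    forecast_window: int = 3
    horizon: int = 4
    growth_threshold: float = 10
    top_n: int = 20
    period_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.backend not in BACKENDS:
            raise ConfigurationError(
                f"unknown backend in field 'backend': {self.backend!r} (choose from {BACKENDS})"
            )

    @staticmethod
    def _parse_month(s: str) -> _dt.date:
        y, m = s.split("-")[:2]
        return _dt.date(int(y), int(m), 1)

    @property
    def span(self) -> tuple[_dt.date, _dt.date]:
        return self._parse_month(self.start), self._parse_month(self.end)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text(encoding="utf-8"))
        else:
            data = json.loads(path.read_text(encoding="utf-8"))
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(manifest: dict, name: str, **artifacts):
    manifest["stages"][name] = {k: str(v) for k, v in artifacts.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute ingest -> vocab -> embed -> tensor -> forecast -> trends.

    Every stage's artifacts are written under ``config.outdir`` and recorded
    in the returned manifest (also written as ``manifest.json``).  Any stage
    failure aborts with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {"cowordcast": __version__, "python": sys.version.split()[0]},
        "stages": {},
    }
    stage = "ingest"
    try:
        # --- ingest ------------------------------------------------------
        merge = load_merge_list(config.merge_list) if config.merge_list else []
        reader = read_corpus(config.corpus, config.corpus_format)
        start, end = config.span
        tokenized = [
            preprocess(doc, merge, include_title=config.include_title)
            for doc in filter_span(reader, start, end)
        ]
        if not tokenized:
            raise CowordcastError("no documents survived ingestion")
        tok_path = outdir / "tokens.jsonl"
        with open(tok_path, "w", encoding="utf-8") as fh:
            for doc in tokenized:
                fh.write(
                    json.dumps(
                        {"doc_id": doc.doc_id, "date": doc.date.isoformat(), "tokens": list(doc.tokens)}
                    )
                    + "\n"
                )
        _stage(manifest, "ingest", tokens=tok_path, n_docs=len(tokenized), n_skipped=reader.n_skipped)

        # --- vocab + embeddings -----------------------------------------
        stage = "embed"
        emb = train_embeddings(
            tokenized, dim=config.dim, window=config.window, seed=config.seed, min_count=config.min_count
        )
        emb_path = outdir / "vectors.txt"
        emb.save(emb_path)
        _stage(manifest, "embed", vectors=emb_path, vocab=len(emb))

        stage = "vocab"
        lex = ReferenceLexicon.from_files(config.bio_lexicon, config.ai_lexicon)
        candidates = {t for doc in tokenized for t in doc.tokens if t in emb}
        freqs = count_frequencies(tokenized, candidates)
        keywords = build_keyword_set(freqs, emb, lex, config.k_ai, config.k_bio)
        kw_path = outdir / "keywords.tsv"
        with open(kw_path, "w", encoding="utf-8") as fh:
            fh.write("term\tfrequency\tdomain\tmean_sim_ai\tmean_sim_bio\n")
            for row in keywords.to_rows():
                fh.write("\t".join(str(x) for x in row) + "\n")
        _stage(manifest, "vocab", keywords=kw_path, n_ai=len(keywords.ai_terms), n_bio=len(keywords.bio_terms))

        # --- tensor ------------------------------------------------------
        stage = "tensor"
        binning = TimeBinning(start, end, config.bin_months)
        ordering = order_axes(emb, keywords, linkage=config.linkage)
        tensor = count_tensor(tokenized, ordering, binning)
        tensor_dir = outdir / "tensor"
        tensor.to_dir(tensor_dir)
        docs_per_bin = np.zeros(binning.n_bins, dtype=np.int64)
        for doc in tokenized:
            docs_per_bin[binning.bin_of(doc.date)] += 1
        np.savetxt(outdir / "docs_per_bin.tsv", docs_per_bin, fmt="%d")
        _stage(manifest, "tensor", tensor=tensor_dir, shape="x".join(map(str, tensor.counts.shape)))

        # --- forecast ----------------------------------------------------
        stage = "forecast"
        spec = WindowSpec(config.forecast_window)
        start_bin = max(2, binning.n_bins - config.horizon)
        run = recurrent_forecast(
            tensor, start_bin=start_bin, horizon=config.horizon, backend=config.backend, spec=spec, seed=config.seed
        )
        fc_path = outdir / "forecast.json"
        fc_path.write_text(
            json.dumps(
                {
                    "backend": run.backend,
                    "window": run.window.w,
                    "seed": run.seed,
                    "start_bin": run.start_bin,
                    "r2_trace": {str(k): v for k, v in run.r2_trace.items()},
                },
                indent=1,
            ),
            encoding="utf-8",
        )
        for t, mat in run.predictions.items():
            np.savetxt(outdir / f"pred_bin_{t:03d}.tsv", mat, delimiter="\t", fmt="%.6f")
        _stage(manifest, "forecast", run=fc_path, n_predicted=len(run.predictions))

        # --- trends ------------------------------------------------------
        stage = "trends"
        n_period = min(config.period_bins, max(1, binning.n_bins // 2))
        recent = list(range(binning.n_bins - n_period, binning.n_bins))
        past = list(range(binning.n_bins - 2 * n_period, binning.n_bins - n_period))
        prop = proportion_table(tensor, recent, docs_per_bin[recent], top_n=config.top_n)
        prop.to_tsv(outdir / "proportion.tsv")
        growth = growth_table(tensor, past, recent, threshold=config.growth_threshold, top_n=config.top_n)
        growth.to_tsv(outdir / "growth.tsv")
        _stage(manifest, "trends", proportion=outdir / "proportion.tsv", growth=outdir / "growth.tsv")
    except Exception as exc:
        raise CowordcastError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
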