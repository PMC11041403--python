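# cowordcast

Background-enhanced forecasting of co-word trends in the biomedical / AI
literature.

`cowordcast` builds time-binned co-occurrence matrices of AI keywords ×
biomedical keywords from dated abstract corpora, orders the keyword axes by
agglomerative clustering of word embeddings (so semantically similar terms
sit on adjacent rows/columns), and forecasts each cell's future "heat" from
the w×w spatial window around it in the previous half-year — the idea being
that a technique's neighbours in embedding space carry predictive signal for
the technique itself. It also derives ranked trend tables (proportion of
publications, percentage growth) from observed or predicted tensors.

## What's in the box

| module | role |
|---|---|
| `cowordcast.corpus_io` | read MEDLINE XML / TSV / JSON-lines corpora; preprocessing with multiword-phrase merging (`machine learning` → `machine+learning`) |
| `cowordcast.vocab` | document-frequency keyword ranking; AI-vs-biomedical domain assignment by mean cosine similarity against two reference lexicons |
| `cowordcast.embeddings` | deterministic PPMI + truncated-SVD word vectors (dim 300, window 5 defaults); cosine similarity; t-SNE projection |
| `cowordcast.cooccurrence` | semiannual time binning, dendrogram leaf ordering of axes, the co-occurrence tensor, log-heat transform |
| `cowordcast.forecast` | windowed feature extraction, six regression backends (SVR, lasso, ridge, elastic net, OMP, passive-aggressive), train-on-all-prior evaluation, recurrent multi-step forecasting, window-size sweeps |
| `cowordcast.trends` | ranked proportion / growth tables with threshold filtering; difference matrices |
| `cowordcast.synthetic` | scenario-driven synthetic corpora and tensors with known Poisson intensities (everything is testable offline) |
| `cowordcast.viz` / `cowordcast.cli` / `cowordcast.pipeline` | plots (heatmaps with optional dendrogram margins, R² traces), the `cowordcast` CLI, and the end-to-end pipeline driver |

## CLI quick start

Everything below runs offline on synthetic data:

```bash
# 1. generate a synthetic corpus with planted co-occurrence dynamics
cat > scenario.json <<'EOF'
{"k_ai": 5, "k_bio": 8, "bins": 8, "base_rate": 4.0,
 "pair_jitter": 0.6, "spatial_corr": 0.4, "seed": 1}
EOF
cowordcast simulate --scenario scenario.json -o corpus.jsonl --truth truth/

# 2. ingest -> embed -> vocab -> tensor -> forecast -> trends
cowordcast ingest corpus.jsonl --format jsonl --merge-list merge.txt \
    --from 2000-01 --to 2003-12 -o tokens.jsonl
cowordcast embed tokens.jsonl --dim 64 --window 5 --min-count 1 -o vectors.txt
cowordcast vocab tokens.jsonl --vectors vectors.txt \
    --bio-lexicon bio.txt --ai-lexicon ai.txt --k-ai 5 --k-bio 8 -o keywords.tsv
cowordcast tensor tokens.jsonl --vectors vectors.txt --keywords keywords.tsv \
    --from 2000-01 --to 2003-12 -o tensor/
cowordcast forecast tensor/ --backend elastic_net --window 3 --horizon 4 -o fc/
cowordcast trends tensor/ --metric growth --past 0:3 --recent 4:7 \
    --threshold 5 -o growth.tsv
cowordcast plot heatmap --tensor-dir tensor/ --dendrograms -o heat
```

Or drive the whole chain from one config file:

```bash
cowordcast run --config config.json   # see cowordcast.pipeline.RunConfig fields
```

## Notes

- Embeddings are trained with a PPMI + truncated-SVD factorization (the
  classical count-based equivalent of skip-gram with negative sampling)
  rather than an SGD trainer: it is fully deterministic under a fixed seed,
  which the forecasting tests and run manifests rely on. Vectors round-trip
  through the standard word2vec text and binary formats.
- The historical `normalize=True` option of lasso/ridge is reproduced as an
  explicit per-column standardization step in their pipelines.
- Recurrent forecasts fit the model once on observed transitions; predicted
  matrices are only ever used as features, never as training targets.
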