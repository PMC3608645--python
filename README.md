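# ragscore

Cross-study consensus scoring of curated endometrial gene lists. Given a
corpus of per-dataset gene calls (expressed / not detected / upregulated /
downregulated), `ragscore` computes vote-counting reliability scores (2
points per supporting dataset, opposing calls scored separately), combines
status and pattern scores into cumulative scores, and classifies
consistently-behaving genes into two sets:

* **Up-Ex** — consistently expressed and upregulated in the first condition
  of a comparison (e.g. receptive vs pre-receptive endometrium),
* **Down-Nd** — consistently not detected and downregulated.

It also identifies reference Up-Ex genes contradicted in a case cohort (e.g.
IVF failure), ships a synthetic-corpus generator with known ground truth for
parameter-recovery testing, and includes small qPCR (2^-ddCt) and
spheroid-attachment utilities.

The published 151-gene Up-Ex and 28-gene Down-Nd reference tables are
packaged under `src/ragscore/data/` and loadable with
`ragscore.load_fixture_tables()`.

## Library overview

| Module | Purpose |
| --- | --- |
| `ragscore.genelists` | TSV/CSV gene-list ingestion, validation, symbol/condition harmonization, JSON corpus persistence, packaged reference tables |
| `ragscore.scoring` | `score_status`, `score_pattern`, `cumulative_scores`, `score_all` |
| `ragscore.rags` | cohort filtering, Up-Ex / Down-Nd derivation, suboptimal-subset, ranked table export |
| `ragscore.simulate` | synthetic corpora with ground truth, recovery metrics, closed-form survival |
| `ragscore.quant` | `delta_ct`, `relative_expression` (2^-ddCt), `percent_attached`, `percent_reduction` |

```python
import ragscore as rs

corpus = rs.harmonize_corpus(rs.read_corpus("corpus.json"))
result = rs.derive_rags(corpus, "receptive_vs_pre_receptive")
rs.export_rag_tables(result, "out/")
```

## CLI

```sh
# simulate a corpus with known ground truth
ragscore simulate --n-genes 500 --n-datasets 12 --p-flip 0.1 --seed 7 \
    --out corpus.json --truth truth.json

# per-gene score table
ragscore score --corpus corpus.json \
    --comparison receptive_vs_pre_receptive --out scores.tsv

# classify and export ranked Up-Ex / Down-Nd tables
ragscore rags --corpus corpus.json --cohorts healthy --out-dir out/

# reference Up-Ex genes contradicted in a case cohort
ragscore suboptimal --reference out/up_ex.tsv --case-corpus ivf.json

# relative expression against a calibrator sample
ragscore qpcr --input ct_table.tsv --calibrator control --out re.tsv
```

Gene-list files are TSV (comma auto-detected) with a header and columns
`symbol`, `call` (one of `expressed`, `not_detected`, `up`, `down`), plus
optional `condition` and `comparison` (`receptive_vs_pre_receptive`)
columns. Corpora persist as schema-versioned JSON.

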