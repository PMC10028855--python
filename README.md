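# sigcompass

A toolkit for scoring, quality-checking and comparing cancer transcriptional
signatures on bulk, single-cell and spatial expression data.

It ships:

- **catalog** — a packaged, queryable catalog of 47 literature signature
  entries (topic, tumor types, author, reference, input types), with full
  gene lists for a 12-signature subset covering all six scoring method
  families.  Users can register their own signatures; each is validated
  against explicit inclusion criteria (clear gene list with well-formed
  symbols, unambiguous method, declared input scale).
- **expression** — readers for dense TSV/CSV tables and sparse 10x-style
  triplet directories (Matrix Market + features + barcodes, optional spot
  positions), gene-ID translation, metric conversion (counts→CPM,
  FPKM→TPM, any→log2(x+1)), and score attachment/export.
- **scoring** — six method families with a single dispatch entry point:
  weighted sum, z-score mean, up-minus-down mean, single-sample rank
  enrichment (ssGSEA-style, full-genome background, alpha=0.25),
  four-category immunophenoscore composite, and centroid-correlation
  consensus subtyping.  Coverage (% of signature genes present) is always
  tracked; scoring is refused below a configurable minimum (default 5%).
- **qc** — five per-signature reliability metrics (mean signature-gene
  expression per observation, % zeros per observation, score vs total
  counts correlation, score vs %-zero correlation, % genes used) and a
  filtering rule that drops signatures with median zeros > 90% **and**
  genes used < 30%.
- **compare** — score correlation matrix, complete-linkage clustering of
  its rows (Euclidean distances), silhouette-based choice of k, median-split
  Kaplan–Meier / log-rank survival association, and Welch t-tests between
  annotated groups with BH adjustment.
- **synthetic** — negative-binomial bulk, dropout-inflated single-cell and
  grid-based spatial simulators with planted signature signal plus truth
  tables, and a generator of random valid catalogs (one signature per
  method family).

## CLI

```sh
# query the packaged catalog
sigcompass list --tissue ovarian --no-include-pan

# simulate a dataset from a design file
sigcompass simulate --design design.json --out sim/

# score signatures (dense or 10x input)
sigcompass score --input sim/matrix.tsv --metric counts \
    --catalog my_catalog/ --out run/

# signature quality check
sigcompass qc --input sim/matrix.tsv --scores run/scores.tsv --out run/ \
    --max-pct-zero 90 --min-genes-used 30

# cross-signature comparison (+ optional survival / group tests)
sigcompass compare --scores run/scores.tsv \
    --survival survival_time,survival_event --groups group --out run/

# figures from the tables of a run directory
sigcompass render --dir run/
```

Every artifact-producing run writes its resolved configuration
(`run_config_<subcommand>.json`) next to the outputs, so results can be
reproduced exactly.  All tables are TSV; figures are PNG + SVG.

## Notes on the packaged catalog

Catalog metadata (names, topics, tumor types, authors, references, input
types) is transcribed from the published collection table.  Gene lists are
packaged only for a subset of signatures; where the original publication's
exact list could not be transcribed verbatim, a representative list of the
documented length for that biological program is provided.  Entries without
a packaged gene list carry `genes_available=false`: they are returned by
metadata queries but refuse scoring with a clear error.  The catalog format
is one JSON file per signature plus an index, so adding signatures is a
matter of dropping in a file and listing it in the index.
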