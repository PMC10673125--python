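# metpath

Benchmark pipeline for predicting the **metabolic pathway involvement of
metabolites** from their molecular structure.

Public metabolite databases link only a fraction of known compounds to the
pathways they participate in, which hinders the metabolic interpretation of
metabolomics experiments.  A practical remedy is to train per-pathway
binary classifiers on the compounds whose involvement *is* recorded and
predict the rest.  `metpath` implements the full benchmarking pipeline for
that task — from raw molfiles to weighted performance tables — and ships a
synthetic-data generator so every stage is testable end-to-end without any
database download.

## What it computes

**Features.**  Each compound's V2000 molfile becomes a heavy-atom graph;
R-group (`R`) and repeat-unit (`*`) placeholder atoms are replaced by
carbon (their flags are kept — such *ambiguous* compounds are evaluated on
but never trained on).  For every atom and every bond inclusivity
k = 0..3, a canonical **atom color** string encodes the atom's element and
chirality plus its bonded neighborhood out to k bonds, including bond
orders and stereo.  Counting colors per compound and concatenating the
k-levels yields the feature matrix; value-duplicate columns are dropped.

**Dataset.**  Compounds are labeled with the 12 broad metabolism
categories sitting above their pathway leaves; entries with equivalent
molfiles are merged with label union; compounds with fewer than a
threshold number of non-hydrogen atoms are filtered out, the threshold
being the first local minimum of a sliding-window misclassification-rate
analysis; a semi-automated curation step handles duplicate feature
vectors and keyword-flagged macromolecules.

**Benchmark.**  Random forest, XGBoost and an MLP (the latter on features
compressed to 10% width by a bottleneck autoencoder) are trained per
category and per training dataset (full / non-ambiguous) — 72 classifiers
under the defaults — each over repeated stratified 95/5 train/test splits.
Per fold and test partition the pipeline records accuracy, precision,
recall, F1, MCC and unit-normalized MCC with zero-denominator validity
flags, then aggregates with category-proportion weights.  Relative feature
importances (per-fold max-normalized, median across folds) and
presence-odds ratios connect predictions back to substructures.

See [docs/methods.md](docs/methods.md) for the model and its assumptions.

## Worked example

Ethanol's heavy-atom graph is the chain C–C–O.  At bond inclusivity 0 its
atom colors are just elemental identities — the non-hydrogen formula — and
at inclusivity 1 each atom sees its bonded neighbors:

```python
from metpath import parse_molfile
from metpath.atom_coloring import compute_color_counts

ethanol = """ethanol\n\n\n  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
"""
g = parse_molfile(ethanol, "ethanol")
for k in (0, 1):
    vec = compute_color_counts(g, k)
    print(f"k={k}:", {c.canonical: n for c, n in vec.counts.items()})
```

prints

```
k=0: {'C0': 2, 'O0': 1}
k=1: {'C0(C0.10)': 1, 'C0(C0.10)(O0.10)': 1, 'O0(C0.10)': 1}
```

— two carbon colors and one oxygen color at k=0, and at k=1 the three
neighborhood colors of the chain: the terminal carbon bonded to a carbon
(`C0(C0.10)`), the central carbon bonded to a carbon and an oxygen, and
the oxygen bonded to a carbon.  The trailing digit on each atom is its
chirality code (0 = achiral) and `.10` is the connecting bond's
order/stereo descriptor (single bond, no stereo).

## Running the pipeline

The `metpath` command chains the stages
fixtures → build → filter → benchmark → report, with per-stage provenance
(input/output checksums, seed, version) and `--resume` support:

```bash
metpath -v run-all --seed 0 --out runs/demo
metpath -v run-all --manifest manifest.yaml --out runs/custom --resume
```

Individual stages are exposed as `make-fixtures`, `featurize`,
`build-dataset`, `info-filter`, `run-benchmark` and `report`; each is a
thin wrapper over the library API in `metpath.*`.

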