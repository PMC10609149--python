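# metabotree

Two-stage hierarchical classification of lung-cancer type from metabolite
molecular descriptors.

Samples (metabolites) carrying per-metabolite p-values, fold changes and
class labels are filtered for significance (p ≤ 0.05, fold change ≥ 1.2),
turned into a real-valued descriptor matrix, min–max normalized, reduced to
a small set of informative features by discretized information gain, and
embedded into 2–3 dimensions by PCA (covariance eigendecomposition) or a
from-scratch t-SNE. A tree of two small feedforward neural networks then
classifies each sample: stage 1 separates non-small-cell (NS) from
small-cell (SC) carcinoma; samples predicted NS are routed to stage 2,
which separates adenocarcinoma (AD) from squamous cell carcinoma (SQ).
Stage accuracies combine into a weighted overall accuracy

```
overall = SC% · stage1_acc + NS% · stage1_acc · stage2_acc
```

and a flat (naive) multiclass classifier over the leaf classes is provided
as the comparison baseline. A seeded synthetic-data generator produces
hierarchical descriptor datasets (optionally with a nonlinear, concentric-
shell top split) so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic dataset (table + descriptor matrix)
metabotree simulate --seed 1 --out data/            # add --paper-scale for 1083 dims

# 5-fold cross-validated two-stage evaluation + artifacts
metabotree run --table data/metabolites.csv --matrix data/descriptors.csv \
    --config config.json --out results/

# individual protocols
metabotree cv       --table data/metabolites.csv --matrix data/descriptors.csv
metabotree baseline --table data/metabolites.csv --matrix data/descriptors.csv
metabotree evaluate --train-table train.csv --test-table test.csv

# direct overall-accuracy combiner
metabotree combine-accuracy --stage1 0.962 --stage2 0.911 --ns-frac 0.487 --sc-frac 0.513
```

Configuration is a JSON file; every omitted field takes a documented
default (`metabotree.config.PipelineConfig`). Example:

```json
{
  "filter": {"p_max": 0.05, "fc_min": 1.2},
  "select": {"k": 170},
  "stage1": {"dimred": "tsne", "tsne": {"perplexity": 10, "n_iter": 1000}},
  "stage2": {"dimred": "tsne"},
  "mlp": {"hidden_sizes": [300, 400, 300], "dropout": 0.5, "epochs": 500},
  "eval": {"k_folds": 5, "seed": 1}
}
```

Every run is deterministic given the config seeds; `run` writes a resolved
`config_echo.json` sufficient to reproduce the report bit-for-bit.

Because t-SNE has no native out-of-sample transform, evaluation protocols
support two policies per stage (`oos`): `transductive` (default — train and
test rows embedded jointly with test labels hidden) and `knn_map` (test
points placed at the distance-weighted mean of their nearest training
embeddings).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form
arithmetic checks, oracle-equivalence and t-SNE law suites, synthetic
recovery, determinism, and the 1083 → 170 feature-selection path).

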