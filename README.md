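# cardiodx

Clinical tabular classification pipeline: K-means noise filtering,
regularized (kernel) discriminant feature extraction, and a spectral
polynomial graph convolutional classifier with a normalized-min-cut
auxiliary loss. Runs end-to-end on synthetic two-class Gaussian tables or
on files in the UCI heart-disease "processed" CSV dialect (14 columns,
`?` for missing values, integer target 0–4 in the last column).

## Layout

| Module | Responsibility |
| --- | --- |
| `cardiodx.datakit` | UCI-dialect I/O, target binarization, imputation, standardization, synthetic data generation, stratified splits |
| `cardiodx.cluster_denoise` | Lloyd K-means (seeded restarts), nearest-centroid assignment, distance-quantile noise filtering |
| `cardiodx.lqda` | Between/within-class scatter, whitening basis, Gram matrices, kernel between-class basis, (α,γ)-regularized class covariances, Mahalanobis/Bayes rule |
| `cardiodx.graphnet` | Gaussian kNN patient graph, graph Fourier transform, spectral and polynomial Laplacian filters, GCN layers, edge-gated multi-head attention, cut / normalized-cut / differentiable min-cut losses, transductive training (numpy backprop) |
| `cardiodx.pipeline` | Stage orchestration, confusion metrics, ROC AUC, dataset summaries, deterministic run reports |
| `cardiodx.cli` | `cardiodx` command group |

## CLI

```bash
# full pipeline from a YAML config; JSON report + per-epoch metrics CSV
cardiodx run --config cfg.yaml --out report.json --metrics-csv metrics.csv

# synthetic two-class table in the processed CSV dialect
cardiodx simulate --n-per-class 200 200 --separation 4.0 --seed 1 --out sim.csv

# K-means noise report (removed rows: index, distance, cluster)
cardiodx cluster --data sim.csv --k 8 --quantile 0.95 --out removed.csv

# discriminant features with labels
cardiodx features --data sim.csv --kernel rbf --out features.csv

# graph classifier on an extracted-feature CSV
cardiodx train --features-csv features.csv --epochs 500 --log-csv log.csv

# per-class counts and prevalence percentages
cardiodx report --data sim.csv
```

A minimal config:

```yaml
seed: 1
data:
  kind: synthetic        # or "uci" with path: processed.csv
  n_per_class: [200, 200]
  separation: 4.0
train:
  epochs: 500
  checkpoints: [100, 200, 300, 400, 500]
```

All stages draw randomness from the single `seed`; identical configs give
byte-identical reports.

## Notes

- The pipeline is transductive: train and test samples share one
  similarity graph; only training labels contribute to the loss.
- The polynomial filter route never eigendecomposes the Laplacian; its
  equivalence with the exact spectral route (and its K-hop locality) are
  asserted in the acceptance suite.
- `--classifier lqda` switches the pipeline to the Mahalanobis/Bayes
  classifier on the discriminant features, with `d_0 - d_1` as the ROC
  score.
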