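# mokpe

Kernel-preserving embedding of drug–target interaction networks on Stiefel
manifolds.

Drugs and protein targets are projected into one low-dimensional Euclidean
space such that Gaussian kernel values between embedded points reproduce
(i) observed drug–target interaction scores, (ii) drug–drug chemical
similarities, and (iii) target–target sequence similarities.  Each coordinate
block is constrained to a Stiefel manifold (orthonormal columns) and trained
by alternating Riemannian limited-memory BFGS solves.  Unseen drugs are
placed into a trained embedding out-of-sample from their similarity profile
alone, which supports cold-start interaction prediction; novel interactions
within a network are ranked by embedded Euclidean distance.

## Library overview

| module            | contents |
|-------------------|----------|
| `mokpe.stiefel`   | Stiefel geometry (random point, tangent projection, QR retraction) and the Riemannian LBFGS / steepest-descent optimizers |
| `mokpe.scoring`   | interaction-score construction (0.9 / missing), Jaccard substructure similarity, (normalized) Smith–Waterman, sparsity statistics |
| `mokpe.model`     | the embedding objective, analytic gradients, alternating `fit`, out-of-sample `embed_new_drug`, `predict_pair_scores` |
| `mokpe.evaluation`| drug-wise cross-validation (`cross_validate`), tie-exact AUROC/AUPRC, `rank_novel_pairs` |
| `mokpe.synthetic` | planted-geometry network generator and mutated-sequence generator for fully offline testing |
| `mokpe.io_cli`    | labeled tab-delimited matrix readers/writers and the `mokpe` command line |

```python
from mokpe import (EmbeddingConfig, SyntheticSpec, cross_validate,
                   fit, generate_network)

network, latent = generate_network(SyntheticSpec(n_drugs=54, n_targets=26,
                                                 R_true=5, seed=1))
result = cross_validate(network, EmbeddingConfig(R=5), folds=10, reps=1, seed=1)
print(result.summary)
```

## Command line

Input matrices are tab-delimited with row labels in the first column and
column labels in the first row (the dialect of the public gold-standard
distribution).  The adjacency file may be oriented either way; it is aligned
against the similarity files on load.

```sh
mokpe simulate --n-drugs 54 --n-targets 26 --r-true 5 --outdir sim/
mokpe fit  --adjacency sim/adjacency.tsv --sim-drugs sim/sim_drugs.tsv \
           --sim-targets sim/sim_targets.tsv --R 5 --outdir fit/
mokpe cv   --adjacency sim/adjacency.tsv --sim-drugs sim/sim_drugs.tsv \
           --sim-targets sim/sim_targets.tsv --R 5 --folds 10 --reps 10 \
           --outdir cv/
mokpe rank --adjacency sim/adjacency.tsv --sim-drugs sim/sim_drugs.tsv \
           --sim-targets sim/sim_targets.tsv --R 2 --k 25 --outdir rank/
mokpe predict --adjacency ... --profiles new_drugs.tsv --outdir pred/
```

Every run writes a `run_manifest.json` (parameter echo, seeds, versions).
Model parameters can also come from a YAML file via `--config`; explicit
flags win.

## Tests and acceptance report

```sh
python -m pytest -q                       # full suite, a couple of minutes
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the benchmark sparsity levels from the
published drug/target/interaction counts and reports the synthetic
structure-recovery AUROC of the full cold-start pipeline.  Reproducing the
published cross-validation metrics requires downloading the gold-standard
data sets; `tests/test_acceptance.py::test_criterion_9_*` documents that
protocol and runs it when `MOKPE_DATA_DIR` points at the files.

## Notes

- Kernel widths default to a scale-aware value per term,
  sigma = sqrt(2 R / N), matching the typical squared inter-point distance of
  Stiefel-constrained rows; override with `EmbeddingConfig(sigma=...)`.
- Because a Stiefel block carries total column energy R, embeddings at
  different R do not nest; training loss is guaranteed non-increasing in R
  only up to the intrinsic dimensionality of the data.
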