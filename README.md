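# csfsub

Molecular subtype discovery for TMT cerebrospinal-fluid proteomics cohorts.

The package implements an end-to-end, fully seeded subtype-discovery
pipeline for multiplexed (TMT) proteomics data, together with a synthetic
cohort generator so that every stage is testable without access-controlled
patient data:

1. **`csfsub.io`** — tabular I/O and validation for intensity matrices,
   16-channel plex layouts (14 samples + 2 pooled reference channels) and
   sample metadata; a linear MAPT-to-t-tau assay harmonization helper.
2. **`csfsub.simulate`** — synthetic cohorts with planted subtypes
   (up/down-shifted protein signatures), multiplicative per-plex and
   per-channel batch factors, reference channels built as the pooled mean of
   each plex, whole-plex missingness blocks, replication cohorts sharing the
   discovery signatures, and a subtype-recovery power analysis.
3. **`csfsub.normalize`** — two-step internal reference scaling (per-channel
   median matching within plexes, then per-protein geometric-mean reference
   factors across plexes), followed by log2 transform and z-scaling to the
   control group, with exclusion provenance.
4. **`csfsub.select`** — Kruskal–Wallis screening of fully observed proteins,
   overall and stratified by cognitive state and tau status, selecting the
   union of any-stratum significance.
5. **`csfsub.subtype`** — consensus clustering by multiplicative-update NMF
   (generalized Kullback–Leibler objective; Frobenius behind a flag) on
   [1, 2]-rescaled proteins; per-rank consensus matrices, cophenetic
   coefficients, consensus silhouettes and fit-improvement ratios against a
   column-permuted random reference; admissible ranks need silhouette > 0.5
   and at least twofold improvement, and the largest admissible rank is
   selected; dual patient/protein labels via argmax of H / W.
6. **`csfsub.coexpression`** — Louvain communities (resolution 1.15) on the
   truncated-positive Pearson coexpression network as a robustness check,
   with exact maximum-assignment cluster overlap.
7. **`csfsub.profiling`** — per-protein OLS contrasts vs controls with
   estimated marginal means, optional age/sex adjustment and a
   ≥5-observations-per-group inclusion rule; generic term-set
   over-representation with one-sided hypergeometric tests and
   Benjamini–Hochberg FDR.
8. **`csfsub.transfer`** — nested protein panels matched to replication
   cohorts, SCUT (SMOTE + cluster-centre undersampling) class balancing,
   repeated 80/20 random-forest training, and probability-averaged subtype
   prediction for replication samples.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (model-selection
recovery on a 5-subtype synthetic cohort, worked-example exactness, oracle
equivalence of the statistical primitives, normalization invariants,
parameter/transfer recovery and CLI determinism); the remaining modules are
unit and property tests. The full suite takes a few minutes; the
acceptance module dominates the runtime.

## CLI

All subcommands accept `--seed`, `--config` (YAML overrides) and
`--log-level`, and are bit-reproducible for a fixed seed:

```sh
csfsub simulate  --out cohort/ --seed 1 --config cfg.yaml
csfsub normalize --in cohort/intensities.tsv --layout cohort/layout.tsv \
                 --meta cohort/metadata.tsv --out norm.tsv --report report.json
csfsub select    --in norm.tsv --meta cohort/metadata.tsv --alpha 0.05 \
                 --out selection.tsv
csfsub subtype   --in norm.tsv --meta cohort/metadata.tsv \
                 --selection selection.tsv --kmin 2 --kmax 10 --runs 30 \
                 --seed 1 --out model/
csfsub robustness --norm norm.tsv --meta cohort/metadata.tsv --model model/ \
                  --resolution 1.15 --seed 1 --out overlap.json
csfsub profile   --norm norm.tsv --labels model/patient_labels.tsv \
                 --meta cohort/metadata.tsv --covariates age,sex --out profile/
csfsub transfer  --discovery-norm norm.tsv --labels model/patient_labels.tsv \
                 --replication rep_norm.tsv --replication-meta rep_meta.tsv \
                 --repeats 100 --ntree 1000 --seed 1 --out predictions.tsv
```

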