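# reprophen

Analysis pipeline for high-content RNAi screens of early cellular
reprogramming. When fibroblasts are reprogrammed to induced pluripotent stem
cells (iPSCs) by OSKM induction, knocking down individual chromatin factors
changes the morphology, marker expression and number of the nascent
colonies. `reprophen` implements the quantitative analysis of such a screen
end to end, together with synthetic-data generators that carry planted
ground truth so every stage can be tested for parameter recovery:

* **Plate normalization** — per-plate Z-scores of every colony feature
  (`z = (x − μ_plate)/σ_plate`, sample SD), replicate averaging per
  knockdown, and greedy elimination of redundant features (pairwise Pearson
  `|r| > 0.8`).
* **Phenotype clustering** — K-means over knockdown feature profiles
  (default `k = 5`) with Euclidean average-linkage ordering of the features,
  and a cluster report that flags the cluster holding most non-targeting
  (nt) controls as the "normal reprogramming" reference.
* **Hit ranking** — Pearson correlation of every knockdown profile with the
  positive-control profiles (Trp53, Myc, Oct4), combined into one score,
  plus a facilitator-probability from an ensemble of two classifiers
  (regularized logistic regression and a random forest) trained on known
  reprogramming facilitators; hits are selected in this 2-D score space.
* **Transcriptome correlation** — CPM + log2 normalization, the top 200
  most-variable transcripts, replicate-averaged knockdown-to-knockdown
  Pearson matrices, and a cross-modal table pairing expression and
  high-content correlations per knockdown pair.
* **Pseudotime projection** — PCA of all transcriptomes with axes swapped
  (x = PC2, the component that tracks time), a 15° rigid rotation, an OLS
  second-order polynomial `y = c₀ + c₁x + c₂x²` fitted to the reprogramming
  time course (days 2–7), and exact orthogonal projection of every sample
  onto that curve (global minimum of the quartic squared-distance via its
  cubic stationarity condition). The projected x is a pseudotime proxy; the
  distance to the curve measures expression change unrelated to
  progression.
* **Epistasis testing** — colony ratios of single and double knockdowns
  against the control mean; under independent effects the expected double
  ratio is the product of the single ratios
  (`E[AB] = r_A · r_B`), and a two-tailed t test of observed − expected
  (with delta-method propagation of the expected product's sampling
  uncertainty) calls functional interactions.

## Worked example

The one-command demo generates a full synthetic study — a 6-plate, 300-gene
screen in quadruplicate with 5 planted phenotype classes, a day 0–7
transcriptome time course with 30 knockdowns planted at known progression
points, and single/double-knockdown colony counts under a multiplicative
interaction model — runs every stage, and scores the results against the
planted truth:

```sh
reprophen demo --seed 1 --out demo_out
```

prints

```json
{
  "seed": 1,
  "config_hash": "7a590d28a22a",
  "cluster_ari": 1.0,
  "blocker_top_decile_recall": 1.0,
  "facilitator_cv_auc": 1.0,
  "pseudotime_spearman": 0.9994437707856938,
  "offset_distance_pearson": 0.982238621709806,
  "epistasis_null_rejection_rate": 0.046,
  "n_retained_features": 16,
  "reference_cluster": 1,
  "n_significant_interactions": 3,
  "runtime_seconds": 3.24
}
```

Reading the numbers: the K-means clusters reproduce the planted phenotype
classes exactly (`cluster_ari = 1`, adjusted Rand index); every planted
"blocker" (a knockdown with a control-like severe-impairment phenotype)
lands in the top decile of the combined control-correlation score
(`recall = 1`); the facilitator ensemble separates planted facilitators
perfectly in cross-validation (`AUC = 1`); the projected pseudotime orders
the knockdowns almost exactly as planted (Spearman ρ = 0.999) and the
residual distance to the fitted time curve recovers the planted
off-trajectory offsets (Pearson r = 0.98); the epistasis test rejects at
4.6% under the simulated no-interaction null (nominal α = 5%) and detects
all three planted interactions (`n_significant_interactions = 3`).
Intermediate tables (profiles, cluster labels, ranking, progression report,
interaction tests) are written under `demo_out/`, each stamped with the
config hash and seed.

Individual stages are available as subcommands on plain TSV files:
`reprophen simulate|normalize|cluster|rank|txome|project|epistasis`.

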