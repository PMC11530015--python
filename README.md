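# premls

Multi-label prediction of concurrent lysine post-translational
modifications — acetylation (A), crotonylation (C), methylation (M) and
succinylation (S) — at a single residue, from sequence context alone.

A lysine site can carry several of these modifications at once
("crosstalk"), so the problem is multi-label: each site maps to a binary
flag vector (A, C, M, S) drawn from 11 admissible combination categories
(A, C, M, S, AC, AM, AS, CM, ACM, ACS, ACMS). Site inventories are
dominated by acetyl-only sites (>70% of annotated sites), so the package
couples the classifier with a prototype-generation undersampler for the
majority category. It is intended for computational biologists triaging
candidate modification sites ahead of mass-spectrometry validation.

## Method

1. **Windowing** — each annotated lysine becomes a 49-mer
   `s[p−24 .. p+24]` centered on K, padded with `X` at termini; duplicate
   windows are merged (modification sets unioned) and each window is
   assigned one of the 11 categories.
2. **MLPSTAAP encoding** (multi-label position-specific triad amino-acid
   propensity) — with the central K removed, a window is a 48-residue
   context with 46 overlapping triads. Per category *t*, the matrix
   `F_t ∈ R^{8000×46}` holds the frequency of triad *i* at position *j*;
   `FF_t` is the same count over the other 10 categories pooled. With
   `F = mean_t F_t` and `FF = mean_t FF_t`, the propensity matrix is
   `F_MLPSTAAP = F − FF`, and a window encodes to the 46-vector
   `x_j = f_{r(c_j), j}` where `r` is the triad row index
   `r(a1 a2 a3) = 400·rank(a1) + 20·rank(a2) + rank(a3) + 1` over the
   alphabet `A C D E F G H I K L M N P Q R S T V W Y`
   (so `r("AGA") = 101`, `r("GAT") = 2017`).
3. **ClusterCentroids undersampling** — the majority category's *N*
   feature vectors are replaced by `k = max(1, round(ratio·N))` mini-batch
   k-means centroids (default ratio 0.1), which become synthetic majority
   prototypes; all other categories pass through untouched.
4. **Classifier** — a 1-D CNN (four conv→ReLU→max-pool blocks, channels
   16/32/64/128, then one dense layer) maps the 46 features to four
   sigmoid probabilities, trained with mean binary cross-entropy; a flag
   is set when its probability ≥ 0.5.
5. **Evaluation** — Chou's five set-based multi-label metrics (Aiming,
   Coverage, Accuracy, Absolute-True, Absolute-False with M = 4), a
   per-category Absolute-True breakdown, stratified 5-fold
   cross-validation, and an undersampling-ratio sweep. Propensity fitting
   and undersampling happen inside each training fold only.

A seeded synthetic-data module generates benchmark datasets with the
reference category imbalance and planted per-modification-type sequence
determinants, so the whole pipeline is testable without any database
download.

## Worked example

```sh
premls simulate --out-fasta synth.fasta --out-annotations synth.tsv --scale 0.05 --seed 7
premls fit --fasta synth.fasta --annotations synth.tsv --out-dir run \
       --seed 7 --epochs 20 --batch-size 32 --category-floor 1
premls evaluate --model run/model.npz --fasta synth.fasta \
       --annotations synth.tsv --out metrics.json --category-floor 1
premls predict --model run/model.npz --fasta synth.fasta --sites synth.tsv --out pred.tsv
```

`simulate` writes 659 synthetic windows (category ratio scaled from the
reference inventory, majority acetyl-only). `fit` trains the full pipeline
(windowing → propensity fit on the 70% training split → encoding →
undersampling at ratio 0.1 → CNN) and stores a single `model.npz` artifact
plus a provenance record. `evaluate` prints the five metrics on the given
data — here, with training-set windows included:

```json
{
  "aiming": 0.9646,
  "coverage": 0.9958,
  "accuracy": 0.9635,
  "absolute_true": 0.9256,
  "absolute_false": 0.0193
}
```

Absolute-True 0.93 means 93% of sites had their full modification set
predicted exactly; Absolute-False 0.02 is the mean per-site fraction of
wrong flags. `predict` emits one row per queried site:

```
Sample          Results  pA       pC        pM        pS        Targets
synth_c1_0:25   A        0.99727  0.000196  0.000123  0.007386  A
```

The same experiment harness is available from Python
(`premls.cross_validate`, `premls.ratio_sweep`) for the cross-validated
ratio experiments.

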