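# barcode-eval

Tools for assessing how well candidate DNA-barcode markers (COI, 16S rDNA,
ITS2, 12S rDNA) identify species — built around the questions a reference
library curator has to answer: how divergent are conspecific versus
congeneric sequences, where should the species boundary sit, which decision
rule identifies queries most reliably, and which unverified public sequences
can be trusted?

The package implements, for aligned marker datasets with species metadata:

* **K2P distances** with pairwise deletion. For transition proportion *P*
  and transversion proportion *Q* over the comparable sites of a pair,

  *d* = −½ ln[(1 − 2*P* − *Q*) √(1 − 2*Q*)],

  with saturated pairs flagged as undefined rather than dropped silently.
* **Six divergence parameters** — average inter-specific distance, θ′ (mean
  congeneric heterospecific distance per genus), minimum inter-specific
  distance, average intra-specific distance, θ (mean conspecific distance
  per species) and coalescent depth (maximum conspecific distance) — plus
  barcoding-gap histograms of nearest-congener distances against depths.
* **Species-boundary optimization.** Scanning thresholds *t* ∈ [0, 0.15],
  false positives (conspecific pairs with *d* > *t*) and false negatives
  (heterospecific pairs with *d* ≤ *t*) are counted; the optimum minimizes
  their sum.
* **Four identification rules** — nearest neighbour, best hit
  (Smith–Waterman with Karlin–Altschul bit scores and E-values), liberal
  tree-based (query sister to or nested in a monospecific clade of a
  neighbour-joining tree), and liberal tree-based with a distance-threshold
  veto — scored as sequence identification success rates, compared across
  markers and methods with Duncan's multiple range test.
* **Screening** of unverified ("unpublished") reference sequences: a record
  is admitted only if its smallest clade containing reliable records holds
  exclusively conspecific ones.
* **Synthetic data** evolved under the K2P substitution process on a
  star-within-star genealogy with controllable intra/inter divergence,
  species-overlap pairs, deep intra-specific splits, and mislabeled records.

## Worked example

```python
from barcode_eval import (
    SimulationConfig, simulate_dataset, distance_matrix, summarize_divergence,
    error_curves, build_evaluation_sets, run_evaluation, ratio_gap_index,
)

config = SimulationConfig(seed=1, overlap_pairs=1)   # one inseparable species pair
dataset, truth = simulate_dataset(config)
matrix = distance_matrix(dataset)
set1, set2, set3 = build_evaluation_sets(dataset)

summary = summarize_divergence(matrix, set1)
print(summary.to_frame().to_string(index=False))
print(f"barcoding-gap ratio: {ratio_gap_index(summary):.2f}")

scan = error_curves(matrix, set1, grid_step=0.001)
print(f"optimal threshold: {scan.optimal:.3f} (FP+FN = {scan.min_error_sum})")

for method in ("nn", "tree", "tree+threshold"):
    rep = run_evaluation(set2, set1, method, threshold=scan.optimal, matrix=matrix)
    print(f"{method:15s} {rep.n_correct}/{rep.n_queries} correct "
          f"({rep.success_rate:.2%}), {rep.n_uncertain} uncertain")
```

prints

```
        parameter     mean       sd
avg_interspecific 0.202428 0.033698
      theta_prime 0.202428 0.010795
min_interspecific 0.132258 0.082384
avg_intraspecific 0.014952 0.004855
            theta 0.014952 0.003631
 coalescent_depth 0.019561 0.004570
barcoding-gap ratio: 6.76
optimal threshold: 0.026 (FP+FN = 15)
nn              76/80 correct (95.00%), 0 uncertain
tree            76/80 correct (95.00%), 3 uncertain
tree+threshold  76/80 correct (95.00%), 3 uncertain
```

Conspecific divergence recovers the simulated 1.5% and congeneric divergence
the simulated 20%. Because one species pair was generated nearly inseparable
(0.5% apart), the minimum inter-specific distance collapses toward zero, no
threshold achieves zero error (FP+FN = 15 at the 2.6% optimum), and each
rule misassigns a handful of queries from the overlapping pair — the
behaviour real libraries show for species pairs like *Rhipicephalus
microplus*/*R. annulatus*.

With no overlap pair (`SimulationConfig(seed=1)`), all four rules reach
100% and the error minimum is zero — the clean-gap baseline.

## Command line

`barcode-eval` exposes each stage (`simulate`, `datasets`, `distances`,
`divergence`, `boundaries`, `identify`, `evaluate`) plus `run-all`, which
drives the whole pipeline from a YAML config and writes all tables (TSV),
trees and a manifest into an output directory. Runs are pure functions of
config and seed: rerunning reproduces every file byte for byte.

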