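# barcodegap

Barcode-gap analysis for fungal nrITS / ITS1 / ITS2 sequence data.

The DNA barcode gap is the separation between the distribution of
**intra-specific** (within-species) and **inter-specific**
(between-species) pairwise genetic distances for a molecular marker.
When the gap exists, a divergence cutoff inside it cleanly clusters
sequences into species; when the distributions overlap, no universal
cutoff can.  For macrofungi the marker is the nuclear ribosomal internal
transcribed spacer region (nrITS = ITS1 + 5.8S + ITS2), and whether a
gap exists — and in which sub-region it is widest — varies strongly
between genera.  This package is for mycologists and barcoding
researchers who want to quantify that, per genus and per region, from
curated aligned datasets or from phylogenetic trees.

## What it computes

Given an aligned multi-FASTA matrix and a species assignment per
sequence (or a newick phylogram), the package computes:

* **Pairwise distances** under the raw model (p-distance, the proportion
  of differing sites) and the Kimura two-parameter model,

  d = −½ · ln((1 − 2P − Q) · √(1 − 2Q)),

  where P and Q are the per-pair proportions of transitions (A↔G, C↔T)
  and transversions among comparable sites.  Sites with gaps or
  ambiguity codes are excluded **pairwise** (pairwise deletion), so a
  ragged sequence only affects its own pairs.  **Patristic
  (cophenetic)** distances — branch-length path sums between tree
  tips — are the tree-based counterpart.
* **Distance pools**: every unordered sequence pair contributes its
  distance to the intra pool (same species) or inter pool (different
  species), under any number of alternative partitions of the same
  sequences ("lumping" vs "splitting" taxonomies).
* **Summaries and the stress test**: means, medians, sample variances,
  type-7 quantiles, and the quantile stress test of the gap: at level p,

  gap(p) = Q_inter(1 − p) − Q_intra(p),  p ∈ {0.85, 0.90, 0.95}.

  A positive gap(p) is the gap's size at that stringency; a negative
  value means the distributions overlap.  The midpoint
  (Q_intra(p) + Q_inter(1 − p))/2 is the candidate clustering cutoff.
* **Report tables**: a per-dataset × region × level stress-test table
  with a Count/AVE footer, a 95%-level cutoff table in percent
  divergence, and per-pool summary exports — all plain CSV.

A **synthetic-data generator** produces aligned multi-species datasets
with known truth — star or Yule species trees, exact K80 mutation
sampling with transition/transversion bias, fast-ITS1/conserved-5.8S/
intermediate-ITS2 rate structure, and gap masking — so the entire
pipeline is testable without downloading anything.

## Worked example

```python
import numpy as np
from barcodegap import pairwise_matrix, split_pools, stress_test
from barcodegap.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=42))       # 10 species x 5 seqs
pools = split_pools(pairwise_matrix(ds.alignments["nrITS"], "k80"),
                    ds.partition, region="nrITS")
print(np.mean(pools.intra), np.mean(pools.inter))
for a in stress_test(pools, [0.85, 0.90, 0.95]):
    print(a.level, round(a.gap_size, 4), a.present)
```

prints

```
0.006010535026078997 0.06088179983503666
0.85 0.0438 True
0.9 0.0422 True
0.95 0.0391 True
```

— the intra pool mean (0.0060 substitutions/site) sits an order of
magnitude below the inter pool mean (0.0609), and the resulting barcode
gap survives all three stress-test levels, shrinking as the quantiles
tighten (0.0438 → 0.0391).  The `examples/` directory has one short
script per capability: simulation and pool measurement, the stress
test, lumping-vs-splitting comparison, patristic distances, and the
file-based multi-dataset workflow.

The same workflow is scriptable from the shell:

```bash
barcode-gap simulate --out-dir data --seed 42
barcode-gap dist data/synthetic_nrITS.fasta --model k80 --out dist.csv
barcode-gap stress run.yaml --out-dir results   # stress_test.csv, cutoffs.csv
```

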