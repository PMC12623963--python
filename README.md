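# foldrank

Model scoring, consensus ranking and evaluation utilities for protein
tertiary-structure prediction pipelines.

Modern structure predictors can generate thousands of candidate models
("decoys") for one protein, yet picking the right one remains the hard
part: a predictor's own confidence (plDDT) and consensus-based quality
estimates both fail when an incorrect conformation dominates the model
pool. `foldrank` implements the non-neural computational machinery
around that problem, for pipeline developers and assessors:

- **MSA engineering** — per-column alignment depth profiling,
  template-hit-based domain segmentation with disorder-aware boundary
  refinement, pairing and gap padding of per-domain alignments into
  full-length domain-based MSAs, and profile-based alignment
  augmentation (HH-suite A3M dialect throughout).
- **Structure comparison** — Kabsch superposition, TM-score and GDT-TS
  over CA traces, and fast all-against-all similarity matrices for
  large pools.
- **Consensus ranking** — the pairwise similarity score (PSS), score
  aggregation, K-means model clustering, greedy diversity filtering,
  and the five CASP16 submission strategies of the MULTICOM predictors
  (`multicom_ai`, `multicom_gate`, `multicom_llm`, `multicom`,
  `multicom_human`).
- **Fragment assembly** — stitching independently predicted,
  overlapping regions into one full-length model by superposition over
  the overlaps.
- **CASP-style evaluation** — GDT-TS → Z-score conversion with outlier
  re-standardisation, positive-sum accumulation with
  alternative-conformation pair averaging, TM-score threshold
  summaries, head-to-head comparison and the one-sided Wilcoxon
  signed-rank test.
- **Synthetic data** — reference CA chains, noise-controlled decoy
  pools with planted conformational clusters and truth tables,
  alignments with controlled per-column depth, and template-hit tables
  around planted segmentations, so everything above is testable
  without any external download.

## The scores at the core

For a model and reference sharing residues $i = 1..n$ with distances
$d_i$ after a rigid superposition,

$$\mathrm{TM} = \max_{\text{superpositions}} \frac{1}{L_{\mathrm{ref}}}
  \sum_{i=1}^{n} \frac{1}{1 + (d_i/d_0)^2},\qquad
  d_0 = \max\!\big(0.5,\ 1.24\,(L_{\mathrm{ref}}-15)^{1/3} - 1.8\big)$$

$$\mathrm{GDT\text{-}TS} = \frac{1}{4} \sum_{t \in \{1,2,4,8\,\text{Å}\}}
  \max_{\text{superpositions}} \frac{|\{i : d_i \le t\}|}{L_{\mathrm{ref}}}$$

Both maximise over superpositions found by a deterministic seed-window
search with iterative refinement (no randomised restarts, so scores are
bit-reproducible). Normalisation is by the reference (first-argument)
length. The CASP evaluation protocol standardises per-domain GDT-TS
across predictors into Z-scores: outliers below −2 are dropped, all
entries are re-standardised against the survivors, alternative
conformations of one domain are averaged, and only positive Z-scores
accumulate into a predictor's total.

## Worked example

Generate a pool in which 90% of the models share a wrong conformation
and 10% the right one, then rank it:

```sh
foldrank simulate decoys --spec pool.yml --seed 7 --out pool/
#  -> # wrote 200 decoys + truth table to pool
```

with `pool.yml`:

```yaml
length: 40
n_models: 200
sigma_grid: [0.8]
conformations:
  - {weight: 0.9, hinge_angle_deg: 120.0}
  - {weight: 0.1, hinge_angle_deg: 0.0}
```

```python
import pandas as pd
from foldrank import (FAST_POOL_PARAMS, ScoreTable, SelectionConfig,
                      io_formats, pairwise_matrix, pss, select_top)

truth = pd.read_csv("pool/truth.tsv", sep="\t")
models = [io_formats.read_pdb_chain(f"pool/{m}.pdb") for m in truth.model_id]
sim = pairwise_matrix(models, params=FAST_POOL_PARAMS)
consensus = pss(sim)
table = ScoreTable(list(truth.model_id), {"gate": consensus})
top5 = select_top(sim, table, SelectionConfig(strategy="multicom_gate",
                                              require_af3=False))
print(truth.set_index("model_id").loc[top5, ["conformation", "true_tm"]])
```

```
            conformation   true_tm
model_id
decoy_0100             0  0.434744
decoy_0025             0  0.401355
decoy_0004             0  0.384263
decoy_0009             0  0.351613
decoy_0152             1  0.742233
```

The consensus signal puts majority-conformation models (conformation 0,
true TM ≈ 0.4 against the reference) at the top — consensus scoring
rewards resemblance to the crowd — but the cluster-based strategy still
carries a minority-cluster model (conformation 1, true TM 0.74) into
the top five. That is the rescue mechanism the `multicom_gate` strategy
exists for: when the pool is dominated by a wrong conformation, one
representative per structural cluster keeps the rare correct fold in
the submission.

Score any two single-chain PDB files directly:

```sh
foldrank tmscore native.pdb model.pdb   # -> e.g. 0.8731
foldrank gdtts   native.pdb model.pdb   # -> e.g. 0.8125
```

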