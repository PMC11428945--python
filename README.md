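# gutnet

Network-based analysis of longitudinal gut-microbiome count data: from
genus/ASV count tables through diversity statistics, per-condition SparCC
co-occurrence networks, WGCNA-style module detection, and a network-shift
("driving force") biomarker score with permutation FDR control and
cross-validated ROC evaluation.

## Who this is for

Studies that profile a microbial community (e.g. fecal 16S amplicon data)
under two conditions — control vs a stressor, health vs disease — at one or
more timepoints, and ask not only *which taxa change in abundance* but *which
taxa restructure the community's co-occurrence network* during the
transition. A synthetic-community generator with planted ground truth
(correlation modules, differential "driver" taxa, group/sex/timepoint
structure) makes every stage testable end to end without touching real
sequencing data.

## The method

For each condition the pipeline infers a basis-correlation network with
SparCC (log-ratio variances under a sparsity assumption — robust to the
compositional nature of sequencing counts), optionally integrates the
per-timepoint networks of a condition by inverse-variance weighting, and
detects modules by clustering the topological overlap of the signed soft
adjacency `s_ij = ((1 + a_ij)/2)^β`. Per node it computes

* connection strength `k_i = Σ_{j≠i} a_ij`, and
* module importance `Σ_{j∈M, j≠i} a_ij − Σ_{j∉M} a_ij`
  (within- minus out-of-module connectivity of the node's module `M`).

The driving-force score of taxon *i* between condition networks *A* and *B*
is

```
NMSS(i) = Σ_{j ∈ NeighborsA(i)} ΔD_ij − Σ_{l ∈ NeighborsB(i)} ΔD_il
ΔD_ij   = d_B(i,j) − d_A(i,j),  d_X(i,j) = 0 if i,j share a module in X else 1
```

summed over the taxa co-occurring with *i* (positive supra-threshold edges)
in each network. A taxon that keeps its module scores 0; a taxon that
migrates between modules accumulates reinforcing terms over its old and new
neighborhoods. Scores are min-max normalized to [0, 1]; significance comes
from a condition-label permutation null that re-runs the whole
network → partition → score chain, with Benjamini-Hochberg FDR. The
module-pair Jaccard distance matrix `D` additionally flags the stable
("intersection") modules of the transition. Panels of significant taxa are
evaluated with stratified 10-fold cross-validated logistic ROC (`netroc`).

## Worked example

```python
from gutnet import (SimulationConfig, simulate_counts,
                    nmss_significance, significant_biomarkers)

cfg = SimulationConfig(n_taxa=30, n_samples_per_group_per_timepoint=40,
                       n_timepoints=1, module_sizes=[12, 12],
                       basis_correlation_within_module=0.7,
                       driver_taxa=[0, 1], driver_log2_effect=2.0,
                       driver_rewire=True, seed=11)
table, meta, truth = simulate_counts(cfg)
m = meta.frame
control = table.select_samples(list(m.loc[m.group == "control", "sample_id"]))
stress = table.select_samples(list(m.loc[m.group == "stress", "sample_id"]))

result = nmss_significance(control, stress, n_permutations=200, seed=0)
print(significant_biomarkers(result).head(6).round(4))
```

prints

```
        raw    nmss  p_value  q_value      direction
taxon
g000   22.0  1.0000   0.0050   0.0187  enriched_in_B
g001   17.0  0.7727   0.0050   0.0187  enriched_in_B
g008    3.0  0.1364   0.0100   0.0187  enriched_in_A
g010    3.0  0.1364   0.0050   0.0187  enriched_in_A
g002    2.0  0.0909   0.0249   0.0355  enriched_in_A
g004    2.0  0.0909   0.0100   0.0187  enriched_in_A
```

The two planted drivers (`g000`, `g001` — rewired into a different
correlation block and up-shifted 4-fold in the stress arm, hence
`enriched_in_B`) dominate the normalized score; their module-mates pick up
small secondary scores because the network genuinely changed around them.

The same analysis is available from the shell:

```bash
gutnet simulate --seed 11 --out run/
gutnet preprocess --counts run/counts.tsv --out run/
gutnet diversity --counts run/counts_filtered.tsv --metadata run/metadata.tsv --out run/
gutnet netmoss --counts run/counts_filtered.tsv --metadata run/metadata.tsv \
       --mode longitudinal --permutations 500 --seed 11 --out run/
gutnet evaluate --counts run/counts_filtered.tsv --metadata run/metadata.tsv \
       --biomarkers run/biomarkers.tsv --out run/
```

or end to end with `gutnet run-all --config pipeline.yaml`.

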