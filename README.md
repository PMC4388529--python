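# cnmod — from copy-number profiles to functional network modules

Heterogeneous tumours such as osteosarcoma rarely share a single mutated
driver gene: each tumour carries its own set of gains and losses, yet those
alterations tend to converge on the same cellular pathways.  `cnmod`
implements an integrative analysis that makes this convergence testable. It
takes segmented, ploidy-corrected total copy-number profiles and paired
expression for a tumour cohort, plus a reference protein-interaction network,
and produces a statistically validated altered-gene network, its functional
modules, hub genes, gene-set annotations and copy-number-stratified survival
comparisons.

The pipeline, stage by stage:

1. **Gene-level calling relative to ploidy.** A segment is gained/lost when
   its copy number deviates from the tumour's ploidy by more than δ = 0.9
   copies over ≥ 10 markers; segments overlapping masked regions
   (telomeres/centromeres/segmental duplications) by > 50% are removed.
   Genes inherit the call of the segment covering their midpoint.
2. **Recurrence and significant regions.** Genes altered in ≥ 20% of samples
   are recurrent; significantly altered regions are delimited either by a
   built-in cyclic-shift permutation scorer (q < 0.25, BH) or by parsing a
   GISTIC all-lesions file.
3. **Copy-number association.** For genes in significant regions, Pearson
   *r* between copy number and expression is tested against a null of 1,000
   whole-cohort sample permutations, `p = #(r_perm > r_obs)/N`; genes with
   BH-FDR q < 0.1 are *drivers*.
4. **Network assembly.** Drivers are superimposed on the interactome; every
   interaction path of length 1 or 2 is kept.  A *linker* (the length-2
   middle node) must touch ≥ 2 drivers and pass a hypergeometric
   neighbourhood-enrichment test (q < 0.05).  The induced subgraph's largest
   connected component is the altered-gene network; its connectedness is
   benchmarked against equally sized random gene draws re-run through the
   identical procedure.
5. **Modules, modularity, hubs.** Girvan–Newman edge-betweenness
   decomposition at the cut maximizing Newman modularity
   `Q = Σ_c [e_c/m − (d_c/2m)²]`; significance from degree-preserving
   double-edge-swap networks via the scaled modularity score
   `(Q_obs − mean Q_null)/sd Q_null`; hubs are the top 5% of nodes by degree
   (ties included) plus each module's max-degree node.
6. **Annotation and survival.** Hypergeometric gene-set enrichment per
   module against the interactome background (any GMT collection), and
   Kaplan–Meier / log-rank comparisons: per gene, copy-number-lost vs
   neutral samples (gained samples excluded); per cohort, ploidy > 3n vs the
   rest.

Because cohorts with paired copy-number + expression data are rarely
redistributable, the package ships a synthetic cohort generator with planted
ground truth (dense interactome modules aligned to genomic blocks, dosage-
coupled expression, survival hazard tied to selected losses) so that every
stage is testable end to end: recovery of the planted structure is the
package's primary validation currency.

## Worked example

Generate a cohort and run the whole pipeline:

```sh
cnmod make-fixture demo --scale tiny --seed 1
cnmod run -c demo/config.yaml -o demo_run
```

Or walk the stages with the numbered scripts (paper-like scale: 5,000 genes,
41 samples, mean ploidy 2.8):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_call_copy_number.py
...
python analysis/06_annotate_survival.py
```

A run of the six scripts prints, along the way:

```
called 5000 genes x 41 samples
  gain-recurrent: 36, loss-recurrent: 24
  significant regions (q<0.25): 13
tested 68 genes inside significant regions
  copy-number associated (q<0.1): 61 (median r of selected: 0.57)
network: 276 nodes / 797 edges (60 drivers + 216 linkers; 216/219 linker candidates accepted)
  connectedness vs 200 random draws: p_nodes=0.0, p_edges=0.0
10 modules, Q = 0.444
  scaled modularity vs 200 edge-swap networks: 19.7 (p = 0.0)
  hub genes (top 5%, ties included): 15
  planted-module recovery ARI: 0.817 over 60 planted genes
```

Reading: of the 5,000 genes, the recurrent/significant-region funnel plus the
expression-association test recovered essentially the 60 planted
dosage-coupled genes; the interaction network built from them is far denser
than random draws (empirical p = 0 at 200 draws); its module decomposition is
vastly more modular than its degree sequence implies (scaled score 19.7) and
matches the planted membership at adjusted Rand index 0.82.  The ploidy and
per-gene survival comparisons run on the same cohort (the planted loss module
carries the hazard).

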