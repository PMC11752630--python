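# apamirnet

Alternative polyadenylation (APA) lets a gene choose among several
cleavage/polyadenylation sites, producing mRNA isoforms with 3'UTRs of
different lengths. Because most microRNA-binding sites live in the 3'UTR, a
cell population that shifts isoform usage toward proximal sites can *lose*
binding sites of specific microRNA families — escaping their repression.
`apamirnet` is a Python library for quantifying this effect in clustered
single-cell data and for relating it to microRNA–TF–gene regulatory
circuits. It is aimed at computational biologists who already have a
polyA-site ("APA") expression matrix, a cell clustering, a binding-site
annotation and regulatory interaction tables, and want a tested, reproducible
statistical core rather than a monolithic pipeline.

## What it computes

**MicroRNA-avoidance test.** For each cluster *c* and microRNA family *f*,
every binding site of *f* in a multi-APA gene is classified per isoform:
*retained* if the site's interval ends at or before the isoform's cleavage
position, *lost* otherwise. Summing the isoform expression mass over the
cluster's cells gives totals L (lost) and R (retained); the statistic is the
lost fraction

&nbsp;&nbsp;&nbsp;&nbsp;T = L / (L + R),

a monotone reparameterization of the lost:retained ratio L/R. Significance
comes from B label permutations (cell-to-cluster assignments shuffled,
cluster sizes preserved): p = (1 + #{T\* ≥ T}) / (B + 1), BH-corrected across
the cluster's testable families.

**Feed-forward-loop (FFL) scoring.** From tables of miRNA→gene, miRNA→TF,
TF→gene and TF→miRNA interactions, all simple FFLs (SFFLs) — triples
(miRNA, TF, gene) where both regulators target the gene and at least one
regulates the other — are enumerated and classed as miRNA-centric,
TF-centric or feedback. Each SFFL passing a 10% expression-prevalence filter
is scored per cluster as the mean of

* node scores Φ⁻¹(1 − p_adj) from one-vs-rest Wilcoxon differential
  expression, and
* edge scores |atanh(r)|·√(n − 3), the Fisher-transformed Pearson
  correlation over the cluster's n cells,

with a miRNA lacking an expression row dropped together with its incident
edges. A null of B random (miRNA, TF, gene) triples drawn from the cluster's
candidate pools gives a permutation p per SFFL, BH-corrected. Significant
SFFLs sharing a center node merge into module FFLs (MFFLs), and SFFLs whose
miRNA family is significantly avoided by APA are flagged.

A seeded synthetic-data generator (negative-binomial counts, Dirichlet
isoform usage, planted avoidance effects and planted coherent FFLs) makes
every stage testable without any external data. See `docs/methods.md` for
model details and caveats.

## Worked example

```bash
python examples/02_avoidance_test.py
```

prints (abridged):

```
cluster C0: 56 testable families, 1 significant at FDR 0.05
family_id   lost  retained  statistic        p    p_adj
  MIRF000 2588.0     682.0   0.791437 0.000100 0.005599
  MIRF004  228.0     526.0   0.302387 0.016498 0.377029

cluster C1: 56 testable families, 0 significant at FDR 0.05
family_id  lost  retained  statistic        p  p_adj
  MIRF000 645.0    2556.0   0.201500 1.000000    1.0
```

The dataset planted a usage shift of δ = 0.8 toward the proximal cleavage
site for family MIRF000's carrier genes in cluster C0 only. In C0 the family's
sites carry 79% of their expression mass on isoforms too short to contain
them (statistic 0.79), an excess no label permutation matches (p = 1/10001,
BH-adjusted 0.006); in C1 the same family shows baseline usage and p = 1.

Other examples: `examples/01_simulate_bundle.py` (generate and write a full
input bundle), `examples/03_ffl_networks.py` (enumerate, score and merge
FFLs), `examples/04_centroid_distances.py` (cluster-proximity summaries).
The same stages are scriptable via the thin CLI:

```bash
apamirnet simulate --out bundle --seed 1
apamirnet run --simulate --out results --seed 1
apamirnet avoidance --apa bundle/apa --binding-sites bundle/binding_sites.tsv \
    --clusters bundle/clusters.tsv --permutations 10000 --seed 1
```

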