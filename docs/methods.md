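# Methods

This note documents the statistical model behind `apamirnet`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## Coordinates and the site-fate rule

Binding sites are 0-based half-open intervals `[start, end)` relative to the
3'UTR start on the mRNA sense strand. Each polyA-site isoform is described
by `cleavage_pos`, the number of 3'UTR bases it retains. A site is
**retained** on an isoform iff `end <= cleavage_pos`, otherwise **lost**: a
site truncated by even one base cannot form a functional seed match, so the
boundary is strict. Genomic-strand handling belongs to upstream
quantification and is out of scope; all inputs are transcript-relative.

Only genes with ≥ 2 annotated polyA sites enter the avoidance statistic.
Loss *due to APA* requires an alternative isoform to exist; a single-site
gene cannot exhibit differential loss, and including such genes would only
dilute the statistic with constant mass.

## The avoidance statistic and its permutation null

For cluster *c* and family *f*, with `s_i` the summed expression of isoform
*i* over the cluster's cells and `n_lost(f, i)` / `n_ret(f, i)` the number of
*f*-sites lost/retained on isoform *i*:

    L = Σ_i s_i · n_lost(f, i),   R = Σ_i s_i · n_ret(f, i),   T = L / (L + R)

T is order-equivalent to the ratio L/R (x ↦ x/(1−x) is monotone) but defined
whenever L + R > 0, which avoids special-casing R = 0. Families with
L + R = 0 in a cluster are untestable there and are excluded from testing
and BH correction. A *binary* counting mode replaces `s_i` by an indicator
that the isoform is "used" (nonzero in ≥ 5% of the cluster's cells); the
expression-weighted mode is the default because it reflects how much
regulatory opportunity is actually lost.

The null is built by shuffling cell-to-cluster labels while preserving
cluster sizes — equivalently, drawing uniform cell subsets of the focal
cluster's size — and recomputing T. The default p-value is the add-one
smoothed tail frequency `(1 + #{T* ≥ T}) / (B + 1)`, a valid and
conservative estimator that cannot return 0 and handles constant statistics
gracefully; the literal strictly-greater count `#{T* > T} / B` is available
via `smooth_permutation_p: false`. BH correction runs per cluster across
families, matching the per-cluster reporting of significant-family counts.
B defaults to 10,000 and the significance threshold to 0.05.

**Exchangeability caveat.** The label-shuffle null assumes cells are
exchangeable under H0. When clusters differ in *expression level* of the
site-carrying genes but not in isoform usage, the expression-weighted
statistic is only approximately exchangeable: the weighting of genes in T
differs between the observed labeling and label permutations, which can
produce apparent avoidance without any usage shift. The calibration studies
therefore use a null with no cluster-specific expression means — the
hypothesis the permutation scheme actually tests — and users should read
significant families in strongly marker-driven clusters with this in mind
(the binary mode is less sensitive to it).

## Differential expression, node scores, edge scores

One-vs-rest DE uses the two-sided Wilcoxon rank-sum test (the common
default for single-cell marker finding): exact when both groups have ≤ 25
cells and the gene's values are tie-free, otherwise the tie- and
continuity-corrected normal approximation; constant genes get p = 1. The
SFFL machinery only consumes a table of adjusted p-values, so any
DE-result-shaped table can be substituted. "Expressed in a cluster" means a
value > 0 in at least `min_expr_frac` (default 10%, boundary inclusive) of
the cluster's cells.

Node score: Φ⁻¹(1 − p_adj), with p clipped to [1e−12, 1 − 1e−12] so scores
stay finite; smaller adjusted p (stronger cluster specificity) gives a
larger score. The DE direction is deliberately ignored — the score measures
cluster-specificity, not up- or down-regulation.

Edge score: |atanh(r)|·√(n − 3), with r the Pearson correlation of the two
nodes' log-normalized expression over the cluster's n cells, clipped to
±(1 − 1e−7). The absolute value treats repression and activation as equally
coherent, appropriate since miRNA edges are repressive and TF edges may be
either; a signed variant exists behind `signed_edges`. Zero-variance
vectors score 0 with a warning; n ≥ 4 is required.

## SFFL scoring, the miRNA drop rule, and the random-triple null

An SFFL's overall score S is the arithmetic mean of all *available* node and
edge scores: three node scores, the miRNA–gene and TF–gene edges, and the
miRNA–TF cross-edge — counted twice for feedback loops, which have two
cross-edges over the same node pair. Small RNAs are often absent from
scRNA-seq; a miRNA without an expression row contributes neither its node
score nor its incident edge scores, and the mean runs over the remainder. At
minimum the TF and gene node scores and the TF–gene edge must be available,
else the SFFL is unscorable.

The null draws B random (miRNA, TF, gene) triples uniformly with replacement
from the cluster's candidate pools (miRNAs without expression rows stay in
the pool) and scores each **under the observed SFFL's edge-presence
pattern**, applying the same drop rules. Random triples generally have no
edges in the graph, so without this convention observed and null scores
would average different numbers of terms and be incomparable. p-values use
the same smoothed ≥-tail estimator as the avoidance test; BH runs per
cluster across all scorable candidates.

MFFL merging: miRNA-centric SFFLs group by their miRNA, TF-centric by their
TF; feedback SFFLs join both groupings (center-type tables in the field
list only miRNA and TF centers, and double membership loses no
information). Singleton groups still form an MFFL.

## Synthetic data

The generator emulates the structure the analyses assume:

* **Counts.** Gene totals are negative binomial (default mean 2.0,
  dispersion r = 0.5 ⇒ var = μ + μ²/r), with per-gene lognormal baseline
  heterogeneity and, by default, 10 marker genes per cluster at 1 log2
  fold-change — a mild, realistic cluster structure.
* **Isoforms.** A fraction `frac_multi_apa` (default 0.166) of genes get
  2–4 cleavage positions; the most distal one sits at the UTR end, so a
  full-length isoform always exists. Usage is a Dirichlet(2, …, 2) draw per
  gene, shared across clusters; per cell the gene total is split
  multinomially, so gene expression equals the isoform sum *exactly*.
* **Binding sites.** 7-base sites placed uniformly, Poisson(0.05) count per
  (family, gene); no site straddles the UTR end.
* **Planted avoidance.** For each planted (cluster, family, δ), dedicated
  carrier genes (default 3, drawn from the multi-APA genes and excluded
  from background site placement) receive the family's sites distal to the
  most proximal cleavage position, and in the planted cluster the usage
  vector becomes (1 − δ)·base + δ·proximal. Private carriers keep every
  non-planted family exactly null — a shift in a shared gene would create
  real collateral avoidance and make ground truth ill-defined.
* **Planted FFLs.** The triple's edges are force-inserted into the random
  graph; within the planted cluster the three nodes share a per-cell
  standard-normal latent factor on the log-mean scale, sized as
  λ = √(ρ/(1−ρ))·0.7 so the realized pairwise correlation approximates the
  target ρ (recorded as a target, not a realized value), plus a mean fold
  change `de_effect`. miRNA families appear as ordinary expression rows; a
  flag removes them to exercise the missing-miRNA path.

What the generator does **not** model: doublets, ambient RNA, batch
effects, read-level noise, UTR sequence composition, or dependence between
expression level and isoform choice. Passing calibration/power tests on
this data shows the statistics are correctly implemented and calibrated
under their own assumptions — not that those assumptions hold in any
particular real dataset.

## Numerical and reproducibility choices

* All randomness flows from one integer seed through named substreams
  (`SeedSequence` keyed by CRC-32 hashes of stage and cluster names), so
  results are independent of stage/cluster execution order and bit-stable
  across platforms for the integer-valued synthetic counts.
* Permutation statistics that are 0/0 in a permuted subset are treated as
  never exceeding the observed value.
* Population SD (divide by n) in centroid-distance summaries.
* Ties in BH are handled by the standard step-up procedure
  (statsmodels `fdr_bh`); input order is preserved.

## Evaluation scenarios and problem sizes

The self-evaluation (tests and `scripts/acceptance.py`) uses two clusters of
200 cells and 1000 permutations per test — sizes at which the studies
complete in seconds while leaving Monte-Carlo error well below the decision
margins. Null calibration uses ~500 families over 1200 genes (~1000
testable family–cluster pairs) and a denser graph (~900 enumerated SFFLs)
so the Kolmogorov–Smirnov uniformity check has resolution well beyond the
0.05 bound; note the p-values are dependent (families share genes, SFFLs
share nodes), which inflates KS fluctuation relative to the i.i.d.
expectation. Power uses 10 planted avoidance pairs (δ = 0.8) and 5 planted
FFLs (ρ = 0.9, 4-fold DE) over 20 seeded replicates.

## Known limitations

* The avoidance test detects *loss* under UTR shortening; gain of sites
  under lengthening is not tested.
* BH is applied per cluster; joint correction across clusters would be more
  conservative and is not offered.
* The Fisher-z edge score assumes approximate bivariate normality of
  log-normalized expression; for very sparse genes the correlation, and
  hence the score, is noisy.
* The score comparison between an observed SFFL and random triples inherits
  whatever composition the candidate pools have; pools are defined by the
  expression filter, and miRNAs without expression rows are included by
  design.
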