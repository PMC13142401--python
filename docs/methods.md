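# Methods

## Dereplication and novelty

BGC similarity is consumed as raw pairwise distances in [0, 1] (BiG-SCAPE
convention: only pairs at or below the clustering cutoff appear in a
network file).  Networks are built per biosynthetic class; edges are kept
at distance ≤ 0.5 — the cutoff is inclusive, so a pair at exactly 0.5 joins
one family.  Gene cluster families (GCFs) are connected components; the
family id is the lexicographically smallest member id, which gives
reproducible labels without a global counter.  A family is putatively known
iff it contains ≥ 1 reference cluster (reference ids are recognised by the
configurable accession pattern `^BGC\d{7}`).

Per-BGC novelty is the minimum distance over **direct** retained edges to a
reference node.  Graph paths through intermediates are deliberately not
used: a pair absent from the network file has unknown distance above the
cutoff, so the correct value for an unconnected BGC is the sentinel 0.51
(just above the cutoff), not a path-sum.  Per sample and class, the minimum
of its BGCs' scores ("minimum novelty") is the response of the novelty
regressions; samples with no BGC of a class are absent from that
regression, not zero-filled.  Novelty operates on the full BGC set — the
sparsity filter below applies only to the profile analyses.  Greedy
modularity communities (unweighted) are computed for reporting parity with
network figures only; they never define families.

## Feature tables

Presence–absence: entry (s, f) = 1 iff at least one member BGC of family f
was detected in sample s; no abundances are inferred, keeping profiles
comparable across heterogeneous sequencing depth.  The sparsity filter
removes features whose prevalence count is strictly below fraction × n
("fewer than 5%" of samples for GCFs, 20% for genera — strict readings, so
at n = 100 a GCF in exactly 5 samples survives).  Taxonomy: genus
assignments are retained when support strictly exceeds 0.70; retained
contig lengths are aggregated per genus and divided by the sample's
classified base pairs; after the prevalence filter the profile is
Hellinger-transformed and summarised by covariance PCA (no unit-variance
scaling — Hellinger output is already commensurable), keeping 10
components by default.  PCA signs follow the largest-|loading|-positive
convention.

## Multivariate inference

All distance statistics operate on Hellinger–Euclidean geometry; because
the response is Hellinger-transformed, RDA on the transformed matrix equals
distance-based RDA (capscale) on Hellinger–Euclidean distances, and the
RDA form is what is implemented.

*Partial RDA.*  Y and the constraint block X are residualized on
[1, Z] (Z = log1p depth by default); constrained axes come from the SVD of
the fitted values of Y_res on X_res.  Two site-score flavours are kept:
weighted-average (wa) scores — Y_res projected on the constrained axes,
where residual structure including technical gradients remains visible —
and linear-combination (lc) scores, the fitted positions.  R² =
SS(fitted)/SS(Y_res); the overall and marginal pseudo-F tests use
Freedman–Lane permutation of reduced-model residuals (plain row permutation
without conditioning).  Collinear constraint columns are reported and
excluded from the rank but kept in the design, so a duplicated term shows
zero marginal sum of squares instead of silently vanishing.

*PERMANOVA.*  McArdle–Anderson partitioning of the Gower-centered matrix
G = −½ J D² J through projection (hat) matrices; marginal SS of a term is
tr((H_full − H_without-term) G).  With conditioning, permutation acts on
the reduced-model residual matrix (I−H_red) G (I−H_red).  For Euclidean
input the pseudo-F is algebraically the classical MANOVA-trace F (tested to
1e-8).

*ANOSIM* uses mid-ranked distances, R = (r̄_between − r̄_within)/(M/2),
M = n(n−1)/2.  *Dispersion homogeneity* (betadisper-style) embeds D by
principal coordinates, corrects squared distances by subtracting the
imaginary-axis parts from negative eigenvalues, measures distances to group
centroids (centroids, not spatial medians), and permutes group labels
around a one-way F.

*Variation partitioning.*  All R² are computed in the conditioned space and
Ezekiel-adjusted, adjR² = 1 − (1−R²)(n−q−1)/(n−q−p−1) with q conditioning
df.  Fractions: unique-env [a] = adjR²(X1+X2) − adjR²(X2), analogously [b],
shared [c] = adjR²(X1) + adjR²(X2) − adjR²(X1+X2); by construction
[a]+[c] = adjR²(X1) exactly.  Unique fractions are tested by Freedman–Lane
permutation with the other block added to the condition.

*Clustering.*  k-means (20 seeded restarts per k, minimal WSS kept) over
the conditioned wa site scores; all positive-eigenvalue constrained axes
enter with their natural (eigenvalue-proportional) scale.  The elbow is the
k maximising the second difference of **log** WSS.  The relative form is
used because the absolute-WSS second difference is maximal at the dominant
split whenever cluster separations are uneven (here the thin-crust contrast
dwarfs the arc/backarc contrast) and would systematically return k−1; the
relative drop decelerates exactly past the true k, and the rule still
selects k = 3 on three well-separated blobs.  Mean silhouette per k is
computed alongside and both criteria are logged; the elbow choice is the
one the pipeline acts on, mirroring practice where silhouette favoured
k = 2 but the elbow and interpretability favoured k = 3.

*Depth diagnostic.*  Spearman ρ (tie-corrected, t-approximation p) of each
ordination axis against log1p depth, run twice: on the unconditioned RDA
(the "initial ordination") and on the conditioned RDA.  The conditioned
axes are linearly orthogonal to depth by construction, so any remaining
|ρ| is rank-noise of order 1/√n.

Permutation p-values are p = (1 + #{stat\* ≥ stat})/(1 + n_perm); the
smallest attainable p is 1/(1 + n_perm); defaults use 999 permutations and
explicit seeds everywhere.

## Univariate statistics

Shannon H = −Σ pᵢ ln pᵢ (natural log) on per-sample GCF **class count**
vectors by default — the alternative bases (family presences, taxa) are one
argument away, since the index's substrate is a modelling choice.
Kruskal–Wallis uses the tie-corrected H with a χ² reference (g−1 df);
Dunn's z uses the pooled-rank variance with the tie term
Σ(t³−t)/(12(N−1)), two-sided normal p, Holm or BH adjustment.  The Wilcoxon
rank-sum test enumerates all C(n, n_x) label assignments over pooled
mid-ranks when n ≤ 20 (exact even under ties), otherwise the tie- and
continuity-corrected normal approximation.  BH is step-up, Holm step-down,
both with monotonicity enforcement.  Multiplicity adjustment spans the set
of omnibus tests run in one invocation; the family size is logged.  Novelty
regressions are OLS with the two-sided F/t p and a 95% mean-response band
exported for plotting.

## The synthetic study

The generator emulates the *structure* of a multi-site geothermal BGC
survey, with every planted quantity recoverable downstream:

* **Families and networks.**  Per class, `n_families_per_class` families;
  within-family distances are drawn uniformly from [0.05, 0.45] (all pairs
  present), cross-family pairs are omitted — mirroring that network files
  only contain pairs within the cutoff — so connected components recover
  the planted partition exactly.  Each family holds a reference member with
  probability `ref_fraction` (default 0.10, echoing the ~3–11% known
  fractions typical of environmental surveys).
* **Composition.**  Five classes with a uniform base simplex; each tectonic
  setting up-weights one signature class (arc → NRPS, backarc → terpene,
  ridge → RiPP) by a log-linear contrast of magnitude `effect_size` (2.2);
  per-sample compositions add logistic-normal jitter (`noise_sd` 0.18).
  The defaults put the setting effect well above noise, the regime the
  recovery tests stipulate.
* **Sequencing depth.**  Log-normal (median ≈ 2×10⁷ reads).  Detection
  probability rises with log1p depth through a floored sigmoid (monotone
  non-decreasing; the floor keeps shallow samples from going empty) raised
  to a per-class exponent: long multi-module NRPS/PKS loci need deeper
  assemblies than compact RiPP/terpene loci, so the depth bias is
  compositional, not just a richness effect.  Mean log depth additionally
  shifts with crustal thickness (`depth_ct_coupling` = −0.45: remote
  thin-crust campaigns sequenced deeper), planting the confounded technical
  gradient that makes depth conditioning necessary and gives the
  pre-conditioning axis-1 depth correlation its sign and size.
* **Novelty gradient.**  Reference-edge distances shrink with the sample's
  crustal thickness (slope 0.08 per SD), planting the negative
  CT–minimum-novelty association the regressions recover.
* **Environment.**  Setting signatures follow geothermal systematics: arcs
  acidic and hot, backarcs cooler and circum-neutral, ridges hot, saline and
  thin-crusted (CT ≈ 40/55/7 km).
* **Taxonomy.**  Genus proportions are Dirichlet draws around per-setting
  means whose signature blocks scale with `taxonomy_coupling`, giving
  variation partitioning a recoverable shared fraction; a CAT-style contig
  table realises the profile (multinomial contig counts, log-normal
  lengths, Beta(8,2) support so retention is independent of genus).

All randomness flows from the single config seed.  What the generator does
**not** emulate: read- or sequence-level structure, assembly artifacts,
fragmented/partial clusters spanning contigs, abundance, covarying
geochemistry beyond the named covariates, or realistic family-size
distributions.  Passing tests therefore demonstrate correctness of the
statistical machinery and the stated rules on data with this structure —
not performance on real assemblies.

## Problem sizes and defaults

The default study is 60 samples × 300 planted families (≈ 5,000 BGC
nodes), chosen so a full pipeline run takes seconds and the whole
calibration suite (500-replicate type-I checks at n = 40, 100-seed power
checks at n = 60) runs in a few minutes on one CPU.  Thresholds default to
cutoff 0.5, sentinel 0.51, prevalence filters 5%/20%, support 0.70, 999
permutations, k ∈ [2, 8]; every value in effect is recorded in the run
manifest.

## Known limitations

* Novelty uses direct edges only; a BGC whose family is known but which
  lacks a direct reference edge scores the sentinel.  This is the
  conservative reading of network-file semantics, not a shortest-path
  distance.
* The elbow rule is deterministic but heuristic; when cluster separations
  are extremely unbalanced no WSS-based rule is reliable, which is why the
  silhouette curve is always reported next to it.
* Ezekiel adjustment of partial R² treats conditioning df by reducing the
  effective n; other conventions exist and differ at third-decimal order
  for these problem sizes.
* The exact Wilcoxon branch is O(C(n, n_x)) and is capped at pooled n = 20.
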