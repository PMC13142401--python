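# thermobgc

Analysis pipeline for surveys of microbial **biosynthetic gene clusters
(BGCs)** across geothermal sites: dereplication of predicted BGCs into
**gene cluster families (GCFs)** on similarity networks, novelty scoring
against reference (MIBiG-style) clusters, and the sequencing-depth-conditioned
multivariate and univariate statistics that relate biosynthetic composition
to environmental gradients and tectonic setting.

It is written for metagenomics researchers who have per-sample BGC
predictions (e.g. antiSMASH regions), pairwise BGC distance networks (e.g.
BiG-SCAPE `.network` files), contig-level taxonomic assignments (e.g. CAT)
and sample metadata, and who want the downstream community statistics fully
scripted and reproducible.  A seeded synthetic-study generator with known
ground truth exercises every stage, so the whole chain is testable without
any sequencing data.

## The model in brief

* **Dereplication.**  Per biosynthetic class (NRPS, PKS, RiPP, terpene, …),
  BGCs are nodes of a network whose edges carry raw pairwise distances
  d ∈ [0, 1]; edges with d ≤ 0.5 (inclusive) are retained and the connected
  components are the GCFs.  A family is *putatively known* iff it contains at
  least one reference cluster.
* **Novelty.**  Each BGC scores min d over its retained edges to reference
  nodes; with no such edge it scores the sentinel 0.51 ("unknown but above
  the cutoff").  Per sample and class, the minimum score is regressed on
  environmental covariates (OLS) — e.g. crustal thickness (CT, km).
* **Profiles.**  Presence–absence matrix: entry (s, f) = 1 iff ≥ 1 member
  BGC of family f was assembled in sample s; families in fewer than 5% of
  samples are dropped; rows are Hellinger-transformed,
  y'ᵢⱼ = √(yᵢⱼ/Σⱼyᵢⱼ), so Euclidean distances are ecologically meaningful.
* **Inference.**  Partial RDA of the transformed profile on the
  environmental gradients, conditioning on log1p sequencing depth (a
  technical covariate); k-means on site scores with elbow/silhouette k
  selection; marginal PERMANOVA (McArdle–Anderson), ANOSIM, dispersion
  homogeneity; variation partitioning between environment and taxonomy PCs
  with Ezekiel-adjusted R²; Shannon diversity, Kruskal–Wallis, Dunn
  post-hoc, Wilcoxon rank-sum, BH/Holm corrections.  Permutation p-values
  use p = (1 + #{stat\* ≥ stat})/(1 + n_perm) with 999 permutations by
  default (Freedman–Lane residual permutation under conditioning).

## Worked example

Run the numbered analysis scripts (each is a thin driver over the
`thermobgc` library; all outputs land in `results/study/`):

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_dereplicate_gcfs.py
python analysis/03_build_feature_tables.py
python analysis/04_ordination_statistics.py --seed 1
python analysis/05_diversity_and_novelty.py --seed 1
```

Output of the run above (abridged):

```
simulated 60 samples over 3 tectonic settings (seed 1)
planted 300 gene cluster families across 5 classes; 28 (9.3%) contain a reference cluster
300 gene cluster families from 4937 nodes
           families  novel  pct_novel
NRPS             60     56       93.3
terpene          60     52       86.7
...
partial RDA (condition: log1p depth): F = 15.53, R^2 = 0.535, p = 0.001
axis-1 vs depth Spearman rho: before conditioning 0.53, after 0.16
k-means: elbow k = 3, silhouette-best k = 3
marginal PERMANOVA:  tectonic_setting: R^2 = 0.051, F = 3.17, p = 0.001
clusters: ANOSIM R = 0.96 (p = 0.001); betadisper p = 0.21
variation partitioning (adjusted R^2): env unique = 0.167 (p = 0.001),
  taxonomy unique = 0.007 (p = 0.08), shared = 0.333
minimum novelty vs crustal thickness (OLS):
      NRPS: slope = -0.0024, R^2 = 0.111, p = 0.00944 (n = 60)
   terpene: slope = -0.0050, R^2 = 0.428, p = 2.5e-08 (n = 58)
```

Reading this: ~90% of families have no network connection to a reference
cluster (putatively novel); the ordination recovers the three planted
tectonic-setting clusters (k = 3) once sequencing depth is conditioned out
(axis-1 depth correlation falls from 0.53 to 0.16); cluster separation is
compositional rather than a dispersion artifact (ANOSIM R = 0.96 with
betadisper p = 0.21); and minimum novelty declines with crustal thickness —
thin-crust samples carry the more novel BGCs — matching the planted effects.

The same stages are available as a CLI (`thermobgc simulate|dereplicate|
features|ordination|stats|all --run-dir DIR [--config cfg.yaml] [--seed N]`)
with a YAML config and a reproducibility manifest recording the seed, config
hash, input digests and every threshold in effect.

## Layout

```
src/thermobgc/   library: sim, io, network, features, ordination, stats,
                 pipeline, cli
analysis/        numbered narrative drivers (simulate → … → statistics)
tests/           pytest suite incl. oracle, calibration and recovery checks
docs/methods.md  model, parameters, numerical choices, limitations
```
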