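"""Feature tables: GCF presence--absence, prevalence filters, class
proportions, Hellinger transform, and the taxonomy feature pipeline.

Biosynthetic profiles are presence--absence matrices of gene cluster
families per metagenome: a family counts as present in a sample when at
least one member BGC was detected there.  No abundances are inferred, which
keeps profiles comparable across samples of heterogeneous sequencing depth.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("thermobgc.features")

GCF_PREVALENCE_FRACTION = 0.05
TAXON_PREVALENCE_FRACTION = 0.20
TAXON_SUPPORT_THRESHOLD = 0.70
N_TAXONOMY_PCS = 10


def presence_matrix(
    inventory: pd.DataFrame,
    family_of: Mapping[str, str],
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x GCFs binary matrix plus a family -> class map.

    Entry (s, f) is 1 iff at least one BGC of family *f* occurs in sample
    *s*.  Reference BGCs carry no sample and are skipped.  Samples listed in
    *samples* but holding no BGC get an all-zero row.  A non-reference BGC
    without a family is an error.
    """
    inv = inventory[~inventory["is_reference"]] if "is_reference" in inventory else inventory
    missing = [b for b in inv["bgc_id"] if b not in family_of]
    if missing:
        raise ValueError(f"{len(missing)} BGCs without family assignment, e.g. {missing[0]!r}")
    fam = inv["bgc_id"].map(family_of)
    tab = pd.crosstab(inv["sample_id"], fam)
    mat = (tab > 0).astype(int)
    if samples is not None:
        mat = mat.reindex(sorted(samples), fill_value=0)
    mat = mat.sort_index().sort_index(axis=1)
    mat.index.name = "sample_id"
    mat.columns.name = "family_id"
    fam_class = (
        inv.assign(family_id=fam)
        .groupby("family_id")["bgc_class"]
        .agg(lambda s: s.mode().iloc[0])
    )
    return mat, fam_class


def prevalence_filter(matrix: pd.DataFrame, min_fraction: float) -> pd.DataFrame:
    """Drop features detected in fewer than ``min_fraction`` of samples.

    "Fewer than" is strict: a feature is removed iff its prevalence count
    (samples with a nonzero entry) is < min_fraction * n_samples.  Samples
    are never dropped.  Idempotent.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    counts = (matrix > 0).sum(axis=0)
    keep = counts >= min_fraction * matrix.shape[0]
    return matrix.loc[:, keep]


def class_proportions(matrix: pd.DataFrame, feature_class: pd.Series) -> pd.DataFrame:
    """Per-sample biosynthetic class percentages of detected GCFs.

    For each sample: 100 x (number of detected GCFs of the class) / (total
    detected GCFs in the sample).  Rows sum to 100.  Samples with zero
    detected GCFs are excluded with a warning.
    """
    detected = matrix > 0
    totals = detected.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("%d samples with zero detected GCFs excluded from class proportions", int(empty.sum()))
    detected = detected.loc[~empty]
    classes = feature_class.reindex(matrix.columns)
    counts = detected.T.groupby(classes).sum().T
    props = counts.div(counts.sum(axis=1), axis=0) * 100.0
    props.columns.name = "bgc_class"
    return props


def hellinger(matrix: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: y'_ij = sqrt(y_ij / row_sum_i).

    Scale-invariant per row; makes Euclidean distances ecologically
    meaningful on sparse presence/count data.  All-zero rows map to all-zero
    rows (logged); negative entries are an error.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative entry in matrix passed to hellinger")
    sums = vals.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        logger.warning("%d all-zero rows in hellinger input (kept as zeros)", int(zero.sum()))
    sums[zero] = 1.0
    out = np.sqrt(vals / sums)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def taxonomy_features(
    contigs: pd.DataFrame,
    support_threshold: float = TAXON_SUPPORT_THRESHOLD,
    prevalence_fraction: float = TAXON_PREVALENCE_FRACTION,
) -> pd.DataFrame:
    """Genus-proportion profile from a contig classification table.

    Assignments are retained only when support strictly exceeds
    *support_threshold* (an assignment at exactly the threshold is
    discarded).  Retained contig lengths are aggregated by genus within each
    sample and divided by the sample's total classified base pairs; genera
    present in fewer than *prevalence_fraction* of samples are then removed.
    """
    if not (0 <= support_threshold <= 1 and 0 <= prevalence_fraction <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    kept = contigs[contigs["support"] > support_threshold]
    bp = kept.pivot_table(
        index="sample_id", columns="genus", values="contig_length", aggfunc="sum", fill_value=0
    ).astype(float)
    totals = bp.sum(axis=1)
    profile = bp.div(totals.where(totals > 0, 1.0), axis=0)
    profile = prevalence_filter(profile, prevalence_fraction)
    profile.index.name = "sample_id"
    profile.columns.name = "genus"
    return profile.sort_index().sort_index(axis=1)


def pca(matrix: pd.DataFrame, n_components: int) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Centered (not scaled) PCA via singular value decomposition.

    Returns (scores, loadings, variance_fractions).  Variance fractions are
    non-increasing; each component's sign is fixed so its largest-magnitude
    loading is positive.
    """
    X = matrix.to_numpy(dtype=float)
    n, m = X.shape
    if n_components > min(n - 1, m):
        raise ValueError(f"n_components={n_components} exceeds min(n_samples - 1, n_features) = {min(n - 1, m)}")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u, vt = u * flip, vt * flip[:, None]
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    scores = pd.DataFrame(
        (u * s)[:, :n_components],
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        vt[:n_components].T,
        index=matrix.columns,
        columns=scores.columns,
    )
    return scores, loadings, frac[:n_components]
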