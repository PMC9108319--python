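"""Per-SNP Hudson F_ST, 2-SD summaries, and genotype PCA.

The per-SNP estimator (Hudson's, in the finite-sample form popularised by
Bhatia and colleagues) for sample alt-allele frequencies p1, p2 with allele
counts n1, n2 (twice the genotyped individuals) is

    fst = [(p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)]
          / [p1(1-p2) + p2(1-p1)]

Negative estimates are retained — they belong to the sampling distribution
whose mean and SD set the Q_ST significance threshold (mean + 2 SD).
Markers monomorphic across both groups have an undefined (missing) value.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import GenotypeMatrix


def _group_freqs(geno: GenotypeMatrix, group: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Sample alt-allele frequency and allele count per marker for a group."""
    sub = geno.subset(list(group))
    called = ~np.isnan(sub.dosages)
    n = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(sub.dosages, axis=0) / n
    return p, n


def hudson_fst_per_snp(
    geno: GenotypeMatrix,
    group1: list[str],
    group2: list[str],
    min_alleles: int = 4,
) -> pd.DataFrame:
    """Hudson F_ST at every marker between two disjoint accession groups.

    Returns a frame with marker_id, p1, p2, n1, n2, fst.  A marker gets a
    missing fst when either group has fewer than ``min_alleles`` called
    alleles (default: two genotyped individuals) or when the denominator is
    zero (monomorphic across both groups).
    """
    g1, g2 = set(group1), set(group2)
    if g1 & g2:
        raise ValueError(f"groups overlap: {sorted(g1 & g2)[:5]}")
    p1, n1 = _group_freqs(geno, sorted(g1))
    p2, n2 = _group_freqs(geno, sorted(g2))

    with np.errstate(invalid="ignore", divide="ignore"):
        # grouping the two corrections keeps the estimator exactly symmetric
        # in the two groups (floating-point addition is commutative)
        correction = p1 * (1 - p1) / (n1 - 1) + p2 * (1 - p2) / (n2 - 1)
        num = (p1 - p2) ** 2 - correction
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    usable = (n1 >= min_alleles) & (n2 >= min_alleles) & (den > 0)
    fst = np.where(usable, fst, np.nan)
    if not usable.any():
        warnings.warn("no marker had enough called alleles in both groups", stacklevel=2)
    return pd.DataFrame(
        {
            "marker_id": geno.marker_ids,
            "p1": p1,
            "p2": p2,
            "n1": n1,
            "n2": n2,
            "fst": fst,
        }
    )


@dataclass
class FstSummary:
    """Mean, sample SD and the mean + 2 SD significance threshold."""

    mean_fst: float
    sd_fst: float
    threshold: float
    n_snps_used: int


def fst_summary(fst: pd.DataFrame | np.ndarray) -> FstSummary:
    """Summarise defined per-SNP values; needs at least two of them."""
    values = fst["fst"].to_numpy() if isinstance(fst, pd.DataFrame) else np.asarray(fst, float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least 2 defined per-SNP F_ST values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return FstSummary(mean, sd, mean + 2.0 * sd, int(values.size))


@dataclass
class PcaResult:
    scores: pd.DataFrame          # accession x component
    pct_var: np.ndarray           # percent variance per component
    loadings: np.ndarray | None = None


def genotype_pca(
    geno: GenotypeMatrix,
    n_components: int = 10,
    scale: bool = False,
) -> PcaResult:
    """PCA of the centered dosage matrix; missing calls mean-imputed per marker.

    ``scale=True`` additionally divides each marker by its SD (off by
    default, the common choice for dosage PCA).
    """
    X = geno.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} clipped to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    pct = 100.0 * pca.explained_variance_ratio_
    frame = pd.DataFrame(
        scores,
        index=pd.Index(geno.accession_ids, name="accession_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return PcaResult(frame, pct, pca.components_)
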