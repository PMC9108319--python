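"""Variance partitioning, Q_ST, and the Q_ST-vs-F_ST divergence scan.

For each trait and population contrast the phenotypic variance is
partitioned with the intercept-only mixed model

    TRAIT ~ 1 + (1|POPULATION) + (1|LINE) + (1|GARDEN) + (1|BLOCK in GARDEN)

fitted by REML on the accessions of the contrast.  The between- and
within-population genetic components give

    Q_ST = s2_GB / (s2_GB + 2 s2_GW)

with s2_GB the POPULATION and s2_GW the LINE component (broad-sense; no
heritability correction by default, a scaling knob exists).  A trait is
flagged as under putative divergent selection when Q_ST exceeds the mean
per-SNP Hudson F_ST between the same two groups by more than two standard
deviations of the per-SNP distribution.

The four standard contrasts are all-Highland vs all-Lowland, all-Mexican vs
all-South-American, Mexican Highland vs Mexican Lowland, and South American
Highland vs South American Lowland.  For the pooled contrasts the
POPULATION term groups accessions by contrast side.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .lmm import LmmResult, build_fixed_design, build_random_design, fit_reml
from .popgen import FstSummary, fst_summary, hudson_fst_per_snp

#: contrast id -> (passport column, side-1 values, side-2 values)
CONTRASTS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "High:Low": ("elev_class", ("High",), ("Low",)),
    "Mex:SA": ("continent", ("Mex",), ("SA",)),
    "MexHigh:MexLow": ("population", ("MexHigh",), ("MexLow",)),
    "SAHigh:SALow": ("population", ("SAHigh",), ("SALow",)),
}


@dataclass
class LmmSpec:
    """A response plus fixed and random (independent intercept) terms."""

    response: str
    fixed_terms: list[str] = field(default_factory=lambda: ["1"])
    random_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.random_terms)) != len(self.random_terms):
            raise ValueError("duplicate random terms")


@dataclass
class VarianceComponents:
    sigma2: dict[str, float]
    se: dict[str, float]
    loglik_reml: float
    converged: bool


def fit_lmm_reml(spec: LmmSpec, data: pd.DataFrame,
                 level_orders: dict | None = None) -> tuple[VarianceComponents, LmmResult]:
    """Fit ``spec`` on ``data`` (rows with a missing response are dropped)."""
    sub = data.dropna(subset=[spec.response]).reset_index(drop=True)
    y = sub[spec.response].to_numpy(float)
    X, names = build_fixed_design(sub, spec.fixed_terms, level_orders)
    for term in spec.random_terms:
        for col in term.split(":"):
            if col not in sub.columns:
                raise ValueError(f"grouping factor '{col}' not in data")
    Zs = {term: build_random_design(sub, term) for term in spec.random_terms}
    fit = fit_reml(y, X, Zs, fixed_names=names)
    vc = VarianceComponents(
        sigma2=dict(fit.sigma2), se=dict(fit.sigma2_se),
        loglik_reml=fit.loglik_reml, converged=fit.converged,
    )
    return vc, fit


def compute_qst(sigma2_gb: float, sigma2_gw: float,
                heritability: float = 1.0) -> float:
    """Q_ST = s2_GB / (s2_GB + 2 h2 * s2_GW); nan when both components are 0.

    ``heritability`` rescales the line variance to a narrow-sense genetic
    variance if desired; the default of 1 uses the accession-line component
    directly (broad sense).
    """
    if sigma2_gb < 0 or sigma2_gw < 0:
        raise ValueError("variance components must be non-negative")
    denom = sigma2_gb + 2.0 * heritability * sigma2_gw
    if denom == 0:
        warnings.warn("both variance components are zero; Q_ST undefined", stacklevel=2)
        return float("nan")
    return float(sigma2_gb / denom)


@dataclass
class QstFstResult:
    trait: str
    contrast: str
    qst: float
    sigma2_gb: float
    sigma2_gw: float
    fst: FstSummary | None
    significant: bool | None
    converged: bool = True

    def as_record(self) -> dict:
        rec = {
            "trait": self.trait,
            "contrast": self.contrast,
            "qst": self.qst,
            "sigma2_GB": self.sigma2_gb,
            "sigma2_GW": self.sigma2_gw,
            "mean_fst": np.nan,
            "sd_fst": np.nan,
            "threshold": np.nan,
            "n_snps": 0,
            "significant": self.significant,
        }
        if self.fst is not None:
            rec.update(
                mean_fst=self.fst.mean_fst, sd_fst=self.fst.sd_fst,
                threshold=self.fst.threshold, n_snps=self.fst.n_snps_used,
            )
        return rec


def contrast_groups(passports: pd.DataFrame, contrast: str) -> tuple[list[str], list[str]]:
    """Accession ids on each side of a named population contrast."""
    column, side1, side2 = CONTRASTS[contrast]
    g1 = passports.loc[passports[column].isin(side1), "accession_id"].tolist()
    g2 = passports.loc[passports[column].isin(side2), "accession_id"].tolist()
    return g1, g2


def _scan_frame(pheno: pd.DataFrame, trait: str, g1: list[str], g2: list[str]) -> pd.DataFrame:
    """Observations of one trait for the contrast, labelled by side."""
    df = pheno.dropna(subset=[trait])
    df = df[df["accession_id"].isin(set(g1) | set(g2))].copy()
    side = np.where(df["accession_id"].isin(set(g1)), "side1", "side2")
    out = pd.DataFrame(
        {
            "y": df[trait].to_numpy(float),
            "POPULATION": side,
            "LINE": df["accession_id"].to_numpy(),
            "GARDEN": df["site_id"].to_numpy(),
            "BLOCK_IN_GARDEN": df["site_id"].astype(str) + "_b" + df["block"].astype(str),
        }
    )
    return out


def qst_from_frame(frame: pd.DataFrame, heritability: float = 1.0) -> tuple[float, VarianceComponents]:
    """Fit the variance-partition model on a prepared frame and return Q_ST.

    Frame columns: y, POPULATION, LINE, GARDEN, BLOCK_IN_GARDEN.
    Random terms with fewer than 2 observed levels are dropped.
    """
    random_terms = [
        t for t in ("POPULATION", "LINE", "GARDEN", "BLOCK_IN_GARDEN")
        if frame[t].nunique() >= 2
    ]
    spec = LmmSpec(response="y", fixed_terms=["1"], random_terms=random_terms)
    vc, _ = fit_lmm_reml(spec, frame)
    qst = compute_qst(vc.sigma2.get("POPULATION", 0.0),
                      vc.sigma2.get("LINE", 0.0), heritability)
    return qst, vc


def qst_fst_scan(
    pheno: pd.DataFrame,
    passports: pd.DataFrame,
    geno: GenotypeMatrix | None,
    traits: list[str],
    contrasts: list[str] | None = None,
    heritability: float = 1.0,
    min_lines_per_side: int = 2,
) -> list[QstFstResult]:
    """Q_ST vs Hudson-F_ST for every trait x contrast.

    Traits with too few lines per side or without any variation are skipped
    with a warning.  When genotypes are absent, Q_ST values are still
    reported with no significance call.
    """
    contrasts = contrasts or list(CONTRASTS)
    genotyped = set(geno.accession_ids) if geno is not None else set()
    results: list[QstFstResult] = []
    for contrast in contrasts:
        g1, g2 = contrast_groups(passports, contrast)
        summary = None
        if geno is not None:
            snp = hudson_fst_per_snp(
                geno,
                [a for a in g1 if a in genotyped],
                [a for a in g2 if a in genotyped],
            )
            summary = fst_summary(snp)
        for trait in traits:
            frame = _scan_frame(pheno, trait, g1, g2)
            n1 = frame.loc[frame["POPULATION"] == "side1", "LINE"].nunique()
            n2 = frame.loc[frame["POPULATION"] == "side2", "LINE"].nunique()
            if min(n1, n2) < min_lines_per_side:
                warnings.warn(
                    f"{trait}/{contrast}: fewer than {min_lines_per_side} lines "
                    "per side; skipped", stacklevel=2,
                )
                continue
            if np.ptp(frame["y"].to_numpy()) == 0:
                warnings.warn(f"{trait}/{contrast}: trait constant; skipped", stacklevel=2)
                continue
            qst, vc = qst_from_frame(frame, heritability)
            significant = None
            if summary is not None and np.isfinite(qst):
                significant = bool(qst > summary.threshold)
            results.append(
                QstFstResult(
                    trait=trait, contrast=contrast, qst=qst,
                    sigma2_gb=vc.sigma2.get("POPULATION", 0.0),
                    sigma2_gw=vc.sigma2.get("LINE", 0.0),
                    fst=summary, significant=significant,
                    converged=vc.converged,
                )
            )
    return results


def scan_table(results: list[QstFstResult]) -> pd.DataFrame:
    """Tidy one-row-per-trait-x-contrast table of a scan."""
    return pd.DataFrame.from_records([r.as_record() for r in results])
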