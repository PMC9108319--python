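"""The full G x E mixed model, marginal means, treatment contrasts, and
reaction norms.

The model for each trait is

    TRAIT ~ GARDEN * CONTINENT * ELEVATION + BLOCK:GARDEN
            + (1|LATITUDE) + (1|LATITUDE:GARDEN)

with GARDEN the common-garden site, CONTINENT and ELEVATION the origin
classes of the accession, BLOCK nested in GARDEN, and the latitude-pair
identifier as the random grouping (each pair holds one highland and one
lowland accession from the same latitude bin).  Marginal means for a
(garden, continent, elevation) cell average the fixed-effect predictions
over blocks with equal weights; contrasts between cells are tested with
Satterthwaite-df t-ratios, and the twelve standard contrasts come in three
families of four (between-garden within population, between-continent
within garden and elevation class, between-elevation-class within garden
and continent), each Bonferroni-corrected at alpha = 0.05/4 = 0.0125.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    CONTINENTS,
    DERIVED_ROW_TRAITS,
    ELEV_CLASSES,
    POPULATIONS,
    ROW_TRAITS,
    SITES,
)
from .lmm import LmmResult, build_fixed_design, build_random_design, fit_reml

#: number of comparisons per contrast family (tests of one trait within one family)
BONFERRONI_FAMILY_SIZE = 4

GXE_FIXED_TERMS = [
    "1", "GARDEN", "CONTINENT", "ELEVATION",
    "GARDEN:CONTINENT", "GARDEN:ELEVATION", "CONTINENT:ELEVATION",
    "GARDEN:CONTINENT:ELEVATION", "BLOCK(GARDEN)",
]
GXE_RANDOM_TERMS = ["LATITUDE", "LATITUDE:GARDEN"]

_LEVEL_ORDERS = {
    "GARDEN": list(SITES),
    "CONTINENT": list(CONTINENTS),
    "ELEVATION": list(ELEV_CLASSES),
    "BLOCK": ["1", "2"],
}

CONTRAST_FAMILIES = ("garden", "continent", "elevation")


def bonferroni_alpha(alpha: float = 0.05,
                     family_size: int = BONFERRONI_FAMILY_SIZE) -> float:
    """Per-test significance level after Bonferroni correction."""
    return alpha / family_size


def trait_level(trait: str) -> str:
    return "row" if trait in ROW_TRAITS + DERIVED_ROW_TRAITS else "plant"


def prepare_gxe_frame(pheno: pd.DataFrame, passports: pd.DataFrame,
                      trait: str) -> pd.DataFrame:
    """Join phenotype records (at the trait's own level) with origin factors."""
    level = trait_level(trait)
    df = pheno[(pheno["level"] == level)].dropna(subset=[trait])
    keep = passports[["accession_id", "continent", "elev_class", "latitude_pair_id"]]
    df = df.merge(keep, on="accession_id", how="left")
    frame = pd.DataFrame(
        {
            "y": df[trait].to_numpy(float),
            "GARDEN": df["site_id"].to_numpy(),
            "CONTINENT": df["continent"].to_numpy(),
            "ELEVATION": df["elev_class"].to_numpy(),
            "BLOCK": df["block"].astype(int).astype(str).to_numpy(),
            "LATITUDE": df["latitude_pair_id"].to_numpy(),
        }
    )
    return frame


@dataclass
class GxeFit:
    """A fitted G x E model bound to its design conventions."""

    trait: str
    result: LmmResult
    n_blocks: int = 2

    def _design_row(self, garden: str, continent: str, elevation: str,
                    block: str) -> np.ndarray:
        cell = pd.DataFrame(
            {"GARDEN": [garden], "CONTINENT": [continent],
             "ELEVATION": [elevation], "BLOCK": [block]}
        )
        X, names = build_fixed_design(cell, GXE_FIXED_TERMS, _LEVEL_ORDERS)
        if names != self.result.fixed_names:
            raise RuntimeError("design row does not match the fitted model")
        return X[0]

    def cell_weights(self, garden: str, continent: str, elevation: str) -> np.ndarray:
        """Fixed-effect weights of the cell's marginal mean (blocks averaged)."""
        blocks = _LEVEL_ORDERS["BLOCK"][: self.n_blocks]
        rows = [self._design_row(garden, continent, elevation, b) for b in blocks]
        return np.mean(rows, axis=0)

    def marginal_mean(self, garden: str, continent: str,
                      elevation: str) -> tuple[float, float]:
        """Estimated marginal mean and its standard error for one cell."""
        w = self.cell_weights(garden, continent, elevation)
        mean = float(w @ self.result.beta)
        se = float(np.sqrt(w @ self.result.cov_beta @ w))
        return mean, se


def fit_gxe_model(trait: str, frame: pd.DataFrame,
                  with_random: bool = True) -> GxeFit:
    """REML fit of the G x E model on a prepared frame.

    ``with_random=False`` drops the latitude random intercepts, reducing the
    model to ordinary least squares (useful for balanced-design checks).
    """
    for col in ("GARDEN", "CONTINENT", "ELEVATION"):
        if frame[col].nunique() < 2:
            raise ValueError(f"factor {col} needs both levels present")
    y = frame["y"].to_numpy(float)
    X, names = build_fixed_design(frame, GXE_FIXED_TERMS, _LEVEL_ORDERS)
    Zs = {}
    if with_random:
        if frame["LATITUDE"].nunique() < 2:
            raise ValueError("need at least 2 latitude groups")
        Zs = {t: build_random_design(frame, t) for t in GXE_RANDOM_TERMS}
    fit = fit_reml(y, X, Zs, fixed_names=names)
    return GxeFit(trait=trait, result=fit, n_blocks=frame["BLOCK"].nunique())


@dataclass
class ContrastResult:
    trait: str
    family: str
    contrast_id: str
    estimate: float
    se: float
    t_ratio: float
    df: float
    p_value: float
    significant_bonferroni: bool

    def as_record(self) -> dict:
        return {
            "trait": self.trait, "family": self.family,
            "contrast_id": self.contrast_id, "estimate": self.estimate,
            "se": self.se, "t_ratio": self.t_ratio, "df": self.df,
            "p_value": self.p_value,
            "significant_bonferroni": self.significant_bonferroni,
        }


def _family_cells(family: str):
    """(contrast_id, plus-cell, minus-cell) triples for one contrast family."""
    if family == "garden":
        for continent, elevation in itertools.product(CONTINENTS, ELEV_CLASSES):
            yield (
                f"HighSite-LowSite|{continent}{elevation}",
                ("HighSite", continent, elevation),
                ("LowSite", continent, elevation),
            )
    elif family == "continent":
        for garden, elevation in itertools.product(SITES, ELEV_CLASSES):
            yield (
                f"Mex-SA|{garden}|{elevation}Pop",
                (garden, "Mex", elevation),
                (garden, "SA", elevation),
            )
    elif family == "elevation":
        for garden, continent in itertools.product(SITES, CONTINENTS):
            yield (
                f"High-Low|{garden}|{continent}",
                (garden, continent, "High"),
                (garden, continent, "Low"),
            )
    else:
        raise ValueError(f"unknown contrast family '{family}'")


def contrast_tratios(fit: GxeFit, family: str,
                     alpha: float = 0.05) -> list[ContrastResult]:
    """The four marginal-mean contrasts of one family, with Satterthwaite df
    and the Bonferroni flag at alpha/4."""
    per_test = bonferroni_alpha(alpha, BONFERRONI_FAMILY_SIZE)
    out = []
    for contrast_id, plus, minus in _family_cells(family):
        c = fit.cell_weights(*plus) - fit.cell_weights(*minus)
        stat = fit.result.contrast(c)
        out.append(
            ContrastResult(
                trait=fit.trait, family=family, contrast_id=contrast_id,
                estimate=stat.estimate, se=stat.se, t_ratio=stat.t,
                df=stat.df, p_value=stat.p,
                significant_bonferroni=bool(stat.p < per_test),
            )
        )
    return out


def all_contrasts(fit: GxeFit, alpha: float = 0.05) -> list[ContrastResult]:
    return [
        r for family in CONTRAST_FAMILIES for r in contrast_tratios(fit, family, alpha)
    ]


def contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame.from_records([r.as_record() for r in results])


# ---------------------------------------------------------------------------
# Reaction norms
# ---------------------------------------------------------------------------


def reaction_norms(pheno: pd.DataFrame, passports: pd.DataFrame,
                   traits: list[str]) -> pd.DataFrame:
    """Population x garden cell means and SDs for each trait.

    Cells without data get missing values (with a warning).
    """
    pops = passports[["accession_id", "population"]]
    records = []
    for trait in traits:
        level = trait_level(trait)
        df = pheno[pheno["level"] == level].dropna(subset=[trait])
        df = df.merge(pops, on="accession_id", how="left")
        grouped = df.groupby(["population", "site_id"])[trait]
        stats_df = grouped.agg(["mean", "std", "count"])
        for pop in sorted(df["population"].dropna().unique()):
            for site in sorted(df["site_id"].unique()):
                if (pop, site) in stats_df.index:
                    m, s, n = stats_df.loc[(pop, site)]
                else:
                    warnings.warn(f"{trait}: empty cell {pop}/{site}", stacklevel=2)
                    m, s, n = np.nan, np.nan, 0
                records.append(
                    {"trait": trait, "population": pop, "site_id": site,
                     "mean": m, "sd": s, "n": int(n)}
                )
    return pd.DataFrame.from_records(records)


def crossing_indicators(norms: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Whether each population pair's reaction norms cross between gardens.

    Crossing means the sign of the between-population mean difference flips
    from one garden to the other (the 'Foreign vs Local' signature when the
    trait is a fitness metric).
    """
    sub = norms[norms["trait"] == trait]
    means = sub.pivot(index="population", columns="site_id", values="mean")
    pops = [p for p in POPULATIONS if p in means.index] or list(means.index)
    gardens = [s for s in SITES if s in means.columns] or list(means.columns)
    if len(gardens) != 2:
        raise ValueError("crossing defined for exactly two gardens")
    records = []
    for a, b in itertools.combinations(pops, 2):
        d1 = means.loc[a, gardens[0]] - means.loc[b, gardens[0]]
        d2 = means.loc[a, gardens[1]] - means.loc[b, gardens[1]]
        crossing = bool(d1 * d2 < 0) if np.isfinite(d1) and np.isfinite(d2) else None
        records.append(
            {"trait": trait, "pop_a": a, "pop_b": b,
             "diff_garden1": d1, "diff_garden2": d2, "crossing": crossing}
        )
    return pd.DataFrame.from_records(records)
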