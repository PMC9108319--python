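"""Environmental-distance fitness decay and garden-specific trait correlations.

Environmental distance for a variable is DISTANCE = Value_GARDEN -
Value_ORIGIN.  The decay test is two-stage: vegetative fitness is first
regressed on DISTANCE alone (absorbing unequal mean fitness between
gardens); the residuals e are then fit with e ~ DISTANCE + DISTANCE^2, and
the quadratic coefficient's t, two-sided p, and the stage-2 R^2 quantify
whether fitness falls away parabolically with distance in either direction.

Trait:trait Pearson correlations are computed per garden on
pairwise-complete observations; significance uses the t-test on r
(t = r sqrt((n-2)/(1-r^2)) on n-2 df, the behavior of R's cor.test), with a
Fisher-z normal test available as an option.  Between-garden differences
r_High - r_Low highlight correlations that change with elevation, and
traits are grouped by average-linkage hierarchical clustering on the
distance 1 - r.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import Dataset, ENV_VARS


def env_distance(origin_value, garden_value):
    """DISTANCE = Value_GARDEN - Value_ORIGIN (elementwise, nan-propagating)."""
    return np.asarray(garden_value, dtype=float) - np.asarray(origin_value, dtype=float)


@dataclass
class EnvDistanceResult:
    variable: str
    quad_coef: float
    t_value: float
    p_value: float
    r2: float
    n: int
    estimable: bool = True

    def as_record(self) -> dict:
        return {
            "variable": self.variable, "quad_coef": self.quad_coef,
            "t_value": self.t_value, "p_value": self.p_value,
            "r2": self.r2, "n": self.n, "estimable": self.estimable,
        }


def quadratic_residual_test(fitness, distances,
                            variable: str = "") -> EnvDistanceResult:
    """Two-stage quadratic decay test on per-accession-x-garden fitness."""
    y = np.asarray(fitness, dtype=float)
    d = np.asarray(distances, dtype=float)
    ok = np.isfinite(y) & np.isfinite(d)
    y, d = y[ok], d[ok]
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 complete observations")
    if np.ptp(d) == 0:
        warnings.warn(f"{variable or 'distance'}: degenerate distances", stacklevel=2)
        return EnvDistanceResult(variable, np.nan, np.nan, np.nan, np.nan, n, False)
    stage1 = sm.OLS(y, sm.add_constant(d)).fit()
    e = stage1.resid
    X2 = sm.add_constant(np.column_stack([d, d**2]))
    stage2 = sm.OLS(e, X2).fit()
    return EnvDistanceResult(
        variable=variable,
        quad_coef=float(stage2.params[2]),
        t_value=float(stage2.tvalues[2]),
        p_value=float(stage2.pvalues[2]),
        r2=float(stage2.rsquared),
        n=n,
    )


def accession_garden_fitness(pheno: pd.DataFrame,
                             trait: str = "FITplantveg") -> pd.DataFrame:
    """Mean fitness per accession x garden (the unit of the decay analysis)."""
    df = pheno.dropna(subset=[trait])
    out = (
        df.groupby(["accession_id", "site_id"])[trait]
        .mean()
        .reset_index()
        .rename(columns={trait: "fitness"})
    )
    return out


def env_distance_scan(
    ds: Dataset,
    variables: list[str] | None = None,
    fitness_trait: str = "FITplantveg",
) -> list[EnvDistanceResult]:
    """Run the quadratic decay test for every environmental variable."""
    variables = variables or [v for v in ENV_VARS if v in ds.env.columns]
    fit = accession_garden_fitness(ds.phenotypes, fitness_trait)
    env = ds.env.set_index("location_id")
    results = []
    for var in variables:
        origin = env.loc[fit["accession_id"], var].to_numpy()
        garden = env.loc[fit["site_id"], var].to_numpy()
        d = env_distance(origin, garden)
        results.append(quadratic_residual_test(fit["fitness"], d, variable=var))
    return results


def env_distance_table(results: list[EnvDistanceResult]) -> pd.DataFrame:
    return pd.DataFrame.from_records([r.as_record() for r in results])


# ---------------------------------------------------------------------------
# Garden-specific trait correlations
# ---------------------------------------------------------------------------


def _r_pvalue(r: float, n: int, method: str) -> float:
    if not np.isfinite(r) or n < 4 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 and n >= 4 else np.nan
    if method == "t":
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        return float(2.0 * stats.t.sf(abs(t), n - 2))
    if method == "fisher-z":
        z = np.arctanh(r) * np.sqrt(n - 3)
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method '{method}'")


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class GardenCorrelation:
    garden: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def garden_correlations(
    pheno: pd.DataFrame,
    traits: list[str],
    garden: str,
    method: str = "t",
    min_n: int = 4,
) -> GardenCorrelation:
    """Pairwise-complete Pearson correlations among traits within one garden.

    Plant- and row-level values are aligned per (accession, site, block,
    row): plant records inherit their row's row-level traits so mixed-level
    pairs are correlated at the plant level.
    """
    df = pheno[pheno["site_id"] == garden]
    key = ["accession_id", "site_id", "block", "row_id"]
    plant = df[df["level"] == "plant"]
    rows = df[df["level"] == "row"]
    row_cols = [t for t in traits if t in rows.columns and rows[t].notna().any()]
    if len(plant) == 0:
        merged = rows.copy()
    else:
        merged = plant.merge(
            rows[key + row_cols].drop_duplicates(subset=key),
            on=key, how="left", suffixes=("", "_row"),
        )
        # prefer the row-derived copy for traits the plant records do not carry
        for t in row_cols:
            if f"{t}_row" in merged.columns and merged[t].isna().all():
                merged[t] = merged[f"{t}_row"]
    wide = pd.DataFrame(index=merged.index)
    for t in traits:
        wide[t] = merged[t].to_numpy(dtype=float) if t in merged.columns else np.nan

    k = len(traits)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        n_mat[i, i] = int(wide[traits[i]].notna().sum())
        for j in range(i + 1, k):
            x, y = wide[traits[i]], wide[traits[j]]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            n_mat[i, j] = n_mat[j, i] = n
            if n < min_n or x[ok].std() == 0 or y[ok].std() == 0:
                r[i, j] = r[j, i] = np.nan
                continue
            rij = float(np.corrcoef(x[ok], y[ok])[0, 1])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = _r_pvalue(rij, n, method)
    idx = pd.Index(traits, name="trait")
    return GardenCorrelation(
        garden=garden,
        r=pd.DataFrame(r, index=idx, columns=traits),
        p=pd.DataFrame(p, index=idx, columns=traits),
        n=pd.DataFrame(n_mat, index=idx, columns=traits),
    )


def correlation_difference(high: pd.DataFrame, low: pd.DataFrame) -> pd.DataFrame:
    """Elementwise r_High - r_Low; positive = more positive in the high garden."""
    if list(high.index) != list(low.index) or list(high.columns) != list(low.columns):
        raise ValueError("correlation matrices cover different trait sets")
    return high - low


def cluster_traits(corr: pd.DataFrame, k: int = 5) -> pd.Series:
    """Average-linkage hierarchical clustering of traits on distance 1 - r.

    Returns cluster labels (1..k) indexed by trait; deterministic given the
    input matrix.
    """
    if k > corr.shape[0]:
        raise ValueError(f"k={k} exceeds the {corr.shape[0]} traits")
    d = 1.0 - corr.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("correlation matrix must be complete for clustering")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(np.clip(d, 0.0, None), checks=False)
    labels = fcluster(linkage(condensed, method="average"), t=k, criterion="maxclust")
    return pd.Series(labels, index=corr.index, name="cluster")
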