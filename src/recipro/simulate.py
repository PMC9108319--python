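"""Synthetic reciprocal-transplant experiments with known truth.

The generator emulates the statistical structure of the field design: four
landrace populations (Mexican/South American x Highland/Lowland) of 30
accessions each, organised in latitude pairs, grown in two common gardens
(LowSite, 54 m; HighSite, 2852 m) with two complete blocks of one row (15
seeds) per accession, two tagged plants per row.

Genotypes follow the Balding-Nichols model: each marker has an ancestral
frequency p ~ Uniform(0.05, 0.95); each population draws its frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F) so pairwise differentiation is approximately the
configured F; dosages are Binomial(2, p_pop) (Hardy-Weinberg within
populations).

Continuous phenotypes follow a Gaussian random-effects model
``y = mu + cell(pop, garden) + garden + block-in-garden + latitude-pair +
pair x garden + line + residual`` with configured variances; the
population x garden cell means come from a configurable G x E offset matrix
(crossed offsets produce crossing reaction norms).  Counts are generated as
STD ~ Binomial(15, p_survival), PE ~ Binomial(STD, p_ear),
EN ~ 1 + Poisson, EW ~ Lognormal; survival and ear probabilities optionally
decay quadratically with the elevation distance between garden and origin,
which is what makes fitness fall off with environmental distance.  Ordinal
0-4 scores threshold a latent Gaussian at its {0.2, 0.4, 0.6, 0.8} quantiles.

Every random draw comes from a stream derived from (seed, purpose-name), so
adding a trait does not perturb the draws of the others and identical
(config, seed) reproduce outputs bit for bit.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datatypes import (
    BIOCLIM_VARS,
    CONTINENTS,
    Dataset,
    ENV_VARS,
    GenotypeMatrix,
    ORDINAL_TRAITS,
    PERCENT_TRAITS,
    POPULATIONS,
    SITES,
)
from .io import write_dataset

GARDEN_ELEVATIONS = {"LowSite": 54.0, "HighSite": 2852.0}
GARDEN_YEARS = {"LowSite": 2017, "HighSite": 2016}


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible RNG stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class TraitSpec:
    """Generative parameters of one trait (variances in squared trait units)."""

    mu: float
    sigma2_pop: float = 0.0
    sigma2_line: float = 1.0
    sigma2_garden: float = 1.0
    sigma2_block: float = 0.25
    sigma2_lat: float = 0.25
    sigma2_latgarden: float = 0.25
    sigma2_resid: float = 1.0
    gxe_scale: float = 0.0  # multiplies the shared pop x garden offset matrix
    integer: bool = False   # round to integer counts (days, branch counts)

    def total_sd(self) -> float:
        return float(
            np.sqrt(
                self.sigma2_pop + self.sigma2_line + self.sigma2_garden
                + self.sigma2_block + self.sigma2_lat + self.sigma2_latgarden
                + self.sigma2_resid
            )
        )


def _default_trait_specs() -> dict[str, TraitSpec]:
    """Field-plausible scales for each generated trait (units of Table codes)."""
    return {
        "DTA": TraitSpec(78, 6, 6, 49, 1, 2, 1, 6, gxe_scale=1.0, integer=True),
        "ASI_latent": TraitSpec(2.0, 0.1, 0.2, 0.5, 0.05, 0.05, 0.05, 1.0, integer=True),
        "PH": TraitSpec(220, 100, 80, 150, 16, 16, 16, 350, gxe_scale=5.0),
        "EH": TraitSpec(110, 60, 50, 80, 9, 9, 9, 250, gxe_scale=3.0),
        "TL": TraitSpec(35, 4, 4, 4, 1, 1, 1, 16, gxe_scale=0.5),
        "TBN": TraitSpec(18, 4, 4, 2, 0.5, 0.5, 0.5, 9, gxe_scale=0.5, integer=True),
        "EL": TraitSpec(14, 1.5, 1.5, 1, 0.25, 0.25, 0.25, 4, gxe_scale=0.3),
        "KPR": TraitSpec(28, 6, 6, 4, 1, 1, 1, 16, gxe_scale=0.5, integer=True),
        "ED": TraitSpec(4.2, 0.04, 0.04, 0.04, 0.01, 0.01, 0.01, 0.16, gxe_scale=0.05),
        "d13C": TraitSpec(-12.5, 0.15, 0.1, 0.2, 0.02, 0.02, 0.02, 0.3, gxe_scale=0.1),
        # log-scale location of ear weight (grams); EW = exp(latent)
        "EW_latent": TraitSpec(np.log(90.0), 0.02, 0.02, 0.05, 0.01, 0.01, 0.01, 0.09,
                               gxe_scale=0.08),
        # latent scales for ordinal / percent visual scores
        "P_INTsolid": TraitSpec(0, 0.4, 0.3, 0.5, 0.05, 0.1, 0.1, 1.0, gxe_scale=0.4),
        "P_INTspot": TraitSpec(0, 0.3, 0.3, 0.5, 0.05, 0.1, 0.1, 1.0, gxe_scale=0.3),
        "P_EXTsolid": TraitSpec(0, 0.4, 0.3, 0.5, 0.05, 0.1, 0.1, 1.0, gxe_scale=0.4),
        "P_EXTspot": TraitSpec(0, 0.3, 0.3, 0.5, 0.05, 0.1, 0.1, 1.0, gxe_scale=0.3),
        "M_DENsolid": TraitSpec(0, 0.6, 0.4, 0.1, 0.05, 0.05, 0.05, 1.0, gxe_scale=0.2),
        "M_DENmarg": TraitSpec(0, 0.3, 0.3, 0.1, 0.05, 0.05, 0.05, 1.0, gxe_scale=0.1),
    }


def _default_gxe_pattern(n_pops: int = 4, n_gardens: int = 2) -> np.ndarray:
    """+1 at a population's home-elevation garden, -1 away (local adaptation).

    Rows follow ``POPULATIONS`` order, columns ``SITES`` order
    (LowSite, HighSite).
    """
    pattern = np.zeros((n_pops, n_gardens))
    for i, pop in enumerate(POPULATIONS[:n_pops]):
        home_high = pop.endswith("High")
        for j, site in enumerate(SITES[:n_gardens]):
            at_high = site == "HighSite"
            pattern[i, j] = 1.0 if home_high == at_high else -1.0
    return pattern


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment."""

    n_pops: int = 4
    n_lines_per_pop: int = 30
    n_markers: int = 2000
    fst_target: float = 0.05
    n_gardens: int = 2
    n_blocks: int = 2
    seeds_per_row: int = 15
    n_plants_per_row: int = 2
    seed: int = 0
    geno_missing_rate: float = 0.02
    p_survival: float = 0.92
    p_ear: float = 0.85
    #: quadratic decay of survival/ear probability per (km elevation distance)^2
    env_decay: float = -0.02
    en_rate: float = 0.4  # EN ~ 1 + Poisson(en_rate)
    ordinal_quantiles: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    variance_spec: dict[str, TraitSpec] = field(default_factory=_default_trait_specs)
    gxe_matrix: np.ndarray | None = None  # default: home-elevation crossing pattern

    def __post_init__(self) -> None:
        if self.gxe_matrix is None:
            self.gxe_matrix = (
                _default_gxe_pattern(self.n_pops, self.n_gardens)
                if self.n_pops == 4
                else np.zeros((self.n_pops, self.n_gardens))
            )
        self.gxe_matrix = np.asarray(self.gxe_matrix, dtype=float)
        if self.gxe_matrix.shape != (self.n_pops, self.n_gardens):
            raise ValueError(
                f"gxe_matrix shape {self.gxe_matrix.shape} must be "
                f"({self.n_pops}, {self.n_gardens})"
            )
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must lie in [0, 1)")
        for name, spec in self.variance_spec.items():
            for f in dataclasses.fields(spec):
                if f.name.startswith("sigma2") and getattr(spec, f.name) < 0:
                    raise ValueError(f"negative variance for trait {name}: {f.name}")

    # -- population / accession bookkeeping --------------------------------

    def population_names(self) -> list[str]:
        if self.n_pops == 4:
            return list(POPULATIONS)
        return [f"Pop{i + 1}" for i in range(self.n_pops)]

    def accession_ids(self) -> list[str]:
        return [
            f"{pop}_{i + 1:03d}"
            for pop in self.population_names()
            for i in range(self.n_lines_per_pop)
        ]

    def garden_names(self) -> list[str]:
        if self.n_gardens == 2:
            return list(SITES)
        return [f"Garden{i + 1}" for i in range(self.n_gardens)]

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            if isinstance(v, np.ndarray):
                return clean(v.tolist())
            if isinstance(v, np.floating):
                return float(v)
            if isinstance(v, np.integer):
                return int(v)
            return v

        d = dataclasses.asdict(self)
        d["gxe_matrix"] = self.gxe_matrix.tolist()
        d["ordinal_quantiles"] = list(self.ordinal_quantiles)
        return clean(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "variance_spec" in d:
            d["variance_spec"] = {
                k: v if isinstance(v, TraitSpec) else TraitSpec(**v)
                for k, v in d["variance_spec"].items()
            }
        if "ordinal_quantiles" in d:
            d["ordinal_quantiles"] = tuple(d["ordinal_quantiles"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Genotypes (Balding-Nichols)
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Balding-Nichols dosages for all accessions; deterministic given seed."""
    rng = substream(config.seed, "genotypes")
    n_pop, n_line, n_mark = config.n_pops, config.n_lines_per_pop, config.n_markers
    p_anc = rng.uniform(0.05, 0.95, size=n_mark)
    F = config.fst_target
    if F == 0.0:
        # degenerate Beta: populations share the ancestral frequency exactly
        p_pop = np.broadcast_to(p_anc, (n_pop, n_mark)).copy()
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_pop = rng.beta(a, b, size=(n_pop, n_mark))
    dosages = np.empty((n_pop * n_line, n_mark), dtype=float)
    for k in range(n_pop):
        rows = slice(k * n_line, (k + 1) * n_line)
        dosages[rows] = rng.binomial(2, p_pop[k], size=(n_line, n_mark))
    if config.geno_missing_rate > 0:
        mask = rng.random(dosages.shape) < config.geno_missing_rate
        dosages[mask] = np.nan
    marker_ids = [f"snp{j + 1:05d}" for j in range(n_mark)]
    return GenotypeMatrix(config.accession_ids(), marker_ids, dosages)


# ---------------------------------------------------------------------------
# Environment and passports
# ---------------------------------------------------------------------------

# affine dependence of each bioclim-style variable on elevation (km):
# (intercept, slope per km, noise sd).  Temperature-like variables cool with
# elevation; precipitation-like variables also trend with elevation, with
# enough noise to mimic the collinear-but-not-identical bioclim panel.
_ENV_AFFINE: dict[str, tuple[float, float, float]] = {}
for _i, _v in enumerate(BIOCLIM_VARS):
    if _v == "annual_mean_temp":
        _ENV_AFFINE[_v] = (27.0, -6.0, 0.8)
    elif _v == "annual_precip":
        _ENV_AFFINE[_v] = (1400.0, -180.0, 110.0)
    elif _v.startswith("bio") and int(_v[3:]) < 12:
        _ENV_AFFINE[_v] = (18.0 + _i, -(3.0 + 0.4 * _i), 1.0)
    else:
        _ENV_AFFINE[_v] = (700.0 + 40.0 * _i, -(60.0 + 8.0 * _i), 60.0)


def _env_values(elev_m: np.ndarray, rng: np.random.Generator | None) -> dict[str, np.ndarray]:
    elev_km = np.asarray(elev_m, dtype=float) / 1000.0
    out = {"elevation": np.asarray(elev_m, dtype=float)}
    for var, (a, b, sd) in _ENV_AFFINE.items():
        noise = rng.normal(0, sd, size=elev_km.shape) if rng is not None else 0.0
        out[var] = a + b * elev_km + noise
    return out


def simulate_environment(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Passports (accession origins) and the per-location environment table.

    Returns ``(passports, env)``.  High-population origins sit above 2000 m,
    Low below 1000 m; each latitude pair holds exactly one High and one Low
    accession from the same continent.  Garden rows of ``env`` use the two
    real site elevations (54 m and 2852 m) and noise-free bioclim values.
    """
    if config.n_pops != 4:
        raise ValueError("the field design requires the four standard populations")
    rng = substream(config.seed, "environment")
    n_pairs = config.n_lines_per_pop  # pairs per continent
    records = []
    lat_ranges = {"Mex": (15.0, 25.0), "SA": (-35.0, -5.0)}
    lon_ranges = {"Mex": (-105.0, -93.0), "SA": (-79.0, -63.0)}
    for continent in CONTINENTS:
        lats = rng.uniform(*lat_ranges[continent], size=n_pairs)
        for i in range(n_pairs):
            pair_id = f"{continent}_pair{i + 1:02d}"
            for elev_class in ("High", "Low"):
                if elev_class == "High":
                    elev = rng.uniform(2100.0, 3400.0)
                else:
                    elev = rng.uniform(60.0, 950.0)
                records.append(
                    {
                        "accession_id": f"{continent}{elev_class}_{i + 1:03d}",
                        "latitude": round(lats[i] + rng.uniform(-0.5, 0.5), 4),
                        "longitude": round(rng.uniform(*lon_ranges[continent]), 4),
                        "elevation": round(elev, 1),
                        "continent": continent,
                        "elev_class": elev_class,
                        "population": f"{continent}{elev_class}",
                        "latitude_pair_id": pair_id,
                    }
                )
    passports = pd.DataFrame.from_records(records)
    # keep accession order aligned with genotype/accession id order
    passports = passports.set_index("accession_id").loc[config.accession_ids()].reset_index()

    env_rows = []
    for site in config.garden_names():
        vals = _env_values(np.array([GARDEN_ELEVATIONS[site]]), rng=None)
        env_rows.append(
            {"location_id": site, "kind": "garden", "year": GARDEN_YEARS[site]}
            | {k: float(v[0]) for k, v in vals.items()}
        )
    origin_vals = _env_values(passports["elevation"].to_numpy(), rng)
    for i, acc in enumerate(passports["accession_id"]):
        env_rows.append(
            {"location_id": acc, "kind": "origin", "year": np.nan}
            | {k: float(v[i]) for k, v in origin_vals.items()}
        )
    env = pd.DataFrame.from_records(env_rows, columns=["location_id", "kind", "year", *ENV_VARS])
    return passports, env


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _draw_effects(rng: np.random.Generator, levels: int, sigma2: float) -> np.ndarray:
    if sigma2 <= 0:
        return np.zeros(levels)
    return rng.normal(0.0, np.sqrt(sigma2), size=levels)


def _continuous_trait(
    name: str,
    spec: TraitSpec,
    config: SimulationConfig,
    pop_idx: np.ndarray,
    garden_idx: np.ndarray,
    block_idx: np.ndarray,
    pair_idx: np.ndarray,
    line_idx: np.ndarray,
    truth: dict,
) -> np.ndarray:
    """One draw of a Gaussian-random-effects trait at given record coordinates."""
    rng = substream(config.seed, f"trait:{name}")
    n_pairs = pair_idx.max() + 1 if pair_idx.size else 0
    n_lines = line_idx.max() + 1 if line_idx.size else 0
    garden_eff = _draw_effects(rng, config.n_gardens, spec.sigma2_garden)
    block_eff = _draw_effects(rng, config.n_gardens * config.n_blocks, spec.sigma2_block)
    lat_eff = _draw_effects(rng, n_pairs, spec.sigma2_lat)
    latgarden_eff = _draw_effects(rng, n_pairs * config.n_gardens, spec.sigma2_latgarden)
    pop_eff = _draw_effects(rng, config.n_pops, spec.sigma2_pop)
    line_eff = _draw_effects(rng, n_lines, spec.sigma2_line)
    resid = rng.normal(0.0, np.sqrt(spec.sigma2_resid), size=len(pop_idx))
    cell = spec.gxe_scale * config.gxe_matrix
    y = (
        spec.mu
        + cell[pop_idx, garden_idx]
        + pop_eff[pop_idx]
        + garden_eff[garden_idx]
        + block_eff[garden_idx * config.n_blocks + block_idx]
        + lat_eff[pair_idx]
        + latgarden_eff[pair_idx * config.n_gardens + garden_idx]
        + line_eff[line_idx]
        + resid
    )
    truth[name] = {
        "mu": spec.mu,
        "cell_means": (spec.mu + cell).tolist(),
        "garden_effects": garden_eff.tolist(),
        "pop_effects": pop_eff.tolist(),
        "total_sd": spec.total_sd(),
    }
    return y


def _ordinal_from_latent(latent: np.ndarray, spec: TraitSpec,
                         quantiles: tuple[float, ...]) -> np.ndarray:
    sd = spec.total_sd()
    cuts = spec.mu + sd * stats.norm.ppf(quantiles)
    return np.digitize(latent, cuts).astype(float)


def simulate_phenotypes(
    config: SimulationConfig,
    passports: pd.DataFrame,
    env: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Generate the full phenotype table (row and plant records) plus truth."""
    gardens = config.garden_names()
    accessions = passports["accession_id"].tolist()
    n_acc = len(accessions)
    pops = config.population_names()
    pop_of_acc = passports["population"].map({p: i for i, p in enumerate(pops)}).to_numpy()
    pair_codes = pd.Categorical(passports["latitude_pair_id"]).codes

    garden_elev = {
        r["location_id"]: r["elevation"]
        for _, r in env[env["kind"] == "garden"].iterrows()
    }
    origin_elev = passports["elevation"].to_numpy()

    # --- record coordinate frame (rows) ------------------------------------
    rows = []
    for g_i, site in enumerate(gardens):
        for b in range(config.n_blocks):
            for a_i, acc in enumerate(accessions):
                rows.append((acc, site, b + 1, f"{site}_b{b + 1}_r{a_i + 1:03d}",
                             g_i, b, a_i))
    row_df = pd.DataFrame(
        rows, columns=["accession_id", "site_id", "block", "row_id",
                       "_g", "_b", "_a"]
    )
    g_idx = row_df["_g"].to_numpy()
    b_idx = row_df["_b"].to_numpy()
    a_idx = row_df["_a"].to_numpy()
    p_idx = pop_of_acc[a_idx]
    pr_idx = pair_codes[a_idx]

    truth: dict = {"seed": config.seed, "traits": {}}

    # --- survival / ear counts with quadratic environmental decay ----------
    d_km = np.array(
        [(garden_elev[s] - origin_elev[a]) / 1000.0
         for s, a in zip(row_df["site_id"], a_idx)]
    )
    p_surv = config.p_survival + config.env_decay * d_km**2
    p_ear = config.p_ear + config.env_decay * d_km**2
    n_clip = int(np.sum((p_surv < 0.01) | (p_surv > 0.999) |
                        (p_ear < 0.01) | (p_ear > 0.999)))
    if n_clip:
        warnings.warn(
            f"{n_clip} survival/ear probabilities outside [0,1] were clipped",
            stacklevel=2,
        )
    p_surv = np.clip(p_surv, 0.01, 0.999)
    p_ear = np.clip(p_ear, 0.01, 0.999)
    rng_counts = substream(config.seed, "counts")
    std = rng_counts.binomial(config.seeds_per_row, p_surv)
    pe = rng_counts.binomial(std, p_ear)
    truth["traits"]["survival"] = {
        "p_survival": config.p_survival, "p_ear": config.p_ear,
        "env_decay": config.env_decay,
    }

    tt = truth["traits"]
    dta = _continuous_trait("DTA", config.variance_spec["DTA"], config,
                            p_idx, g_idx, b_idx, pr_idx, a_idx, tt)
    asi = _continuous_trait("ASI_latent", config.variance_spec["ASI_latent"], config,
                            p_idx, g_idx, b_idx, pr_idx, a_idx, tt)
    dta = np.round(dta)
    dts = dta + np.round(asi)

    row_records = row_df[["accession_id", "site_id", "block", "row_id"]].copy()
    row_records["plant_id"] = pd.NA
    row_records["level"] = "row"
    row_records["STD"] = std.astype(float)
    row_records["PE"] = pe.astype(float)
    row_records["DTA"] = dta
    row_records["DTS"] = dts

    # --- plant-level records ------------------------------------------------
    n_plants = config.n_plants_per_row
    plant_df = row_df.loc[row_df.index.repeat(n_plants)].reset_index(drop=True)
    plant_df["plant_id"] = [
        f"p{i % n_plants + 1}" for i in range(len(plant_df))
    ]
    pg = plant_df["_g"].to_numpy()
    pb = plant_df["_b"].to_numpy()
    pa = plant_df["_a"].to_numpy()
    pp = pop_of_acc[pa]
    ppr = pair_codes[pa]

    plant_records = plant_df[["accession_id", "site_id", "block", "row_id", "plant_id"]].copy()
    plant_records["level"] = "plant"

    for name in ("PH", "EH", "TL", "TBN", "EL", "KPR", "ED", "d13C"):
        spec = config.variance_spec[name]
        y = _continuous_trait(name, spec, config, pp, pg, pb, ppr, pa, tt)
        if spec.integer:
            y = np.round(np.maximum(y, 0))
        plant_records[name] = y

    rng_en = substream(config.seed, "trait:EN")
    plant_records["EN"] = 1.0 + rng_en.poisson(config.en_rate, size=len(plant_df))
    tt["EN"] = {"rate": config.en_rate}

    ew_latent = _continuous_trait("EW_latent", config.variance_spec["EW_latent"],
                                  config, pp, pg, pb, ppr, pa, tt)
    plant_records["EW"] = np.exp(ew_latent)

    for name in ORDINAL_TRAITS + PERCENT_TRAITS:
        spec = config.variance_spec[name]
        latent = _continuous_trait(name, spec, config, pp, pg, pb, ppr, pa, tt)
        score = _ordinal_from_latent(latent, spec, config.ordinal_quantiles)
        plant_records[name] = score * 25.0 if name in PERCENT_TRAITS else score

    # row-level trait columns stay missing on plant records and vice versa
    pheno = pd.concat([row_records, plant_records], ignore_index=True, sort=False)
    id_cols = ["accession_id", "site_id", "block", "row_id", "plant_id", "level"]
    trait_cols = [c for c in pheno.columns if c not in id_cols]
    pheno = pheno[id_cols + trait_cols]
    return pheno, truth


# ---------------------------------------------------------------------------
# Whole experiments
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig,
                     with_genotypes: bool = True) -> tuple[Dataset, dict]:
    """Generate a complete in-memory experiment."""
    passports, env = simulate_environment(config)
    pheno, truth = simulate_phenotypes(config, passports, env)
    geno = simulate_genotypes(config) if with_genotypes else None
    return Dataset(pheno, passports, geno, env), truth


def simulate_experiment(config: SimulationConfig, out_dir: str | Path,
                        with_genotypes: bool = True) -> dict[str, Path]:
    """Generate an experiment and write it to disk (loadable by read_dataset)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = simulate_dataset(config, with_genotypes=with_genotypes)
    paths = write_dataset(ds, out)
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    config_path = out / "sim_config.yaml"
    config.to_yaml(config_path)
    paths["config"] = config_path
    return paths


# ---------------------------------------------------------------------------
# Focused variance-partition draws for calibration studies
# ---------------------------------------------------------------------------


def simulate_variance_partition(
    n_pops: int,
    n_lines_per_pop: int,
    sigma2_pop: float,
    sigma2_line: float,
    sigma2_resid: float,
    n_gardens: int = 2,
    n_blocks: int = 2,
    sigma2_garden: float = 0.0,
    sigma2_block: float = 0.0,
    mu: float = 0.0,
    pop_means: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one balanced dataset from the Q_ST variance-partition model.

    Columns: POPULATION, LINE, GARDEN, BLOCK_IN_GARDEN, y.  ``pop_means``
    (length n_pops) replaces random population effects with fixed offsets,
    which is how divergent-selection scenarios are constructed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pop_eff = (
        np.asarray(pop_means, dtype=float)
        if pop_means is not None
        else rng.normal(0, np.sqrt(sigma2_pop), size=n_pops)
    )
    line_eff = rng.normal(0, np.sqrt(sigma2_line), size=n_pops * n_lines_per_pop)
    garden_eff = rng.normal(0, np.sqrt(sigma2_garden), size=n_gardens)
    block_eff = rng.normal(0, np.sqrt(sigma2_block), size=n_gardens * n_blocks)
    rows = []
    for p in range(n_pops):
        for l in range(n_lines_per_pop):
            line = p * n_lines_per_pop + l
            for g in range(n_gardens):
                for b in range(n_blocks):
                    rows.append((f"pop{p + 1}", f"line{line + 1}", f"g{g + 1}",
                                 f"g{g + 1}_b{b + 1}", p, line, g, g * n_blocks + b))
    df = pd.DataFrame(rows, columns=["POPULATION", "LINE", "GARDEN",
                                     "BLOCK_IN_GARDEN", "_p", "_l", "_g", "_gb"])
    y = (
        mu
        + pop_eff[df["_p"]]
        + line_eff[df["_l"]]
        + garden_eff[df["_g"]]
        + block_eff[df["_gb"]]
        + rng.normal(0, np.sqrt(sigma2_resid), size=len(df))
    )
    df["y"] = y
    return df.drop(columns=["_p", "_l", "_g", "_gb"])
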