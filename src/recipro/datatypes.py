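"""Domain types and trait vocabulary for the reciprocal-transplant analysis.

The experiment grows maize landrace accessions from four populations
(Mexican Highland, Mexican Lowland, South American Highland, South American
Lowland) in two common gardens at contrasting elevations.  Phenotypes are
recorded either per row (a row is 15 planted seeds of one accession) or per
tagged plant.  Trait codes follow the field notebook convention; ``d13C``
stands in for the carbon-isotope ratio trait (delta-13-C, per mil).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Trait vocabulary
# ---------------------------------------------------------------------------

#: Raw traits recorded at the row level.
ROW_TRAITS = ("STD", "PE", "DTA", "DTS")

#: Raw traits recorded on individual tagged plants.
PLANT_TRAITS = (
    "PH", "EH", "TL", "TBN", "EN", "EW", "EL", "KPR", "ED", "d13C",
    "P_INTsolid", "P_INTspot", "P_EXTsolid", "P_EXTspot",
    "M_DENsolid", "M_DENmarg",
)

RAW_TRAITS = ROW_TRAITS + PLANT_TRAITS

#: Derived traits and the level they live at.
DERIVED_ROW_TRAITS = ("BRN", "ASI")
DERIVED_PLANT_TRAITS = ("FITplantveg", "FITplant")
DERIVED_TRAITS = DERIVED_ROW_TRAITS + DERIVED_PLANT_TRAITS

ALL_TRAITS = RAW_TRAITS + DERIVED_TRAITS

#: Visual 0-4 code-scale traits (anthocyanin intensity, macrohair density).
ORDINAL_TRAITS = ("P_INTsolid", "P_INTspot", "M_DENsolid", "M_DENmarg")

#: Percent-extent traits scored at 25% intervals.
PERCENT_TRAITS = ("P_EXTsolid", "P_EXTspot")
PERCENT_LEVELS = (0, 25, 50, 75, 100)

#: Non-negative integer count traits.
COUNT_TRAITS = ("STD", "PE", "DTA", "DTS", "TBN", "EN", "KPR")

SEEDS_PER_ROW = 15

# ---------------------------------------------------------------------------
# Factor vocabulary
# ---------------------------------------------------------------------------

CONTINENTS = ("Mex", "SA")
ELEV_CLASSES = ("High", "Low")
POPULATIONS = ("MexHigh", "MexLow", "SAHigh", "SALow")
SITES = ("LowSite", "HighSite")
BLOCKS = (1, 2)

#: Elevation band limits for accession eligibility (meters).
LOWLAND_MAX_ELEV = 1000.0
HIGHLAND_MIN_ELEV = 2000.0

#: Identifier columns of a phenotype table (before trait columns).
ID_COLUMNS = ("accession_id", "site_id", "block", "row_id", "plant_id", "level")

PASSPORT_COLUMNS = (
    "accession_id", "latitude", "longitude", "elevation",
    "continent", "elev_class", "population", "latitude_pair_id",
)

#: Environment variables every garden-site record must carry.
CORE_ENV_VARS = ("elevation", "annual_mean_temp", "annual_precip")

#: The 20 location-level environmental variables used by the distance scan:
#: elevation plus 19 bioclim-style variables (bio1 = annual mean temperature,
#: bio12 = annual precipitation, under their descriptive aliases).
BIOCLIM_VARS = tuple(
    ["annual_mean_temp"]
    + [f"bio{i}" for i in range(2, 12)]
    + ["annual_precip"]
    + [f"bio{i}" for i in range(13, 20)]
)
ENV_VARS = ("elevation",) + BIOCLIM_VARS

ENV_COLUMNS = ("location_id", "kind", "year") + ENV_VARS


def population_of(continent: str, elev_class: str) -> str:
    """Compose the population label from continent and elevation class."""
    return f"{continent}{elev_class}"


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Accession x biallelic-SNP alt-allele dosage matrix.

    ``dosages`` is a float array with entries in {0, 1, 2} and ``nan`` for
    missing calls.  Accessions index rows, markers index columns (0-based).
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (nan)")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, accessions: list[str]) -> "GenotypeMatrix":
        """Row-subset to ``accessions`` (order preserved as given)."""
        index = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in accessions if a not in index]
        if missing:
            raise KeyError(f"accessions not genotyped: {missing[:5]}")
        rows = [index[a] for a in accessions]
        return GenotypeMatrix(list(accessions), list(self.marker_ids), self.dosages[rows])

    def marker_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=pd.Index(self.accession_ids, name="accession_id"),
            columns=self.marker_ids,
        )


# ---------------------------------------------------------------------------
# Dataset bundle and validation report
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """One loaded experiment: phenotypes, passports, genotypes, environments.

    ``env`` holds one row per location (two garden sites plus each accession
    origin) with elevation and the bioclim-style variables; garden rows carry
    ``kind == "garden"`` and a year.
    """

    phenotypes: pd.DataFrame
    passports: pd.DataFrame
    genotypes: GenotypeMatrix | None
    env: pd.DataFrame

    @property
    def gardens(self) -> pd.DataFrame:
        """Garden-site environment records (LowSite / HighSite)."""
        return self.env[self.env["kind"] == "garden"].reset_index(drop=True)


@dataclass
class ValidationReport:
    """Outcome of dataset validation; violations are data, not exceptions."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_accessions: int = 0
    n_markers: int = 0
    n_records: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        status = "PASS" if self.ok else "FAIL"
        return (
            f"{status}: {self.n_records} records, {self.n_accessions} accessions, "
            f"{self.n_markers} markers; {len(self.errors)} errors, "
            f"{len(self.warnings)} warnings"
        )
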