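"""Dataset validation against the design invariants of the experiment.

Validation is pure: it never mutates the dataset and repeated calls return
identical reports.  Violations are reported with record coordinates so they
can be traced back to the offending row of the source table.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    CONTINENTS,
    CORE_ENV_VARS,
    COUNT_TRAITS,
    Dataset,
    ELEV_CLASSES,
    HIGHLAND_MIN_ELEV,
    LOWLAND_MAX_ELEV,
    ORDINAL_TRAITS,
    PERCENT_LEVELS,
    PERCENT_TRAITS,
    SEEDS_PER_ROW,
    ValidationReport,
    population_of,
)


def _passport_errors(passports: pd.DataFrame, errors: list[str]) -> None:
    for _, row in passports.iterrows():
        acc = row["accession_id"]
        elev = row["elevation"]
        klass = row["elev_class"]
        if klass not in ELEV_CLASSES:
            errors.append(f"passport {acc}: unknown elev_class '{klass}'")
            continue
        if klass == "High" and not elev > HIGHLAND_MIN_ELEV:
            errors.append(
                f"passport {acc}: elev_class High requires elevation > "
                f"{HIGHLAND_MIN_ELEV:.0f} m (got {elev:.0f} m)"
            )
        if klass == "Low" and not elev < LOWLAND_MAX_ELEV:
            errors.append(
                f"passport {acc}: elev_class Low requires elevation < "
                f"{LOWLAND_MAX_ELEV:.0f} m (got {elev:.0f} m)"
            )
        if row["continent"] not in CONTINENTS:
            errors.append(f"passport {acc}: unknown continent '{row['continent']}'")
        elif row["population"] != population_of(row["continent"], klass):
            errors.append(
                f"passport {acc}: population '{row['population']}' inconsistent with "
                f"continent/elev_class"
            )
    if passports["accession_id"].duplicated().any():
        dups = passports.loc[passports["accession_id"].duplicated(), "accession_id"]
        errors.append(f"passport: duplicated accession ids {sorted(set(dups))[:5]}")
    for pair_id, grp in passports.groupby("latitude_pair_id"):
        classes = sorted(grp["elev_class"].tolist())
        if classes != ["High", "Low"]:
            errors.append(
                f"latitude pair {pair_id}: expected exactly one High and one Low "
                f"member, got {classes}"
            )


def _pheno_errors(pheno: pd.DataFrame, known_acc: set, known_sites: set,
                  errors: list[str], seeds_per_row: int) -> None:
    def coord(row) -> str:
        return (
            f"record(accession={row['accession_id']}, site={row['site_id']}, "
            f"block={row['block']}, row={row['row_id']}, plant={row['plant_id']})"
        )

    for _, row in pheno.iterrows():
        if row["accession_id"] not in known_acc:
            errors.append(f"{coord(row)}: unknown accession id")
        if row["site_id"] not in known_sites:
            errors.append(f"{coord(row)}: unknown site id '{row['site_id']}'")
        if row["level"] not in ("row", "plant"):
            errors.append(f"{coord(row)}: level must be 'row' or 'plant'")
        std = row.get("STD", np.nan)
        pe = row.get("PE", np.nan)
        if pd.notna(std) and pd.notna(pe):
            if not 0 <= pe <= std:
                errors.append(f"{coord(row)}: requires 0 <= PE <= STD (PE={pe}, STD={std})")
        if pd.notna(std) and std > seeds_per_row:
            errors.append(
                f"{coord(row)}: STD={std} exceeds seeds planted per row ({seeds_per_row})"
            )
        for t in ORDINAL_TRAITS:
            v = row.get(t, np.nan)
            if pd.notna(v) and v not in (0, 1, 2, 3, 4):
                errors.append(f"{coord(row)}: {t}={v} outside the visual 0-4 code scale")
        for t in PERCENT_TRAITS:
            v = row.get(t, np.nan)
            if pd.notna(v) and v not in PERCENT_LEVELS:
                errors.append(f"{coord(row)}: {t}={v} not a 25% interval value")
        for t in COUNT_TRAITS:
            v = row.get(t, np.nan)
            if pd.notna(v) and (v < 0 or float(v) != int(v)):
                errors.append(f"{coord(row)}: {t}={v} is not a non-negative integer")


def validate_dataset(
    ds: Dataset,
    seeds_per_row: int = SEEDS_PER_ROW,
    max_marker_missing: float = 0.5,
) -> ValidationReport:
    """Check every type invariant of the dataset and report violations."""
    errors: list[str] = []
    warns: list[str] = []

    _passport_errors(ds.passports, errors)
    known_acc = set(ds.passports["accession_id"])
    gardens = ds.gardens
    known_sites = set(gardens["location_id"]) if len(gardens) else set()
    if not known_sites:
        known_sites = set(ds.phenotypes["site_id"].unique())
        warns.append("no garden environment records; site ids taken from phenotypes")
    else:
        for var in CORE_ENV_VARS:
            if var not in ds.env.columns:
                errors.append(f"environment table missing core variable '{var}'")

    _pheno_errors(ds.phenotypes, known_acc, known_sites, errors, seeds_per_row)

    n_markers = 0
    if ds.genotypes is not None:
        n_markers = ds.genotypes.n_markers
        unknown = [a for a in ds.genotypes.accession_ids if a not in known_acc]
        if unknown:
            errors.append(f"genotypes: accessions absent from passport {unknown[:5]}")
        miss = ds.genotypes.marker_missing_rate()
        bad = np.flatnonzero(miss > max_marker_missing)
        if bad.size:
            errors.append(
                f"genotypes: {bad.size} markers exceed missingness ceiling "
                f"{max_marker_missing:.2f} (first: {ds.genotypes.marker_ids[bad[0]]})"
            )

    return ValidationReport(
        errors=errors,
        warnings=warns,
        n_accessions=len(ds.passports),
        n_markers=n_markers,
        n_records=len(ds.phenotypes),
    )
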