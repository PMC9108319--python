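"""Derived and composite traits computed from raw field records.

Fitness combines row-level survival with plant-level ear traits:

    FITplantveg = PE/15 * sqrt(EN)
    FITplant    = PE/15 * sqrt(EN) * EW

where PE is the row's ear-producing stand count, 15 the seeds planted per
row, EN the tagged plant's ear number and EW its primary-ear weight (grams).
Barrenness is BRN = 1 - PE/STD, anthesis-silking interval ASI = DTS - DTA
(negative values preserved: slightly early pollen shed is biologically
meaningful), and the carbon-isotope composition is
delta13C = (R_sample/R_standard - 1) * 1000 per mil against the Vienna Pee
Dee Belemnite standard.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import SEEDS_PER_ROW


def compute_fitness(
    pe,
    en,
    ew=None,
    seeds_per_row: int = SEEDS_PER_ROW,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (FITplant, FITplantveg); FITplant is missing where EW is.

    Accepts scalars or arrays.  PE must not exceed the seeds planted.
    """
    pe = np.asarray(pe, dtype=float)
    en = np.asarray(en, dtype=float)
    if np.any(pe[~np.isnan(pe)] > seeds_per_row) or np.any(pe[~np.isnan(pe)] < 0):
        raise ValueError(f"PE must lie in [0, {seeds_per_row}]")
    if np.any(en[~np.isnan(en)] < 0):
        raise ValueError("EN must be non-negative")
    fitveg = pe / seeds_per_row * np.sqrt(en)
    if ew is None:
        fit = np.full_like(fitveg, np.nan)
    else:
        ew = np.asarray(ew, dtype=float)
        if np.any(ew[~np.isnan(ew)] < 0):
            raise ValueError("EW must be non-negative")
        fit = fitveg * ew
    return fit, fitveg


def compute_barrenness(std, pe) -> np.ndarray:
    """BRN = 1 - PE/STD; missing (with a warning) where STD = 0."""
    std = np.asarray(std, dtype=float)
    pe = np.asarray(pe, dtype=float)
    ok = ~(np.isnan(std) | np.isnan(pe))
    if np.any(pe[ok] > std[ok]) or np.any(pe[ok] < 0):
        raise ValueError("requires STD >= PE >= 0")
    zero = ok & (std == 0)
    if np.any(zero):
        warnings.warn(
            f"BRN undefined for {int(zero.sum())} records with STD = 0", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        brn = 1.0 - pe / std
    return np.where(std == 0, np.nan, brn)


def compute_asi(dta, dts) -> np.ndarray:
    """ASI = DTS - DTA in days; missing if either flowering date is."""
    return np.asarray(dts, dtype=float) - np.asarray(dta, dtype=float)


def compute_delta13c(ratio_sample, ratio_standard) -> np.ndarray:
    """delta13C = (R_sample/R_standard - 1) * 1000, in per mil."""
    rs = np.asarray(ratio_sample, dtype=float)
    rstd = np.asarray(ratio_standard, dtype=float)
    if np.any(rs[~np.isnan(rs)] <= 0) or np.any(rstd[~np.isnan(rstd)] <= 0):
        raise ValueError("isotope ratios must be positive")
    return (rs / rstd - 1.0) * 1000.0


def add_derived_traits(pheno: pd.DataFrame,
                       seeds_per_row: int = SEEDS_PER_ROW) -> pd.DataFrame:
    """Append BRN/ASI to row records and FITplant/FITplantveg to plant records.

    Plant fitness mixes levels by design: the row's PE (matched on
    site/block/row) is combined with the tagged plant's EN and EW.
    """
    out = pheno.copy()
    is_row = out["level"] == "row"
    is_plant = out["level"] == "plant"

    for col in ("BRN", "ASI", "FITplant", "FITplantveg"):
        out[col] = np.nan

    if is_row.any():
        rows = out.loc[is_row]
        if {"STD", "PE"}.issubset(rows.columns):
            out.loc[is_row, "BRN"] = compute_barrenness(rows["STD"], rows["PE"])
        if {"DTA", "DTS"}.issubset(rows.columns):
            out.loc[is_row, "ASI"] = compute_asi(rows["DTA"], rows["DTS"])

    if is_plant.any():
        key = ["accession_id", "site_id", "block", "row_id"]
        row_pe = (
            out.loc[is_row, key + ["PE"]]
            .rename(columns={"PE": "_row_pe"})
            .drop_duplicates(subset=key)
        )
        plants = out.loc[is_plant, key + ["EN", "EW"]].merge(
            row_pe, on=key, how="left"
        )
        fit, fitveg = compute_fitness(
            plants["_row_pe"], plants["EN"], plants["EW"], seeds_per_row
        )
        out.loc[is_plant, "FITplant"] = fit
        out.loc[is_plant, "FITplantveg"] = fitveg
    return out
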