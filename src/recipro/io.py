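"""Readers and writers for the delimited tables and VCF files of the pipeline.

Tables are CSV or TSV with a header row; trait columns use the field-notebook
codes.  Missing values are accepted as empty cells or ``NA`` and always
written back as ``NA``.  Genotypes are read either from a VCF (biallelic SNP
records only; others are skipped with a warning count) or from a TSV dosage
matrix with accessions as rows.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    Dataset,
    ENV_COLUMNS,
    GenotypeMatrix,
    ID_COLUMNS,
    PASSPORT_COLUMNS,
    RAW_TRAITS,
)

NA_VALUES = ["", "NA"]


class SchemaError(ValueError):
    """A mandatory column is absent or a table is structurally malformed."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path, required: tuple[str, ...], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} table not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), na_values=NA_VALUES, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{label} table {path} is missing mandatory column '{col}'")
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ID_COLUMNS, "phenotype")
    traits = [c for c in df.columns if c in RAW_TRAITS or c not in ID_COLUMNS]
    if not traits:
        raise SchemaError(f"phenotype table {path} has no trait columns")
    return df


def read_passports(path: str | Path) -> pd.DataFrame:
    return _read_table(path, PASSPORT_COLUMNS, "passport")


def read_env(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ("location_id", "kind", "elevation"), "environment")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (``.vcf``) or a TSV dosage matrix into a GenotypeMatrix."""
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_dosage_tsv(path)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into alt-allele dosages.

    Non-biallelic records (multi-allelic, symbolic or indel alleles) are
    skipped; the number skipped is reported through ``warnings``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    skipped = 0
    bases = {"A", "C", "G", "T"}
    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1 or variant.REF not in bases or alts[0] not in bases:
            skipped += 1
            continue
        marker_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        dose = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 >= 0 and a1 >= 0:
                dose[i] = float(a0 + a1)
        columns.append(dose)
    vcf.close()
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic/non-SNP VCF records", stacklevel=2)
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, marker_ids, dosages)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = _read_table(path, ("accession_id",), "genotype dosage")
    markers = [c for c in df.columns if c != "accession_id"]
    dosages = df[markers].to_numpy(dtype=float)
    return GenotypeMatrix(df["accession_id"].astype(str).tolist(), markers, dosages)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal single-contig VCFv4.2 with GT calls."""
    path = Path(path)
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accession_ids)
            + "\n"
        )
        for j, marker in enumerate(geno.marker_ids):
            calls = [
                "./." if np.isnan(d) else gt_code[float(d)]
                for d in geno.dosages[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{marker}\tA\tG\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    geno.to_frame().reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Dataset-level IO
# ---------------------------------------------------------------------------


def read_dataset(
    pheno_path: str | Path,
    passport_path: str | Path,
    geno_path: str | Path | None = None,
    env_path: str | Path | None = None,
) -> Dataset:
    """Load one experiment from disk; genotypes are optional."""
    phenotypes = read_phenotypes(pheno_path)
    passports = read_passports(passport_path)
    genotypes = read_genotypes(geno_path) if geno_path is not None else None
    env = read_env(env_path) if env_path is not None else pd.DataFrame(columns=list(ENV_COLUMNS))
    return Dataset(phenotypes, passports, genotypes, env)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result/phenotype table as TSV with deterministic formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(Path(path)), index=False, na_rep="NA")


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out / "pheno.tsv",
        "passports": out / "passport.tsv",
        "env": out / "env.tsv",
    }
    write_table(ds.phenotypes, paths["phenotypes"])
    write_table(ds.passports, paths["passports"])
    write_table(ds.env, paths["env"])
    if ds.genotypes is not None:
        paths["genotypes"] = out / "geno.vcf"
        write_vcf(ds.genotypes, paths["genotypes"])
    return paths


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_results(results: dict[str, pd.DataFrame | object], out_dir: str | Path) -> list[Path]:
    """Write each result family as a flat TSV plus one machine-readable JSON.

    ``results`` maps a family name (e.g. ``qst_fst``) to either a tidy
    DataFrame or any dataclass/dict structure.  Field ordering is
    deterministic, so re-running on identical inputs reproduces the files
    byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    blob: dict[str, object] = {}
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.tsv"
            write_table(obj, path)
            written.append(path)
        blob[name] = _jsonable(obj)
    json_path = out / "results.json"
    with open(json_path, "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    written.append(json_path)
    return written
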