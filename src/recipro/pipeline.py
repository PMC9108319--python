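"""End-to-end orchestration: simulate -> derive traits -> popgen ->
Q_ST/F_ST -> G x E -> environmental distance & correlations.

Each run is driven by one YAML config and a seed; the manifest records
per-stage status and SHA-256 checksums of every file written, so identical
(config, seed) runs reproduce identical checksums.  A stage failure leaves
earlier outputs intact and is recorded in the manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import envcorr, gxe, popgen, quantgen
from .datatypes import Dataset
from .io import write_table
from .simulate import SimulationConfig, simulate_experiment
from .traits import add_derived_traits
from .validate import validate_dataset

log = logging.getLogger("recipro")

STAGES = ("simulate", "derive_traits", "popgen", "qst_fst", "gxe", "envdist_corr")

#: traits analysed by default in the scan / G x E / correlation stages
DEFAULT_SCAN_TRAITS = [
    "FITplant", "FITplantveg", "STD", "PE", "BRN", "DTA", "DTS", "ASI",
    "PH", "EH", "TL", "TBN", "EN", "EW", "EL", "KPR", "ED", "d13C",
    "P_INTsolid", "P_INTspot", "P_EXTsolid", "P_EXTspot",
    "M_DENsolid", "M_DENmarg",
]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    with_genotypes: bool = True
    traits: list[str] = field(default_factory=lambda: list(DEFAULT_SCAN_TRAITS))
    gxe_traits: list[str] | None = None     # default: same as traits
    corr_traits: list[str] | None = None    # default: traits minus d13C
    contrasts: list[str] = field(default_factory=lambda: list(quantgen.CONTRASTS))
    n_clusters: int = 5
    pca_components: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    if seed is not None:
        config.simulation.seed = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": config.simulation.seed,
        "stages": {},
        "checksums": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, status: str, files: list[Path] = (), note: str = ""):
        manifest["stages"][stage] = {"status": status, "note": note,
                                     "files": [f.name for f in files]}
        for f in files:
            manifest["checksums"][f.name] = _sha256(Path(f))

    ds: Dataset | None = None
    derived: pd.DataFrame | None = None

    # -- simulate ------------------------------------------------------------
    try:
        paths = simulate_experiment(config.simulation, out / "data",
                                    with_genotypes=config.with_genotypes)
        from .io import read_dataset

        ds = read_dataset(
            paths["phenotypes"], paths["passports"],
            paths.get("genotypes"), paths["env"],
        )
        report = validate_dataset(ds, seeds_per_row=config.simulation.seeds_per_row)
        if not report.ok:
            raise RuntimeError(f"synthetic dataset failed validation: {report.errors[:3]}")
        record("simulate", "ok", list(paths.values()), report.summary())
    except Exception as exc:  # noqa: BLE001 - manifest must record any failure
        log.exception("simulate stage failed")
        record("simulate", "failed", note=str(exc))
        _write_manifest(manifest, out)
        raise

    # -- derived traits ------------------------------------------------------
    try:
        derived = add_derived_traits(ds.phenotypes, config.simulation.seeds_per_row)
        path = out / "derived.tsv"
        write_table(derived, path)
        record("derive_traits", "ok", [path])
    except Exception as exc:  # noqa: BLE001
        log.exception("derive_traits stage failed")
        record("derive_traits", "failed", note=str(exc))
        _write_manifest(manifest, out)
        raise

    # -- popgen ---------------------------------------------------------------
    if ds.genotypes is None:
        record("popgen", "skipped", note="no genotypes in config")
        record("qst_fst", "skipped", note="no genotypes in config")
    else:
        try:
            files = []
            pca = popgen.genotype_pca(ds.genotypes, n_components=config.pca_components)
            pca_path = out / "pca_scores.tsv"
            write_table(pca.scores.reset_index(), pca_path)
            files.append(pca_path)
            pct_path = out / "pca_pct_var.tsv"
            write_table(
                pd.DataFrame({"component": pca.scores.columns, "pct_var": pca.pct_var}),
                pct_path,
            )
            files.append(pct_path)
            for contrast in config.contrasts:
                g1, g2 = quantgen.contrast_groups(ds.passports, contrast)
                snp = popgen.hudson_fst_per_snp(ds.genotypes, g1, g2)
                p = out / f"fst_{contrast.replace(':', '_vs_')}.tsv"
                write_table(snp, p)
                files.append(p)
            record("popgen", "ok", files)

            results = quantgen.qst_fst_scan(
                derived, ds.passports, ds.genotypes, config.traits, config.contrasts
            )
            scan_path = out / "qst_fst.tsv"
            write_table(quantgen.scan_table(results), scan_path)
            record("qst_fst", "ok", [scan_path])
        except Exception as exc:  # noqa: BLE001
            log.exception("popgen/qst_fst stage failed")
            record("qst_fst", "failed", note=str(exc))
            _write_manifest(manifest, out)
            raise

    # -- G x E ----------------------------------------------------------------
    try:
        gxe_traits = config.gxe_traits or config.traits
        all_rows = []
        for trait in gxe_traits:
            frame = gxe.prepare_gxe_frame(derived, ds.passports, trait)
            if len(frame) == 0:
                continue
            fit = gxe.fit_gxe_model(trait, frame)
            all_rows.extend(gxe.all_contrasts(fit))
        contrasts_df = gxe.contrast_table(all_rows)
        c_path = out / "gxe_contrasts.tsv"
        write_table(contrasts_df, c_path)
        norms = gxe.reaction_norms(derived, ds.passports, gxe_traits)
        n_path = out / "reaction_norms.tsv"
        write_table(norms, n_path)
        record("gxe", "ok", [c_path, n_path])
    except Exception as exc:  # noqa: BLE001
        log.exception("gxe stage failed")
        record("gxe", "failed", note=str(exc))
        _write_manifest(manifest, out)
        raise

    # -- environmental distance + correlations -------------------------------
    try:
        files = []
        env_results = envcorr.env_distance_scan(
            Dataset(derived, ds.passports, ds.genotypes, ds.env)
        )
        e_path = out / "envdist.tsv"
        write_table(envcorr.env_distance_table(env_results), e_path)
        files.append(e_path)
        corr_traits = config.corr_traits or [t for t in config.traits if t != "d13C"]
        mats = {}
        for garden in sorted(derived["site_id"].unique()):
            gc = envcorr.garden_correlations(derived, corr_traits, garden)
            mats[garden] = gc
            p = out / f"corr_{garden}.tsv"
            write_table(gc.r.reset_index(), p)
            files.append(p)
        if {"HighSite", "LowSite"}.issubset(mats):
            diff = envcorr.correlation_difference(
                mats["HighSite"].r, mats["LowSite"].r
            )
            p = out / "corr_diff.tsv"
            write_table(diff.reset_index(), p)
            files.append(p)
            for garden, gc in mats.items():
                if not gc.r.isna().any().any():
                    clusters = envcorr.cluster_traits(gc.r, k=config.n_clusters)
                    p = out / f"trait_clusters_{garden}.tsv"
                    write_table(clusters.reset_index(), p)
                    files.append(p)
        record("envdist_corr", "ok", files)
    except Exception as exc:  # noqa: BLE001
        log.exception("envdist_corr stage failed")
        record("envdist_corr", "failed", note=str(exc))
        _write_manifest(manifest, out)
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> Path:
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
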