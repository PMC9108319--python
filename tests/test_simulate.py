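"""The synthetic-experiment generator: determinism, design structure, and
the statistical targets of its genotype and phenotype models."""
from __future__ import annotations

import time

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recipro.popgen import fst_summary, hudson_fst_per_snp
from recipro.simulate import (
    GARDEN_ELEVATIONS,
    SimulationConfig,
    _default_trait_specs,
    simulate_dataset,
    simulate_environment,
    simulate_experiment,
    simulate_genotypes,
)
from recipro.traits import add_derived_traits
from recipro.validate import validate_dataset


def test_determinism_bit_for_bit(small_config):
    a, _ = simulate_dataset(small_config)
    b, _ = simulate_dataset(small_config)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.env, b.env)
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    other, _ = simulate_dataset(SimulationConfig(
        n_lines_per_pop=small_config.n_lines_per_pop,
        n_markers=small_config.n_markers, seed=small_config.seed + 1,
    ))
    assert not np.array_equal(a.genotypes.dosages, other.genotypes.dosages)


def test_genotype_shape_and_missingness():
    cfg = SimulationConfig(n_pops=3, n_lines_per_pop=5, n_markers=77, seed=2,
                           geno_missing_rate=0.05)
    geno = simulate_genotypes(cfg)
    assert geno.dosages.shape == (15, 77)
    assert 0 < np.isnan(geno.dosages).mean() < 0.15


@pytest.mark.parametrize("f_target,tol", [(0.0, 0.01), (0.10, 0.02)])
def test_balding_nichols_differentiation(f_target, tol):
    """Mean per-SNP Hudson F_ST tracks the Balding-Nichols parameter.

    2000 markers keep the Monte-Carlo error well below the tolerance; the
    mean of per-SNP ratios sits slightly below the nominal F (a known
    property of averaging ratio estimators), inside the band."""
    cfg = SimulationConfig(n_pops=2, n_lines_per_pop=100, n_markers=2000,
                           fst_target=f_target, seed=1, geno_missing_rate=0.0)
    geno = simulate_genotypes(cfg)
    ids = cfg.accession_ids()
    summary = fst_summary(hudson_fst_per_snp(geno, ids[:100], ids[100:]))
    assert abs(summary.mean_fst - f_target) <= tol


def test_environment_design_structure():
    """Default design: 120 passports in 60 latitude pairs, High > 2000 m and
    Low < 1000 m, gardens at 54 m and 2852 m."""
    passports, env = simulate_environment(SimulationConfig(seed=4))
    assert len(passports) == 120
    high = passports[passports["elev_class"] == "High"]
    low = passports[passports["elev_class"] == "Low"]
    assert len(high) == len(low) == 60
    assert (high["elevation"] > 2000).all()
    assert (low["elevation"] < 1000).all()
    pair_classes = passports.groupby("latitude_pair_id")["elev_class"].agg(sorted)
    assert (pair_classes.map(tuple) == ("High", "Low")).all()
    gardens = env[env["kind"] == "garden"].set_index("location_id")
    assert gardens.loc["LowSite", "elevation"] == GARDEN_ELEVATIONS["LowSite"] == 54.0
    assert gardens.loc["HighSite", "elevation"] == GARDEN_ELEVATIONS["HighSite"] == 2852.0
    # bioclim panel is collinear with elevation, as in real data
    origins = env[env["kind"] == "origin"]
    r = np.corrcoef(origins["elevation"], origins["annual_mean_temp"])[0, 1]
    assert r < -0.9


def test_zero_variance_traits_constant():
    spec = _default_trait_specs()
    for s in spec.values():
        for name in ("sigma2_pop", "sigma2_line", "sigma2_garden", "sigma2_block",
                     "sigma2_lat", "sigma2_latgarden", "sigma2_resid"):
            setattr(s, name, 0.0)
        s.gxe_scale = 0.0
    cfg = SimulationConfig(n_lines_per_pop=4, seed=5, variance_spec=spec)
    ds, _ = simulate_dataset(cfg, with_genotypes=False)
    ph = ds.phenotypes.loc[ds.phenotypes["level"] == "plant", "PH"]
    assert (ph == spec["PH"].mu).all()


def test_crossed_gxe_reproduces_cell_means():
    """Sample population x garden means follow the configured crossing
    pattern within Monte-Carlo error."""
    spec = _default_trait_specs()
    spec["PH"].gxe_scale = 60.0
    cfg = SimulationConfig(n_lines_per_pop=12, seed=6, variance_spec=spec)
    ds, truth = simulate_dataset(cfg, with_genotypes=False)
    merged = ds.phenotypes[ds.phenotypes["level"] == "plant"].merge(
        ds.passports[["accession_id", "population"]], on="accession_id"
    )
    cells = merged.groupby(["population", "site_id"])["PH"].mean().unstack()
    configured = np.array(truth["traits"]["PH"]["cell_means"])
    pops = cfg.population_names()
    for i, pop in enumerate(pops):
        observed = cells.loc[pop, ["LowSite", "HighSite"]].to_numpy()
        # crossing direction of the configured offsets is reproduced
        assert np.sign(np.diff(observed)) == np.sign(np.diff(configured[i]))


def test_negative_env_decay_lowers_fitness_at_distance():
    """More elevationally displaced accessions have lower vegetative fitness
    (rank correlation test)."""
    cfg = SimulationConfig(n_lines_per_pop=12, seed=8, env_decay=-0.02)
    ds, _ = simulate_dataset(cfg, with_genotypes=False)
    pheno = add_derived_traits(ds.phenotypes)
    fit = (
        pheno.dropna(subset=["FITplantveg"])
        .groupby(["accession_id", "site_id"])["FITplantveg"].mean().reset_index()
    )
    elev = ds.passports.set_index("accession_id")["elevation"]
    d2 = np.array([
        (GARDEN_ELEVATIONS[s] - elev[a]) ** 2 / 1e6
        for a, s in zip(fit["accession_id"], fit["site_id"])
    ])
    rho = stats.spearmanr(d2, fit["FITplantveg"]).statistic
    assert rho < -0.3


def test_experiment_on_disk_valid_and_deterministic(tmp_path):
    import hashlib

    cfg = SimulationConfig(n_lines_per_pop=4, n_markers=50, seed=9)
    t0 = time.time()
    paths_a = simulate_experiment(cfg, tmp_path / "a")
    assert time.time() - t0 < 5.0  # smoke-config budget
    paths_b = simulate_experiment(cfg, tmp_path / "b")
    for key in paths_a:
        ha = hashlib.sha256(paths_a[key].read_bytes()).hexdigest()
        hb = hashlib.sha256(paths_b[key].read_bytes()).hexdigest()
        assert ha == hb, key
    from recipro.io import read_dataset

    ds = read_dataset(paths_a["phenotypes"], paths_a["passports"],
                      paths_a["genotypes"], paths_a["env"])
    report = validate_dataset(ds)
    assert report.ok, report.errors[:3]


def test_config_validation():
    with pytest.raises(ValueError, match="fst_target"):
        SimulationConfig(fst_target=1.5)
    with pytest.raises(ValueError, match="gxe_matrix"):
        SimulationConfig(gxe_matrix=np.zeros((3, 3)))
    spec = _default_trait_specs()
    spec["PH"].sigma2_line = -1.0
    with pytest.raises(ValueError, match="negative variance"):
        SimulationConfig(variance_spec=spec)
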