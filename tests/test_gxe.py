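"""G x E model: OLS oracle equivalence, marginal means, contrasts,
Bonferroni flags, and reaction-norm crossing."""
from __future__ import annotations

import numpy as np
import pytest

from recipro.gxe import (
    BONFERRONI_FAMILY_SIZE,
    bonferroni_alpha,
    all_contrasts,
    contrast_tratios,
    crossing_indicators,
    fit_gxe_model,
    prepare_gxe_frame,
    reaction_norms,
)
from recipro.simulate import SimulationConfig, simulate_dataset, _default_trait_specs


def test_bonferroni_alpha_exact():
    assert bonferroni_alpha() == 0.05 / 4 == 0.0125
    assert BONFERRONI_FAMILY_SIZE == 4


@pytest.fixture(scope="module")
def ph_frame(small_dataset):
    ds, _ = small_dataset
    return prepare_gxe_frame(ds.phenotypes, ds.passports, "PH")


def test_ols_oracle_equivalence(ph_frame):
    """Without random effects the fit reproduces least squares, and cell
    marginal means equal balanced sample means."""
    fit = fit_gxe_model("PH", ph_frame, with_random=False)
    from recipro.lmm import build_fixed_design
    from recipro.gxe import GXE_FIXED_TERMS, _LEVEL_ORDERS

    X, _ = build_fixed_design(ph_frame, GXE_FIXED_TERMS, _LEVEL_ORDERS)
    beta_ols, *_ = np.linalg.lstsq(X, ph_frame["y"].to_numpy(), rcond=None)
    np.testing.assert_allclose(fit.result.beta, beta_ols, atol=1e-6)

    for garden in ("LowSite", "HighSite"):
        for cont in ("Mex", "SA"):
            for elev in ("High", "Low"):
                mean, se = fit.marginal_mean(garden, cont, elev)
                sample = ph_frame[
                    (ph_frame["GARDEN"] == garden)
                    & (ph_frame["CONTINENT"] == cont)
                    & (ph_frame["ELEVATION"] == elev)
                ]["y"].mean()
                np.testing.assert_allclose(mean, sample, atol=1e-8)


def test_cell_weights_normalised(ph_frame):
    fit = fit_gxe_model("PH", ph_frame, with_random=False)
    w = fit.cell_weights("HighSite", "Mex", "High")
    # intercept weight 1 = the weights over the averaged grid sum to one
    assert w[0] == 1.0
    # contrast of a cell with itself is exactly null
    c = w - w
    stat = fit.result.contrast(c)
    assert stat.estimate == 0.0 and stat.t == 0.0


def test_mixed_fit_converges_with_nonneg_components(ph_frame):
    fit = fit_gxe_model("PH", ph_frame)
    assert fit.result.converged
    assert all(v >= 0 for v in fit.result.sigma2.values())
    for res in all_contrasts(fit):
        assert 1.0 <= res.df <= fit.result.resid_df
        assert res.significant_bonferroni == (res.p_value < 0.0125)
        np.testing.assert_allclose(res.t_ratio * res.se, res.estimate, rtol=1e-9)


def test_type_i_error_at_bonferroni_level(ph_frame, rng):
    """Zero-effect simulations reject at the 0.0125 per-test level within
    Monte-Carlo error (random variances at zero -> OLS algebra)."""
    from recipro.gxe import GXE_FIXED_TERMS, _LEVEL_ORDERS, _family_cells
    from recipro.lmm import build_fixed_design, fit_reml

    fit0 = fit_gxe_model("PH", ph_frame, with_random=False)
    contrasts = [
        fit0.cell_weights(*plus) - fit0.cell_weights(*minus)
        for _, plus, minus in _family_cells("elevation")
    ]
    X, names = build_fixed_design(ph_frame, GXE_FIXED_TERMS, _LEVEL_ORDERS)
    n_rep, hits, total = 2000, 0, 0
    for _ in range(n_rep):
        y = rng.normal(0, 1, X.shape[0])
        fit = fit_reml(y, X, fixed_names=names)
        for c in contrasts:
            hits += fit.contrast(c).p < 0.0125
            total += 1
    rate = hits / total
    assert abs(rate - 0.0125) < 0.005, rate


def test_additive_truth_has_null_interaction():
    """With no configured G x E the three-way interaction is within 3 SE of
    zero."""
    spec = _default_trait_specs()
    for s in spec.values():
        s.gxe_scale = 0.0
    cfg = SimulationConfig(n_lines_per_pop=8, seed=21, variance_spec=spec)
    ds, _ = simulate_dataset(cfg, with_genotypes=False)
    frame = prepare_gxe_frame(ds.phenotypes, ds.passports, "PH")
    fit = fit_gxe_model("PH", frame)
    i = fit.result.fixed_names.index(
        "GARDEN[HighSite]:CONTINENT[SA]:ELEVATION[Low]"
    )
    est = fit.result.beta[i]
    se = np.sqrt(fit.result.cov_beta[i, i])
    assert abs(est) < 3 * se


def test_reaction_norms_match_groupby(small_dataset):
    ds, _ = small_dataset
    norms = reaction_norms(ds.phenotypes, ds.passports, ["PH"])
    merged = ds.phenotypes[ds.phenotypes["level"] == "plant"].merge(
        ds.passports[["accession_id", "population"]], on="accession_id"
    )
    for _, row in norms.iterrows():
        cell = merged[
            (merged["population"] == row["population"])
            & (merged["site_id"] == row["site_id"])
        ]["PH"]
        np.testing.assert_allclose(row["mean"], cell.mean(), rtol=1e-12)
        np.testing.assert_allclose(row["sd"], cell.std(ddof=1), rtol=1e-12)


def test_crossing_indicator():
    """A strongly crossed G x E matrix crosses the configured
    opposite-elevation pairs; a constant trait crosses nothing."""
    spec = _default_trait_specs()
    resid_sd = np.sqrt(spec["PH"].sigma2_resid)
    spec["PH"].gxe_scale = 5 * resid_sd
    cfg = SimulationConfig(n_lines_per_pop=8, seed=31, variance_spec=spec)
    ds, _ = simulate_dataset(cfg, with_genotypes=False)
    norms = reaction_norms(ds.phenotypes, ds.passports, ["PH"])
    cross = crossing_indicators(norms, "PH").set_index(["pop_a", "pop_b"])
    assert cross.loc[("MexHigh", "MexLow"), "crossing"]
    assert cross.loc[("SAHigh", "SALow"), "crossing"]

    pheno = ds.phenotypes.copy()
    pheno["PH"] = np.where(pheno["level"] == "plant", 100.0, np.nan)
    flat = crossing_indicators(reaction_norms(pheno, ds.passports, ["PH"]), "PH")
    assert not flat["crossing"].any()
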