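"""REML engine: closed-form oracles, boundary behavior, lme4 agreement."""
from __future__ import annotations

import subprocess

import numpy as np
import pytest

from recipro.lmm import build_fixed_design, fit_reml, indicator
from recipro.simulate import simulate_variance_partition
from recipro.quantgen import LmmSpec, fit_lmm_reml


def _balanced_oneway(rng, groups=10, reps=8, s2_between=1.5, s2_within=1.0):
    codes = np.repeat(np.arange(groups), reps)
    y = rng.normal(0, np.sqrt(s2_within), groups * reps)
    y += np.repeat(rng.normal(0, np.sqrt(s2_between), groups), reps)
    return y, codes


def test_balanced_oneway_matches_anova_mom(rng):
    """On balanced one-way data REML equals (MSB - MSW)/n0 when positive."""
    groups, reps = 10, 8
    y, codes = _balanced_oneway(rng, groups, reps)
    fit = fit_reml(y, np.ones((len(y), 1)), {"group": indicator(codes)})
    gm = y.reshape(groups, reps).mean(axis=1)
    msb = reps * np.sum((gm - y.mean()) ** 2) / (groups - 1)
    msw = np.sum((y.reshape(groups, reps) - gm[:, None]) ** 2) / (groups * (reps - 1))
    assert fit.converged
    np.testing.assert_allclose(fit.sigma2["group"], (msb - msw) / reps, atol=1e-6)
    np.testing.assert_allclose(fit.sigma2["resid"], msw, atol=1e-6)


def test_zero_signal_hits_boundary(rng):
    """With group means forced equal, the between-group component must land
    exactly on the zero boundary."""
    codes = np.repeat(np.arange(10), 8)
    y = rng.normal(0, 1, 80)
    y -= y.reshape(10, 8).mean(axis=1)[codes]  # remove all between-group signal
    fit = fit_reml(y, np.ones((80, 1)), {"group": indicator(codes)})
    assert fit.sigma2["group"] == 0.0
    assert fit.sigma2["resid"] > 0


def test_reml_is_maximum_on_grid(rng):
    """The optimizer's value beats a brute-force grid evaluation of the
    restricted likelihood."""
    from recipro.lmm import _neg2_reml

    y, codes = _balanced_oneway(rng, groups=6, reps=5)
    X = np.ones((len(y), 1))
    Z = indicator(codes)
    fit = fit_reml(y, X, {"group": Z})
    f_opt, _, _ = _neg2_reml(
        np.array([fit.sigma2["group"], fit.sigma2["resid"]]), y, X, [Z],
        want_grad=False,
    )
    grid = np.linspace(0.05, 4.0, 25)
    for sb in grid:
        for sw in grid:
            f, _, _ = _neg2_reml(np.array([sb, sw]), y, X, [Z], want_grad=False)
            assert f_opt <= f + 1e-9


def test_variance_recovery_within_3se():
    """Estimated components sit within 3 reported SEs of the generating
    values on one balanced draw."""
    df = simulate_variance_partition(
        8, 20, sigma2_pop=2.0, sigma2_line=1.0, sigma2_resid=1.0,
        sigma2_garden=0.2, sigma2_block=0.1, seed=5,
    )
    spec = LmmSpec("y", ["1"], ["POPULATION", "LINE", "GARDEN", "BLOCK_IN_GARDEN"])
    vc, _ = fit_lmm_reml(spec, df)
    truth = {"POPULATION": 2.0, "LINE": 1.0, "resid": 1.0}
    for term, value in truth.items():
        assert abs(vc.sigma2[term] - value) < 3 * max(vc.se[term], 1e-6), term


def test_singular_design_names_aliased_column(rng):
    X, names = np.column_stack([np.ones(10), np.ones(10)]), ["Intercept", "dup"]
    with pytest.raises(ValueError, match="dup|Intercept"):
        fit_reml(rng.normal(size=10), X, {}, fixed_names=names)


def test_ols_path_matches_pooled_two_sample_t(rng):
    from scipy import stats

    grp = np.repeat([0.0, 1.0], 25)
    y = rng.normal(0, 1, 50) + 0.4 * grp
    fit = fit_reml(y, np.column_stack([np.ones(50), grp]))
    stat = fit.contrast(np.array([0.0, 1.0]))
    t_ref, p_ref = stats.ttest_ind(y[grp == 1], y[grp == 0])
    np.testing.assert_allclose(stat.t, t_ref, atol=1e-6)
    np.testing.assert_allclose(stat.df, 48.0)
    np.testing.assert_allclose(stat.p, p_ref, atol=1e-10)


def test_build_fixed_design_interactions_and_nesting():
    import pandas as pd

    df = pd.DataFrame(
        {"A": ["x", "x", "y", "y"], "B": ["u", "v", "u", "v"],
         "C": ["1", "2", "1", "2"]}
    )
    X, names = build_fixed_design(df, ["1", "A", "B", "A:B"])
    assert names == ["Intercept", "A[y]", "B[v]", "A[y]:B[v]"]
    np.testing.assert_array_equal(X[:, 3], [0, 0, 0, 1])
    Xn, nn = build_fixed_design(df, ["C(A)"])
    assert nn == ["C[2]:A[x]", "C[2]:A[y]"]
    np.testing.assert_array_equal(Xn, [[0, 0], [1, 0], [0, 0], [0, 1]])


def test_agrees_with_lme4_reference():
    """Variance components and REML log-likelihood match an independent
    lme4 fit on a small crossed design."""
    df = simulate_variance_partition(
        4, 8, sigma2_pop=1.5, sigma2_line=1.0, sigma2_resid=0.8,
        sigma2_garden=0.2, sigma2_block=0.1, seed=11,
    )
    spec = LmmSpec("y", ["1"], ["POPULATION", "LINE", "GARDEN", "BLOCK_IN_GARDEN"])
    vc, _ = fit_lmm_reml(spec, df)
    csv = df.to_csv(index=False)
    r_code = f"""
suppressMessages(library(lme4))
d <- read.csv(text={csv!r})
m <- lmer(y ~ 1 + (1|POPULATION) + (1|LINE) + (1|GARDEN) + (1|BLOCK_IN_GARDEN),
          data=d, REML=TRUE, control=lmerControl(check.conv.singular="ignore"))
v <- as.data.frame(VarCorr(m))
for (i in seq_len(nrow(v))) cat(v$grp[i], v$vcov[i], "\\n")
cat("loglik", as.numeric(logLik(m)), "\\n")
"""
    out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                         text=True, timeout=120)
    assert out.returncode == 0, out.stderr[-500:]
    ref = {}
    for line in out.stdout.strip().splitlines():
        tokens = line.split()
        ref[tokens[0]] = float(tokens[1])
    for term in ("POPULATION", "LINE", "GARDEN", "BLOCK_IN_GARDEN"):
        np.testing.assert_allclose(vc.sigma2[term], ref[term], atol=2e-4)
    np.testing.assert_allclose(vc.sigma2["resid"], ref["Residual"], atol=2e-4)
    np.testing.assert_allclose(vc.loglik_reml, ref["loglik"], atol=1e-3)
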