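"""Hudson per-SNP F_ST, its 2-SD summary, and genotype PCA."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recipro.datatypes import GenotypeMatrix
from recipro.popgen import fst_summary, genotype_pca, hudson_fst_per_snp
from recipro.simulate import SimulationConfig, simulate_genotypes


def _geno_from_dosages(dosages: np.ndarray) -> GenotypeMatrix:
    n, m = dosages.shape
    return GenotypeMatrix(
        [f"a{i}" for i in range(n)], [f"m{j}" for j in range(m)], dosages
    )


def literal_hudson(p1, p2, n1, n2) -> float:
    """Independent, literal evaluation of the estimator formula."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den > 0 else np.nan


def test_fixed_difference_gives_one():
    dos = np.array([[2.0, 2.0]] * 5 + [[0.0, 0.0]] * 5)
    geno = _geno_from_dosages(dos)
    res = hudson_fst_per_snp(geno, [f"a{i}" for i in range(5)],
                             [f"a{i}" for i in range(5, 10)])
    np.testing.assert_array_equal(res["fst"], 1.0)


def test_hand_value():
    """p1=0.6 (n1=20), p2=0.2 (n2=20) -> 0.24812... from the formula."""
    g1 = np.array([2.0] * 6 + [0.0] * 4)   # 12/20 alt alleles
    g2 = np.array([2.0] * 2 + [0.0] * 8)   # 4/20
    dos = np.concatenate([g1, g2])[:, None]
    geno = _geno_from_dosages(dos)
    res = hudson_fst_per_snp(geno, [f"a{i}" for i in range(10)],
                             [f"a{i}" for i in range(10, 20)])
    np.testing.assert_allclose(res["fst"].iloc[0], 0.24812030075187969, rtol=1e-12)


def test_monomorphic_missing():
    dos = np.zeros((8, 1))
    geno = _geno_from_dosages(dos)
    res = hudson_fst_per_snp(geno, [f"a{i}" for i in range(4)],
                             [f"a{i}" for i in range(4, 8)])
    assert np.isnan(res["fst"].iloc[0])


def test_symmetry_and_allele_flip(rng):
    dos = rng.integers(0, 3, size=(20, 50)).astype(float)
    geno = _geno_from_dosages(dos)
    g1 = [f"a{i}" for i in range(10)]
    g2 = [f"a{i}" for i in range(10, 20)]
    ab = hudson_fst_per_snp(geno, g1, g2)["fst"]
    ba = hudson_fst_per_snp(geno, g2, g1)["fst"]
    np.testing.assert_array_equal(ab, ba)
    flipped = _geno_from_dosages(2.0 - dos)
    fl = hudson_fst_per_snp(flipped, g1, g2)["fst"]
    np.testing.assert_allclose(ab, fl, rtol=1e-10, equal_nan=True)


def test_oracle_equivalence_with_missingness(rng):
    """100 random markers (some calls missing) match the literal formula to
    1e-12."""
    dos = rng.integers(0, 3, size=(30, 100)).astype(float)
    dos[rng.random(dos.shape) < 0.1] = np.nan
    geno = _geno_from_dosages(dos)
    g1 = [f"a{i}" for i in range(15)]
    g2 = [f"a{i}" for i in range(15, 30)]
    res = hudson_fst_per_snp(geno, g1, g2)
    for j in range(100):
        c1 = dos[:15, j]
        c2 = dos[15:, j]
        n1 = 2.0 * np.sum(~np.isnan(c1))
        n2 = 2.0 * np.sum(~np.isnan(c2))
        p1 = np.nansum(c1) / n1
        p2 = np.nansum(c2) / n2
        expected = literal_hudson(p1, p2, n1, n2)
        got = res["fst"].iloc[j]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            np.testing.assert_allclose(got, expected, atol=1e-12)


def test_overlapping_groups_rejected():
    geno = _geno_from_dosages(np.zeros((4, 2)))
    with pytest.raises(ValueError, match="overlap"):
        hudson_fst_per_snp(geno, ["a0", "a1"], ["a1", "a2"])


def test_fst_summary_hand_values():
    s = fst_summary(np.array([0.1, 0.2, 0.3]))
    np.testing.assert_allclose([s.mean_fst, s.sd_fst, s.threshold], [0.2, 0.1, 0.4])
    assert s.n_snps_used == 3
    const = fst_summary(np.array([0.15, 0.15, 0.15]))
    assert const.sd_fst == 0.0 and const.threshold == 0.15
    with_missing = fst_summary(np.array([0.1, np.nan, 0.3]))
    assert with_missing.n_snps_used == 2
    with pytest.raises(ValueError):
        fst_summary(np.array([0.1, np.nan]))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_rank_one_structure():
    dos = np.array([[0.0] * 6] * 5 + [[2.0] * 6] * 5)
    geno = _geno_from_dosages(dos)
    res = genotype_pca(geno, n_components=2)
    np.testing.assert_allclose(res.pct_var[0], 100.0, atol=1e-8)


def test_pca_matches_svd_oracle(rng):
    dos = rng.integers(0, 3, size=(20, 100)).astype(float)
    geno = _geno_from_dosages(dos)
    res = genotype_pca(geno, n_components=5)
    centered = dos - dos.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    oracle = U[:, :5] * S[:5]
    for k in range(5):
        a, b = res.scores.iloc[:, k].to_numpy(), oracle[:, k]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8
    np.testing.assert_allclose(
        res.pct_var[:5], 100 * S[:5] ** 2 / (S**2).sum(), rtol=1e-10
    )


def test_pca_separates_balding_nichols_populations():
    cfg = SimulationConfig(n_pops=2, n_lines_per_pop=30, n_markers=300,
                           fst_target=0.2, seed=3)
    geno = simulate_genotypes(cfg)
    res = genotype_pca(geno, n_components=2)
    labels = np.array([0] * 30 + [1] * 30)
    r = np.corrcoef(res.scores["PC1"], labels)[0, 1]
    assert abs(r) > 0.9
    assert np.all(np.diff(res.pct_var) <= 1e-9) and res.pct_var.sum() <= 100 + 1e-9


def test_pca_clips_components():
    geno = _geno_from_dosages(np.eye(4) * 2)
    with pytest.warns(UserWarning, match="clipped"):
        res = genotype_pca(geno, n_components=10)
    assert res.scores.shape[1] == 3
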