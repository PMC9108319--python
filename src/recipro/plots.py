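"""Basic diagnostic plots: Q_ST against the F_ST distribution, quadratic
fitness-decay residual fits, and population reaction norms."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_qst_fst(scan: pd.DataFrame, contrast: str, out_path: str | Path) -> Path:
    """Q_ST points over the F_ST mean and +/- 2 SD band for one contrast."""
    sub = scan[scan["contrast"] == contrast].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(sub))
    ax.scatter(x, sub["qst"], color="black", zorder=3, s=18)
    if sub["mean_fst"].notna().any():
        mean = float(sub["mean_fst"].iloc[0])
        thr = float(sub["threshold"].iloc[0])
        ax.axhline(mean, color="red")
        ax.axhline(thr, color="red", linestyle="--")
        ax.axhline(max(mean - (thr - mean), 0), color="red", linestyle="--")
    ax.set_xticks(x)
    ax.set_xticklabels(sub["trait"], rotation=90, fontsize=7)
    ax.set_ylabel(r"$Q_{ST}$")
    ax.set_title(contrast)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_env_decay(fitness, distances, variable: str, out_path: str | Path) -> Path:
    """Stage-1 fitness residuals vs distance with the quadratic fit."""
    import statsmodels.api as sm

    y = np.asarray(fitness, float)
    d = np.asarray(distances, float)
    ok = np.isfinite(y) & np.isfinite(d)
    y, d = y[ok], d[ok]
    e = sm.OLS(y, sm.add_constant(d)).fit().resid
    fit2 = sm.OLS(e, sm.add_constant(np.column_stack([d, d**2]))).fit()
    grid = np.linspace(d.min(), d.max(), 200)
    pred = fit2.params[0] + fit2.params[1] * grid + fit2.params[2] * grid**2
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(d, e, s=10, alpha=0.6)
    ax.plot(grid, pred, color="tab:blue")
    ax.set_xlabel(f"{variable} distance (garden - origin)")
    ax.set_ylabel("fitness residual e")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_reaction_norms(norms: pd.DataFrame, trait: str, out_path: str | Path) -> Path:
    """Population mean +/- SD across the two gardens."""
    sub = norms[norms["trait"] == trait]
    fig, ax = plt.subplots(figsize=(5, 4))
    for pop, grp in sub.groupby("population"):
        grp = grp.sort_values("site_id")
        ax.errorbar(grp["site_id"], grp["mean"], yerr=grp["sd"], marker="o",
                    capsize=3, label=pop)
    ax.set_ylabel(trait)
    ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
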