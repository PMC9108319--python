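"""REML estimation for Gaussian linear mixed models with independent
random intercepts.

The model is ``y = X beta + sum_k Z_k u_k + e`` with ``u_k ~ N(0, s2_k I)``
and ``e ~ N(0, s2_e I)``, so ``V = s2_e I + sum_k s2_k Z_k Z_k'``.  Fixed
effects are profiled analytically; the restricted likelihood is maximised
over log-variances with a quasi-Newton step (analytic gradient) followed by
a Newton polish, which keeps estimates accurate to near machine precision on
well-conditioned problems.  Variances are bounded below by zero at the
boundary (a log-parameter running to minus infinity), where the profile is
flat and the component is reported as exactly zero.

Inference on fixed-effect contrasts uses the Satterthwaite approximation:
for contrast c, ``g(theta) = c' (X'V^-1 X)^-1 c`` and
``df = 2 g^2 / (grad g' Cov(theta) grad g)`` with Cov(theta) taken from the
observed information of the restricted likelihood.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_ZERO_TOL = 1e-8  # relative threshold below which a variance sits on the boundary


# ---------------------------------------------------------------------------
# Design-matrix construction (treatment coding, interactions, nesting)
# ---------------------------------------------------------------------------


def indicator(codes: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Dense 0/1 indicator matrix for integer level codes."""
    codes = np.asarray(codes)
    q = int(n_levels if n_levels is not None else codes.max() + 1)
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _levels(series: pd.Series, order: list | None) -> list:
    if order is not None:
        return list(order)
    return list(pd.unique(series))


def build_fixed_design(
    data: pd.DataFrame,
    terms: list[str],
    level_orders: dict[str, list] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed design for a list of terms.

    Supported terms: ``"1"`` (intercept), ``"A"`` (categorical main effect,
    reference = first level), ``"A:B"`` (interaction of treatment-coded
    dummies) and ``"A(B)"`` (A nested in B: non-reference dummies of A within
    every level of B).  Numeric columns enter as-is.
    """
    level_orders = level_orders or {}
    cols: list[np.ndarray] = []
    names: list[str] = []

    def dummies(factor: str, drop_first: bool = True):
        s = data[factor]
        if pd.api.types.is_numeric_dtype(s) and factor not in level_orders:
            return [np.asarray(s, float)], [factor]
        levels = _levels(s, level_orders.get(factor))
        use = levels[1:] if drop_first else levels
        return (
            [(s == lv).to_numpy(float) for lv in use],
            [f"{factor}[{lv}]" for lv in use],
        )

    for term in terms:
        if term == "1":
            cols.append(np.ones(len(data)))
            names.append("Intercept")
        elif "(" in term:
            inner, outer = term[:-1].split("(")
            in_cols, in_names = dummies(inner)
            out_cols, out_names = dummies(outer, drop_first=False)
            for oc, on in zip(out_cols, out_names):
                for ic, iname in zip(in_cols, in_names):
                    cols.append(ic * oc)
                    names.append(f"{iname}:{on}")
        elif ":" in term:
            parts = term.split(":")
            prod_cols, prod_names = dummies(parts[0])
            for part in parts[1:]:
                nxt_cols, nxt_names = dummies(part)
                prod_cols = [a * b for a in prod_cols for b in nxt_cols]
                prod_names = [f"{a}:{b}" for a in prod_names for b in nxt_names]
            cols.extend(prod_cols)
            names.extend(prod_names)
        else:
            c, n = dummies(term)
            cols.extend(c)
            names.extend(n)
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names


def build_random_design(data: pd.DataFrame, term: str) -> np.ndarray:
    """Indicator matrix for a grouping factor or ``A:B`` crossed grouping."""
    if ":" in term:
        combined = data[term.split(":")].astype(str).agg("|".join, axis=1)
    else:
        combined = data[term].astype(str)
    codes = pd.Categorical(combined).codes
    return indicator(codes)


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------


def _chol_with_jitter(V: np.ndarray) -> np.ndarray:
    """Cholesky factor, adding an escalating diagonal jitter if V is
    numerically indefinite (extreme variance ratios during optimisation)."""
    scale = np.trace(V) / V.shape[0]
    jitter = 0.0
    for _ in range(8):
        try:
            return linalg.cholesky(V + jitter * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * scale)
    raise linalg.LinAlgError("covariance matrix is numerically indefinite")


def _neg2_reml(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
               Zs: list[np.ndarray], want_grad: bool = True):
    """-2 restricted log-likelihood (without constant) and its theta-gradient.

    theta = (s2_1 .. s2_K, s2_resid).
    """
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for s2, Z in zip(theta[:-1], Zs):
        V += s2 * (Z @ Z.T)
    L = _chol_with_jitter(V)
    ViX = linalg.cho_solve((L, True), X)
    Viy = linalg.cho_solve((L, True), y)
    A = X.T @ ViX
    LA = linalg.cholesky(A, lower=True)
    beta = linalg.cho_solve((LA, True), X.T @ Viy)
    u = Viy - ViX @ beta                      # V^-1 (y - X beta)
    r = y - X @ beta
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    logdet_a = 2.0 * np.log(np.diag(LA)).sum()
    quad = float(r @ u)
    f = logdet_v + logdet_a + quad
    if not want_grad:
        return f, None, (L, ViX, A, beta, u)
    grad = np.empty_like(theta)
    for k, Z in enumerate(Zs):
        ViZ = linalg.cho_solve((L, True), Z)
        t1 = float(np.sum(Z * ViZ))                   # tr(V^-1 Z Z')
        B = X.T @ ViZ                                 # p x q
        t2 = float(np.sum(B * linalg.cho_solve((LA, True), B)))
        zu = Z.T @ u
        grad[k] = t1 - t2 - float(zu @ zu)
    Linv = linalg.solve_triangular(L, np.eye(n), lower=True)
    t1 = float(np.sum(Linv * Linv))                   # tr(V^-1)
    C = ViX.T @ ViX
    t2 = float(np.trace(linalg.cho_solve((LA, True), C)))
    grad[-1] = t1 - t2 - float(u @ u)
    return f, grad, (L, ViX, A, beta, u)


@dataclass
class ContrastStat:
    estimate: float
    se: float
    t: float
    df: float
    p: float


@dataclass
class LmmResult:
    """A fitted random-intercept mixed model."""

    beta: np.ndarray
    fixed_names: list[str]
    cov_beta: np.ndarray
    sigma2: dict[str, float]
    sigma2_se: dict[str, float]
    loglik_reml: float
    converged: bool
    n: int
    p: int
    random_names: list[str] = field(default_factory=list)
    _y: np.ndarray | None = None
    _X: np.ndarray | None = None
    _Zs: list[np.ndarray] | None = None
    _theta: np.ndarray | None = None
    _cov_theta: np.ndarray | None = None

    @property
    def resid_df(self) -> int:
        return self.n - self.p

    def fixef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.fixed_names)

    # -- variance-parameter covariance (lazy) -------------------------------

    def cov_theta(self) -> np.ndarray:
        if self._cov_theta is None:
            self._cov_theta = _theta_covariance(
                self._theta, self._y, self._X, self._Zs
            )
        return self._cov_theta

    # -- contrast inference --------------------------------------------------

    def contrast(self, c: np.ndarray) -> ContrastStat:
        """t-test of c' beta with Satterthwaite degrees of freedom."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        g = float(c @ self.cov_beta @ c)
        se = float(np.sqrt(g))
        if se == 0:
            return ContrastStat(est, 0.0, 0.0, float(self.resid_df), 1.0)
        t = est / se
        df = self._satterthwaite_df(c, g)
        p = 2.0 * stats.t.sf(abs(t), df)
        return ContrastStat(est, se, t, df, float(p))

    def _satterthwaite_df(self, c: np.ndarray, g: float) -> float:
        if self._Zs is None or len(self._Zs) == 0:
            return float(self.resid_df)
        theta = self._theta
        n = self.n
        V = theta[-1] * np.eye(n)
        for s2, Z in zip(theta[:-1], self._Zs):
            V += s2 * (Z @ Z.T)
        L = _chol_with_jitter(V)
        ViX = linalg.cho_solve((L, True), self._X)
        A = self._X.T @ ViX
        w = ViX @ linalg.solve(A, c, assume_a="pos")   # V^-1 X A^-1 c
        grad = np.empty_like(theta)
        for k, Z in enumerate(self._Zs):
            zw = Z.T @ w
            grad[k] = float(zw @ zw)
        grad[-1] = float(w @ w)
        denom = float(grad @ self.cov_theta() @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.resid_df)
        df = 2.0 * g * g / denom
        return float(np.clip(df, 1.0, self.resid_df))


def _theta_covariance(theta, y, X, Zs, rel_step: float = 1e-5) -> np.ndarray:
    """Asymptotic Cov(theta-hat) = 2 H^-1 from the observed information of
    -2 l_R, by central finite differences of the analytic gradient.

    Components on the zero boundary are treated as fixed (zero rows/cols).
    """
    m = len(theta)
    scale = max(theta.max(), 1e-12)
    active = theta > _ZERO_TOL * scale
    H = np.zeros((m, m))
    for j in range(m):
        if not active[j]:
            continue
        h = rel_step * max(theta[j], 1e-3 * scale)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] = max(tm[j] - h, 1e-12 * scale)
        _, gp, _ = _neg2_reml(tp, y, X, Zs)
        _, gm, _ = _neg2_reml(tm, y, X, Zs)
        H[:, j] = (gp - gm) / (tp[j] - tm[j])
    H = 0.5 * (H + H.T)
    cov = np.zeros((m, m))
    idx = np.flatnonzero(active)
    if idx.size:
        sub = H[np.ix_(idx, idx)]
        try:
            cov_sub = 2.0 * linalg.inv(sub)
        except linalg.LinAlgError:
            cov_sub = 2.0 * linalg.pinvh(sub)
        cov[np.ix_(idx, idx)] = cov_sub
    return cov


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.size == 0:
        raise ValueError("empty fixed design")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[i] for i in piv[rank:]]
        raise ValueError(f"singular fixed design; aliased columns: {aliased}")


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    random_designs: dict[str, np.ndarray] | None = None,
    fixed_names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> LmmResult:
    """Fit the mixed model by REML; exact closed form when no random terms.

    ``random_designs`` maps term names to indicator matrices.  The returned
    result carries variance components in the units of ``y`` squared, REML
    fixed effects with their covariance, and supports Satterthwaite-df
    contrast tests.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = fixed_names or [f"x{i}" for i in range(p)]
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("y and X must be complete (drop missing rows first)")
    _check_full_rank(X, names)
    random_designs = random_designs or {}
    rnames = list(random_designs)
    Zs = [np.asarray(random_designs[k], dtype=float) for k in rnames]
    for k, Z in zip(rnames, Zs):
        if Z.shape[0] != n:
            raise ValueError(f"random design {k} has {Z.shape[0]} rows, expected {n}")
        if Z.shape[1] < 2:
            raise ValueError(f"random term {k} needs >= 2 levels")

    # --- pure fixed-effects model: closed-form REML ------------------------
    if not Zs:
        XtX = X.T @ X
        beta = linalg.solve(XtX, X.T @ y, assume_a="pos")
        r = y - X @ beta
        s2 = float(r @ r) / (n - p)
        cov_beta = s2 * linalg.inv(XtX)
        _, logdet_xtx = np.linalg.slogdet(XtX)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + (n - p) * np.log(s2)
                     + logdet_xtx + (n - p))
        return LmmResult(
            beta=beta, fixed_names=names, cov_beta=cov_beta,
            sigma2={"resid": s2}, sigma2_se={"resid": s2 * np.sqrt(2.0 / (n - p))},
            loglik_reml=float(ll), converged=True, n=n, p=p,
            random_names=[], _y=y, _X=X, _Zs=[], _theta=np.array([s2]),
        )

    # --- scaled optimisation over log-variances -----------------------------
    y_sd = y.std() or 1.0
    ys = y / y_sd
    m = len(Zs) + 1
    theta0 = np.full(m, 1.0 / m)

    def fun(phi):
        f, g, _ = _neg2_reml(np.exp(phi), ys, X, Zs)
        return f, g * np.exp(phi)

    res = optimize.minimize(
        fun, np.log(theta0), jac=True, method="L-BFGS-B",
        bounds=[(np.log(1e-10), np.log(1e4))] * m,
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-9},
    )
    phi = res.x

    # Newton polish on active (interior) components for near-exact optima
    for _ in range(8):
        theta = np.exp(phi)
        f, g_theta, _ = _neg2_reml(theta, ys, X, Zs)
        g_phi = g_theta * theta
        active = theta > 1e-9
        if np.max(np.abs(g_phi[active])) < tol:
            break
        idx = np.flatnonzero(active)
        H = np.zeros((idx.size, idx.size))
        for jj, j in enumerate(idx):
            h = 1e-6 * max(abs(phi[j]), 1.0)
            pp, pm = phi.copy(), phi.copy()
            pp[j] += h
            pm[j] -= h
            _, gp, _ = _neg2_reml(np.exp(pp), ys, X, Zs)
            _, gm, _ = _neg2_reml(np.exp(pm), ys, X, Zs)
            H[:, jj] = ((gp * np.exp(pp) - gm * np.exp(pm)) / (2 * h))[idx]
        H = 0.5 * (H + H.T)
        try:
            step = linalg.solve(H + 1e-12 * np.eye(idx.size), -g_phi[idx])
        except linalg.LinAlgError:
            break
        step = np.clip(step, -2.0, 2.0)
        trial = phi.copy()
        trial[idx] += step
        f_new, _, _ = _neg2_reml(np.exp(trial), ys, X, Zs, want_grad=False)
        if f_new <= f + 1e-12:
            phi = trial
        else:
            trial[idx] = phi[idx] + 0.25 * step
            f_half, _, _ = _neg2_reml(np.exp(trial), ys, X, Zs, want_grad=False)
            if f_half <= f:
                phi = trial
            else:
                break

    theta_s = np.exp(phi)
    f, g_theta, (L, ViX, A, beta_s, _) = _neg2_reml(theta_s, ys, X, Zs)
    g_phi = g_theta * theta_s
    active = theta_s > 1e-9
    score_norm = float(np.max(np.abs(g_phi[active]))) if active.any() else 0.0
    converged = bool(res.success or score_norm < 1e-4)
    if not converged:
        warnings.warn("REML did not converge; treat estimates with caution", stacklevel=2)

    # back to original units
    theta = theta_s * y_sd**2
    theta[theta_s <= 1e-9] = 0.0
    beta = beta_s * y_sd
    cov_beta = linalg.inv(A) * y_sd**2
    loglik = -0.5 * (f + (n - p) * np.log(2 * np.pi) + (n - p) * np.log(y_sd**2))

    result = LmmResult(
        beta=beta, fixed_names=names, cov_beta=cov_beta,
        sigma2={**{k: float(t) for k, t in zip(rnames, theta[:-1])},
                "resid": float(theta[-1])},
        sigma2_se={}, loglik_reml=float(loglik), converged=converged,
        n=n, p=p, random_names=rnames,
        _y=y, _X=X, _Zs=Zs, _theta=theta,
    )
    cov_t = result.cov_theta()
    ses = np.sqrt(np.clip(np.diag(cov_t), 0.0, None))
    result.sigma2_se = {
        **{k: float(s) for k, s in zip(rnames, ses[:-1])},
        "resid": float(ses[-1]),
    }
    return result
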