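"""Random-intercept linear mixed model with REML and Satterthwaite contrasts.

The model is ``y = X beta + Z b + e`` with one random intercept per
participant, ``b ~ N(0, sigma_b^2)``, and ``e ~ N(0, sigma_e^2 / w_ij)`` for
known per-observation precision weights ``w``. Because the random-effect
design is a single grouping factor, every quantity the REML criterion needs
is available in closed form per participant via Sherman-Morrison, so fits are
fast enough for simulation studies with thousands of replicate fits.

Degrees of freedom for contrasts use the Satterthwaite approximation: the
contrast variance ``g(theta) = var(c' beta_hat)`` is differentiated
numerically in the variance components ``theta = (sigma_b^2, sigma_e^2)`` and
combined with the inverse curvature of the REML log-likelihood. When the
curvature is ill-conditioned (e.g. the intercept variance collapses to the
boundary), a residual-degrees-of-freedom fallback is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["SingularDesignError", "RandomInterceptFit", "fit_random_intercept"]


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; carries the aliased column names."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"singular design; aliased columns: {aliased}")


def _check_rank(X: np.ndarray, names: list[str] | None) -> None:
    n, p = X.shape
    if n < p or np.linalg.matrix_rank(X) < p:
        # identify aliased columns by greedy QR-style scan
        aliased = []
        keep: list[int] = []
        for j in range(p):
            cols = keep + [j]
            if np.linalg.matrix_rank(X[:, cols]) == len(cols):
                keep.append(j)
            else:
                aliased.append(names[j] if names else f"col{j}")
        raise SingularDesignError(aliased)


@dataclass
class _Blocks:
    """Per-participant sufficient statistics for the profiled REML criterion."""

    XtWX: np.ndarray  # p x p
    XtWy: np.ndarray
    ytWy: float
    Xtw: np.ndarray  # n_groups x p, rows X_i' w_i
    ytw: np.ndarray  # n_groups, y_i' w_i
    s: np.ndarray  # n_groups, sum of weights
    sum_log_w: float
    n: int
    p: int


def _build_blocks(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, w: np.ndarray
) -> _Blocks:
    n, p = X.shape
    ng = codes.max() + 1
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ y
    ytWy = float(y @ (w * y))
    Xtw = np.zeros((ng, p))
    ytw = np.zeros(ng)
    s = np.zeros(ng)
    np.add.at(Xtw, codes, Xw)
    np.add.at(ytw, codes, w * y)
    np.add.at(s, codes, w)
    return _Blocks(XtWX, XtWy, ytWy, Xtw, ytw, s, float(np.sum(np.log(w))), n, p)


def _profile(blocks: _Blocks, lam: float):
    """GLS pieces at a given variance ratio lambda = sigma_b^2 / sigma_e^2."""
    c = lam / (1.0 + lam * blocks.s)  # per-group Sherman-Morrison factor
    XtUX = blocks.XtWX - (blocks.Xtw * c[:, None]).T @ blocks.Xtw
    XtUy = blocks.XtWy - blocks.Xtw.T @ (c * blocks.ytw)
    ytUy = blocks.ytWy - float(c @ blocks.ytw**2)
    beta = np.linalg.solve(XtUX, XtUy)
    rss = ytUy - float(beta @ XtUy)
    logdet_U = float(np.sum(np.log1p(lam * blocks.s))) - blocks.sum_log_w
    sign, logdet_XtUX = np.linalg.slogdet(XtUX)
    return beta, XtUX, rss, logdet_U, logdet_XtUX


def _reml_neg2(blocks: _Blocks, sigma_b2: float, sigma_e2: float) -> float:
    """-2 x REML log-likelihood (up to an additive constant)."""
    lam = sigma_b2 / sigma_e2
    _, _, rss, logdet_U, logdet_XtUX = _profile(blocks, lam)
    npp = blocks.n - blocks.p
    return npp * np.log(sigma_e2) + logdet_U + logdet_XtUX + rss / sigma_e2


@dataclass
class RandomInterceptFit:
    """REML fit of the random-intercept model."""

    beta: np.ndarray
    sigma_b2: float
    sigma_e2: float
    cov_beta: np.ndarray
    n_obs: int
    n_groups: int
    reml_converged: bool
    column_names: list[str] | None = None
    _blocks: _Blocks | None = None

    @property
    def icc(self) -> float:
        tot = self.sigma_b2 + self.sigma_e2
        return self.sigma_b2 / tot if tot > 0 else 0.0

    def coef(self) -> pd.Series:
        idx = self.column_names or [f"b{j}" for j in range(len(self.beta))]
        return pd.Series(self.beta, index=idx)

    # -- contrast machinery --------------------------------------------------

    def _contrast_var(self, c: np.ndarray, sigma_b2: float, sigma_e2: float) -> float:
        lam = max(sigma_b2, 0.0) / sigma_e2
        _, XtUX, _, _, _ = _profile(self._blocks, lam)
        return sigma_e2 * float(c @ np.linalg.solve(XtUX, c))

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Satterthwaite df: 2 g^2 / (grad g' A grad g) with A the inverse REML curvature."""
        b = self._blocks
        th = np.array([self.sigma_b2, self.sigma_e2])
        g0 = self._contrast_var(c, *th)
        resid_df = float(b.n - b.p)
        try:
            steps = np.maximum(np.abs(th), 1e-6) * 1e-4
            grad = np.zeros(2)
            for k in range(2):
                tp, tm = th.copy(), th.copy()
                tp[k] += steps[k]
                tm[k] = max(tm[k] - steps[k], 1e-12)
                grad[k] = (
                    self._contrast_var(c, *tp) - self._contrast_var(c, *tm)
                ) / (tp[k] - tm[k])
            # Hessian of -2*loglik via central differences; A = 2 * H^{-1}
            H = np.zeros((2, 2))
            f0 = _reml_neg2(b, *th)
            hs = np.maximum(np.abs(th), 1e-6) * 1e-3
            for k in range(2):
                for l in range(k, 2):
                    if k == l:
                        tp, tm = th.copy(), th.copy()
                        tp[k] += hs[k]
                        tm[k] = max(tm[k] - hs[k], 1e-12)
                        H[k, k] = (
                            _reml_neg2(b, *tp) - 2 * f0 + _reml_neg2(b, *tm)
                        ) / ((tp[k] - th[k]) * (th[k] - tm[k]))
                    else:
                        tpp, tpm, tmp, tmm = (
                            th.copy(),
                            th.copy(),
                            th.copy(),
                            th.copy(),
                        )
                        tpp[k] += hs[k]
                        tpp[l] += hs[l]
                        tpm[k] += hs[k]
                        tpm[l] = max(tpm[l] - hs[l], 1e-12)
                        tmp[k] = max(tmp[k] - hs[k], 1e-12)
                        tmp[l] += hs[l]
                        tmm[k] = max(tmm[k] - hs[k], 1e-12)
                        tmm[l] = max(tmm[l] - hs[l], 1e-12)
                        H[k, l] = H[l, k] = (
                            _reml_neg2(b, *tpp)
                            - _reml_neg2(b, *tpm)
                            - _reml_neg2(b, *tmp)
                            + _reml_neg2(b, *tmm)
                        ) / ((tpp[k] - tmp[k]) * (tpp[l] - tpm[l]))
            # -2 loglik curvature: information = H/2, A = inverse information
            A = np.linalg.inv(H / 2.0)
            denom = float(grad @ A @ grad)
            if denom <= 0 or not np.isfinite(denom):
                return resid_df
            df = 2.0 * g0**2 / denom
            if not np.isfinite(df) or df <= 0:
                return resid_df
            return min(df, resid_df)
        except np.linalg.LinAlgError:
            return resid_df

    def contrast(self, c: np.ndarray) -> dict:
        """Estimate, SE, t, Satterthwaite df and two-sided p for ``c' beta``."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        var = self._contrast_var(c, self.sigma_b2, self.sigma_e2)
        se = float(np.sqrt(var))
        if se == 0.0:
            return {"estimate": est, "se": 0.0, "t": 0.0, "df": np.nan, "p": 1.0}
        df = self.satterthwaite_df(c)
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return {"estimate": est, "se": se, "t": t, "df": df, "p": p}


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    weights: np.ndarray | None = None,
    column_names: list[str] | None = None,
    lam_bounds: tuple[float, float] = (-12.0, 12.0),
) -> RandomInterceptFit:
    """REML fit of ``y = X beta + (1 | group) + e`` with optional precision weights.

    The REML criterion is profiled down to the scalar variance ratio
    ``lambda = sigma_b^2 / sigma_e^2`` and optimized on the log scale over
    ``lam_bounds``; ``lambda = 0`` (no participant variance, i.e. OLS/WLS) is
    always considered, so a fit with one observation per participant reduces
    exactly to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    _check_rank(X, column_names)
    codes, _ = pd.factorize(np.asarray(groups))
    w = (
        np.ones_like(y)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    blocks = _build_blocks(y, X, codes, w)

    def crit(loglam: float) -> float:
        lam = np.exp(loglam)
        _, _, rss, logdet_U, logdet_XtUX = _profile(blocks, lam)
        npp = blocks.n - blocks.p
        sigma_e2 = rss / npp
        return npp * np.log(sigma_e2) + logdet_U + logdet_XtUX

    res = optimize.minimize_scalar(
        crit, bounds=lam_bounds, method="bounded", options={"xatol": 1e-8}
    )
    lam = float(np.exp(res.x))
    # boundary check: lambda ~ 0 (no participant variance)
    if crit(lam_bounds[0]) <= res.fun + 1e-10:
        lam = 0.0
    beta, XtUX, rss, _, _ = _profile(blocks, lam)
    sigma_e2 = rss / (blocks.n - blocks.p)
    sigma_b2 = lam * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(XtUX)
    return RandomInterceptFit(
        beta=beta,
        sigma_b2=sigma_b2,
        sigma_e2=sigma_e2,
        cov_beta=cov_beta,
        n_obs=blocks.n,
        n_groups=int(codes.max()) + 1,
        reml_converged=bool(res.success),
        column_names=column_names,
        _blocks=blocks,
    )
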