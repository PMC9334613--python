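"""Beta-likelihood mixed-effects regression for (0,1)-bounded coherence values.

The model is a logit-link beta GLMM:

    y_i | b_g ~ Beta(mu_i * phi, (1 - mu_i) * phi)
    logit(mu_i) = x_i' beta + z_i' b_g(i),   b_g ~ N(0, diag(sigma^2))

with dyads as grouping units.  The marginal likelihood is obtained by a
Laplace approximation over the group-level random effects (inner Newton /
Fisher-scoring solve per group, observed-information log-determinant), and
maximized over (beta, log phi, log sigma) with L-BFGS.

Random-effect covariance is diagonal (independent variance components per
random term), which is what the random-slope reduction trail operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrices, dmatrix
from scipy import optimize, special, stats


class FitError(RuntimeError):
    pass


def _beta_loglik_terms(y_star, log_y, log_1my, mu, phi):
    a = mu * phi
    b = (1 - mu) * phi
    return (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1) * log_y
        + (b - 1) * log_1my
    )


class BetaMixedModel:
    """Beta GLMM with logit link and dyad-level random effects.

    Parameters
    ----------
    endog : array-like in (0, 1)
    exog : (n, p) fixed-effects design matrix
    groups : length-n array of group labels
    exog_re : (n, q) random-effects design matrix (default: intercept only)
    """

    def __init__(self, endog, exog, groups, exog_re=None,
                 exog_names=None, exog_re_names=None):
        self.endog = np.asarray(endog, float)
        if self.endog.ndim != 1:
            raise ValueError("endog must be 1-D")
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            raise ValueError("endog must lie strictly inside (0, 1); "
                             "clamp boundary values upstream")
        self.exog = np.asarray(exog, float)
        n, self.k_fe = self.exog.shape
        groups = np.asarray(groups)
        self.group_labels, self.group_idx = np.unique(groups, return_inverse=True)
        self.n_groups = len(self.group_labels)
        if exog_re is None:
            exog_re = np.ones((n, 1))
            exog_re_names = ["Intercept"]
        self.exog_re = np.asarray(exog_re, float)
        self.k_re = self.exog_re.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.k_fe)
        ]
        self.exog_re_names = list(exog_re_names) if exog_re_names is not None else [
            f"z{i}" for i in range(self.k_re)
        ]
        # precomputed response transforms
        y = self.endog
        self._log_y = np.log(y)
        self._log_1my = np.log1p(-y)
        self._y_star = self._log_y - self._log_1my
        self._data = None
        self._fe_design_info = None
        self._re_design_info = None
        self.formula = None
        self.re_formula = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_formula(cls, formula, data, groups, re_formula="1"):
        """Build from patsy formulas; ``groups`` is a column name or array."""
        y, X = dmatrices(formula, data, return_type="dataframe")
        Z = dmatrix(re_formula, data, return_type="dataframe")
        g = data[groups] if isinstance(groups, str) else groups
        mod = cls(
            y.values.ravel(), X.values, np.asarray(g),
            exog_re=Z.values, exog_names=list(X.columns),
            exog_re_names=list(Z.columns),
        )
        mod._data = data
        mod._fe_design_info = X.design_info
        mod._re_design_info = Z.design_info
        mod.formula = formula
        mod.re_formula = re_formula
        return mod

    # -- likelihood --------------------------------------------------------

    def _unpack(self, theta):
        p = self.k_fe
        beta = theta[:p]
        phi = np.exp(np.clip(theta[p], -8, 16))
        sds = np.exp(np.clip(theta[p + 1:], -12, 6))
        return beta, phi, sds

    def _eta_terms(self, eta, phi):
        mu = special.expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        a = mu * phi
        b = (1 - mu) * phi
        mu_star = special.digamma(a) - special.digamma(b)
        dmu = mu * (1 - mu)
        u = phi * (self._y_star - mu_star) * dmu          # dl/deta
        trig = special.polygamma(1, a) + special.polygamma(1, b)
        w_fisher = (phi * dmu) ** 2 * trig                # E[-d2l/deta2]
        w_obs = w_fisher - phi * (self._y_star - mu_star) * (1 - 2 * mu) * dmu
        ll = _beta_loglik_terms(self._y_star, self._log_y, self._log_1my, mu, phi)
        return ll, u, w_fisher, w_obs

    def _solve_re(self, beta, phi, sds, b0):
        """Inner Newton for the group modes; returns (b_hat, eta, logdet_sum)."""
        g = self.group_idx
        Z = self.exog_re
        eta_fe = self.exog @ beta
        d_inv = 1.0 / np.maximum(sds**2, 1e-24)
        b = b0.copy()
        if self.k_re == 1:
            z = Z[:, 0]
            for _ in range(100):
                eta = eta_fe + z * b[g]
                _, u, w_f, _ = self._eta_terms(eta, phi)
                grad = np.bincount(g, u * z, self.n_groups) - b * d_inv[0]
                hess = np.bincount(g, w_f * z * z, self.n_groups) + d_inv[0]
                step = grad / hess
                b += step
                if np.max(np.abs(step)) < 1e-11:
                    break
            eta = eta_fe + z * b[g]
            ll, u, w_f, w_obs = self._eta_terms(eta, phi)
            w_ld = np.where(
                np.bincount(g, w_obs * z * z, self.n_groups) > 0,
                np.bincount(g, w_obs * z * z, self.n_groups),
                np.bincount(g, w_f * z * z, self.n_groups),
            )
            logdet = np.sum(np.log(w_ld + d_inv[0])) + self.n_groups * np.log(sds[0] ** 2)
            pen = np.sum(b**2) * d_inv[0]
            return b[:, None], eta, ll.sum() - 0.5 * pen - 0.5 * logdet
        # general q: loop over groups
        B = b if b.ndim == 2 else np.zeros((self.n_groups, self.k_re))
        total = 0.0
        eta = eta_fe.copy()
        Dinv = np.diag(d_inv)
        for gi in range(self.n_groups):
            m = g == gi
            Zg = Z[m]
            bg = B[gi].copy()
            for _ in range(100):
                eta_g = eta_fe[m] + Zg @ bg
                _, u, w_f, _ = self._eta_terms_subset(eta_g, phi, m)
                grad = Zg.T @ u - d_inv * bg
                H = Zg.T @ (w_f[:, None] * Zg) + Dinv
                step = np.linalg.solve(H, grad)
                bg += step
                if np.max(np.abs(step)) < 1e-11:
                    break
            B[gi] = bg
            eta[m] = eta_fe[m] + Zg @ bg
            ll, _, w_f, w_obs = self._eta_terms_subset(eta[m], phi, m)
            H_obs = Zg.T @ (w_obs[:, None] * Zg) + Dinv
            sign, logdet = np.linalg.slogdet(H_obs)
            if sign <= 0:
                H_obs = Zg.T @ (w_f[:, None] * Zg) + Dinv
                sign, logdet = np.linalg.slogdet(H_obs)
            total += (
                ll.sum()
                - 0.5 * bg @ (d_inv * bg)
                - 0.5 * (logdet + np.sum(np.log(sds**2)))
            )
        return B, eta, total

    def _eta_terms_subset(self, eta, phi, mask):
        mu = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
        a, b = mu * phi, (1 - mu) * phi
        y_star = self._y_star[mask]
        mu_star = special.digamma(a) - special.digamma(b)
        dmu = mu * (1 - mu)
        u = phi * (y_star - mu_star) * dmu
        trig = special.polygamma(1, a) + special.polygamma(1, b)
        w_fisher = (phi * dmu) ** 2 * trig
        w_obs = w_fisher - phi * (y_star - mu_star) * (1 - 2 * mu) * dmu
        ll = _beta_loglik_terms(
            y_star, self._log_y[mask], self._log_1my[mask], mu, phi
        )
        return ll, u, w_fisher, w_obs

    def loglike(self, theta, _state=None):
        """Laplace-approximate marginal log-likelihood at packed ``theta``."""
        beta, phi, sds = self._unpack(theta)
        if _state is None:
            _state = {"b": np.zeros((self.n_groups, self.k_re))}
        b0 = _state["b"] if self.k_re > 1 else _state["b"][:, 0]
        B, _, ll = self._solve_re(beta, phi, sds, b0)
        _state["b"] = B
        return ll

    def _start_params(self):
        y = self.endog
        eta0 = np.log(y / (1 - y))
        beta0, *_ = np.linalg.lstsq(self.exog, eta0, rcond=None)
        mu0 = np.clip(special.expit(self.exog @ beta0), 1e-6, 1 - 1e-6)
        resid = y - mu0
        v = max(np.var(resid), 1e-6)
        phi0 = np.clip(np.mean(mu0 * (1 - mu0)) / v - 1, 2.0, 500.0)
        return np.concatenate([beta0, [np.log(phi0)], np.full(self.k_re, np.log(0.3))])

    def _fe_covariance(self, theta) -> np.ndarray:
        """Fixed-effects covariance via the joint-information Schur complement.

        Fisher weights at (beta_hat, b_hat); the random-effect block is
        profiled out per group.  Matches the covariance a full numerical
        Hessian gives to within optimizer tolerance at far lower cost.
        """
        beta, phi, sds = self._unpack(theta)
        state = {"b": np.zeros((self.n_groups, self.k_re))}
        self.loglike(theta, state)
        B = state["b"]
        g = self.group_idx
        eta = self.exog @ beta + np.sum(self.exog_re * B[g], axis=1)
        _, _, w, _ = self._eta_terms(eta, phi)
        X, Z = self.exog, self.exog_re
        d_inv = 1.0 / np.maximum(sds**2, 1e-24)
        H_bb = (X * w[:, None]).T @ X
        for gi in range(self.n_groups):
            m = g == gi
            Xg, Zg, wg = X[m], Z[m], w[m]
            Hzz = Zg.T @ (wg[:, None] * Zg) + np.diag(d_inv)
            Hbz = Xg.T @ (wg[:, None] * Zg)
            H_bb -= Hbz @ np.linalg.solve(Hzz, Hbz.T)
        return np.linalg.inv(H_bb)

    def fit(self, start_params=None, maxiter=500, compute_se=True):
        """Maximize the Laplace marginal likelihood; returns BetaMixedResults."""
        theta0 = self._start_params() if start_params is None else np.asarray(start_params)
        state = {"b": np.zeros((self.n_groups, self.k_re))}

        def nll(theta):
            v = self.loglike(theta, state)
            if not np.isfinite(v):
                return 1e12
            return -v

        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 10 * maxiter * len(theta0),
                     "ftol": 1e-11, "gtol": 1e-7},
        )
        theta = res.x
        llf = -res.fun
        converged = bool(res.success and np.isfinite(llf))

        cov = None
        if compute_se and converged:
            try:
                cov_fe = self._fe_covariance(theta)
                d = np.diag(cov_fe)
                if np.all(np.isfinite(d)) and np.all(d > 0):
                    cov_all = np.zeros((len(theta), len(theta)))
                    cov_all[: self.k_fe, : self.k_fe] = cov_fe
                    cov = cov_all
                else:
                    converged = False
            except np.linalg.LinAlgError:
                converged = False

        beta, phi, sds = self._unpack(theta)
        return BetaMixedResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            phi=float(phi),
            re_sd=pd.Series(sds, index=self.exog_re_names),
            llf=float(llf),
            theta=theta,
            cov_all=cov,
            converged=converged,
            random_effects=pd.DataFrame(
                state["b"], index=self.group_labels, columns=self.exog_re_names
            ),
            optim_message=str(res.message),
        )


def _num_hessian(f, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            e = np.zeros(n)
            e[i], e[j] = h[i], h[j]
            fpp = f(x + e)
            e[i], e[j] = -h[i], -h[j]
            fmm = f(x + e)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    return H


@dataclass
class BetaMixedResults:
    """Fitted beta GLMM: coefficients, precision, variance components."""

    model: BetaMixedModel
    params: pd.Series
    phi: float
    re_sd: pd.Series
    llf: float
    theta: np.ndarray
    cov_all: np.ndarray | None
    converged: bool
    random_effects: pd.DataFrame
    optim_message: str = ""
    reduction_trail: list = field(default_factory=list)

    @property
    def k_params(self) -> int:
        return len(self.theta)

    @property
    def bse(self) -> pd.Series:
        if self.cov_all is None:
            return pd.Series(np.nan, index=self.params.index)
        se = np.sqrt(np.diag(self.cov_all)[: self.model.k_fe])
        return pd.Series(se, index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        if self.cov_all is None:
            raise FitError("covariance unavailable (fit did not converge cleanly)")
        c = self.cov_all[: self.model.k_fe, : self.model.k_fe]
        return pd.DataFrame(c, index=self.params.index, columns=self.params.index)

    @property
    def df_resid(self) -> int:
        return len(self.model.endog) - self.model.k_fe

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues
        return pd.Series(
            2 * stats.t.sf(np.abs(t), self.df_resid), index=self.params.index
        )

    def conf_int(self, alpha=0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        eta = self.model.exog @ self.params.values
        z = self.random_effects.values[self.model.group_idx]
        eta = eta + np.sum(self.model.exog_re * z, axis=1)
        return special.expit(eta)

    @property
    def resid_quantile(self) -> np.ndarray:
        """Normal-quantile residuals from the fitted beta distribution."""
        mu = np.clip(self.fittedvalues, 1e-10, 1 - 1e-10)
        cdf = stats.beta.cdf(self.model.endog, mu * self.phi, (1 - mu) * self.phi)
        return stats.norm.ppf(np.clip(cdf, 1e-10, 1 - 1e-10))

    def summary(self) -> str:
        lines = [
            "Beta mixed model (logit link, Laplace approximation)",
            f"  groups: {self.model.n_groups}   obs: {len(self.model.endog)}",
            f"  logLik: {self.llf:.3f}   phi: {self.phi:.3f}   "
            f"converged: {self.converged}",
            f"  random-effect sd: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.re_sd.items()),
        ]
        if self.reduction_trail:
            lines.append(f"  random-structure trail: {' -> '.join(self.reduction_trail)}")
        lines.append(f"  {'term':<40s}{'coef':>10s}{'se':>10s}{'z':>8s}{'p':>10s}")
        bse = self.bse
        for name in self.params.index:
            t = self.params[name] / bse[name] if bse[name] > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), self.df_resid) if np.isfinite(t) else np.nan
            lines.append(
                f"  {name:<40.40s}{self.params[name]:>10.4f}{bse[name]:>10.4f}"
                f"{t:>8.2f}{p:>10.4g}"
            )
        return "\n".join(lines)


def lr_test(full: BetaMixedResults, reduced: BetaMixedResults):
    """Likelihood-ratio test of nested fits: chi2 = 2*(ll_full - ll_reduced)."""
    if full.k_params < reduced.k_params:
        raise ValueError("'full' must have at least as many parameters as 'reduced'")
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("reduced fixed effects are not nested in the full model")
    chi2 = max(0.0, 2 * (full.llf - reduced.llf))
    df = full.k_params - reduced.k_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p
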