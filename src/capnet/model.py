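"""Mixed-effects logistic models for DR-severity discrimination.

The severity analysis models a 3-level outcome (control / mild / referable
DR) or its constrained binary contrasts (any DR vs control, referable vs
mild) as logistic regressions with random intercepts for eye-nesting within
subject and for ophthalmic center:

    logit P(y_ij) = x_ij' beta + u_i + v_c,   u_i ~ N(0, s_u^2), v_c ~ N(0, s_c^2)

Estimation is marginal maximum likelihood.  The subject intercept of a
binary model is integrated by adaptive Gauss-Hermite quadrature; models with
a crossed center intercept, and the shared-intercept multinomial model, use
a Laplace approximation.  All inner optimizations are Newton-Raphson with
ridging (Levenberg-style diagonal inflation on non-positive-definite
Hessians).  Fixed-effect inference is Wald.

Odds ratios are reported on clinical reporting scales (e.g. per 0.001-unit
VSD, per 0.01-unit VDI): OR = exp(beta * delta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, logsumexp

__all__ = [
    "MixedLogit",
    "MixedLogitResults",
    "MixedMultinomialLogit",
    "MixedMultinomialResults",
    "ConvergenceError",
    "SingularDesignError",
    "constrained_comparison",
    "stepwise_select",
    "scale_odds_ratio",
    "hosmer_lemeshow",
    "REPORTING_DELTAS",
]

#: Default odds-ratio reporting increments per predictor.
REPORTING_DELTAS = {"vsd": 0.001, "vdi": 0.01}


class ConvergenceError(RuntimeError):
    """Optimization failed (e.g. complete separation)."""


class SingularDesignError(ValueError):
    """The fixed-effects design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    if X.ndim != 2 or X.shape[0] <= X.shape[1]:
        raise SingularDesignError("need more observations than parameters")
    sd = X.std(axis=0)
    for j, name in enumerate(names):
        if name != "const" and sd[j] == 0:
            raise SingularDesignError(f"predictor {name!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient (collinear predictors)")


class _Standardizer:
    """Center/scale non-constant columns; maps estimates back afterwards."""

    def __init__(self, X: np.ndarray, names: Sequence[str]):
        self.names = list(names)
        self.mean = X.mean(axis=0)
        self.scale = X.std(axis=0)
        for j, name in enumerate(self.names):
            if name == "const" or self.scale[j] == 0:
                self.mean[j] = 0.0
                self.scale[j] = 1.0
        self.has_const = "const" in self.names

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def jacobian(self) -> np.ndarray:
        """T such that beta_orig = T @ beta_std."""
        p = len(self.names)
        T = np.diag(1.0 / self.scale)
        if self.has_const:
            i0 = self.names.index("const")
            for j in range(p):
                if j != i0:
                    T[i0, j] = -self.mean[j] / self.scale[j]
        return T


def _groups_to_codes(labels) -> tuple[np.ndarray, int]:
    codes, uniq = pd.factorize(np.asarray(labels), sort=True)
    return codes.astype(np.intp), len(uniq)


# ---------------------------------------------------------------------------
# plain (fixed-effects-only) Newton fits, with ridging


def _newton_logistic(X, y, tol=1e-12, maxiter=100, ridge=0.0):
    n, p = X.shape
    beta = np.zeros(p)
    eye = np.eye(p)
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        g = X.T @ (y - mu) - ridge * beta
        w = mu * (1 - mu)
        H = (X * w[:, None]).T @ X + ridge * eye
        step = _ridged_solve(H, g)
        beta_new = beta + step
        if np.linalg.norm(step) < tol * (1 + np.linalg.norm(beta)):
            beta = beta_new
            break
        beta = beta_new
        if np.linalg.norm(beta) > 1e4:
            j = int(np.argmax(np.abs(beta)))
            raise ConvergenceError(
                f"coefficients diverging (possible complete separation); "
                f"largest coefficient on standardized predictor index {j}"
            )
    eta = X @ beta
    if np.max(np.abs(eta)) > 500:
        raise ConvergenceError("fitted logits unbounded (complete separation)")
    mu = expit(eta)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll


def _ridged_solve(H, g):
    """Solve H x = g with Levenberg-style ridging when H is not PD."""
    lam = 0.0
    eye = np.eye(H.shape[0])
    for _ in range(12):
        try:
            c = np.linalg.cholesky(H + lam * eye)
            x = np.linalg.solve(H + lam * eye, g)
            return x
        except np.linalg.LinAlgError:
            lam = 1e-8 if lam == 0 else lam * 10
    return np.linalg.lstsq(H, g, rcond=None)[0]


def _newton_multinomial(X, Y, tol=1e-12, maxiter=100):
    """Baseline-category multinomial Newton; Y is (n,) codes in {0..K-1}."""
    n, p = X.shape
    K = int(Y.max()) + 1
    nc = K - 1
    B = np.zeros((nc, p))
    for _ in range(maxiter):
        eta = X @ B.T  # (n, nc)
        P = _softmax_nonref(eta)
        g = np.concatenate([X.T @ ((Y == c + 1).astype(float) - P[:, c]) for c in range(nc)])
        H = np.zeros((nc * p, nc * p))
        for c in range(nc):
            for d in range(nc):
                w = P[:, c] * ((1.0 if c == d else 0.0) - P[:, d])
                H[c * p:(c + 1) * p, d * p:(d + 1) * p] = (X * w[:, None]).T @ X
        step = _ridged_solve(H, g)
        B_new = B + step.reshape(nc, p)
        if np.linalg.norm(step) < tol * (1 + np.linalg.norm(B)):
            B = B_new
            break
        B = B_new
        if np.linalg.norm(B) > 1e4:
            raise ConvergenceError("multinomial coefficients diverging (separation)")
    eta = X @ B.T
    ll = float(np.sum(np.take_along_axis(_log_softmax_full(eta), Y[:, None], axis=1)))
    return B, ll


def _softmax_nonref(eta):
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    m = full.max(axis=1, keepdims=True)
    e = np.exp(full - m)
    return (e / e.sum(axis=1, keepdims=True))[:, 1:]


def _log_softmax_full(eta):
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    return full - logsumexp(full, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# scalar-random-intercept machinery (shared by binary and multinomial)
#
# Both the binary model and the shared-intercept multinomial reduce, per
# subject, to integrating a product of Bernoulli-like terms over one scalar
# u: for the multinomial, the u-dependence enters only through the total
# non-reference probability, whose logit shifts one-for-one with u.


def _profile_u(eta_fix, y_like, starts, counts, sigma, ll_terms, u0=None, maxiter=50):
    """Per-subject Newton for the posterior mode of the scalar intercept.

    ``ll_terms(eta_off)`` must return (ll_obs, mu, w) where mu is the
    derivative of ll wrt u per observation and w the negative second
    derivative.  Vectorized over all observations; subjects are contiguous
    slices given by (starts, counts).
    """
    m = len(starts)
    u = np.zeros(m) if u0 is None else u0.copy()
    inv_s2 = 1.0 / (sigma * sigma)
    for _ in range(maxiter):
        _, score, w = ll_terms(eta_fix + np.repeat(u, counts))
        g = np.add.reduceat(score, starts) - u * inv_s2
        h = np.add.reduceat(w, starts) + inv_s2
        step = g / h
        # damped update keeps the mode search stable for extreme etas
        step = np.clip(step, -4.0, 4.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-11:
            break
    return u


def _marginal_ll_scalar(eta_fix, starts, counts, sigma, ll_terms, nq, u0=None):
    """AGQ (nq nodes; nq=1 is Laplace) marginal log-likelihood over subjects.

    Returns (ll, u_mode).
    """
    if sigma < 1e-10:
        ll_obs, _, _ = ll_terms(eta_fix)
        return float(ll_obs.sum()), np.zeros(len(starts))
    u = _profile_u(eta_fix, None, starts, counts, sigma, ll_terms, u0=u0)
    inv_s2 = 1.0 / (sigma * sigma)
    ll_obs, _, w = ll_terms(eta_fix + np.repeat(u, counts))
    c = np.add.reduceat(w, starts) + inv_s2  # posterior curvature
    if nq <= 1:
        ll_dat = np.add.reduceat(ll_obs, starts)
        ll = ll_dat - 0.5 * u * u * inv_s2 - 0.5 * np.log(sigma * sigma * c)
        return float(ll.sum()), u
    x, wq = hermgauss(nq)
    s = 1.0 / np.sqrt(c)  # adaptive scale per subject
    ll_total = np.zeros((len(starts), nq))
    for k in range(nq):
        uk = u + math.sqrt(2.0) * s * x[k]
        ll_obs_k, _, _ = ll_terms(eta_fix + np.repeat(uk, counts))
        ll_dat = np.add.reduceat(ll_obs_k, starts)
        log_prior = -0.5 * uk * uk * inv_s2 - 0.5 * math.log(2 * math.pi * sigma * sigma)
        ll_total[:, k] = (
            math.log(wq[k]) + x[k] * x[k] + ll_dat + log_prior
            + np.log(math.sqrt(2.0) * s)
        )
    return float(logsumexp(ll_total, axis=1).sum()), u


def _binary_terms(y):
    def terms(eta):
        mu = expit(eta)
        ll = y * eta - np.logaddexp(0.0, eta)
        return ll, y - mu, mu * (1 - mu)

    return terms


def _multinomial_terms(X, Y, B):
    """Terms as a function of the shared-intercept offset, at fixed B."""
    eta_fix = X @ B.T  # (n, nc)
    y_nonref = (Y > 0).astype(float)

    def terms(u_off):
        eta = eta_fix + u_off[:, None]
        logp = _log_softmax_full(eta)
        ll = np.take_along_axis(logp, Y[:, None], axis=1).ravel()
        p12 = 1.0 - np.exp(logp[:, 0])
        return ll, y_nonref - p12, p12 * (1 - p12)

    return terms, eta_fix


# ---------------------------------------------------------------------------
# crossed subject + center intercepts (binary)
#
# Subjects are many and tiny (1-2 eyes), so their intercept must be
# integrated accurately (AGQ); centers are few and large, where a Laplace
# treatment is essentially exact.  The center effects v ride along in the
# outer optimizer as penalized parameters (they sit at their posterior mode
# at the optimum), with the Laplace log-determinant correction for the
# center block added explicitly.


def _crossed_ll(beta, v, sigmas, X, y, subj_starts, subj_counts, cent, n_cent,
                terms, nq, u0=None):
    s_u, s_c = max(sigmas[0], 1e-8), max(sigmas[1], 1e-8)
    eta_fix = X @ beta + v[cent]
    ll_subj, u = _marginal_ll_scalar(
        eta_fix, subj_starts, subj_counts, s_u, terms, nq, u0=u0
    )
    # center prior + Laplace correction (curvature from conditional weights)
    _, _, w = terms(eta_fix + np.repeat(u, subj_counts))
    h_c = np.bincount(cent, weights=w, minlength=n_cent)
    ll = (
        ll_subj
        - 0.5 * float(v @ v) / s_c**2
        - 0.5 * float(np.sum(np.log(s_c**2 * h_c + 1.0)))
    )
    return ll, u


# ---------------------------------------------------------------------------
# results containers


class _ResultsBase:
    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def zvalues(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self):
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    def odds_ratios(self, deltas: Optional[dict] = None, alpha: float = 0.05) -> pd.DataFrame:
        """Table-style OR report on the clinical reporting scales."""
        deltas = {**REPORTING_DELTAS, **(deltas or {})}
        ci = self.conf_int(alpha)
        rows = []
        for name in self.params.index:
            if name == "const":
                continue
            d = deltas.get(_base_name(name), 1.0)
            rows.append(
                dict(
                    variable=name,
                    delta=d,
                    odds_ratio=math.exp(self.params[name] * d),
                    ci_low=math.exp(ci.loc[name, "lower"] * d),
                    ci_high=math.exp(ci.loc[name, "upper"] * d),
                    p_value=self.pvalues[name],
                )
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"{self._title}",
            f"N obs: {self.nobs}   log-likelihood: {self.llf:.3f}   "
            f"converged: {self.converged}",
        ]
        if self.vc_sd:
            lines.append(
                "random-intercept SD: "
                + ", ".join(f"{k}={v:.4f}" for k, v in self.vc_sd.items())
            )
        lines.append(f"{'':<16}{'coef':>12}{'se':>12}{'z':>9}{'P>|z|':>9}"
                     f"{'[0.025':>12}{'0.975]':>12}")
        for name in self.params.index:
            lines.append(
                f"{name:<16}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{self.zvalues[name]:>9.2f}{self.pvalues[name]:>9.3g}"
                f"{ci.loc[name, 'lower']:>12.4f}{ci.loc[name, 'upper']:>12.4f}"
            )
        return "\n".join(lines)


def _base_name(name: str) -> str:
    return name.split(":")[-1]


@dataclass
class MixedLogitResults(_ResultsBase):
    model: "MixedLogit"
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    llf: float
    converged: bool
    vc_sd: dict
    nobs: int
    method: str

    _title: str = "Mixed-effects binary logistic regression"

    def predict_linear(self, df: pd.DataFrame) -> np.ndarray:
        """Fixed-effects linear predictor for new data (frozen coefficients)."""
        X = self.model.build_design(df)
        return X @ self.params.to_numpy()

    def predict_proba(self, df: Optional[pd.DataFrame] = None) -> np.ndarray:
        if df is None:
            return expit(self.model.exog @ self.params.to_numpy())
        return expit(self.predict_linear(df))

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict_proba()


@dataclass
class MixedMultinomialResults(_ResultsBase):
    model: "MixedMultinomialLogit"
    params: pd.Series  # index "level:variable"
    bse: pd.Series
    cov_params: pd.DataFrame
    llf: float
    converged: bool
    vc_sd: dict
    nobs: int
    method: str
    levels: tuple = ()

    _title: str = "Mixed-effects multinomial logistic regression (shared subject intercept)"


# ---------------------------------------------------------------------------
# model classes


class MixedLogit:
    """Binary logistic regression with optional subject and center intercepts.

    Parameters
    ----------
    endog : array-like of 0/1
    exog : (n, p) design matrix (include the constant yourself, or use
        :meth:`from_dataframe` which adds it)
    exog_names : column names
    groups : subject labels (random intercept), optional
    centers : center labels (second, crossed random intercept), optional
    """

    def __init__(self, endog, exog, exog_names=None, groups=None, centers=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("outcome has a single observed level")
        self.exog = np.asarray(exog, dtype=float)
        self.exog_names = list(
            exog_names
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        _check_design(self.exog, self.exog_names)
        self.groups = None if groups is None else np.asarray(groups)
        self.centers = None if centers is None else np.asarray(centers)
        self._fixed_cols = None  # set by from_dataframe
        self._order = None
        if self.groups is not None:
            # sort observations so each subject is a contiguous slice
            codes, m = _groups_to_codes(self.groups)
            order = np.argsort(codes, kind="stable")
            self._order = order
            self._subj = codes[order]
            self._n_subj = m
            self._y = self.endog[order]
            self._X = self.exog[order]
            self._starts = np.flatnonzero(np.r_[1, np.diff(self._subj)])
            self._counts = np.diff(np.r_[self._starts, len(self._subj)])
            if self.centers is not None:
                ccodes, mc = _groups_to_codes(self.centers)
                self._cent = ccodes[order]
                self._n_cent = mc
        else:
            self._y = self.endog
            self._X = self.exog

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        fixed: Sequence[str],
        subject: Optional[str] = "subject_id",
        center: Optional[str] = None,
        add_intercept: bool = True,
    ) -> "MixedLogit":
        names = (["const"] if add_intercept else []) + list(fixed)
        X = _design_from_df(df, fixed, add_intercept)
        obj = cls(
            endog=df[outcome].to_numpy(),
            exog=X,
            exog_names=names,
            groups=df[subject].to_numpy() if subject else None,
            centers=df[center].to_numpy() if center else None,
        )
        obj._fixed_cols = list(fixed)
        obj._add_intercept = add_intercept
        return obj

    def build_design(self, df: pd.DataFrame) -> np.ndarray:
        if self._fixed_cols is None:
            raise ValueError("build_design requires a model built from a dataframe")
        missing = [c for c in self._fixed_cols if c not in df.columns]
        if missing:
            raise KeyError(f"new data is missing model variable(s): {missing}")
        return _design_from_df(df, self._fixed_cols, self._add_intercept)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        method: str = "auto",
        nq: int = 7,
        fix_re_sd: Optional[float] = None,
        maxiter: int = 300,
        ridge: float = 0.0,
    ) -> MixedLogitResults:
        """Marginal ML fit.

        method "auto" picks adaptive quadrature for a subject-only model,
        Laplace when a center intercept is present, and a plain ridged-Newton
        logistic fit when no random effect is requested.  ``fix_re_sd``
        freezes the random-intercept SD (0 gives the plain-logistic limit
        exactly).
        """
        std = _Standardizer(self.exog, self.exog_names)
        Xs = std.transform(self._X)
        names = self.exog_names

        plain = self.groups is None or (fix_re_sd is not None and fix_re_sd == 0)
        if plain:
            beta_s, ll = _newton_logistic(Xs, self._y, ridge=ridge)
            cov_s = self._plain_cov(Xs, beta_s, ridge=ridge)
            return self._package(std, beta_s, cov_s, ll, True, {}, "newton")

        if method == "laplace":
            nq = 1
        crossed = self.centers is not None

        beta0, _ = _newton_logistic(Xs, self._y, ridge=ridge)
        terms = _binary_terms(self._y)
        state = {"u": None}
        p = len(beta0)

        if not crossed:

            def negll(theta):
                beta, sigma = theta[:-1], abs(theta[-1])
                ll, u = _marginal_ll_scalar(
                    Xs @ beta, self._starts, self._counts, sigma, terms, nq,
                    u0=state["u"],
                )
                state["u"] = u
                return -ll

            n_extra = 0
        else:
            n_cent = self._n_cent

            def negll(theta):
                beta = theta[:p]
                v = theta[p:p + n_cent]
                sigmas = (abs(theta[-2]), abs(theta[-1]))
                ll, u = _crossed_ll(
                    beta, v, sigmas, Xs, self._y, self._starts, self._counts,
                    self._cent, n_cent, terms, nq, u0=state["u"],
                )
                state["u"] = u
                return -ll

            n_extra = n_cent

        n_sig = 2 if crossed else 1
        if fix_re_sd is not None:
            sig0 = [fix_re_sd] * n_sig
            sig_bounds = [(fix_re_sd, fix_re_sd)] * n_sig
        else:
            sig0 = [0.5] * n_sig
            sig_bounds = [(1e-6, 8.0)] * n_sig
        theta0 = np.r_[beta0, np.zeros(n_extra), sig0]
        bounds = [(None, None)] * (p + n_extra) + sig_bounds
        res = optimize.minimize(
            negll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        theta = res.x
        ll = -float(res.fun)
        beta_s = theta[:p]
        sigmas = np.abs(theta[p + n_extra:])
        vc = {"subject": float(sigmas[0])}
        if crossed:
            vc["center"] = float(sigmas[1])

        cov_s = _numeric_beta_cov(negll, theta, p)
        return self._package(std, beta_s, cov_s, ll, bool(res.success), vc,
                             "laplace" if nq == 1 else f"agq{nq}")

    def _plain_cov(self, Xs, beta_s, ridge: float = 0.0):
        mu = expit(Xs @ beta_s)
        w = mu * (1 - mu)
        H = (Xs * w[:, None]).T @ Xs + ridge * np.eye(Xs.shape[1])
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)

    def _package(self, std, beta_s, cov_s, ll, converged, vc, method):
        T = std.jacobian()
        beta = T @ beta_s
        cov = T @ cov_s @ T.T
        params = pd.Series(beta, index=self.exog_names)
        bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=self.exog_names)
        return MixedLogitResults(
            model=self,
            params=params,
            bse=bse,
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            llf=ll,
            converged=converged,
            vc_sd=vc,
            nobs=len(self.endog),
            method=method,
        )


def _design_from_df(df: pd.DataFrame, fixed: Sequence[str], add_intercept: bool) -> np.ndarray:
    cols = []
    for c in fixed:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            # binary string columns like sex: first sorted level is reference
            levels = sorted(v.unique())
            if len(levels) > 2:
                raise ValueError(f"column {c!r} has >2 string levels; encode it numerically")
            cols.append((v == levels[-1]).astype(float).to_numpy())
        else:
            cols.append(v.to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
    return X


def _numeric_beta_cov(negll, theta, p):
    """Central-difference Hessian of the negative marginal ll; beta block."""
    k = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((k, k))
    f0 = negll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (negll(theta + ei) - 2 * f0 + negll(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    negll(theta + ei + ej) - negll(theta + ei - ej)
                    - negll(theta - ei + ej) + negll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov[:p, :p]


class MixedMultinomialLogit:
    """3-level severity model with a subject intercept shared across contrasts.

    The outcome is nominal with a reference level (control); each non-reference
    level gets its own coefficient vector, while a single subject random
    intercept shifts both non-reference logits together (severity propensity
    of the subject).  Fitted by Laplace-approximate ML (or AGQ, since the
    shared intercept is scalar per subject).
    """

    def __init__(self, endog, exog, exog_names=None, groups=None, levels=None):
        endog = np.asarray(endog)
        if levels is None:
            levels = list(pd.unique(endog))
            # conventional severity order when recognized
            known = ["control", "mild", "referable"]
            if set(levels) <= set(known):
                levels = [k for k in known if k in levels]
            else:
                levels = sorted(levels)
        if len(levels) < 2:
            raise ValueError("outcome has a single observed level")
        self.levels = tuple(levels)
        lut = {v: i for i, v in enumerate(levels)}
        self.endog = np.asarray([lut[v] for v in endog], dtype=np.intp)
        self.exog = np.asarray(exog, dtype=float)
        self.exog_names = list(
            exog_names
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        _check_design(self.exog, self.exog_names)
        self.groups = None if groups is None else np.asarray(groups)
        if self.groups is not None:
            codes, m = _groups_to_codes(self.groups)
            order = np.argsort(codes, kind="stable")
            self._order = order
            self._subj = codes[order]
            self._n_subj = m
            self._y = self.endog[order]
            self._X = self.exog[order]
            self._starts = np.flatnonzero(np.r_[1, np.diff(self._subj)])
            self._counts = np.diff(np.r_[self._starts, len(self._subj)])
        else:
            self._y = self.endog
            self._X = self.exog

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        fixed: Sequence[str],
        subject: Optional[str] = "subject_id",
        add_intercept: bool = True,
        levels=None,
    ) -> "MixedMultinomialLogit":
        names = (["const"] if add_intercept else []) + list(fixed)
        X = _design_from_df(df, fixed, add_intercept)
        obj = cls(
            endog=df[outcome].to_numpy(),
            exog=X,
            exog_names=names,
            groups=df[subject].to_numpy() if subject else None,
            levels=levels,
        )
        obj._fixed_cols = list(fixed)
        obj._add_intercept = add_intercept
        return obj

    def fit(
        self,
        method: str = "agq",
        nq: int = 7,
        fix_re_sd: Optional[float] = None,
        maxiter: int = 400,
    ) -> MixedMultinomialResults:
        """Marginal ML fit; adaptive quadrature by default (the shared
        intercept is scalar per subject, so AGQ applies; a Laplace
        approximation under-penalizes large variances at 1-2 eyes/subject).
        """
        std = _Standardizer(self.exog, self.exog_names)
        Xs = std.transform(self._X)
        p = Xs.shape[1]
        nc = len(self.levels) - 1
        Y = self._y

        B0, ll0 = _newton_multinomial(Xs, Y)
        plain = self.groups is None or (fix_re_sd is not None and fix_re_sd == 0)
        if plain:
            cov_s = self._plain_cov(Xs, Y, B0)
            return self._package(std, B0, cov_s, ll0, True, {}, "newton")

        if method == "laplace":
            nq = 1
        state = {"u": None}

        def negll(theta):
            B = theta[: nc * p].reshape(nc, p)
            sigma = abs(theta[-1])
            terms, _ = _multinomial_terms(Xs, Y, B)
            ll, u = _marginal_ll_scalar(
                np.zeros(len(Y)), self._starts, self._counts, sigma, terms, nq,
                u0=state["u"],
            )
            state["u"] = u
            return -ll

        if fix_re_sd is not None:
            bounds = [(None, None)] * (nc * p) + [(fix_re_sd, fix_re_sd)]
            theta0 = np.r_[B0.ravel(), fix_re_sd]
        else:
            bounds = [(None, None)] * (nc * p) + [(1e-6, 8.0)]
            theta0 = np.r_[B0.ravel(), 0.5]
        res = optimize.minimize(
            negll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        B = res.x[: nc * p].reshape(nc, p)
        sigma = float(abs(res.x[-1]))
        ll = -float(res.fun)
        cov_s = _numeric_beta_cov(negll, res.x, nc * p)
        return self._package(
            std, B, cov_s, ll, bool(res.success), {"subject": sigma},
            "laplace" if nq == 1 else f"agq{nq}",
        )

    def _plain_cov(self, Xs, Y, B):
        p = Xs.shape[1]
        nc = B.shape[0]
        eta = Xs @ B.T
        P = _softmax_nonref(eta)
        H = np.zeros((nc * p, nc * p))
        for c in range(nc):
            for d in range(nc):
                w = P[:, c] * ((1.0 if c == d else 0.0) - P[:, d])
                H[c * p:(c + 1) * p, d * p:(d + 1) * p] = (Xs * w[:, None]).T @ Xs
        return np.linalg.inv(H)

    def _package(self, std, B, cov_s, ll, converged, vc, method):
        nc, p = B.shape
        T = std.jacobian()
        Tfull = np.kron(np.eye(nc), T)
        beta = Tfull @ B.ravel()
        cov = Tfull @ cov_s @ Tfull.T
        idx = [
            f"{self.levels[c + 1]}:{name}"
            for c in range(nc)
            for name in self.exog_names
        ]
        params = pd.Series(beta, index=idx)
        bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=idx)
        return MixedMultinomialResults(
            model=self,
            params=params,
            bse=bse,
            cov_params=pd.DataFrame(cov, index=idx, columns=idx),
            llf=ll,
            converged=converged,
            vc_sd=vc,
            nobs=len(self.endog),
            method=method,
            levels=self.levels,
        )


# ---------------------------------------------------------------------------
# analysis operations


CONTRASTS = ("any_vs_control", "referable_vs_mild")


def constrained_comparison(
    df: pd.DataFrame,
    contrast: str,
    fixed: Sequence[str],
    subject: str = "subject_id",
    center: Optional[str] = None,
    class_col: str = "dr_class",
    **fit_kw,
) -> MixedLogitResults:
    """Refit the model as a binary contrast of interest.

    ``any_vs_control`` codes mild+referable = 1 against control = 0 on the
    full table; ``referable_vs_mild`` drops controls and codes referable = 1.
    """
    if contrast == "any_vs_control":
        sub = df.copy()
        sub["_y"] = (sub[class_col] != "control").astype(int)
    elif contrast == "referable_vs_mild":
        sub = df[df[class_col].isin(["mild", "referable"])].copy()
        sub["_y"] = (sub[class_col] == "referable").astype(int)
    else:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {CONTRASTS}")
    if sub["_y"].nunique() < 2:
        raise ValueError(f"contrast {contrast!r} has a single observed level")
    model = MixedLogit.from_dataframe(
        sub, "_y", fixed, subject=subject, center=center
    )
    return model.fit(**fit_kw)


def stepwise_select(
    df: pd.DataFrame,
    candidates: Sequence[str],
    alpha: float = 0.05,
    outcome: Optional[str] = None,
    contrast: Optional[str] = None,
    subject: Optional[str] = "subject_id",
    center: Optional[str] = None,
    **fit_kw,
) -> list:
    """Backward elimination with one forward re-entry sweep, at level alpha.

    Starting from all candidates, repeatedly drop the least significant
    fixed effect with Wald p >= alpha and refit; then sweep once over the
    dropped variables in their original order, re-admitting any that is
    significant when added back.  Deterministic given the data.
    """

    def fit_with(cols):
        if contrast is not None:
            return constrained_comparison(
                df, contrast, cols, subject=subject, center=center, **fit_kw
            )
        model = MixedLogit.from_dataframe(df, outcome, cols, subject=subject, center=center)
        return model.fit(**fit_kw)

    retained = list(candidates)
    while retained:
        res = fit_with(retained)
        pvals = res.pvalues.drop("const", errors="ignore")
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        retained.remove(worst)
    dropped = [c for c in candidates if c not in retained]
    for cand in dropped:
        trial = retained + [cand]
        res = fit_with(trial)
        if res.pvalues[cand] < alpha:
            retained = trial
    return [c for c in candidates if c in retained]


def scale_odds_ratio(
    fit,
    variable: str,
    delta: Optional[float] = None,
    direction: str = "increase",
    alpha: float = 0.05,
) -> dict:
    """Percent change in odds per ``delta``-unit change of a predictor.

    direction "increase": 100*(exp(beta*delta) - 1); "decrease":
    100*(exp(-beta*delta) - 1) — the odds change associated with a
    delta-unit *decrease* of the predictor.  CI endpoints are transformed
    monotonically and reported in increasing order; ``percent_rounded``
    rounds to integer percent for reporting.
    """
    if variable not in fit.params.index:
        raise KeyError(f"variable {variable!r} not in fitted model")
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    d = delta if delta is not None else REPORTING_DELTAS.get(_base_name(variable), 1.0)
    sign = 1.0 if direction == "increase" else -1.0
    ci = fit.conf_int(alpha).loc[variable]
    pct = 100.0 * (math.exp(sign * fit.params[variable] * d) - 1.0)
    bounds = sorted(
        100.0 * (math.exp(sign * b * d) - 1.0) for b in (ci["lower"], ci["upper"])
    )
    return {
        "variable": variable,
        "delta": d,
        "direction": direction,
        "percent": pct,
        "percent_ci": tuple(bounds),
        "percent_rounded": int(round(pct)),
        "percent_ci_rounded": tuple(int(round(b)) for b in bounds),
    }


def hosmer_lemeshow(probs, y, g: int = 10) -> dict:
    """Hosmer-Lemeshow decile-of-risk goodness-of-fit test.

    Observations are sorted by fitted probability and split into ``g``
    near-equal groups; the statistic sums (O-E)^2 / (n pi (1-pi)) over
    groups and is referred to chi-square with g-2 df.
    """
    if g < 3:
        raise ValueError("hosmer_lemeshow requires g >= 3 groups")
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(probs, kind="stable")
    stat = 0.0
    for idx in np.array_split(order, g):
        n_g = len(idx)
        if n_g == 0:
            continue
        obs = y[idx].sum()
        pi = probs[idx].mean()
        exp_ = n_g * pi
        denom = n_g * pi * (1 - pi)
        if denom <= 0:
            continue
        stat += (obs - exp_) ** 2 / denom
    pval = float(stats.chi2.sf(stat, g - 2))
    return {"statistic": float(stat), "p_value": pval, "df": g - 2, "g": g}
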