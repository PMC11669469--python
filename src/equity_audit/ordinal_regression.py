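"""Ordinal probit (cumulative-link) regression of outcome-change categories.

The outcome is the ordered set of observed integer changes in HoNOS item 6
(follow-up minus initial, -4..+4; unobserved extreme categories collapse
inward).  With design row x, coefficients b and strictly increasing
cutpoints a_1 < ... < a_{J-1},

    P(y = j | x) = Phi(a_j - x b) - Phi(a_{j-1} - x b),

with a_0 = -inf and a_J = +inf.  There is no intercept column; location is
absorbed by the cutpoints.  A positive coefficient shifts mass toward more
positive change (less improvement, worse outcome); negative coefficients
indicate improvement.

Fitting is maximum likelihood with an exact analytic gradient under the
standard unconstrained reparameterisation (first cutpoint free, increments
log-parameterised), by L-BFGS.  Standard errors come from the inverse
observed information at the optimum; p-values are two-sided normal on
z = estimate / SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri
from scipy.stats import false_discovery_control
from sklearn.base import BaseEstimator

from .data_model import AgeGroup, CohortTable, Ethnicity, Gender

logger = logging.getLogger("equity_audit")

__all__ = [
    "DEFAULT_REFERENCE_LEVELS",
    "build_design",
    "neg_loglik",
    "neg_loglik_grad",
    "OrdinalProbit",
    "fit_ordinal_probit",
    "CoefficientTest",
    "wald_tests",
    "significant_interactions",
    "tests_frame",
]

DEFAULT_REFERENCE_LEVELS = {
    "gender": Gender.FEMALE.value,
    "ethnicity": Ethnicity.WHITE.value,
    "age_group": AgeGroup.A35_44.value,
}

#: Separator marking interaction columns ("<level> x <treatment>").
INTERACTION_SEP = " x "

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_TINY = 1e-300


def build_design(cohort: CohortTable, include_interactions: bool = False,
                 interaction_whitelist: list[tuple[str, str]] | None = None,
                 reference_levels: dict[str, str] | None = None,
                 min_support: int = 1) -> pd.DataFrame:
    """Intercept-free design matrix for the outcome-change model.

    Columns, in deterministic order: initial score (integer covariate),
    binary uptake per treatment, one-hot demographics with reference levels
    dropped, and optionally interaction columns — elementwise products of a
    demographic one-hot and a treatment binary, named
    ``"<variable>[<level>] x <treatment>"``.  ``interaction_whitelist`` is a
    list of ("variable:level", treatment) pairs restricting which products
    enter; by default all demographic-by-treatment pairs do.

    All-zero, duplicated, and fewer-than-``min_support``-nonzero columns are
    dropped with a warning; columns with only a handful of active patients
    are quasi-separated and stall the optimiser, so pipeline callers pass
    the low-count suppression floor here.
    """
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)

    cols: dict[str, np.ndarray] = {}
    cols["initial_score"] = cohort.df["honos6_initial"].astype(float).to_numpy()
    upt = cohort.uptake_binary()
    for t in cohort.treatments:
        cols[t] = upt[t].to_numpy(dtype=float)

    demo_cols: list[tuple[str, str, str]] = []  # (column, variable, level)
    for var in ("gender", "age_group", "ethnicity"):
        series = cohort.demographic_series(var)
        for lev in sorted(pd.unique(series)):
            if lev == refs.get(var):
                continue
            col = f"{var}[{lev}]"
            cols[col] = (series == lev).to_numpy(dtype=float)
            demo_cols.append((col, var, str(lev)))

    if include_interactions:
        wanted = None
        if interaction_whitelist is not None:
            wanted = {(key, t) for key, t in interaction_whitelist}
        for col, var, lev in demo_cols:
            for t in cohort.treatments:
                if wanted is not None and (f"{var}:{lev}", t) not in wanted:
                    continue
                cols[f"{col}{INTERACTION_SEP}{t}"] = cols[col] * cols[t]

    keep: dict[str, np.ndarray] = {}
    seen: dict[bytes, str] = {}
    for col, v in cols.items():
        nonzero = int(np.count_nonzero(v))
        if nonzero == 0:
            logger.warning("design column %r is all zero; dropped", col)
            continue
        if nonzero < min_support:
            logger.warning("design column %r has support %d < %d; dropped",
                           col, nonzero, min_support)
            continue
        key = v.tobytes()
        if key in seen:
            logger.warning("design column %r duplicates %r; dropped", col, seen[key])
            continue
        seen[key] = col
        keep[col] = v
    return pd.DataFrame(keep, index=cohort.df.index)


def _cutpoints_from_theta(theta: np.ndarray, J: int) -> np.ndarray:
    """theta = (a_1, log d_1, ..., log d_{J-2}) -> strictly increasing cutpoints."""
    alpha = np.empty(J - 1)
    alpha[0] = theta[0]
    if J > 2:
        alpha[1:] = theta[0] + np.cumsum(np.exp(theta[1:]))
    return alpha


def _interval_probs(z_lo: np.ndarray, z_hi: np.ndarray) -> np.ndarray:
    """Phi(z_hi) - Phi(z_lo), computed in the tail-stable direction."""
    flip = z_lo > 0
    p = np.where(flip, ndtr(-z_lo) - ndtr(-z_hi), ndtr(z_hi) - ndtr(z_lo))
    return np.clip(p, _TINY, 1.0)


def _phi(z: np.ndarray) -> np.ndarray:
    out = np.zeros_like(z)
    finite = np.isfinite(z)
    out[finite] = np.exp(-0.5 * z[finite] ** 2) / _SQRT_2PI
    return out


def _nll_core(beta: np.ndarray, alpha: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Negative log-likelihood and its gradient wrt (beta, alpha)."""
    n, p = X.shape
    J = alpha.size + 1
    eta = X @ beta
    a_ext = np.concatenate(([-np.inf], alpha, [np.inf]))
    z_lo = a_ext[y] - eta
    z_hi = a_ext[y + 1] - eta
    prob = _interval_probs(z_lo, z_hi)
    nll = -np.log(prob).sum()

    r_hi = _phi(z_hi) / prob
    r_lo = _phi(z_lo) / prob
    grad_beta = X.T @ (r_hi - r_lo)
    # d nll / d a_j = -(sum_{y=j} r_hi - sum_{y=j+1} r_lo)
    grad_alpha = -(np.bincount(y, weights=r_hi, minlength=J)[: J - 1]
                   - np.bincount(y, weights=r_lo, minlength=J + 1)[1:J])
    return nll, grad_beta, grad_alpha


def neg_loglik(beta, cutpoints, X, y) -> float:
    """Negative log-likelihood at explicit coefficients and cutpoints.

    ``y`` holds 0-based category codes (0..J-1 with J-1 = len(cutpoints)).
    """
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(cutpoints, dtype=float)
    if np.any(np.diff(alpha) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    nll, _, _ = _nll_core(beta, alpha, np.asarray(X, dtype=float), np.asarray(y))
    return float(nll)


def neg_loglik_grad(beta, cutpoints, X, y) -> np.ndarray:
    """Analytic gradient of :func:`neg_loglik` wrt (beta, cutpoints)."""
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(cutpoints, dtype=float)
    _, gb, ga = _nll_core(beta, alpha, np.asarray(X, dtype=float), np.asarray(y))
    return np.concatenate([gb, ga])


class OrdinalProbit(BaseEstimator):
    """Maximum-likelihood ordinal probit regression (sklearn estimator shape).

    Parameters
    ----------
    max_iter : optimiser iteration cap (the ~160-column all-interactions
        design needs just over 500 L-BFGS iterations).
    gtol : gradient-norm tolerance for convergence.

    Fitted attributes
    -----------------
    classes_ : observed outcome categories, ascending.
    coef_ : coefficient per design column.
    cutpoints_ : strictly increasing cutpoints (J-1 for J categories).
    cov_params_ : inverse observed information over (coef_, cutpoints_).
    bse_, zvalues_, pvalues_ : Wald quantities for the coefficients.
    loglik_ : log-likelihood at the optimum.
    converged_ : honest convergence flag.
    """

    def __init__(self, max_iter: int = 1000, gtol: float = 1e-6):
        self.max_iter = max_iter
        self.gtol = gtol

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray([f"x{i}" for i in range(X.shape[1])],
                                                dtype=object)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        classes, codes = np.unique(y, return_inverse=True)
        J = classes.size
        n, p = X.shape
        if J < 2:
            raise ValueError("need at least 2 observed outcome categories")
        if n <= p + J - 1:
            raise ValueError("need more observations than parameters")

        # start: beta = 0, cutpoints at Phi^-1(cumulative frequencies)
        freq = np.bincount(codes, minlength=J) / n
        cum = np.clip(np.cumsum(freq)[:-1], 1e-6, 1 - 1e-6)
        alpha0 = ndtri(cum)
        alpha0 = np.maximum.accumulate(alpha0 + 1e-8 * np.arange(J - 1))
        theta0 = np.concatenate([np.zeros(p), [alpha0[0]],
                                 np.log(np.maximum(np.diff(alpha0), 1e-6))])

        def objective(params):
            beta = params[:p]
            alpha = _cutpoints_from_theta(params[p:], J)
            nll, gb, ga = _nll_core(beta, alpha, X, codes)
            # chain rule through the log-increment reparameterisation
            gtheta = np.empty(J - 1)
            gtheta[0] = ga.sum()
            if J > 2:
                # d alpha_j / d theta_k = exp(theta_k) for j >= k
                rev = np.cumsum(ga[::-1])[::-1]
                gtheta[1:] = rev[1:] * np.exp(params[p + 1:])
            return nll, np.concatenate([gb, gtheta])

        res = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B",
                                options={"maxiter": self.max_iter, "ftol": 1e-12,
                                         "gtol": self.gtol})
        beta = res.x[:p]
        alpha = _cutpoints_from_theta(res.x[p:], J)
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        converged = bool(res.success or grad_norm < 1e-4)

        # observed information in the original (beta, alpha) parameterisation
        u = np.concatenate([beta, alpha])

        def grad_orig(v):
            _, gb, ga = _nll_core(v[:p], v[p:], X, codes)
            return np.concatenate([gb, ga])

        k = u.size
        H = np.empty((k, k))
        h = 1e-5 * np.maximum(1.0, np.abs(u))
        for i in range(k):
            up, dn = u.copy(), u.copy()
            up[i] += h[i]
            dn[i] -= h[i]
            H[:, i] = (grad_orig(up) - grad_orig(dn)) / (2 * h[i])
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-positive variances")
        except np.linalg.LinAlgError:
            logger.warning("observed information singular; using pseudo-inverse")
            cov = np.linalg.pinv(H)
            converged = False

        self.classes_ = classes
        self.coef_ = beta
        self.cutpoints_ = alpha
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.clip(np.diag(cov), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / self.bse_[:p]
        self.zvalues_ = z
        self.pvalues_ = 2.0 * ndtr(-np.abs(z))
        self.loglik_ = float(-res.fun)
        self.converged_ = converged
        self.n_iter_ = int(res.nit)
        self.n_features_in_ = p
        if not converged:
            logger.warning("ordinal probit did not converge (|grad|=%.3g)", grad_norm)
        return self

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        """Category probabilities per row (columns ordered as ``classes_``)."""
        self._check_fitted()
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        eta = X @ self.coef_
        a_ext = np.concatenate(([-np.inf], self.cutpoints_, [np.inf]))
        cum = ndtr(a_ext[None, :] - eta[:, None])
        return np.diff(cum, axis=1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y) -> float:
        """Mean log-likelihood of ``y`` under the fitted model."""
        self._check_fitted()
        proba = self.predict_proba(X)
        codes = np.searchsorted(self.classes_, np.asarray(y))
        return float(np.log(np.clip(proba[np.arange(len(codes)), codes], _TINY, 1)).mean())


def fit_ordinal_probit(X, y, max_iter: int = 1000, gtol: float = 1e-6) -> OrdinalProbit:
    """Functional wrapper: fit and return an :class:`OrdinalProbit`."""
    return OrdinalProbit(max_iter=max_iter, gtol=gtol).fit(X, y)


@dataclass(frozen=True)
class CoefficientTest:
    name: str
    estimate: float
    std_error: float
    z: float
    p_value: float
    significant: bool


def wald_tests(fit: OrdinalProbit, alpha: float = 0.05) -> list[CoefficientTest]:
    """Two-sided z-based Wald test per coefficient (cutpoints excluded)."""
    fit._check_fitted()
    if not fit.converged_:
        raise ValueError("fit did not converge; tests suppressed")
    out = []
    for name, est, se, z, p in zip(fit.feature_names_in_, fit.coef_, fit.bse_,
                                   fit.zvalues_, fit.pvalues_):
        out.append(CoefficientTest(str(name), float(est), float(se), float(z),
                                   float(p), bool(p < alpha)))
    return out


def significant_interactions(tests: list[CoefficientTest], alpha: float = 0.05,
                             mtc: str = "none") -> list[CoefficientTest]:
    """Interaction terms passing the significance threshold.

    ``mtc="benjamini_hochberg"`` applies FDR control across the interaction
    p-values before thresholding; the default applies none.  Negative
    estimates indicate the combination improves symptom severity.
    """
    if mtc not in ("none", "benjamini_hochberg"):
        raise ValueError("mtc must be 'none' or 'benjamini_hochberg'")
    inter = [t for t in tests if INTERACTION_SEP in t.name]
    if not inter:
        return []
    if mtc == "benjamini_hochberg":
        adj = false_discovery_control([t.p_value for t in inter], method="bh")
        return [t for t, q in zip(inter, adj) if q < alpha]
    return [t for t in inter if t.p_value < alpha]


def tests_frame(tests: list[CoefficientTest]) -> pd.DataFrame:
    """Coefficient table (term, estimate, 95% CI, z, p) as a frame."""
    rows = []
    for t in tests:
        rows.append((t.name, t.estimate, t.estimate - 1.96 * t.std_error,
                     t.estimate + 1.96 * t.std_error, t.z, t.p_value, t.significant))
    return pd.DataFrame(rows, columns=["term", "estimate", "ci_low", "ci_high",
                                       "z", "p_value", "significant"])
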