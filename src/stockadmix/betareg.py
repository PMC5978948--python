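"""Beta regression by maximum likelihood, with the model metrics used for
selection (AICc, pseudo-R², VIF, Wald tests).

The response y in (0, 1) is modeled as Beta(μφ, (1-μ)φ) — the mean/precision
parameterization — with a logit link, logit(μ) = x'β. Var(y) = μ(1-μ)/(1+φ).
The likelihood is maximized over (β, log φ) by quasi-Newton iteration with
an analytic gradient; standard errors come from the inverse observed
information (finite differences of the gradient). A derivative-free restart
handles the rare non-convergent start.

Predictors are centered and scaled before fitting; interaction columns are
products of the standardized main effects. The per-variable (mean, SD) pairs
are frozen in the design so later predictions (jackknife folds, cessation
projections) reuse the fitting-time standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, expit, gammaln, logit


@dataclass
class StandardizedDesign:
    """Design matrix with intercept plus standardized terms and a frozen scaler."""

    X: np.ndarray
    term_names: list[str]
    scaler: dict[str, tuple[float, float]]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k_slopes(self) -> int:
        return self.X.shape[1] - 1


@dataclass
class BetaRegFit:
    beta: np.ndarray
    phi: float
    se: np.ndarray  # for beta entries; se_phi separate
    se_phi: float
    z: np.ndarray
    p_values: np.ndarray
    loglik: float
    n: int
    k_slopes: int
    aic: float
    aicc: float
    pseudo_r2: float
    adj_pseudo_r2: float
    converged: bool
    term_names: list[str] = field(default_factory=list)
    scaler: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def df_total(self) -> int:
        """Estimated parameters: slopes + intercept + precision."""
        return self.k_slopes + 2

    def coef(self, term: str) -> float:
        return float(self.beta[self.term_names.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.beta,
                "se": self.se,
                "z": self.z,
                "p_value": self.p_values,
            }
        )


def _term_variables(terms: list[str]) -> list[str]:
    seen: list[str] = []
    for term in terms:
        for var in term.split(":"):
            if var not in seen:
                seen.append(var)
    return seen


def standardize(raw: pd.DataFrame, terms: list[str]) -> StandardizedDesign:
    """Build an intercept + z-scored design; interactions multiply z-scores.

    Sample SD uses the n-1 denominator. The (mean, SD) of every main-effect
    variable is stored so that new observations (a held-out lake, a shifted
    time value) can be projected onto the same scale.
    """
    scaler: dict[str, tuple[float, float]] = {}
    zcols: dict[str, np.ndarray] = {}
    for var in _term_variables(terms):
        x = raw[var].to_numpy(dtype=float)
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"variable {var!r} is constant; cannot standardize")
        scaler[var] = (mean, sd)
        zcols[var] = (x - mean) / sd
    return _assemble(zcols, terms, scaler, len(raw))


def apply_scaler(
    raw: pd.DataFrame, terms: list[str], scaler: dict[str, tuple[float, float]]
) -> StandardizedDesign:
    """Project new raw observations with a frozen (mean, SD) scaler."""
    zcols = {}
    for var in _term_variables(terms):
        mean, sd = scaler[var]
        zcols[var] = (raw[var].to_numpy(dtype=float) - mean) / sd
    return _assemble(zcols, terms, dict(scaler), len(raw))


def _assemble(zcols, terms, scaler, n) -> StandardizedDesign:
    cols = [np.ones(n)]
    for term in terms:
        col = np.ones(n)
        for var in term.split(":"):
            col = col * zcols[var]
        cols.append(col)
    return StandardizedDesign(
        X=np.column_stack(cols), term_names=["(Intercept)"] + list(terms), scaler=scaler
    )


def squeeze_unit_interval(y: np.ndarray) -> np.ndarray:
    """Pull boundary observations into (0, 1): y' = (y(n-1) + 1/2)/n.

    Applied only when some y sits exactly at 0 or 1; interior data pass
    through untouched.
    """
    y = np.asarray(y, dtype=float)
    if ((y < 0) | (y > 1)).any():
        raise ValueError("response values outside [0, 1]")
    if ((y == 0) | (y == 1)).any():
        n = y.size
        y = (y * (n - 1) + 0.5) / n
    return y


def loglik_beta(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Beta log-likelihood in the mean/precision parameterization."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError(
            "response on the boundary of (0, 1); apply squeeze_unit_interval first"
        )
    if phi <= 0:
        raise ValueError("phi must be positive")
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(
        np.sum(
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
    )


def _negloglik_and_grad(theta, X, y, logy, log1my):
    beta, logphi = theta[:-1], theta[-1]
    phi = np.exp(logphi)
    eta = X @ beta
    mu = expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = np.sum(gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * logy + (b - 1) * log1my)
    ystar = logy - log1my
    mustar = digamma(a) - digamma(b)
    dl_deta = phi * (ystar - mustar) * mu * (1.0 - mu)
    grad_beta = X.T @ dl_deta
    dl_dphi = np.sum(
        digamma(phi) - mu * digamma(a) - (1.0 - mu) * digamma(b) + mu * logy + (1.0 - mu) * log1my
    )
    grad = np.concatenate([grad_beta, [dl_dphi * phi]])
    return -ll, -grad


def _start_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS on logit(y) for β; method-of-moments for φ from the OLS residuals."""
    z = logit(y)
    beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta0
    sigma2 = float(resid @ resid) / max(len(y) - X.shape[1], 1)
    mu0 = expit(X @ beta0)
    # delta method: Var(logit y) ~= Var(y) / (mu(1-mu))^2  =>  solve for phi
    var_y = sigma2 * (mu0 * (1.0 - mu0)) ** 2
    with np.errstate(divide="ignore"):
        phi_i = mu0 * (1.0 - mu0) / np.maximum(var_y, 1e-12) - 1.0
    phi0 = float(np.clip(np.mean(phi_i), 0.5, 1e4))
    return np.concatenate([beta0, [np.log(phi0)]])


def _numeric_hessian(fun, theta, h=1e-5):
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = h * max(1.0, abs(theta[j]))
        _, gp = fun(theta + step)
        _, gm = fun(theta - step)
        H[:, j] = (gp - gm) / (2.0 * step[j])
    return 0.5 * (H + H.T)


def fit_betareg(design: StandardizedDesign, y: np.ndarray) -> BetaRegFit:
    """Maximum-likelihood beta regression on a standardized design.

    Pseudo-R² is the squared Pearson correlation between logit(y) and the
    fitted linear predictor; its adjusted version applies the Wherry
    correction 1 - (1-R²)(n-1)/(n-k-1) with k the number of slope terms
    (so it can be negative for weak models). AIC/AICc count slopes +
    intercept + φ as estimated parameters.
    """
    X = design.X
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p - 1} slopes plus intercept and phi")
    y = squeeze_unit_interval(y)
    logy, log1my = np.log(y), np.log1p(-y)
    fun = lambda t: _negloglik_and_grad(t, X, y, logy, log1my)

    theta0 = _start_values(X, y)
    ll0 = -fun(theta0)[0]
    res = optimize.minimize(fun, theta0, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    if not res.success or -res.fun < ll0 - 1e-8:
        # derivative-free fallback from the same start
        res_nm = optimize.minimize(
            lambda t: fun(t)[0], theta0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
        )
        if res_nm.fun < res.fun:
            res = res_nm
    theta = res.x
    # BFGS can exit on precision loss with the gradient already flat; judge
    # convergence by the score at the optimum, not the optimizer's flag
    grad_opt = fun(theta)[1]
    converged = bool(res.success) or bool(np.max(np.abs(grad_opt)) < 1e-4 * max(1.0, n))
    if -res.fun < ll0 - 1e-6:
        warnings.warn("optimizer failed to improve on the starting values")

    H = _numeric_hessian(fun, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular observed information; model unidentifiable") from exc
    diag = np.diag(cov)
    if (diag <= 0).any():
        warnings.warn("non-positive variance estimates; SEs set to nan where invalid")
    with np.errstate(invalid="ignore"):
        se_all = np.sqrt(np.where(diag > 0, diag, np.nan))

    beta = theta[:-1]
    phi = float(np.exp(theta[-1]))
    se = se_all[:-1]
    se_phi = float(phi * se_all[-1])  # delta method from log phi
    z = beta / se
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    ll = float(-res.fun)

    eta = X @ beta
    if np.std(eta) == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(logit(y), eta)[0, 1] ** 2)
    k = p - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    df_total = k + 2
    aic = -2.0 * ll + 2.0 * df_total
    return BetaRegFit(
        beta=beta,
        phi=phi,
        se=se,
        se_phi=se_phi,
        z=z,
        p_values=p_values,
        loglik=ll,
        n=n,
        k_slopes=k,
        aic=aic,
        aicc=aicc(ll, df_total, n),
        pseudo_r2=r2,
        adj_pseudo_r2=float(adj),
        converged=converged,
        term_names=list(design.term_names),
        scaler=dict(design.scaler),
    )


def predict(fit: BetaRegFit, raw: pd.DataFrame) -> np.ndarray:
    """Predicted mean response for new raw observations (frozen scaler)."""
    terms = [t for t in fit.term_names if t != "(Intercept)"]
    design = apply_scaler(raw, terms, fit.scaler)
    return expit(design.X @ fit.beta)


def fit_to_dict(fit: BetaRegFit) -> dict:
    """JSON-serializable snapshot of a fit (enough to predict and project)."""
    return {
        "term_names": fit.term_names,
        "beta": fit.beta.tolist(),
        "phi": fit.phi,
        "se": fit.se.tolist(),
        "se_phi": fit.se_phi,
        "p_values": fit.p_values.tolist(),
        "loglik": fit.loglik,
        "n": fit.n,
        "k_slopes": fit.k_slopes,
        "aic": fit.aic,
        "aicc": fit.aicc,
        "pseudo_r2": fit.pseudo_r2,
        "adj_pseudo_r2": fit.adj_pseudo_r2,
        "converged": fit.converged,
        "scaler": {k: list(v) for k, v in fit.scaler.items()},
    }


def fit_from_dict(payload: dict) -> BetaRegFit:
    beta = np.asarray(payload["beta"], dtype=float)
    se = np.asarray(payload["se"], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    return BetaRegFit(
        beta=beta,
        phi=float(payload["phi"]),
        se=se,
        se_phi=float(payload["se_phi"]),
        z=z,
        p_values=np.asarray(payload["p_values"], dtype=float),
        loglik=float(payload["loglik"]),
        n=int(payload["n"]),
        k_slopes=int(payload["k_slopes"]),
        aic=float(payload["aic"]),
        aicc=float(payload["aicc"]),
        pseudo_r2=float(payload["pseudo_r2"]),
        adj_pseudo_r2=float(payload["adj_pseudo_r2"]),
        converged=bool(payload["converged"]),
        term_names=list(payload["term_names"]),
        scaler={k: (float(v[0]), float(v[1])) for k, v in payload["scaler"].items()},
    )


def aicc(loglik: float, df_total: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= df_total + 1:
        raise ValueError(f"AICc undefined for n={n} with {df_total} parameters")
    aic = -2.0 * loglik + 2.0 * df_total
    return aic + 2.0 * df_total * (df_total + 1) / (n - df_total - 1)


@dataclass
class DesignDiagnostics:
    vif: dict[str, float]
    correlations: pd.DataFrame
    correlation_p: pd.DataFrame


def vif(columns: pd.DataFrame) -> DesignDiagnostics:
    """Variance inflation factors plus the pairwise Pearson matrix.

    VIF_j = 1/(1 - R²_j), with R²_j from OLS of column j on the others
    (with intercept). Perfect collinearity yields an infinite VIF and a
    warning rather than an exception.
    """
    names = list(columns.columns)
    if len(names) < 2:
        raise ValueError("VIF needs at least two terms")
    Xall = columns.to_numpy(dtype=float)
    n = Xall.shape[0]
    if n <= len(names):
        raise ValueError("need more observations than terms for VIF")
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        yj = Xall[:, j]
        others = np.column_stack([np.ones(n), np.delete(Xall, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"perfect collinearity involving {name!r}; VIF infinite")
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)

    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pmat = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r, p = stats.pearsonr(Xall[:, i], Xall[:, j])
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return DesignDiagnostics(vif=out, correlations=corr, correlation_p=pmat)
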