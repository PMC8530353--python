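"""Logistic quantile regression for the bounded collision-risk index.

The risk index y is bounded in [y_min, y_max] (0-100%), so quantile
regression is run on the logistic transform

    z = log((y - y_min) / (y_max - y)),

which maps the interior of the bounds to the real line.  Because quantiles
are equivariant to monotone transforms, the conditional tau-quantile of y is

    Q_y(tau) = (y_max * exp(X b_tau) + y_min) / (1 + exp(X b_tau)),

where b_tau minimizes the check loss sum_i rho_tau(z_i - x_i b) on the
transformed scale, rho_tau(u) = u * (tau - 1{u < 0}).  Fitted quantiles
therefore always respect the bounds.

AIC for a quantile fit uses the asymmetric-Laplace working likelihood with
the scale at its MLE, sigma = (check loss)/n:

    loglik = n*log(tau*(1-tau)) - n*log(sigma) - n
    AIC    = 2k - 2*loglik

which is used consistently, so AIC comparisons across models at a fixed
quantile are meaningful.

The hierarchical model selection first fits a baseline of control
variables (AVGHR, age, mean speed, and sex when it varies), then all nine
combinations of one sympathetic-reflecting variable (LF_score, LF/HF,
SDNN) with one parasympathetic-reflecting variable (HF_score, NN50,
RMSSD).  Models are ranked by AIC within each quantile; among models whose
two added coefficients are significant at every quantile, the one with the
lowest average rank is selected.  A VIF < 10 screen guards against
multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

DEFAULT_QUANTILES = (0.25, 0.50, 0.75, 0.90, 0.95)
DEFAULT_BOUNDS = (0.0, 100.0)
DEFAULT_EPS = 0.1

SNS_VARS = ("lf_score", "lfhf_ratio", "sdnn")
PNS_VARS = ("hf_score", "nn50", "rmssd")
CONTROL_VARS = ("avghr", "age", "mean_speed")


# ---------------------------------------------------------------------------
# transform

def logistic_transform(y, y_min: float = 0.0, y_max: float = 100.0,
                       eps: float = DEFAULT_EPS) -> np.ndarray:
    """Map a bounded response to the real line: log((y-y_min)/(y_max-y)).

    Values are first clamped into [y_min+eps, y_max-eps]; values outside
    [y_min, y_max] raise.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < y_min) or np.any(y > y_max):
        raise ValueError("response outside [y_min, y_max]")
    yc = np.clip(y, y_min + eps, y_max - eps)
    return np.log((yc - y_min) / (y_max - yc))


def inverse_logistic_transform(z, y_min: float = 0.0,
                               y_max: float = 100.0) -> np.ndarray:
    """Inverse of :func:`logistic_transform` (without the eps clamp)."""
    z = np.asarray(z, dtype=float)
    e = np.exp(z)
    return (y_max * e + y_min) / (1.0 + e)


def check_loss(resid: np.ndarray, tau: float) -> float:
    """Quantile check loss sum rho_tau(u), rho_tau(u) = u*(tau - 1{u<0})."""
    u = np.asarray(resid, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


# ---------------------------------------------------------------------------
# model / results objects

@dataclass
class LQRResults:
    """Fit of a logistic quantile regression at one quantile.

    Coefficients live on the transformed (z) scale; ``predict`` returns
    conditional quantiles back on the original bounded scale.
    """

    tau: float
    params: pd.Series
    bse: pd.Series                 # asymptotic (kernel) SEs from the solver
    nobs: int
    bounds: tuple[float, float]
    eps: float
    loss: float                    # check loss at the optimum
    converged: bool
    exog_names: list[str]
    bse_boot: pd.Series | None = None

    @property
    def se(self) -> pd.Series:
        """Bootstrap SEs when available, else asymptotic."""
        return self.bse_boot if self.bse_boot is not None else self.bse

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided p-values from a normal reference on params/SE."""
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.tvalues)),
                         index=self.params.index)

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        """Asymmetric-Laplace working-likelihood AIC (see module docstring)."""
        n = self.nobs
        sigma = self.loss / n
        if sigma <= 0:
            raise ValueError("degenerate fit: zero check loss")
        loglik = n * np.log(self.tau * (1.0 - self.tau)) - n * np.log(sigma) - n
        return 2.0 * self.k - 2.0 * loglik

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Conditional tau-quantile of y on the original bounded scale."""
        if isinstance(X, pd.DataFrame):
            X = X[self.exog_names].to_numpy(float)
        z = np.asarray(X, float) @ self.params.to_numpy()
        return inverse_logistic_transform(z, *self.bounds)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, z, two-sided p."""
        return pd.DataFrame({
            "coef": self.params,
            "se": self.se,
            "z": self.tvalues,
            "P>|z|": self.pvalues,
        })


class LogisticQuantReg:
    """Logistic quantile regression model for a bounded response.

    Parameters
    ----------
    endog : response values in [bounds[0], bounds[1]]
    exog : design matrix *without* intercept; a constant is added.
    bounds, eps : response bounds and the boundary clamp.

    ``fit(tau)`` returns an :class:`LQRResults`; ``fit_boot`` additionally
    attaches bootstrap standard errors.
    """

    def __init__(self, endog, exog: pd.DataFrame | np.ndarray,
                 bounds: tuple[float, float] = DEFAULT_BOUNDS,
                 eps: float = DEFAULT_EPS,
                 exog_names: list[str] | None = None):
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            exog = exog.to_numpy(float)
        exog = np.asarray(exog, float)
        if exog.ndim == 1:
            exog = exog[:, None]
        if exog_names is None:
            exog_names = [f"x{j + 1}" for j in range(exog.shape[1])]
        self.endog = np.asarray(endog, float)
        n, p = exog.shape
        if n <= 10 * (p + 1):
            # soft guidance from practice; warn via exception only when hopeless
            if n <= p + 1:
                raise ValueError("more coefficients than observations")
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), exog])) < p + 1:
            raise ValueError("design matrix is rank deficient")
        self.exog = np.column_stack([np.ones(n), exog])
        self.exog_names = ["const"] + list(exog_names)
        self.bounds = tuple(bounds)
        self.eps = eps
        self.z = logistic_transform(self.endog, *self.bounds, eps=eps)

    def fit(self, tau: float, max_iter: int = 2000) -> LQRResults:
        if not 0.0 < tau < 1.0:
            raise ValueError("tau must be in (0, 1)")
        qr = QuantReg(self.z, self.exog)
        import warnings

        from statsmodels.tools.sm_exceptions import IterationLimitWarning
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IterationLimitWarning)
            res = qr.fit(q=tau, max_iter=max_iter)
        params = pd.Series(res.params, index=self.exog_names)
        bse = pd.Series(res.bse, index=self.exog_names)
        loss = check_loss(self.z - self.exog @ res.params, tau)
        converged = bool(getattr(res, "iterations", 0) < max_iter)
        return LQRResults(tau, params, bse, len(self.z), self.bounds,
                          self.eps, loss, converged, self.exog_names)

    def fit_boot(self, tau: float, n_boot: int = 2000,
                 seed: int = 0) -> LQRResults:
        """Fit and attach bootstrap SEs (records resampled i.i.d.)."""
        res = self.fit(tau)
        res.bse_boot = bootstrap_se(self.exog[:, 1:], self.endog, tau,
                                    self.bounds, n_boot=n_boot, seed=seed,
                                    eps=self.eps,
                                    names=self.exog_names)
        return res


def fit_lqr(X, y, tau: float, bounds: tuple[float, float] = DEFAULT_BOUNDS,
            eps: float = DEFAULT_EPS) -> LQRResults:
    """Convenience wrapper: fit a logistic quantile regression of y on X
    (intercept added) at one quantile."""
    return LogisticQuantReg(y, X, bounds=bounds, eps=eps).fit(tau)


def bootstrap_se(X, y, tau: float,
                 bounds: tuple[float, float] = DEFAULT_BOUNDS,
                 n_boot: int = 2000, seed: int = 0,
                 eps: float = DEFAULT_EPS,
                 names: list[str] | None = None) -> pd.Series:
    """Bootstrap SEs of the logistic-quantile-regression coefficients.

    Records are resampled with replacement ``n_boot`` times; the SE is the
    SD (ddof=1) of the coefficient vectors across resamples.  Seeded and
    reproducible.  Resamples on which the fit is degenerate (rank
    deficiency) are redrawn, up to a small cap.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float)
    n = len(y)
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    while len(draws) < n_boot:
        idx = rng.integers(0, n, n)
        try:
            res = LogisticQuantReg(y[idx], X[idx], bounds=bounds, eps=eps).fit(tau)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > max(20, n_boot // 10):
                raise RuntimeError("repeated rank deficiency across bootstrap "
                                   "resamples")
            continue
        draws.append(res.params.to_numpy())
    se = np.std(np.asarray(draws), axis=0, ddof=1)
    index = names if names is not None else [f"b{j}" for j in range(len(se))]
    return pd.Series(se, index=index)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j).

    Each column is regressed on the others (with intercept).  Exact
    collinearity yields an infinite VIF.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    out = {}
    arr = X.to_numpy(float)
    for j, name in enumerate(X.columns):
        others = np.column_stack([np.ones(len(arr)),
                                  np.delete(arr, j, axis=1)])
        r2 = sm.OLS(arr[:, j], others).fit().rsquared
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# hierarchical selection

def rank_models(aic: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-quantile ascending AIC ranks (ties get average rank) and the
    per-model average rank across quantiles."""
    ranks = aic.apply(lambda col: stats.rankdata(col), axis=0)
    ranks = pd.DataFrame(ranks, index=aic.index, columns=aic.columns)
    return ranks, ranks.mean(axis=1)


@dataclass
class SelectionTable:
    """Outcome of the hierarchical Step-1/Step-2 model selection."""

    models: dict[str, list[str]]          # model id -> full variable list
    baseline_aic: pd.Series               # AIC per quantile, Step-1 model
    aic: pd.DataFrame                     # models x quantiles
    ranks: pd.DataFrame
    avg_rank: pd.Series
    significant: pd.Series                # both Step-2 coefs significant at all tau
    vif: pd.Series                        # over the full candidate design
    chosen: str | None
    fits: dict[tuple[str, float], LQRResults] = field(default_factory=dict)
    diagnostics: str = ""

    def summary(self) -> pd.DataFrame:
        """Table-5-style layout: one row per model, AIC per quantile,
        average rank, significance and selection flags."""
        out = self.aic.copy()
        out.insert(0, "model", [" + ".join(self.models[m][:2]) for m in out.index])
        out["avg_rank"] = self.avg_rank
        out["step2_significant"] = self.significant
        out["chosen"] = [m == self.chosen for m in out.index]
        return out


def hierarchical_select(records: pd.DataFrame,
                        quantiles=DEFAULT_QUANTILES,
                        response: str = "risk_pct",
                        bounds: tuple[float, float] = DEFAULT_BOUNDS,
                        eps: float = DEFAULT_EPS,
                        sns_vars=SNS_VARS, pns_vars=PNS_VARS,
                        controls=CONTROL_VARS,
                        alpha: float = 0.05,
                        se_method: str = "asymptotic",
                        n_boot: int = 200, seed: int = 0) -> SelectionTable:
    """Hierarchical AIC selection of the risk-vs-ANF regression model.

    Step 1 fits the control-only baseline; Step 2 fits all nine
    SNS x PNS two-variable additions at every quantile.  Within each
    quantile models are ranked by AIC; among models whose two added
    coefficients are significant (normal test at ``alpha``) at *all*
    quantiles, the lowest average rank wins.  ``se_method='bootstrap'``
    uses ``n_boot`` bootstrap resamples for the significance SEs instead
    of the solver's asymptotic ones.

    Control variables that are constant in the data (e.g. sex in an
    all-male cohort) are dropped automatically.
    """
    controls = [c for c in controls if c in records.columns
                and records[c].nunique() > 1]
    y = records[response].to_numpy(float)

    candidate_cols = list(dict.fromkeys([*sns_vars, *pns_vars, *controls]))
    vif_series = vif(records[candidate_cols])

    model_vars = {"baseline": list(controls)}
    for i, sv in enumerate(sns_vars):
        for j, pv in enumerate(pns_vars):
            model_vars[f"m{i * len(pns_vars) + j + 1}"] = [sv, pv, *controls]

    fits: dict[tuple[str, float], LQRResults] = {}
    aic_rows = {}
    sig = {}
    for mid, cols in model_vars.items():
        aics = []
        all_sig = True
        for tau in quantiles:
            model = LogisticQuantReg(y, records[cols], bounds=bounds, eps=eps)
            if se_method == "bootstrap":
                res = model.fit_boot(tau, n_boot=n_boot, seed=seed)
            else:
                res = model.fit(tau)
            fits[(mid, tau)] = res
            aics.append(res.aic)
            if mid != "baseline":
                p2 = res.pvalues[list(cols[:2])]
                if (p2 >= alpha).any():
                    all_sig = False
        if mid == "baseline":
            baseline_aic = pd.Series(aics, index=list(quantiles))
        else:
            aic_rows[mid] = aics
            sig[mid] = all_sig

    aic = pd.DataFrame(aic_rows, index=list(quantiles)).T
    ranks, avg_rank = rank_models(aic)
    significant = pd.Series(sig)

    eligible = avg_rank[significant]
    if eligible.empty:
        chosen, diag = None, ("no Step-2 model had both added coefficients "
                              "significant at every quantile")
    else:
        chosen, diag = eligible.idxmin(), ""
    return SelectionTable(model_vars, baseline_aic, aic, ranks, avg_rank,
                          significant, vif_series, chosen, fits, diag)


# ---------------------------------------------------------------------------
# mean-effect model

def fit_mean_model(X, y, bounds: tuple[float, float] = DEFAULT_BOUNDS,
                   eps: float = DEFAULT_EPS):
    """Mean-effect analog of the quantile fits: OLS of the
    logistic-transformed response on X (intercept added).

    Returns the statsmodels OLS results object (coefficients, SEs,
    p-values, summary()).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        names = [f"x{j + 1}" for j in range(Xa.shape[1])]
    z = logistic_transform(np.asarray(y, float), *bounds, eps=eps)
    design = pd.DataFrame(np.column_stack([np.ones(len(z)), Xa]),
                          columns=["const"] + names)
    return sm.OLS(z, design).fit()
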