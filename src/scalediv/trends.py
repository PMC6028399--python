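"""Temporal trend estimation for diversity metrics.

Every "change" quantity in the pipeline is the fitted slope of a metric
against calendar year.  The model is a linear mixed model with a grid-cell
random intercept and AR(1)-correlated residuals,

    y_ct = b0 + b1 * year_t + u_c + e_ct,
    u_c ~ N(0, s_u^2),   corr(e_ct, e_cs) = phi^|t - s|,

fitted by (restricted) maximum likelihood with the fixed effects profiled
out.  Unbalanced panels (cells missing years) are handled through the actual
year gaps in the AR(1) correlation.  A single-cell series drops the random
intercept and reduces to GLS with AR(1) errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


def relative_to_baseline(series) -> np.ndarray:
    """Divide a series by its first value (first entry becomes 1)."""
    arr = np.asarray(series, dtype=float)
    if arr[0] == 0 or not np.isfinite(arr[0]):
        warnings.warn("baseline value is zero or non-finite; relative series undefined")
        return np.full_like(arr, np.nan)
    return arr / arr[0]


def scale_summary(cell_slopes) -> pd.Series:
    """2.5/25/50/75/97.5 percentiles of per-cell slopes (linear interpolation)."""
    arr = np.asarray(cell_slopes, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no slopes to summarise")
    qs = [2.5, 25, 50, 75, 97.5]
    return pd.Series(np.percentile(arr, qs), index=[f"p{q}" for q in qs])


class TemporalTrendModel:
    """Metric-vs-year mixed model with cell random intercept and AR(1) errors.

    Parameters
    ----------
    data : pandas.DataFrame
        Long format with columns ``cell``, ``year``, ``value`` (missing
        cell-years simply absent).  Rows with NaN values are dropped.
    ar_order : int
        Residual autocorrelation order; only AR(1) is implemented (the
        minimal structure for serially-visited sites), ``0`` disables it.
    """

    def __init__(self, data: pd.DataFrame, ar_order: int = 1):
        if ar_order not in (0, 1):
            raise NotImplementedError("only AR(0)/AR(1) residuals are supported")
        df = data[["cell", "year", "value"]].dropna().copy()
        if df["year"].nunique() < 3:
            raise ValueError("need at least 3 distinct time points")
        self.ar_order = ar_order
        self.year_center = df["year"].mean()
        df = df.sort_values(["cell", "year"])
        self.data = df
        self.cells = list(df["cell"].unique())
        self._blocks = []
        for c in self.cells:
            sub = df[df["cell"] == c]
            t = sub["year"].to_numpy(dtype=float)
            X = np.column_stack([np.ones_like(t), t - self.year_center])
            self._blocks.append((t, X, sub["value"].to_numpy(dtype=float)))

    # ----------------------------------------------------------------- fit
    def _neg_loglik(self, theta, reml):
        log_s2, z_phi, log_ratio = theta
        s2 = np.exp(log_s2)
        phi = np.tanh(z_phi) if self.ar_order else 0.0
        su2 = s2 * np.exp(log_ratio) if len(self.cells) > 1 else 0.0
        XtVX = np.zeros((2, 2))
        XtVy = np.zeros(2)
        logdet = 0.0
        chols = []
        for t, X, y in self._blocks:
            n = len(t)
            if self.ar_order and abs(phi) > 0:
                R = phi ** np.abs(t[:, None] - t[None, :])
            else:
                R = np.eye(n)
            V = s2 * R + su2
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e12
            chols.append((L, X, y))
            logdet += 2.0 * np.log(np.diag(L)).sum()
            Xw = np.linalg.solve(L, X)
            yw = np.linalg.solve(L, y)
            XtVX += Xw.T @ Xw
            XtVy += Xw.T @ yw
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return 1e12
        quad = 0.0
        for L, X, y in chols:
            rw = np.linalg.solve(L, y - X @ beta)
            quad += rw @ rw
        nll = 0.5 * (logdet + quad)
        if reml:
            sign, ld = np.linalg.slogdet(XtVX)
            if sign <= 0:
                return 1e12
            nll += 0.5 * ld
        return nll

    def fit(self, method: str = "reml", seed=None) -> "TrendResults":
        """Fit by REML (default) or ML; returns a :class:`TrendResults`."""
        reml = method.lower() == "reml"
        multi = len(self.cells) > 1
        # starting values from pooled OLS residuals
        allX = np.vstack([X for _, X, _ in self._blocks])
        ally = np.concatenate([y for _, _, y in self._blocks])
        b_ols, *_ = np.linalg.lstsq(allX, ally, rcond=None)
        resid = ally - allX @ b_ols
        s2_0 = max(resid.var(), 1e-12)
        x0 = np.array([np.log(s2_0), 0.2 if self.ar_order else 0.0, 0.0])
        bounds = [
            (-30.0, 20.0),
            (-5.0, 5.0) if self.ar_order else (0.0, 0.0),
            (-15.0, 15.0) if multi else (-30.0, -30.0),
        ]
        if not multi:
            x0[2] = -30.0
        if not self.ar_order:
            x0[1] = 0.0
        res = optimize.minimize(
            self._neg_loglik, x0, args=(reml,), method="L-BFGS-B", bounds=bounds
        )
        converged = bool(res.success) or res.fun < self._neg_loglik(x0, reml)
        theta = res.x if converged else x0
        if not converged:
            warnings.warn("variance optimisation did not converge; falling back to OLS start")

        # GLS fixed effects and covariance at the optimum
        log_s2, z_phi, log_ratio = theta
        s2 = np.exp(log_s2)
        phi = np.tanh(z_phi) if self.ar_order else 0.0
        su2 = s2 * np.exp(log_ratio) if multi else 0.0
        XtVX = np.zeros((2, 2))
        XtVy = np.zeros(2)
        for t, X, y in self._blocks:
            n = len(t)
            R = phi ** np.abs(t[:, None] - t[None, :]) if (self.ar_order and abs(phi) > 0) else np.eye(n)
            V = s2 * R + su2
            L = np.linalg.cholesky(V)
            Xw = np.linalg.solve(L, X)
            yw = np.linalg.solve(L, y)
            XtVX += Xw.T @ Xw
            XtVy += Xw.T @ yw
        cov = np.linalg.inv(XtVX)
        beta = cov @ XtVy

        cell_slopes = {}
        for cid, (t, X, y) in zip(self.cells, self._blocks):
            if len(np.unique(t)) >= 2:
                cell_slopes[cid] = np.polyfit(t, y, 1)[0]
        return TrendResults(
            model=self,
            params=pd.Series({"intercept": beta[0], "slope": beta[1]}),
            cov_params=cov,
            sigma2=s2,
            sigma2_cell=su2,
            phi=phi,
            method="REML" if reml else "ML",
            converged=converged,
            cell_slopes=pd.Series(cell_slopes, name="slope"),
        )


@dataclass
class TrendResults:
    """Fitted temporal trend: slope per year, uncertainty, and diagnostics."""

    model: TemporalTrendModel
    params: pd.Series
    cov_params: np.ndarray
    sigma2: float
    sigma2_cell: float
    phi: float
    method: str
    converged: bool
    cell_slopes: pd.Series = field(default_factory=pd.Series)

    @property
    def slope(self) -> float:
        return float(self.params["slope"])

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
            }
        )
        out.attrs.update(
            sigma2=self.sigma2, sigma2_cell=self.sigma2_cell, phi=self.phi, method=self.method
        )
        return out

    def percentiles(self) -> pd.Series:
        return scale_summary(self.cell_slopes.to_numpy())


def fit_trend(metric_table: pd.DataFrame, ar_order: int = 1, method: str = "reml") -> TrendResults:
    """Slope of ``value`` on ``year`` with cell random intercept + AR(1) errors.

    ``metric_table`` needs columns ``cell``, ``year``, ``value``.  Falls back
    to the mean of per-cell OLS slopes (with a warning) if the likelihood
    optimisation fails outright.
    """
    model = TemporalTrendModel(metric_table, ar_order=ar_order)
    try:
        return model.fit(method=method)
    except np.linalg.LinAlgError:
        warnings.warn("mixed-model fit failed; reporting mean of per-cell OLS slopes")
        slopes = []
        for _, sub in metric_table.dropna().groupby("cell"):
            if sub["year"].nunique() >= 2:
                slopes.append(np.polyfit(sub["year"], sub["value"], 1)[0])
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes)) if len(slopes) > 1 else np.nan
        return TrendResults(
            model=model,
            params=pd.Series({"intercept": np.nan, "slope": slopes.mean()}),
            cov_params=np.array([[np.nan, 0.0], [0.0, se**2]]),
            sigma2=np.nan,
            sigma2_cell=np.nan,
            phi=np.nan,
            method="ols-fallback",
            converged=False,
            cell_slopes=pd.Series(slopes),
        )
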