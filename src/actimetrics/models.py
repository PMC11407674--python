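"""Compositional association models, statsmodels-style.

Two model classes cover the statistical questions of the pipeline:

* :class:`CompositionOutcomeModel` — ordinary least squares of a
  (possibly log-transformed) cardiometabolic outcome on the three ILR
  coordinates of the daily time-use composition plus covariates, on
  complete cases.  Its results object carries the global composition
  F test, residual diagnostics, and proportional time-reallocation
  predictions with standardized effect sizes.

* :class:`MetricCompositionComparison` — do the four accelerometer
  metrics produce different mean 24-h compositions?  The ILR vectors of
  all metrics are compared within participant.  The default method is
  an exact repeated-measures MANOVA (Hotelling T^2 on within-person
  differences); a stacked linear mixed model with a random intercept
  per participant and a variance component per log-ratio is available
  as ``method="mixedlm"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coda import DAY_MINUTES, PARTS, close_composition, ilr_transform, reallocate_time

DEFAULT_COVARIATES = ("sex", "age", "education", "smoking",
                      "med_glucose", "med_lipid", "med_bp", "pathology")

ILR_NAMES = ("ilr1", "ilr2", "ilr3")


def encode_covariates(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Reference-coded numeric design columns for the adjustment set.

    Categorical covariates (object/category dtype) are dummy-coded
    dropping the first level; booleans become 0/1; numeric pass through.
    """
    cols = []
    for c in covariates:
        v = df[c]
        if v.dtype == bool:
            cols.append(v.astype(float).rename(c))
        elif v.dtype == object or str(v.dtype) == "category":
            d = pd.get_dummies(v, prefix=c, drop_first=True).astype(float)
            cols.append(d)
        else:
            cols.append(v.astype(float).rename(c))
    return pd.concat(cols, axis=1) if cols else pd.DataFrame(index=df.index)


class CompositionOutcomeModel:
    """OLS of an outcome on ILR time-use coordinates and covariates.

    Parameters
    ----------
    data : DataFrame
        One row per participant with composition part columns (minutes),
        the outcome and the covariates.
    outcome : str
    covariates : sequence of str
    log_outcome : bool
        Fit on ln(outcome); predictions are back-transformed before
        differencing.
    parts : sequence of str
        Composition columns in pivot order (first part = first pivot).
    """

    def __init__(self, data: pd.DataFrame, outcome: str,
                 covariates=DEFAULT_COVARIATES, log_outcome: bool = False,
                 parts=PARTS):
        needed = [outcome, *parts, *covariates]
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        d = data[needed].dropna().copy()  # complete-case analysis
        comps = close_composition(d[list(parts)].to_numpy())
        z = ilr_transform(comps)
        X = pd.DataFrame(z, columns=ILR_NAMES, index=d.index)
        X = pd.concat([X, encode_covariates(d, covariates)], axis=1)
        n_params = X.shape[1] + 1
        if len(d) < n_params + 10:
            raise ValueError(
                f"{len(d)} complete cases for {n_params} parameters; need >= {n_params + 10}")
        y_raw = d[outcome].to_numpy(dtype=float)
        if log_outcome and np.any(y_raw <= 0):
            raise ValueError("log outcome requires positive values")
        self.data = d
        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.log_outcome = log_outcome
        self.parts = tuple(parts)
        self.compositions = comps
        self.exog = X
        self.endog = np.log(y_raw) if log_outcome else y_raw
        self.endog_raw = y_raw

    @classmethod
    def from_dataframe(cls, data, outcome, **kwargs) -> "CompositionOutcomeModel":
        return cls(data, outcome, **kwargs)

    def fit(self) -> "CompositionOutcomeResults":
        import statsmodels.api as sm

        X = sm.add_constant(self.exog)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            corr = X.iloc[:, 1:].corr().abs()
            np.fill_diagonal(corr.values, 0)
            worst = corr.stack().idxmax()
            raise ValueError(f"rank-deficient design; near-collinear columns {worst}")
        res = sm.OLS(self.endog, X).fit()
        return CompositionOutcomeResults(self, res)


class CompositionOutcomeResults:
    """Results wrapper: estimates, global composition test, diagnostics
    and reallocation predictions."""

    def __init__(self, model: CompositionOutcomeModel, sm_results):
        self.model = model
        self._res = sm_results
        self.params = sm_results.params
        self.bse = sm_results.bse
        self.tvalues = sm_results.tvalues
        self.pvalues = sm_results.pvalues
        self.rsquared_adj = float(sm_results.rsquared_adj)
        self.nobs = int(sm_results.nobs)
        self.resid = np.asarray(sm_results.resid)
        self.sigma = float(np.sqrt(sm_results.scale))

    def composition_test(self):
        """Global F test that all three ILR coefficients are zero."""
        k = len(self.params)
        R = np.zeros((3, k))
        for i, name in enumerate(ILR_NAMES):
            R[i, list(self.params.index).index(name)] = 1.0
        ft = self._res.f_test(R)
        return {"F": float(ft.fvalue), "df": (int(ft.df_num), int(ft.df_denom)),
                "p": float(ft.pvalue)}

    def diagnostics(self) -> dict:
        """Residual-based model checks: normality (Shapiro), variance
        homogeneity (Breusch-Pagan), linearity proxy (residual-vs-fitted
        correlation of squares), influence (max Cook's D) and
        collinearity (max VIF)."""
        import statsmodels.api as sm
        from statsmodels.stats.diagnostic import het_breuschpagan
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = sm.add_constant(self.model.exog).to_numpy()
        resid = self.resid
        sw_p = float(stats.shapiro(resid).pvalue) if len(resid) <= 5000 else \
            float(stats.normaltest(resid).pvalue)
        bp_p = float(het_breuschpagan(resid, X)[1])
        fitted = np.asarray(self._res.fittedvalues)
        lin_r = float(stats.pearsonr(fitted, resid ** 2).statistic) if len(resid) > 3 else np.nan
        cooks = self._res.get_influence().cooks_distance[0]
        vifs = [variance_inflation_factor(X, i) for i in range(1, X.shape[1])]
        return {"shapiro_p": sw_p, "breusch_pagan_p": bp_p,
                "resid2_vs_fitted_r": lin_r, "max_cooks_d": float(np.max(cooks)),
                "max_vif": float(np.max(vifs))}

    def mean_composition(self) -> np.ndarray:
        """Closed geometric-mean composition of the estimation sample."""
        gm = np.exp(np.log(self.model.compositions).mean(axis=0))
        return close_composition(gm)

    def _predict_linear(self, comp, cov_row):
        z = ilr_transform(np.asarray(comp, dtype=float))
        x = np.concatenate([[1.0], z, cov_row])
        return float(x @ self.params.to_numpy())

    def predict_reallocation(self, focal, deltas=None,
                             base_composition=None) -> pd.DataFrame:
        """Outcome change for proportional time reallocations.

        For each ``delta`` (minutes, default -20..+20), ``delta`` min are
        moved into the focal behaviour, proportionally exchanged with the
        remaining behaviours, starting from the sample mean composition;
        covariates are held at their estimation-sample means.  Log-model
        predictions are back-transformed before differencing.  The
        standardized effect size divides the absolute difference by the
        SD of the raw outcome in the estimation sample.
        """
        if deltas is None:
            deltas = np.arange(-20, 21)
        base = self.mean_composition() if base_composition is None \
            else close_composition(base_composition)
        cov_mean = self.model.exog.iloc[:, 3:].mean().to_numpy()
        sd_out = float(np.std(self.model.endog_raw, ddof=1))
        p0 = self._predict_linear(base, cov_mean)
        if self.model.log_outcome:
            p0 = np.exp(p0)
        rows = []
        for dlt in deltas:
            try:
                comp = reallocate_time(base, focal, float(dlt), parts=self.model.parts)
            except ValueError as err:
                rows.append({"focal": focal, "delta": float(dlt),
                             "difference": np.nan, "es": np.nan,
                             "note": str(err)})
                continue
            p1 = self._predict_linear(comp, cov_mean)
            if self.model.log_outcome:
                p1 = np.exp(p1)
            diff = p1 - p0
            rows.append({"focal": focal, "delta": float(dlt),
                         "difference": diff, "es": abs(diff) / sd_out,
                         "note": ""})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ct = self.composition_test()
        lines = [
            f"Composition-outcome model: {self.model.outcome}"
            + (" (log scale)" if self.model.log_outcome else ""),
            f"n = {self.nobs} complete cases, adj R^2 = {self.rsquared_adj:.3f}",
            f"Global composition test: F({ct['df'][0]}, {ct['df'][1]}) = "
            f"{ct['F']:.2f}, p = {ct['p']:.4g}",
            f"{'term':<22}{'estimate':>12}{'t':>9}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<22}{self.params[name]:>12.4f}"
                         f"{self.tvalues[name]:>9.2f}{self.pvalues[name]:>10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


@dataclass
class MetricComparisonResults:
    statistic: float
    df: tuple
    pvalue: float
    method: str
    n: int

    def summary(self) -> str:
        return (f"Metric x ILR comparison ({self.method}): "
                f"F({self.df[0]}, {self.df[1]}) = {self.statistic:.3f}, "
                f"p = {self.pvalue:.4g}, n = {self.n} participants")


class MetricCompositionComparison:
    """Within-participant comparison of metric-specific compositions.

    Parameters
    ----------
    data : DataFrame
        Long over metrics: columns id, metric and the four composition
        parts in minutes.  Every participant must have all metrics.
    """

    def __init__(self, data: pd.DataFrame, parts=PARTS):
        metrics = sorted(data["metric"].unique())
        counts = data.groupby("id")["metric"].nunique()
        if (counts != len(metrics)).any():
            raise ValueError("every participant needs a composition per metric")
        wide = {}
        for m in metrics:
            d = data[data["metric"] == m].set_index("id").sort_index()
            wide[m] = ilr_transform(close_composition(d[list(parts)].to_numpy()))
        self.metrics = metrics
        self.ids = sorted(data["id"].unique())
        self.ilr = wide  # metric -> (n, 3)
        self.n = len(self.ids)

    @classmethod
    def from_dataframe(cls, data, **kwargs) -> "MetricCompositionComparison":
        return cls(data, **kwargs)

    def fit(self, method: str = "mm") -> MetricComparisonResults:
        if method == "mm":
            return self._fit_mm()
        if method == "mixedlm":
            return self._fit_mixedlm()
        raise ValueError(f"unknown method {method!r}")

    def _fit_mm(self) -> MetricComparisonResults:
        """Exact repeated-measures MANOVA: Hotelling T^2 on the stacked
        within-participant ILR differences against the first metric."""
        ref = self.ilr[self.metrics[0]]
        diffs = np.hstack([self.ilr[m] - ref for m in self.metrics[1:]])
        n, q = diffs.shape
        if n <= q:
            raise ValueError("need more participants than contrast dimensions")
        mean = diffs.mean(axis=0)
        S = np.cov(diffs, rowvar=False, ddof=1)
        t2 = n * mean @ np.linalg.solve(S, mean)
        f = (n - q) / (q * (n - 1)) * t2
        p = float(stats.f.sf(f, q, n - q))
        return MetricComparisonResults(float(f), (q, n - q), p, "mm", n)

    def _fit_mixedlm(self) -> MetricComparisonResults:
        """Stacked-ILR linear mixed model: fixed metric x ILR-index
        interaction, random intercept per participant and a variance
        component per ILR index; Wald F for the interaction."""
        import statsmodels.formula.api as smf

        rows = []
        for m in self.metrics:
            z = self.ilr[m]
            for j in range(3):
                for i, pid in enumerate(self.ids):
                    rows.append({"id": pid, "metric": m, "ilr_idx": f"z{j+1}",
                                 "value": z[i, j]})
        long = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("value ~ C(metric) * C(ilr_idx)", long,
                             groups=long["id"],
                             vc_formula={"ilr": "0 + C(ilr_idx)"})
            try:
                res = md.fit(reml=True, method="lbfgs")
            except Exception:
                warnings.warn("mixed model failed to converge; "
                              "falling back to the repeated-measures test")
                return self._fit_mm()
        names = [p for p in res.fe_params.index if ":" in p]
        if not names or not res.converged:
            warnings.warn("singular mixed fit; falling back to the "
                          "repeated-measures test")
            return self._fit_mm()
        k = len(res.params)
        R = np.zeros((len(names), k))
        idx = list(res.params.index)
        for i, nm in enumerate(names):
            R[i, idx.index(nm)] = 1.0
        wt = res.wald_test(R, use_f=True, scalar=True)
        return MetricComparisonResults(
            float(wt.statistic), (int(wt.df_num), int(wt.df_denom)),
            float(wt.pvalue), "mixedlm", self.n)
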