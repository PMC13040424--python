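"""Statistical battery for cervical biometry cohorts.

Mirrors the analysis pipeline of the associated cohort study design:
Shapiro-Wilk normality screening, 1.5xIQR outlier removal before model
fitting, two-way random-effects intraclass correlation for rater
agreement, and generalised linear models (Gaussian-identity for
continuous biometry, binomial-logit for birth outcomes) with Wald 95%
confidence intervals and raw (uncorrected) p-values.

The ICC is computed in-package from the mean-squares decomposition;
model fits are delegated to statsmodels behind this module's surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ICCResult",
    "GLMResult",
    "SeparationError",
    "shapiro_wilk",
    "iqr_outlier_filter",
    "icc",
    "fit_linear",
    "fit_logistic",
    "association_report",
    "forest_plot",
]


class SeparationError(RuntimeError):
    """Logistic fit shows (quasi-)complete separation; estimates diverge."""


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""

    coefficient: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.coefficient <= self.ci_high:
            raise ValueError("ICC confidence bounds must bracket the estimate")


@dataclass
class GLMResult:
    """Tidy fit summary for one linear or logistic model."""

    terms: list[str]
    coefficients: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n_used: int
    outliers_removed: int
    family: str  # "gaussian" or "binomial"
    odds_ratios: np.ndarray | None = None
    or_ci_low: np.ndarray | None = None
    or_ci_high: np.ndarray | None = None
    converged: bool = True

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        out = {
            "coef": float(self.coefficients[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p": float(self.p_values[i]),
        }
        if self.odds_ratios is not None:
            out.update(odds_ratio=float(self.odds_ratios[i]),
                       or_ci_low=float(self.or_ci_low[i]),
                       or_ci_high=float(self.or_ci_high[i]))
        return out


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("Shapiro-Wilk needs a 1D sample with n >= 3")
    if len(x) > 5000:
        raise ValueError("Shapiro-Wilk is defined here for n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def iqr_outlier_filter(values, k: float = 1.5
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Remove values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (type 7).  Returns (kept values,
    indices of removed values).  Idempotent only in the sense of a single
    pass: fences are computed once on the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("outlier filter needs a 1D sample with n >= 4")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    removed = np.flatnonzero((x < lo) | (x > hi))
    kept = np.delete(x, removed)
    return kept, removed


def _icc_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way crossed subjects x raters layout."""
    n, k = m.shape
    grand = m.mean()
    row_m = m.mean(axis=1)
    col_m = m.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    sse = np.sum((m - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with an F-based 95% confidence interval.

    ``ratings`` is a complete subjects x raters matrix.  The coefficient is
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n); the interval
    follows the standard Satterthwaite-df construction for the two-way
    random-effects, absolute-agreement, single-rater form.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.any(~np.isfinite(m)):
        raise ValueError("ratings matrix contains missing or non-finite cells")

    msr, msc, mse = _icc_mean_squares(m)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:  # all cells identical
        return ICCResult(1.0, 1.0, 1.0, "ICC(2,1)", n, k)
    est = (msr - mse) / denom

    if mse == 0 and msc == 0:
        return ICCResult(est, est, est, "ICC(2,1)", n, k)
    # Satterthwaite df for the rater/error mixture (McGraw & Wong case 2A)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = msc / mse if mse > 0 else np.inf
        vn = (k - 1) * (n - 1) * (
            k * est * fc + n * (1 + (k - 1) * est) - k * est) ** 2
        vd = ((n - 1) * k**2 * est**2 * fc**2
              + (n * (1 + (k - 1) * est) - k * est) ** 2)
        v = vn / vd if np.isfinite(vn) and vd > 0 else (n - 1) * (k - 1)
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    mix = k * msc + (k * n - k - n) * mse
    lo = n * (msr - f_u * mse) / (f_u * mix + n * msr)
    hi = n * (f_l * msr - mse) / (mix + n * f_l * msr)
    lo = min(lo, est)
    hi = max(hi, est)
    return ICCResult(float(est), float(lo), float(hi), "ICC(2,1)", n, k)


def _design(x, covariates, names: list[str] | None
            ) -> tuple[np.ndarray, list[str]]:
    cols = [np.asarray(x, dtype=float)]
    labels = ["x"] if names is None else [names[0]]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(cols[0]):
            cov = cov.T
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            labels.append(f"cov{j}" if names is None else names[j + 1])
    X = np.column_stack(cols)
    return X, labels


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    Xc = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [lab for j, lab in enumerate(labels)
               if np.linalg.matrix_rank(np.delete(Xc, j + 1, axis=1))
               == np.linalg.matrix_rank(Xc)]
        raise ValueError(f"design matrix is rank deficient; collinear terms: "
                         f"{bad or labels}")


def fit_linear(y, x, covariates=None, term_names: list[str] | None = None,
               filter_outliers: bool = True) -> GLMResult:
    """OLS of y on x (+ covariates) with Wald t CIs.

    By default the response is passed through the 1.5xIQR outlier filter
    first, matching the cohort-analysis protocol; rows removed are counted
    in ``outliers_removed``.
    """
    y = np.asarray(y, dtype=float)
    X, labels = _design(x, covariates, term_names)
    removed = np.array([], dtype=int)
    if filter_outliers and len(y) >= 4:
        _, removed = iqr_outlier_filter(y)
        keep = np.setdiff1d(np.arange(len(y)), removed)
        y, X = y[keep], X[keep]
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few observations for the number of terms")
    _check_rank(X, labels)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    return GLMResult(
        terms=labels,
        coefficients=np.asarray(model.params[1:]),
        ci_low=np.asarray(ci[1:, 0]),
        ci_high=np.asarray(ci[1:, 1]),
        p_values=np.asarray(model.pvalues[1:]),
        n_used=int(model.nobs),
        outliers_removed=int(len(removed)),
        family="gaussian",
    )


def fit_logistic(outcome, x, covariates=None,
                 term_names: list[str] | None = None,
                 max_iter: int = 100, tol: float = 1e-8) -> GLMResult:
    """Maximum-likelihood logistic regression with Wald CIs on odds ratios.

    Fitted by iteratively reweighted least squares.  Raises
    :class:`SeparationError` when the likelihood shows complete or
    quasi-complete separation (diverging coefficients).
    """
    yb = np.asarray(outcome, dtype=float)
    if set(np.unique(yb)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(yb)) < 2:
        raise ValueError("outcome has a single class; logistic model undefined")
    X, labels = _design(x, covariates, term_names)
    if len(yb) <= X.shape[1] + 1:
        raise ValueError("too few observations for the number of terms")
    _check_rank(X, labels)

    Xc = sm.add_constant(X)
    glm = sm.GLM(yb, Xc, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = glm.fit(maxiter=max_iter, tol=tol)
    params = np.asarray(res.params)
    # separation: diverging slopes or vanishing fitted-probability spread
    mu = res.fittedvalues
    if (np.any(np.abs(params[1:]) > 15)
            or np.any(~np.isfinite(res.bse))
            or (np.all((mu < 1e-8) | (mu > 1 - 1e-8)) and len(mu) > 0)):
        raise SeparationError(
            "logistic fit indicates (quasi-)complete separation; "
            "coefficients are not identifiable")
    ci = res.conf_int(alpha=0.05)
    coefs = params[1:]
    lo, hi = np.asarray(ci[1:, 0]), np.asarray(ci[1:, 1])
    return GLMResult(
        terms=labels,
        coefficients=coefs,
        ci_low=lo, ci_high=hi,
        p_values=np.asarray(res.pvalues[1:]),
        n_used=int(res.nobs),
        outliers_removed=0,
        family="binomial",
        odds_ratios=np.exp(coefs),
        or_ci_low=np.exp(lo),
        or_ci_high=np.exp(hi),
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# association battery

REQUIRED_COHORT_COLUMNS = [
    "age", "ethnicity", "ga_weeks", "length_2pt_mm",
    "stroma_vol_cm3", "canal_vol_cm3", "total_vol_cm3",
    "int_os_diam_mm", "ext_os_diam_mm", "uca_deg",
    "caesarean", "induced",
]

#: (name, family, response, focal term, extra covariate columns)
BATTERY = [
    ("total_vol~length", "gaussian", "total_vol_cm3", "length_2pt_mm", []),
    ("stroma_vol~length", "gaussian", "stroma_vol_cm3", "length_2pt_mm", []),
    ("canal_vol~length", "gaussian", "canal_vol_cm3", "length_2pt_mm", []),
    ("int_os~length", "gaussian", "int_os_diam_mm", "length_2pt_mm", []),
    ("ext_os~length", "gaussian", "ext_os_diam_mm", "length_2pt_mm", []),
    ("uca~length", "gaussian", "uca_deg", "length_2pt_mm", []),
    ("stroma_vol~age", "gaussian", "stroma_vol_cm3", "age", []),
    ("caesarean~total_vol+age+ethnicity", "binomial", "caesarean",
     "total_vol_cm3", ["age", "ethnicity"]),
    ("induced~ext_os+ga", "binomial", "induced",
     "ext_os_diam_mm", ["ga_weeks"]),
]


def _encode(df: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, list[str]]:
    """Numeric design columns; categorical columns become dummy indicators."""
    blocks, names = [], []
    for c in cols:
        s = df[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True)
            # drop empty / constant indicator columns (unrepresented levels)
            for dc in dummies.columns:
                col = dummies[dc].to_numpy(dtype=float)
                if col.std() > 0:
                    blocks.append(col)
                    names.append(dc)
        else:
            blocks.append(s.to_numpy(dtype=float))
            names.append(c)
    if not blocks:
        return np.empty((len(df), 0)), []
    return np.column_stack(blocks), names


def association_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Run the fixed association battery on a cohort table.

    Returns a tidy frame with one row per model: the focal-term estimate
    (slope for Gaussian models, odds ratio for logistic models), its 95%
    CI, raw p-value and the number of observations used.  Models that
    fail (e.g., separation) are reported with NaN estimates and an error
    note rather than aborting the battery.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")

    rows = []
    for name, family, resp, focal, extra in BATTERY:
        sub = cohort[[resp, focal] + extra].dropna()
        try:
            cov, cov_names = (None, [])
            if extra:
                cov, cov_names = _encode(sub, extra)
            if family == "gaussian":
                res = fit_linear(sub[resp], sub[focal], covariates=cov,
                                 term_names=[focal] + cov_names)
                est, unit = res.term(focal)["coef"], "slope"
                t = res.term(focal)
                lo, hi = t["ci_low"], t["ci_high"]
            else:
                res = fit_logistic(sub[resp], sub[focal], covariates=cov,
                                   term_names=[focal] + cov_names)
                t = res.term(focal)
                est, unit = t["odds_ratio"], "odds_ratio"
                lo, hi = t["or_ci_low"], t["or_ci_high"]
            rows.append({
                "model": name, "family": family, "term": focal,
                "estimate_type": unit, "estimate": est,
                "ci_low": lo, "ci_high": hi, "p": t["p"],
                "n_used": res.n_used,
                "outliers_removed": res.outliers_removed,
                "error": "",
            })
        except (ValueError, SeparationError) as exc:
            rows.append({
                "model": name, "family": family, "term": focal,
                "estimate_type": "", "estimate": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "n_used": 0, "outliers_removed": 0, "error": str(exc),
            })
    return pd.DataFrame(rows)


def forest_plot(report: pd.DataFrame, path: str | None = None):
    """Forest plot of the battery's odds-ratio rows (log-scaled axis)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = report[(report["estimate_type"] == "odds_ratio")
                  & report["estimate"].notna()]
    fig, ax = plt.subplots(figsize=(6, 1 + 0.6 * max(len(rows), 1)))
    for i, (_, r) in enumerate(rows.iterrows()):
        ax.plot([r.ci_low, r.ci_high], [i, i], "-", color="0.3")
        ax.plot(r.estimate, i, "s", color="k")
    ax.axvline(1.0, color="0.6", linestyle="--")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(rows["model"])
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (95% CI)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
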