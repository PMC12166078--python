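"""Association screening: incremental-R2 regressions and corrections.

Stage-1 screening regresses each continuous outcome on each musicality
predictor beyond covariates (sex, age, ancestry PCs), comparing reduced
and full linear models by an F test on the residual sums of squares;
the polygenic-confounder adjustment adds a PGS to *both* models.
Stage-2 associates a polygenic score with ordinal items through
proportional-odds logistic regression, quantified as incremental
Nagelkerke pseudo-R2.  Multiple testing is handled by Bonferroni over
the literal test count and by the effective number of independent
phenotypes from the spectral decomposition of the phenotype correlation
matrix (Li-Ji or Nyholt estimator).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel


@dataclass
class ScreenResult:
    predictor: str
    outcome: str
    n: int
    incremental_r2: float
    statistic: float
    df: tuple[int, int] | int
    p_value: float
    beta: float = np.nan
    se: float = np.nan
    adjusted_for_pgs: bool = False
    kind: str = "linear"      # 'linear' or 'ordinal'
    flags: dict[str, bool] = field(default_factory=dict)


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = df[cols].to_numpy(dtype=float) if cols else np.empty((len(df), 0))
    return sm.add_constant(X, has_constant="add")


def incremental_r2(
    data: pd.DataFrame, outcome: str, predictor: str,
    covariates: list[str], extra_adjusters: list[str] | None = None,
) -> ScreenResult:
    """Incremental R2 of a predictor beyond covariates, with an F test.

    Fits reduced (covariates + extra adjusters) and full (+ predictor)
    least-squares models on complete cases and compares them by the
    nested-model ANOVA F statistic.  ``extra_adjusters`` (e.g. a PGS for
    educational attainment) enter both models.
    """
    extra = list(extra_adjusters or [])
    used = [outcome, predictor] + covariates + extra
    d = data[used].dropna()
    n = len(d)
    reduced_cols = covariates + extra
    full_cols = reduced_cols + [predictor]
    if n <= len(full_cols) + 1:
        raise ValueError(f"n = {n} too small for {len(full_cols)} regressors")
    if d[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} constant after "
                         "complete-case filtering")
    y = d[outcome].to_numpy(dtype=float)
    fit_r = sm.OLS(y, _design(d, reduced_cols)).fit()
    fit_f = sm.OLS(y, _design(d, full_cols)).fit()
    df_num = 1
    df_den = int(fit_f.df_resid)
    rss_r, rss_f = fit_r.ssr, fit_f.ssr
    F = ((rss_r - rss_f) / df_num) / (rss_f / df_den) if rss_f > 0 else np.inf
    p = float(stats.f.sf(F, df_num, df_den))
    inc = max(float(fit_f.rsquared - fit_r.rsquared), 0.0)
    return ScreenResult(
        predictor=predictor, outcome=outcome, n=n, incremental_r2=inc,
        statistic=float(F), df=(df_num, df_den), p_value=p,
        beta=float(fit_f.params[-1]), se=float(fit_f.bse[-1]),
        adjusted_for_pgs=bool(extra), kind="linear",
    )


def fit_proportional_odds(data: pd.DataFrame, outcome: str,
                          design_cols: list[str]):
    """Cumulative-logit model with shared slopes, fitted by ML.

    Returns the statsmodels results object; its ``llf`` feeds the
    Nagelkerke computation.  Raises on fewer than 2 observed levels or
    when the optimiser diverges (e.g. complete separation).
    """
    d = data[[outcome] + design_cols].dropna()
    y = d[outcome]
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has fewer than 2 observed levels")
    y = pd.Series(pd.Categorical(y, ordered=True), index=d.index)
    X = d[design_cols].astype(float) if design_cols else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y, X, distr="logit")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    if not np.isfinite(res.llf):
        raise ValueError(f"proportional-odds fit for {outcome!r} diverged "
                         "(complete separation?)")
    return res


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2 of a model against the intercept-only null."""
    cox_snell = 1.0 - math.exp((2.0 / n) * (ll_null - ll_model))
    max_r2 = 1.0 - math.exp((2.0 / n) * ll_null)
    return cox_snell / max_r2 if max_r2 > 0 else 0.0


def incremental_nagelkerke(
    data: pd.DataFrame, outcome: str, pgs: str, covariates: list[str],
) -> ScreenResult:
    """Incremental Nagelkerke-R2 of a PGS on an ordinal outcome.

    Reduced (covariates) and full (covariates + PGS) proportional-odds
    models are compared; each model's Nagelkerke-R2 is taken against the
    intercept-only null and the increment is their difference, with the
    p-value from the 1-df likelihood-ratio chi-square.
    """
    used = [outcome, pgs] + covariates
    d = data[used].dropna()
    n = len(d)
    res_null = fit_proportional_odds(d, outcome, [])
    res_red = fit_proportional_odds(d, outcome, covariates)
    res_full = fit_proportional_odds(d, outcome, covariates + [pgs])
    r2_red = nagelkerke_r2(res_red.llf, res_null.llf, n)
    r2_full = nagelkerke_r2(res_full.llf, res_null.llf, n)
    lr = max(2.0 * (res_full.llf - res_red.llf), 0.0)
    p = float(stats.chi2.sf(lr, 1))
    beta = float(res_full.params[pgs])
    se = float(res_full.bse[pgs])
    return ScreenResult(
        predictor=pgs, outcome=outcome, n=n,
        incremental_r2=max(r2_full - r2_red, 0.0),
        statistic=lr, df=1, p_value=p, beta=beta, se=se, kind="ordinal",
    )


def bonferroni(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def meff_spectral(R: np.ndarray, method: str = "li_ji") -> tuple[float, int]:
    """Effective number of independent tests from correlation eigenvalues.

    li_ji:   Meff = sum_i [ I(ev_i >= 1) + (ev_i - floor(ev_i)) ]
    nyholt:  Meff = 1 + (M - 1) * (1 - Var(ev) / M)

    Returns (raw value, integer used for thresholding = ceil(raw), a
    conservative rounding since fewer assumed-independent tests would be
    anti-conservative).
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    ev = np.linalg.eigvalsh(R)[::-1]
    ev = np.clip(ev, 0.0, None)
    M = R.shape[0]
    if method == "li_ji":
        raw = float(np.sum((ev >= 1).astype(float) + (ev - np.floor(ev))))
    elif method == "nyholt":
        raw = float(1.0 + (M - 1) * (1.0 - np.var(ev, ddof=1) / M))
    else:
        raise ValueError(f"unknown method {method!r}")
    return raw, int(math.ceil(raw - 1e-12))


def filter_predictors(results: list[ScreenResult],
                      min_max_r2: float = 0.01) -> list[str]:
    """Retain predictors whose best incremental R2 reaches the floor.

    A predictor is kept iff its maximum incremental R2 across outcomes
    is >= ``min_max_r2`` (boundary retained).  Mirrors dropping infant
    nursery-rhyme items that explain under 1% everywhere.
    """
    if not results:
        raise ValueError("empty screen: nothing to filter")
    best: dict[str, float] = {}
    for r in results:
        best[r.predictor] = max(best.get(r.predictor, 0.0), r.incremental_r2)
    kept = [p for p, r2 in best.items() if r2 >= min_max_r2]
    if not kept:
        warnings.warn("no predictor reached the retention floor; all dropped",
                      stacklevel=2)
    return kept


def pgs_power(n_target: int, r2: float, alpha: float) -> float:
    """Power of the 1-df polygenic association test.

    Uses the noncentral chi-square with NCP = n * r2 / (1 - r2).
    """
    if not 0.0 < r2 < 1.0:
        raise ValueError("r2 must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ncp = n_target * r2 / (1.0 - r2)
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def screen_table(results: list[ScreenResult],
                 thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Long-format results table; one flag column per threshold."""
    rows = []
    for r in results:
        row = {"predictor": r.predictor, "outcome": r.outcome, "n": r.n,
               "kind": r.kind, "stat": r.statistic, "df": str(r.df),
               "beta": r.beta, "se": r.se,
               "incremental_r2": r.incremental_r2, "p": r.p_value,
               "adjusted_for_pgs": r.adjusted_for_pgs}
        for name, thr in (thresholds or {}).items():
            row[f"pass_{name}"] = r.p_value < thr
        rows.append(row)
    return pd.DataFrame(rows)


def residualize(data: pd.DataFrame, measures: list[str],
                covariates: list[str], *, standardize: bool = True,
                ) -> pd.DataFrame:
    """Regress covariates out of each measure (per-measure complete cases).

    Returns a frame of residualised (optionally Z-scored) measures with
    NaN preserved where the measure was missing — the transformation the
    factor models consume.
    """
    out = pd.DataFrame(index=data.index)
    for m in measures:
        d = data[[m] + covariates].dropna()
        X = _design(d, covariates)
        beta = np.linalg.lstsq(X, d[m].to_numpy(dtype=float), rcond=None)[0]
        resid = d[m].to_numpy(dtype=float) - X @ beta
        if standardize:
            sd = resid.std(ddof=1)
            if sd <= 0:
                raise ValueError(f"measure {m!r} constant after adjustment")
            resid = (resid - resid.mean()) / sd
        out.loc[d.index, m] = resid
    return out
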