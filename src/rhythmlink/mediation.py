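"""PGS-embedded mediation decomposition of factor relationships.

Starting from a confirmed CFA, the polygenic score enters as an observed
exogenous variable with a free path ``a`` onto the predictor factor and
``b_k`` onto each outcome factor; the predictor-outcome factor
correlations are replaced by directed paths ``c_k`` (temporal order:
preschool factor -> school-age factors, never reverse) while outcome-
factor disturbances stay freely correlated.  The association between the
predictor factor and outcome factor k then decomposes exactly into a
genetically shared component a*b_k (both factors responding to the same
polygenic cause) and a direct component c_k, with total a*b_k + c_k.

The model is parameterised directly on the standardised scale: factor
disturbance variances are constrained so every factor keeps unit total
variance (1 - a^2 for the predictor factor; 1 - b^2 - c^2 - 2abc for
each outcome factor), so free-parameter estimates and their information-
matrix SEs are the standardised ones.  The product SE uses the delta
method, SE(a*b) = sqrt(a^2 SE_b^2 + b^2 SE_a^2); a case-resampling
bootstrap is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sem import (Cell, FactorModelSpec, FitResult, bootstrap_se, fit_ml,
                  standardize)


def build_mediation_spec(cfa_spec: FactorModelSpec, pgs_name: str,
                         predictor_factor: str,
                         outcome_factors: list[str]) -> FactorModelSpec:
    """Embed a standardised PGS into a CFA as a common exogenous cause.

    The measurement part is copied unchanged; correlations between the
    predictor factor and the outcome factors are removed in favour of
    directed c-paths; ``shared_k = a * b_k`` and ``total_k = a * b_k +
    c_k`` are registered as defined parameters.
    """
    if predictor_factor not in cfa_spec.factors:
        raise ValueError(f"unknown predictor factor {predictor_factor!r}")
    for f in outcome_factors:
        if f not in cfa_spec.factors:
            raise ValueError(f"unknown outcome factor {f!r}")
    if pgs_name in cfa_spec.observed:
        raise ValueError(f"{pgs_name!r} is already an indicator")

    structural = set(outcome_factors) | {predictor_factor}
    cells: list[Cell] = []
    for c in cfa_spec.cells:
        # drop factor (co)variance cells of restructured factors; keep
        # correlations among untouched factors and all measurement cells
        if c.matrix == "S" and {c.row, c.col} & structural and \
                c.row in cfa_spec.factors and c.col in cfa_spec.factors:
            continue
        cells.append(Cell(c.matrix, c.row, c.col, c.free, c.value,
                          c.label, c.expr))

    cells.append(Cell("S", pgs_name, pgs_name, free=False, value=1.0,
                      label="var_pgs"))
    cells.append(Cell("A", predictor_factor, pgs_name, free=True, value=0.05,
                      label="a"))
    cells.append(Cell("S", predictor_factor, predictor_factor, free=False,
                      value=1.0, expr="1 - a**2",
                      label=f"dist_{predictor_factor}"))
    defined = {}
    for f in outcome_factors:
        b, c_ = f"b_{f}", f"c_{f}"
        cells.append(Cell("A", f, pgs_name, free=True, value=0.05, label=b))
        cells.append(Cell("A", f, predictor_factor, free=True, value=0.3,
                          label=c_))
        cells.append(Cell(
            "S", f, f, free=False, value=1.0,
            expr=f"1 - {b}**2 - {c_}**2 - 2*a*{b}*{c_}", label=f"dist_{f}",
        ))
        defined[f"shared_{f}"] = f"a*{b}"
        defined[f"total_{f}"] = f"a*{b} + {c_}"
    for i, f1 in enumerate(outcome_factors):
        for f2 in outcome_factors[i + 1:]:
            cells.append(Cell("S", f1, f2, free=True, value=0.3,
                              label=f"dist_{f1}_{f2}"))

    return FactorModelSpec(
        observed=list(cfa_spec.observed), factors=list(cfa_spec.factors),
        cells=cells, exogenous=list(cfa_spec.exogenous) + [pgs_name],
        defined={**cfa_spec.defined, **defined},
    )


@dataclass
class MediationResult:
    a: float
    a_se: float
    b: dict[str, float]
    b_se: dict[str, float]
    c: dict[str, float]
    c_se: dict[str, float]
    shared: dict[str, float]
    shared_se: dict[str, float]
    shared_p: dict[str, float]
    total: dict[str, float]
    total_se: dict[str, float]
    total_p: dict[str, float]
    fit: FitResult
    loading_shift: pd.DataFrame | None = None
    se_method: str = "delta"

    def table(self) -> pd.DataFrame:
        rows = []
        for f in self.b:
            rows.append({
                "outcome_factor": f, "a": self.a, "a_se": self.a_se,
                "b": self.b[f], "b_se": self.b_se[f],
                "c": self.c[f], "c_se": self.c_se[f],
                "shared": self.shared[f], "shared_se": self.shared_se[f],
                "shared_p": self.shared_p[f],
                "total": self.total[f], "total_se": self.total_se[f],
                "total_p": self.total_p[f],
            })
        return pd.DataFrame(rows)


def _two_sided_p(est: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(est) / se))


def estimate_effects(spec: FactorModelSpec, data: pd.DataFrame,
                     pgs_name: str, predictor_factor: str,
                     outcome_factors: list[str], *, seed: int = 0,
                     se_method: str = "delta", b_boot: int = 200,
                     cfa_fit: FitResult | None = None) -> MediationResult:
    """Fit the mediation model and decompose factor associations.

    ``data`` holds the residualised indicators plus the standardised
    PGS column; estimation is ML on the complete-case covariance.  With
    ``se_method='bootstrap'``, product/total SEs come from ``b_boot``
    case-resampling replicates instead of the delta method.  When the
    matching PGS-free CFA fit is supplied, the measurement loadings are
    compared against it (each should sit within 2 SE).
    """
    cols = spec.manifest
    d = data[cols].dropna()
    pg = d[pgs_name]
    if pg.std(ddof=1) <= 1e-12:
        raise ValueError("PGS column is constant")
    S = np.cov(d.to_numpy(dtype=float), rowvar=False, ddof=1)
    fit = fit_ml(spec, S, len(d), seed=seed)
    if not fit.converged:
        raise RuntimeError(
            f"mediation model did not converge "
            f"({fit.n_restarts_converged} restarts converged)"
        )

    est, se = fit.estimates, fit.se
    a, a_se = est["a"], se.get("a", math.nan)
    b = {f: est[f"b_{f}"] for f in outcome_factors}
    c = {f: est[f"c_{f}"] for f in outcome_factors}
    b_se = {f: se.get(f"b_{f}", math.nan) for f in outcome_factors}
    c_se = {f: se.get(f"c_{f}", math.nan) for f in outcome_factors}
    shared = {f: a * b[f] for f in outcome_factors}
    total = {f: a * b[f] + c[f] for f in outcome_factors}

    if se_method == "delta":
        shared_se = {f: math.sqrt(a ** 2 * b_se[f] ** 2 +
                                  b[f] ** 2 * a_se ** 2)
                     for f in outcome_factors}
        # total adds the c-path; delta with the same independence
        # approximation used for the product term
        total_se = {f: math.sqrt(shared_se[f] ** 2 + c_se[f] ** 2)
                    for f in outcome_factors}
    elif se_method == "bootstrap":
        _, reps = bootstrap_se(d, spec, b_boot, seed=seed)
        shared_se, total_se = {}, {}
        for f in outcome_factors:
            sh = reps["a"] * reps[f"b_{f}"]
            shared_se[f] = float(sh.std(ddof=1))
            total_se[f] = float((sh + reps[f"c_{f}"]).std(ddof=1))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    shared_p = {f: _two_sided_p(shared[f], shared_se[f])
                for f in outcome_factors}
    total_p = {f: _two_sided_p(total[f], total_se[f])
               for f in outcome_factors}

    shift = None
    if cfa_fit is not None:
        shift = compare_loadings(cfa_fit, fit)
    return MediationResult(
        a=a, a_se=a_se, b=b, b_se=b_se, c=c, c_se=c_se,
        shared=shared, shared_se=shared_se, shared_p=shared_p,
        total=total, total_se=total_se, total_p=total_p,
        fit=fit, loading_shift=shift, se_method=se_method,
    )


def compare_loadings(cfa_fit: FitResult, med_fit: FitResult) -> pd.DataFrame:
    """Loading shift between the PGS-free CFA and the mediation model.

    Flags any standardised loading moving more than 2 combined SEs —
    embedding the PGS should leave the measurement part essentially
    unchanged.
    """
    base = cfa_fit.standardized
    med = med_fit.standardized
    rows = []
    for _, r in base[base.matrix == "A"].iterrows():
        m = med[(med.matrix == "A") & (med.row == r.row) & (med.col == r.col)]
        if m.empty:
            continue
        delta = float(m.iloc[0]["std_est"] - r["std_est"])
        tol = 2.0 * math.hypot(r["se"] if np.isfinite(r["se"]) else 0.0,
                               m.iloc[0]["se"] if np.isfinite(m.iloc[0]["se"])
                               else 0.0)
        rows.append({"item": r.row, "factor": r.col,
                     "cfa": r["std_est"], "mediation": m.iloc[0]["std_est"],
                     "delta": delta, "within_2se": abs(delta) <= max(tol, 1e-6)})
    return pd.DataFrame(rows)
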