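"""Data-driven factor-structure discovery.

The model-building recipe: (1) estimate the number of factors from the
eigenvalues of the phenotype correlation matrix (Kaiser rule), (2) split
the cohort into two halves matched on sex and per-measure missingness
patterns, (3) fit a two-block exploratory factor analysis on half A —
one block for predictors, one for outcomes, factors free to correlate
across blocks — under both varimax and oblimin rotations, (4) convert
retained loadings (|lambda| > 0.1, strict) into a confirmatory spec,
(5) confirm on half B, pick the better-fitting rotation (lowest RMSEA,
ties by higher CFI), and refit on the full sample with bootstrap SEs.

Rotations are computed from the unrotated maximum-likelihood solution
(scikit-learn's ML factor analysis) with a gradient-projection
implementation of oblimin and the classical varimax iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .sem import FactorModelSpec, FitResult, bootstrap_se, fit_ml
from .simulate import CohortTable


# ----------------------------------------------------------------------
# factor-count estimation
# ----------------------------------------------------------------------
def estimate_n_factors(R: np.ndarray) -> tuple[int, np.ndarray]:
    """Kaiser rule: count eigenvalues strictly greater than 1.

    Returns (count, eigenvalues descending) so the scree can be
    inspected.  A flat scree (all eigenvalues within 1e-8 of each other)
    triggers a warning because the strict rule then returns 0.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    ev = np.linalg.eigvalsh(R)[::-1]
    if ev[-1] < -1e-8:
        raise ValueError(
            f"correlation matrix not PSD (smallest eigenvalue {ev[-1]:.3e})"
        )
    if np.ptp(ev) < 1e-8:
        warnings.warn("flat scree: all eigenvalues equal; Kaiser count is 0",
                      stacklevel=2)
    return int(np.sum(ev > 1.0)), ev


# ----------------------------------------------------------------------
# matched split-half
# ----------------------------------------------------------------------
def split_half(cohort: CohortTable, seed: int,
               stratifiers: tuple[str, ...] = ("sex", "missingness"),
               min_stratum: int = 4) -> tuple[CohortTable, CohortTable]:
    """Random halves matched on sex and per-measure missingness patterns.

    Individuals are grouped by the joint stratum (sex x observed/missing
    signature over the measures; strata smaller than ``min_stratum`` are
    pooled), shuffled within stratum and assigned alternately.  The
    starting half alternates across strata to keep the overall size
    difference at most 1.
    """
    df = cohort.data
    n = len(df)
    if n < 4:
        raise ValueError("cohort too small to split")
    keys = pd.Series("", index=df.index)
    for s in stratifiers:
        if s == "missingness":
            sig = df[cohort.measures].isna().astype(int).astype(str).agg(
                "".join, axis=1)
            keys = keys + "|" + sig
        elif s in df.columns:
            keys = keys + "|" + df[s].astype(str)
        else:
            raise ValueError(f"stratifier column {s!r} absent from cohort")
    counts = keys.value_counts()
    rare = counts[counts < min_stratum].index
    keys[keys.isin(rare)] = "__pooled__"

    rng = np.random.default_rng(seed)
    assign = pd.Series(index=df.index, dtype=int)
    imbalance = 0  # (size A) - (size B)
    for _, idx in df.groupby(keys, sort=True).groups.items():
        order = np.array(idx)[rng.permutation(len(idx))]
        start = 0 if imbalance <= 0 else 1
        half = (np.arange(len(order)) + start) % 2
        assign.loc[order] = half
        imbalance += int(np.sum(half == 0) - np.sum(half == 1))
    a = CohortTable(df[assign == 0].copy(), cohort.metadata.copy())
    b = CohortTable(df[assign == 1].copy(), cohort.metadata.copy())
    return a, b


# ----------------------------------------------------------------------
# rotations
# ----------------------------------------------------------------------
def varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix."""
    p, k = L.shape
    if k < 2:
        return L.copy()
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag(np.sum(Lr ** 2, axis=0)) / p)
        )
        R = u @ vt
        d_new = np.sum(s)
        if d_new < d * (1 + tol):
            break
        d = d_new
    return L @ R


def _oblimin_criterion(L: np.ndarray, gamma: float = 0.0):
    p, k = L.shape
    L2 = L ** 2
    N = np.ones((k, k)) - np.eye(k)
    C = np.eye(p) - gamma * np.ones((p, p)) / p
    f = np.sum(L2 * (C @ L2 @ N)) / 4.0
    G = L * (C @ L2 @ N)
    return f, G


def oblimin(L: np.ndarray, gamma: float = 0.0, max_iter: int = 500,
            tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Oblique (direct) oblimin rotation by gradient projection.

    Returns (pattern loadings, factor correlation matrix).  Uses the
    Bernaards-Jennrich gradient-projection iteration on the rotation
    matrix T with unit-length columns of inv(T).
    """
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    Lr = L @ Ti.T
    f, G = _oblimin_criterion(Lr)
    Gt = -(Lr.T @ G @ Ti).T
    for _ in range(max_iter):
        Gp = Gt - T * np.sum(T * Gt, axis=0)  # project: zero diag of T'Gt
        s = np.sqrt(np.sum(Gp ** 2))
        if s < tol:
            break
        al = 2.0 * al
        for _ in range(20):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X ** 2, axis=0))
            Ti_new = np.linalg.inv(X)
            L_new = L @ Ti_new.T
            f_new, G_new = _oblimin_criterion(L_new)
            if f_new < f - 0.5 * s ** 2 * al:
                break
            al = al / 2.0
        T, Ti, Lr, f = X, Ti_new, L_new, f_new
        Gt = -(Lr.T @ G_new @ Ti).T
    Phi = T.T @ T
    return Lr, Phi


# ----------------------------------------------------------------------
# two-block EFA
# ----------------------------------------------------------------------
@dataclass
class EfaResult:
    rotation: str
    loadings: pd.DataFrame           # measures x all factors (cross-block 0)
    factor_correlations: pd.DataFrame
    predictor_factors: list[str]
    outcome_factors: list[str]


def _block_efa(X: np.ndarray, k: int, rotation: str, seed: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Unrotated ML EFA then the requested rotation; standardised input."""
    if k > X.shape[1]:
        raise ValueError(f"{k} factors exceed the {X.shape[1]}-variable "
                         "block identification limit")
    fa = FactorAnalysis(n_components=k, random_state=seed, max_iter=5000)
    fa.fit(X)
    L = fa.components_.T  # p x k standardised loadings (X is Z-scored)
    if rotation == "varimax":
        Lr = varimax(L)
        Phi = np.eye(k)
    elif rotation == "oblimin":
        Lr, Phi = oblimin(L)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    # orient each factor so its largest loading is positive
    for j in range(k):
        if Lr[np.argmax(np.abs(Lr[:, j])), j] < 0:
            Lr[:, j] = -Lr[:, j]
            Phi[j, :] = -Phi[j, :]
            Phi[:, j] = -Phi[:, j]
    return Lr, Phi


def efa_two_block(data: pd.DataFrame, predictor_measures: list[str],
                  outcome_measures: list[str], k_predictor_factors: int,
                  k_outcome_factors: int, rotation: str = "varimax",
                  seed: int = 0) -> EfaResult:
    """Two-block EFA with cross-block factor correlations.

    ``data`` holds covariate-residualised measures; each block's factor
    solution is extracted by ML on the block's complete cases and
    rotated; inter-block factor correlations are estimated from
    regression-method factor scores on the joint complete cases.
    """
    blocks = {
        "P": (predictor_measures, k_predictor_factors),
        "O": (outcome_measures, k_outcome_factors),
    }
    load = {}
    phis = {}
    fnames = {}
    for tag, (cols, k) in blocks.items():
        if k < 1:
            raise ValueError("factor counts must be >= 1")
        d = data[cols].dropna()
        X = (d - d.mean()) / d.std(ddof=1)
        L, Phi = _block_efa(X.to_numpy(), k, rotation, seed)
        load[tag] = pd.DataFrame(L, index=cols,
                                 columns=[f"{tag}{j + 1}" for j in range(k)])
        phis[tag] = Phi
        fnames[tag] = list(load[tag].columns)

    all_factors = fnames["P"] + fnames["O"]
    measures = predictor_measures + outcome_measures
    full = pd.DataFrame(0.0, index=measures, columns=all_factors)
    for tag in blocks:
        full.loc[load[tag].index, load[tag].columns] = load[tag]

    # factor scores (regression method) on joint complete cases
    joint = data[measures].dropna()
    Z = ((joint - joint.mean()) / joint.std(ddof=1))
    scores = {}
    for tag, (cols, k) in blocks.items():
        Xb = Z[cols].to_numpy()
        L = load[tag].to_numpy()
        Sigma_xf = L @ phis[tag]          # structure matrix
        Rb = np.corrcoef(Xb, rowvar=False)
        B = np.linalg.solve(Rb, Sigma_xf)
        scores[tag] = Xb @ B
    Fs = np.hstack([scores["P"], scores["O"]])
    Rf = np.corrcoef(Fs, rowvar=False)
    # within-block correlations come from the rotation itself
    kp = len(fnames["P"])
    Rf[:kp, :kp] = phis["P"]
    Rf[kp:, kp:] = phis["O"]
    fcorr = pd.DataFrame(Rf, index=all_factors, columns=all_factors)
    return EfaResult(rotation=rotation, loadings=full,
                     factor_correlations=fcorr,
                     predictor_factors=fnames["P"],
                     outcome_factors=fnames["O"])


# ----------------------------------------------------------------------
# CFA spec construction and confirmation
# ----------------------------------------------------------------------
def build_cfa_spec(loadings: pd.DataFrame, retain_threshold: float = 0.1,
                   factor_correlations: pd.DataFrame | None = None
                   ) -> FactorModelSpec:
    """Free a loading wherever |lambda| exceeds the threshold (strict).

    Measures with no retained loading are dropped with a warning; an
    empty model is an error.  Factors are variance-standardised with all
    correlations free.
    """
    if not np.isfinite(loadings.to_numpy()).all():
        raise ValueError("non-finite loadings")
    pattern: dict[str, dict[str, float]] = {f: {} for f in loadings.columns}
    dropped = []
    for m, row in loadings.iterrows():
        kept = row[row.abs() > retain_threshold]
        if kept.empty:
            dropped.append(m)
            continue
        for f, lam in kept.items():
            pattern[f][m] = float(lam)
    if dropped:
        warnings.warn(f"measures with no retained loading dropped: {dropped}",
                      stacklevel=2)
    pattern = {f: items for f, items in pattern.items() if items}
    if not pattern:
        raise ValueError("empty model: no loading exceeded the threshold")
    fc = None
    if factor_correlations is not None:
        fc = {(f1, f2): float(factor_correlations.loc[f1, f2])
              for i, f1 in enumerate(pattern)
              for f2 in list(pattern)[i + 1:]}
    return FactorModelSpec.cfa(pattern, factor_correlations=fc)


@dataclass
class DiscoveryResult:
    n_factors: int
    eigenvalues: np.ndarray
    chosen_rotation: str
    spec: FactorModelSpec
    holdout_fit: FitResult
    full_fit: FitResult
    interpretation: pd.DataFrame
    bootstrap: dict[str, float] = field(default_factory=dict)
    candidate_fits: dict[str, FitResult] = field(default_factory=dict)


def _cov_complete(data: pd.DataFrame, cols: list[str]
                  ) -> tuple[np.ndarray, int]:
    d = data[cols].dropna()
    return np.cov(d.to_numpy(dtype=float), rowvar=False, ddof=1), len(d)


def confirm_and_refit(specs: dict[str, FactorModelSpec], half_b: pd.DataFrame,
                      full: pd.DataFrame, b_boot: int = 1000, seed: int = 0,
                      meaningful: float = 0.3) -> DiscoveryResult:
    """Confirm candidate CFA specs on the holdout half, refit on all data.

    The spec with the lowest holdout RMSEA wins (ties by higher CFI,
    then by parsimony: the spec with more residual degrees of freedom).
    The full-sample refit optionally gets case-resampling bootstrap SEs
    (``b_boot`` replicates); the interpretation table flags standardised
    |loading| > ``meaningful`` and |factor correlation| > ``meaningful``
    (both strict).
    """
    fits = {}
    for rot, spec in specs.items():
        S, n = _cov_complete(half_b, spec.manifest)
        fits[rot] = fit_ml(spec, S, n, seed=seed)
        if not fits[rot].converged:
            raise RuntimeError(f"holdout CFA ({rot}) did not converge")

    def key(rot):
        f = fits[rot]
        rmsea = f.indices["rmsea"] if f.indices["rmsea"] is not None else 0.0
        cfi = f.indices["cfi"] if f.indices["cfi"] is not None else 1.0
        return (rmsea, -cfi, -f.df)

    best = min(fits, key=key)
    spec = specs[best]
    S_full, n_full = _cov_complete(full, spec.manifest)
    full_fit = fit_ml(spec, S_full, n_full, seed=seed)

    boot = {}
    if b_boot >= 2:
        boot, _ = bootstrap_se(full[spec.manifest].dropna(), spec, b_boot,
                               seed=seed)
        full_fit.se = {**full_fit.se, **boot}
        full_fit.standardized = None
        if full_fit.admissible:
            from .sem import standardize
            full_fit.standardized = standardize(full_fit)

    tab = full_fit.standardized.copy()
    is_loading = (tab.matrix == "A")
    is_fcorr = ((tab.matrix == "S") & tab.row.isin(spec.factors)
                & tab.col.isin(spec.factors) & (tab.row != tab.col))
    tab["meaningful"] = False
    tab.loc[is_loading | is_fcorr, "meaningful"] = (
        tab.loc[is_loading | is_fcorr, "std_est"].abs() > meaningful
    )
    return DiscoveryResult(
        n_factors=len(spec.factors), eigenvalues=np.array([]),
        chosen_rotation=best, spec=spec, holdout_fit=fits[best],
        full_fit=full_fit, interpretation=tab, bootstrap=boot,
        candidate_fits=fits,
    )


def discover(cohort: CohortTable, residualized: pd.DataFrame, seed: int,
             retain_threshold: float = 0.1, b_boot: int = 0,
             rotations: tuple[str, ...] = ("varimax", "oblimin"),
             ) -> DiscoveryResult:
    """End-to-end structure discovery on a residualised cohort.

    Factor counts come from per-block Kaiser rules (the overall count
    from the full correlation matrix is recorded for the scree); the
    split, EFA, CFA-confirmation and full refit follow the recipe above.
    """
    meta = cohort.metadata
    predictors = [m for m in cohort.measures
                  if meta.loc[m, "role"] == "predictor"
                  and not meta.loc[m].get("composite", False)]
    outcomes = [m for m in cohort.measures
                if meta.loc[m, "role"] == "outcome"
                and not meta.loc[m].get("composite", False)]
    measures = predictors + outcomes

    R_all = residualized[measures].dropna().corr().to_numpy()
    k_all, ev = estimate_n_factors(R_all)
    k_pred, _ = estimate_n_factors(
        residualized[predictors].dropna().corr().to_numpy())
    k_out, _ = estimate_n_factors(
        residualized[outcomes].dropna().corr().to_numpy())
    k_pred, k_out = max(k_pred, 1), max(k_out, 1)

    res_cohort = CohortTable(
        data=pd.concat([residualized[measures],
                        cohort.data[["sex"]]], axis=1),
        metadata=meta.loc[measures],
    )
    half_a, half_b = split_half(res_cohort, seed=seed)

    specs = {}
    for rot in rotations:
        efa = efa_two_block(half_a.data, predictors, outcomes, k_pred, k_out,
                            rotation=rot, seed=seed)
        specs[rot] = build_cfa_spec(efa.loadings, retain_threshold,
                                    efa.factor_correlations)
    result = confirm_and_refit(specs, half_b.data, residualized[measures],
                               b_boot=b_boot, seed=seed)
    result.n_factors = k_pred + k_out
    result.eigenvalues = ev
    return result
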