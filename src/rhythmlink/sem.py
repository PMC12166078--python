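"""Covariance-structure (SEM) estimation engine.

Implements a RAM-parameterised structural equation model: every variable
(observed indicator, observed exogenous regressor such as a polygenic
score, or latent factor) is a node; directed paths (loadings, regressions)
live in an asymmetric matrix ``A`` and (co)variances in a symmetric matrix
``S``.  The model-implied covariance of the observed variables is

    Sigma = F (I - A)^{-1} S (I - A)^{-T} F^T

where ``F`` filters observed rows.  Estimation is normal-theory maximum
likelihood on a sample covariance matrix, with the discrepancy

    F_ML = ln|Sigma| + tr(S_sample Sigma^{-1}) - ln|S_sample| - p

minimised by quasi-Newton iteration with analytic gradients (numeric when
the spec contains nonlinearly constrained cells) and multiple random
restarts.  Standard errors come from the inverse observed information; a
nonparametric case-resampling bootstrap is available as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize


class IdentificationError(ValueError):
    """Model has negative degrees of freedom or an unanchored factor."""


class ConvergenceError(RuntimeError):
    """Optimiser failed to converge from any restart."""


@dataclass
class Cell:
    """One entry of the RAM ``A`` (paths) or ``S`` (covariances) matrix.

    A cell is fixed (``free=False, expr=None``), free (``free=True``;
    ``value`` is the start value), or constrained (``expr`` is an
    expression in the labels of free parameters, evaluated at every
    objective call).  Cells sharing a label are equality-constrained.
    """

    matrix: str  # 'A' or 'S'
    row: str
    col: str
    free: bool = True
    value: float = 0.5
    label: str | None = None
    expr: str | None = None


@dataclass
class FactorModelSpec:
    """Declarative SEM specification.

    ``observed`` are the indicator variables, ``exogenous`` observed
    variables modelled alongside them (e.g. a standardised polygenic
    score), ``factors`` the latent variables.  ``cells`` hold every
    nonzero entry of A and S; anything not listed is structurally zero.
    ``defined`` maps a name to an arithmetic expression in parameter
    labels (e.g. ``"a*b_speech + c_speech"``) evaluated on the estimates.
    """

    observed: list[str]
    factors: list[str]
    cells: list[Cell] = field(default_factory=list)
    exogenous: list[str] = field(default_factory=list)
    defined: dict[str, str] = field(default_factory=dict)

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def cfa(
        cls,
        loadings: dict[str, dict[str, float]],
        *,
        factor_correlations: dict[tuple[str, str], float] | None = None,
        correlations_free: bool = True,
        residuals: dict[str, float] | None = None,
        loadings_free: bool = True,
        residuals_free: bool = True,
        standardized_factors: bool = True,
    ) -> "FactorModelSpec":
        """Confirmatory factor model: ``loadings[factor][item] = value``.

        Factors are identified by fixing their variance to 1
        (standardised factors); all pairwise factor covariances are free
        unless ``correlations_free`` is False, in which case the supplied
        ``factor_correlations`` are fixed values.
        """
        factors = list(loadings)
        observed: list[str] = []
        cells: list[Cell] = []
        for f in factors:
            for item, lam in loadings[f].items():
                if item not in observed:
                    observed.append(item)
                cells.append(
                    Cell("A", item, f, free=loadings_free, value=lam,
                         label=f"lambda_{item}_{f}")
                )
        for item in observed:
            start = 0.5 if residuals is None else residuals.get(item, 0.5)
            cells.append(Cell("S", item, item, free=residuals_free,
                              value=start, label=f"theta_{item}"))
        for f in factors:
            if not standardized_factors:
                raise NotImplementedError("marker-variable identification "
                                          "is handled via explicit cells")
            cells.append(Cell("S", f, f, free=False, value=1.0,
                              label=f"psi_{f}_{f}"))
        fc = factor_correlations or {}
        for i, f1 in enumerate(factors):
            for f2 in factors[i + 1:]:
                val = fc.get((f1, f2), fc.get((f2, f1), 0.2))
                cells.append(Cell("S", f1, f2, free=correlations_free,
                                  value=val, label=f"psi_{f1}_{f2}"))
        return cls(observed=observed, factors=factors, cells=cells)

    # ------------------------------------------------------------------
    # layout
    # ------------------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return self.observed + self.exogenous + self.factors

    @property
    def manifest(self) -> list[str]:
        """Variables appearing in the modelled covariance matrix."""
        return self.observed + self.exogenous

    def free_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.cells:
            if c.free and c.expr is None and c.label not in seen:
                seen.append(c.label)
        return seen

    @property
    def n_free(self) -> int:
        return len(self.free_labels())

    @property
    def df(self) -> int:
        p = len(self.manifest)
        return p * (p + 1) // 2 - self.n_free

    def start_vector(self) -> np.ndarray:
        starts = {}
        for c in self.cells:
            if c.free and c.expr is None and c.label not in starts:
                starts[c.label] = c.value
        return np.array([starts[l] for l in self.free_labels()])

    def validate(self) -> None:
        """Identification checks run before any fit."""
        if self.df < 0:
            raise IdentificationError(
                f"model not identified: {self.n_free} free parameters for "
                f"{len(self.manifest) * (len(self.manifest) + 1) // 2} moments "
                f"(df = {self.df})"
            )
        for f in self.factors:
            var_cells = [c for c in self.cells if c.matrix == "S"
                         and c.row == f and c.col == f]
            anchored = any(not c.free or c.expr is not None for c in var_cells)
            loading_anchor = any(
                c.matrix == "A" and c.col == f and not c.free and c.value != 0
                for c in self.cells
            )
            incoming = any(c.matrix == "A" and c.row == f for c in self.cells)
            if not (anchored or loading_anchor or incoming):
                raise IdentificationError(
                    f"factor {f!r} is unanchored: fix its variance to 1 or "
                    "one loading to a nonzero constant"
                )
        names = set(self.variables)
        for c in self.cells:
            if c.row not in names or c.col not in names:
                raise ValueError(f"cell references unknown variable: {c}")

    # ------------------------------------------------------------------
    # matrix assembly
    # ------------------------------------------------------------------
    def _index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    def build_matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, S) for a free-parameter vector ``theta``."""
        labels = self.free_labels()
        if len(theta) != len(labels):
            raise ValueError(
                f"parameter vector length {len(theta)} != "
                f"{len(labels)} free parameters"
            )
        values = dict(zip(labels, np.asarray(theta, dtype=float)))
        idx = self._index()
        k = len(idx)
        A = np.zeros((k, k))
        S = np.zeros((k, k))
        ns = {"sqrt": math.sqrt, "abs": abs}
        for c in self.cells:
            if c.expr is not None:
                v = float(eval(c.expr, {"__builtins__": {}}, {**ns, **values}))
            elif c.free:
                v = values[c.label]
            else:
                v = c.value
            i, j = idx[c.row], idx[c.col]
            if c.matrix == "A":
                A[i, j] = v
            else:
                S[i, j] = v
                S[j, i] = v
        return A, S

    def has_expr(self) -> bool:
        return any(c.expr is not None for c in self.cells)

    def defined_values(self, estimates: dict[str, float]) -> dict[str, float]:
        out = {}
        for name, expr in self.defined.items():
            out[name] = float(eval(expr, {"__builtins__": {}}, dict(estimates)))
        return out


def implied_covariance(spec: FactorModelSpec, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance of the manifest variables.

    For a pure CFA this is the familiar ``Lambda Psi Lambda^T + Theta``.
    """
    A, S = spec.build_matrices(theta)
    k = A.shape[0]
    B = np.linalg.solve(np.eye(k) - A, np.eye(k))
    V = B @ S @ B.T
    p = len(spec.manifest)
    return V[:p, :p]


def _fml(Sigma: np.ndarray, S_samp: np.ndarray, logdet_S: float) -> float:
    p = S_samp.shape[0]
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    try:
        tr = float(np.trace(np.linalg.solve(Sigma, S_samp)))
    except np.linalg.LinAlgError:
        return np.inf
    return logdet + tr - logdet_S - p


@dataclass
class FitResult:
    """Estimates, fit statistics and diagnostics from one ML fit."""

    spec: FactorModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    fml: float
    statistic: float          # T = (n-1) * F_ML
    df: int
    baseline_statistic: float
    baseline_df: int
    n: int
    converged: bool
    admissible: bool
    sample_cov: np.ndarray
    implied_cov: np.ndarray
    indices: dict[str, float | None] = field(default_factory=dict)
    defined: dict[str, float] = field(default_factory=dict)
    standardized: "pd.DataFrame | None" = None
    n_restarts_converged: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.estimates[l] for l in self.spec.free_labels()])

    def parameter_table(self) -> pd.DataFrame:
        if self.standardized is not None:
            return self.standardized
        rows = []
        for c in self.spec.cells:
            est = (self.estimates[c.label] if c.free and c.expr is None
                   else c.value)
            rows.append({"matrix": c.matrix, "row": c.row, "col": c.col,
                         "label": c.label, "est": est,
                         "se": self.se.get(c.label, np.nan)})
        return pd.DataFrame(rows)

    def std_lookup(self, matrix: str, row: str, col: str) -> float:
        tab = self.standardized
        if tab is None:
            raise ValueError("call standardize() first")
        m = tab[(tab.matrix == matrix) & (tab.row == row) & (tab.col == col)]
        if m.empty:
            m = tab[(tab.matrix == matrix) & (tab.row == col) & (tab.col == row)]
        if m.empty:
            raise KeyError((matrix, row, col))
        return float(m.iloc[0]["std_est"])

    def loading(self, item: str, factor: str) -> float:
        """Standardised loading of ``item`` on ``factor``."""
        return self.std_lookup("A", item, factor)

    def factor_correlation(self, f1: str, f2: str) -> float:
        return self.std_lookup("S", f1, f2)


def _gradient(spec: FactorModelSpec, theta: np.ndarray,
              S_samp: np.ndarray, logdet_S: float) -> np.ndarray:
    """Analytic gradient of F_ML; valid only for expr-free specs."""
    A, S = spec.build_matrices(theta)
    k = A.shape[0]
    p = S_samp.shape[0]
    B = np.linalg.solve(np.eye(k) - A, np.eye(k))
    V = B @ S @ B.T
    Sigma = V[:p, :p]
    Sigma_inv = np.linalg.inv(Sigma)
    W = Sigma_inv - Sigma_inv @ S_samp @ Sigma_inv  # dF/dSigma (symmetric)
    Wfull = np.zeros((k, k))
    Wfull[:p, :p] = W
    H = B.T @ Wfull @ B            # for S-cells
    G = (B @ S @ B.T) @ Wfull @ B  # for A-cells (note: V @ Wfull @ B)
    idx = spec._index()
    labels = spec.free_labels()
    pos = {l: i for i, l in enumerate(labels)}
    grad = np.zeros(len(labels))
    for c in spec.cells:
        if not c.free or c.expr is not None:
            continue
        i, j = idx[c.row], idx[c.col]
        if c.matrix == "A":
            g = 2.0 * G[j, i]
        else:
            g = H[i, j] if i == j else 2.0 * H[i, j]
        grad[pos[c.label]] += g
    return grad


def _check_sample_cov(S_samp: np.ndarray, names: list[str]) -> float:
    S_samp = np.asarray(S_samp, dtype=float)
    if S_samp.shape != (len(names), len(names)):
        raise ValueError("sample covariance does not match manifest variables")
    if not np.allclose(S_samp, S_samp.T, atol=1e-10):
        raise ValueError("sample covariance is not symmetric")
    evals = np.linalg.eigvalsh(S_samp)
    if evals[0] <= 0:
        raise ValueError(
            f"sample covariance not positive definite "
            f"(smallest eigenvalue {evals[0]:.3e})"
        )
    sign, logdet = np.linalg.slogdet(S_samp)
    return logdet


def baseline_statistic(S_samp: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-model statistic T0 and df0 for incremental fit indices."""
    p = S_samp.shape[0]
    logdet_S = np.linalg.slogdet(S_samp)[1]
    f0 = float(np.sum(np.log(np.diag(S_samp))) - logdet_S)
    return (n - 1) * max(f0, 0.0), p * (p - 1) // 2


def fit_indices(T: float, df: int, T0: float, df0: int, n: int,
                S: np.ndarray | None = None,
                Sigma: np.ndarray | None = None) -> dict[str, float | None]:
    """CFI, TLI, RMSEA and SRMR from chi-square-type statistics.

    df = 0 leaves RMSEA and TLI undefined (None), never silently zero.
    CFI is capped to [0, 1]; TLI is reported uncapped.
    """
    if df < 0 or df0 < df or T < 0 or T0 < 0:
        raise ValueError("require T, T0 >= 0 and df0 >= df >= 0")
    num = max(T - df, 0.0)
    den = max(T0 - df0, T - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    cfi = min(max(cfi, 0.0), 1.0)
    if df == 0 or df0 == 0:
        tli = None
        rmsea = None if df == 0 else 0.0
    else:
        ratio0 = T0 / df0
        tli = (ratio0 - T / df) / (ratio0 - 1.0) if ratio0 != 1.0 else None
        rmsea = math.sqrt(max(T - df, 0.0) / (df * (n - 1)))
    srmr = None
    if S is not None and Sigma is not None:
        d = 1.0 / np.sqrt(np.diag(S))
        R = (S - Sigma) * np.outer(d, d)
        iu = np.tril_indices_from(R)
        srmr = float(np.sqrt(np.mean(R[iu] ** 2)))
    return {"cfi": cfi, "tli": tli, "rmsea": rmsea, "srmr": srmr}


def fit_ml(spec: FactorModelSpec, S_samp: np.ndarray, n: int, *,
           n_restarts: int = 5, seed: int = 0, tol: float = 1e-10,
           compute_se: bool = True) -> FitResult:
    """Fit a spec to a sample covariance by normal-theory ML.

    Runs ``n_restarts`` quasi-Newton starts (the declared start values
    plus jittered versions); restarts are ranked by discrepancy, ties
    broken by restart order.  Raises on non-PD input or a non-identified
    spec; non-convergence of every restart raises ``ConvergenceError``.
    """
    spec.validate()
    names = spec.manifest
    if n <= len(names):
        raise ValueError(f"n = {n} too small for {len(names)} variables")
    logdet_S = _check_sample_cov(S_samp, names)
    S_samp = np.asarray(S_samp, dtype=float)
    labels = spec.free_labels()
    use_grad = not spec.has_expr()

    def objective(theta):
        Sigma = implied_covariance(spec, theta)
        return _fml(Sigma, S_samp, logdet_S)

    grad = (lambda th: _gradient(spec, th, S_samp, logdet_S)) if use_grad else None

    bounds = _bounds(spec)
    rng = np.random.default_rng(seed)
    x0 = spec.start_vector()
    best = None
    n_conv = 0
    for r in range(max(n_restarts, 1)):
        start = x0 if r == 0 else x0 + rng.normal(0, 0.1, size=len(x0))
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                objective, start, jac=grad, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 2000, "ftol": tol, "gtol": 1e-9},
            )
        if not np.isfinite(res.fun):
            continue
        if res.success:
            n_conv += 1
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("all optimisation restarts failed")

    theta = best.x
    estimates = dict(zip(labels, theta))
    Sigma = implied_covariance(spec, theta)
    fml = max(float(best.fun), 0.0)
    T = max((n - 1) * fml, 0.0)
    T0, df0 = baseline_statistic(S_samp, n)
    df = spec.df

    admissible = _admissible(spec, theta)
    se = {}
    if compute_se:
        se = _information_se(spec, theta, S_samp, logdet_S, n, bounds)

    fit = FitResult(
        spec=spec, estimates=estimates, se=se, fml=fml, statistic=T, df=df,
        baseline_statistic=T0, baseline_df=df0, n=n,
        converged=n_conv > 0 or bool(best.success), admissible=admissible,
        sample_cov=S_samp, implied_cov=Sigma,
        n_restarts_converged=n_conv,
    )
    fit.indices = fit_indices(T, df, T0, df0, n, S=S_samp, Sigma=Sigma)
    fit.defined = spec.defined_values(estimates)
    if admissible:
        fit.standardized = standardize(fit)
    return fit


def _bounds(spec: FactorModelSpec) -> list[tuple[float, float]]:
    lo = {}
    for c in spec.cells:
        if not c.free or c.expr is not None:
            continue
        is_var = c.matrix == "S" and c.row == c.col
        b = (1e-8, np.inf) if is_var else (-np.inf, np.inf)
        prev = lo.get(c.label)
        lo[c.label] = b if prev is None else (max(prev[0], b[0]), min(prev[1], b[1]))
    return [lo[l] for l in spec.free_labels()]


def _admissible(spec: FactorModelSpec, theta: np.ndarray) -> bool:
    A, S = spec.build_matrices(theta)
    if np.any(np.diag(S) < -1e-8):
        return False
    k = A.shape[0]
    B = np.linalg.solve(np.eye(k) - A, np.eye(k))
    V = B @ S @ B.T
    return bool(np.all(np.diag(V) > 1e-10))


def _information_se(spec, theta, S_samp, logdet_S, n, bounds):
    """SEs from the numerically differentiated observed information.

    acov(theta) = (2 / (n-1)) H^{-1} where H is the Hessian of F_ML.
    """
    labels = spec.free_labels()
    k = len(labels)
    h = 1e-5

    def f(th):
        return _fml(implied_covariance(spec, th), S_samp, logdet_S)

    H = np.zeros((k, k))
    f0 = f(theta)
    steps = np.full(k, h)
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        e = np.zeros(k); e[i] = steps[i]
        fp[i], fm[i] = f(theta + e), f(theta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            e_i = np.zeros(k); e_i[i] = steps[i]
            e_j = np.zeros(k); e_j[j] = steps[j]
            fpp = f(theta + e_i + e_j)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + f0
            ) / (steps[i] * steps[j])
    try:
        acov = 2.0 / (n - 1) * np.linalg.pinv(H)
        d = np.diag(acov).copy()
        d[d < 0] = np.nan
        return dict(zip(labels, np.sqrt(d)))
    except np.linalg.LinAlgError:
        return {l: np.nan for l in labels}


def standardize(fit: FitResult) -> pd.DataFrame:
    """Standardised solution: every path rescaled by implied SDs.

    Loadings and regressions are multiplied by sd(source)/sd(target);
    (co)variances are rescaled to correlations of residuals/disturbances
    against total variable SDs, so exogenous factor covariances become
    correlations with unit diagonal.
    """
    if not fit.admissible:
        raise ValueError("standardised solution requires an admissible fit")
    spec = fit.spec
    A, S = spec.build_matrices(fit.theta)
    k = A.shape[0]
    B = np.linalg.solve(np.eye(k) - A, np.eye(k))
    V = B @ S @ B.T
    sd = np.sqrt(np.diag(V))
    if np.any(sd <= 0):
        raise ValueError("zero implied variance; cannot standardise")
    idx = spec._index()
    rows = []
    for c in spec.cells:
        i, j = idx[c.row], idx[c.col]
        if c.free and c.expr is None:
            est = fit.estimates[c.label]
        else:
            est = (A if c.matrix == "A" else S)[i, j]
        if c.matrix == "A":
            std = est * sd[j] / sd[i]
        else:
            std = est / (sd[i] * sd[j])
        rows.append({"matrix": c.matrix, "row": c.row, "col": c.col,
                     "label": c.label, "est": est,
                     "se": fit.se.get(c.label, np.nan), "std_est": std})
    return pd.DataFrame(rows)


def bootstrap_se(data: pd.DataFrame, spec: FactorModelSpec, B: int,
                 seed: int, *, n_restarts: int = 1,
                 max_nonconvergence: float = 0.5
                 ) -> tuple[dict[str, float], pd.DataFrame]:
    """Nonparametric case-resampling bootstrap SEs.

    ``data`` holds one column per manifest variable; rows are resampled
    with replacement, the covariance recomputed and the model refitted.
    Returns (SE dict, replicate-estimate DataFrame with percentile CIs
    obtainable from its quantiles).  Fails if more than
    ``max_nonconvergence`` of replicates do not converge.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    spec.validate()
    cols = spec.manifest
    X = data[cols].to_numpy(dtype=float)
    n = X.shape[0]
    if n <= len(cols):
        raise ValueError(f"cohort of n = {n} too small to bootstrap")
    rng = np.random.default_rng(seed)
    reps = []
    failed = 0
    for b in range(B):
        take = rng.integers(0, n, size=n)
        Xb = X[take]
        Sb = np.cov(Xb, rowvar=False, ddof=1)
        try:
            fb = fit_ml(spec, Sb, n, n_restarts=n_restarts,
                        seed=int(rng.integers(2**31)), compute_se=False)
        except (ValueError, ConvergenceError, np.linalg.LinAlgError):
            failed += 1
            continue
        if not fb.converged:
            failed += 1
            continue
        reps.append(fb.estimates)
    if failed > max_nonconvergence * B:
        raise ConvergenceError(
            f"{failed}/{B} bootstrap replicates failed to converge"
        )
    tab = pd.DataFrame(reps)
    se = {l: float(tab[l].std(ddof=1)) for l in tab.columns}
    return se, tab
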