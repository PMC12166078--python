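"""Synthetic cohort, genotype and summary-statistic generation.

Emulates the statistical structure of a longitudinal birth cohort in
which preschool musicality items (3-category parent reports), school-age
communication subscales and cognition scores load on correlated latent
factors, a standardised polygenic score exerts small effects on the
factors, covariates (sex, age, ancestry principal components) can be
layered on, and each measure has its own missingness rate.  All draws
are governed by explicit seeds, so every generated object is
reproducible byte for byte.

The generating model per measure y is

    y = lambda * F + (covariate effects) + e,   Var(lambda*F + e) = 1

with factors F multivariate normal (optionally F = a * PGS + d so a
standardised score explains a^2 of factor variance) and ordinal items
obtained by thresholding the unit-variance latent response at normal
quantiles of the target category probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import presets

N_PCS = 10
COVARIATE_COLS = ["sex", "age"] + [f"PC{i}" for i in range(1, N_PCS + 1)]
_UNAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                      ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


class SimulationError(ValueError):
    pass


def _check_correlation(R: np.ndarray, what: str) -> None:
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise SimulationError(f"{what} must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise SimulationError(f"{what} must have unit diagonal")
    evals = np.linalg.eigvalsh(R)
    if evals[0] < -1e-10:
        raise SimulationError(
            f"{what} is not positive semi-definite "
            f"(smallest eigenvalue {evals[0]:.3e})"
        )


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    ``loading_matrix`` maps measure -> (factor, standardised loading);
    ``ordinal_specs`` maps the ordinal measures to their 3 category
    probabilities; ``pgs_paths`` maps factor -> standardised PGS effect
    (a-path); ``covariate_effects`` maps measure -> {covariate: beta}.
    """

    n_individuals: int
    factor_names: list[str]
    loading_matrix: dict[str, tuple[str, float]]
    factor_correlations: np.ndarray
    ordinal_specs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    pgs_paths: dict[str, float] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    measure_roles: dict[str, str] = field(default_factory=dict)  # predictor|outcome

    def __post_init__(self) -> None:
        self.factor_correlations = np.asarray(self.factor_correlations, float)
        _check_correlation(self.factor_correlations, "factor_correlations")
        if self.factor_correlations.shape != (len(self.factor_names),) * 2:
            raise SimulationError("factor_correlations shape does not match "
                                  "factor_names")
        for m, (f, lam) in self.loading_matrix.items():
            if f not in self.factor_names:
                raise SimulationError(f"measure {m!r} loads on unknown factor {f!r}")
            if not -1.0 <= lam <= 1.0:
                raise SimulationError(f"loading for {m!r} outside [-1, 1]")
            a = self.pgs_paths.get(f, 0.0)
            if lam ** 2 > 1.0 + 1e-12 or a ** 2 > 1.0:
                raise SimulationError(f"communality for {m!r} exceeds 1")
        for m, probs in self.ordinal_specs.items():
            if abs(sum(probs) - 1.0) > 1e-8:
                raise SimulationError(f"category probabilities for {m!r} "
                                      "do not sum to 1")
        for m, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise SimulationError(f"missing rate for {m!r} outside [0, 1)")

    @property
    def measures(self) -> list[str]:
        return list(self.loading_matrix)


@dataclass
class CohortTable:
    """Individuals x measures plus covariates and measure metadata."""

    data: pd.DataFrame           # individual_id index; measures + covariates
    metadata: pd.DataFrame       # index measure; role, scale, instrument

    @property
    def measures(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def measure_frame(self) -> pd.DataFrame:
        return self.data[self.measures]

    def covariate_frame(self) -> pd.DataFrame:
        cols = [c for c in COVARIATE_COLS if c in self.data.columns]
        return self.data[cols]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with per-SNP allele info."""

    dosages: pd.DataFrame        # individual_id index, snp_id columns
    snps: pd.DataFrame           # index snp_id; chr, bp, effect_allele,
                                 # other_allele, maf

    def __post_init__(self) -> None:
        if self.snps.index.duplicated().any():
            raise SimulationError("duplicate snp_id in genotype matrix")
        d = self.dosages.to_numpy()
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise SimulationError("dosages outside [0, 2]")


def default_config(n_individuals: int = presets.STAGE3_N,
                   pgs_paths: dict[str, float] | None = None) -> SimConfig:
    """The confirmed three-factor parameterisation as a generating model.

    Preschool musicality items are ordinal with the descriptive category
    frequencies of the source cohort; communication and cognition
    outcomes are continuous.
    """
    loadings = {}
    roles = {}
    for factor, items in presets.STAGE3_LOADINGS.items():
        for item, lam in items.items():
            loadings[item] = (factor, lam)
            roles[item] = "predictor" if factor == "musicality" else "outcome"
    names = list(presets.STAGE3_LOADINGS)
    R = np.eye(3)
    for (f1, f2), r in presets.STAGE3_FACTOR_CORRELATIONS.items():
        i, j = names.index(f1), names.index(f2)
        R[i, j] = R[j, i] = r
    ordinal = {m: presets.category_probs(m)
               for m in presets.PRESCHOOL_CATEGORY_COUNTS}
    return SimConfig(
        n_individuals=n_individuals,
        factor_names=names,
        loading_matrix=loadings,
        factor_correlations=R,
        ordinal_specs=ordinal,
        pgs_paths=pgs_paths or {},
        measure_roles=roles,
    )


def ordinalize(latent: np.ndarray,
               category_probs: tuple[float, float, float]) -> np.ndarray:
    """Threshold a unit-variance latent response into categories 1/2/3.

    Thresholds sit at standard-normal quantiles of the cumulative
    probabilities, so empirical frequencies converge to the target
    probabilities.  A zero-probability middle category collapses the
    scale to two levels (warned, still valid).
    """
    p1, p2, p3 = category_probs
    if abs(p1 + p2 + p3 - 1.0) > 1e-8:
        raise SimulationError("category probabilities must sum to 1")
    if p2 == 0:
        warnings.warn("middle category has probability 0; item collapses "
                      "to 2 levels", stacklevel=2)
    t1 = stats.norm.ppf(p1) if p1 > 0 else -np.inf
    t2 = stats.norm.ppf(p1 + p2) if p1 + p2 < 1 else np.inf
    x = np.asarray(latent, dtype=float)
    out = np.ones(x.shape, dtype=float)
    out[x > t1] = 2
    out[x > t2] = 3
    # p1 == 0 means nothing stays in category 1
    if p1 == 0:
        out[out == 1] = 2
    out[np.isnan(x)] = np.nan
    return out


def generate_cohort(config: SimConfig, seed: int,
                    pgs: np.ndarray | None = None) -> CohortTable:
    """Draw a cohort from the latent-factor generating model.

    Factor scores are multivariate normal with the configured
    correlations; when PGS paths are set, each factor is a * PGS plus a
    disturbance, with disturbance covariances chosen so total factor
    correlations still match the configuration.  Each measure is
    lambda * factor + covariate effects + scaled Gaussian residual
    (unit total variance before covariate effects and ordinalisation).
    """
    rng = np.random.default_rng(seed)
    n = config.n_individuals
    k = len(config.factor_names)
    a = np.array([config.pgs_paths.get(f, 0.0) for f in config.factor_names])

    if pgs is None:
        pgs = rng.standard_normal(n)
    else:
        pgs = np.asarray(pgs, dtype=float)
        if len(pgs) != n:
            raise SimulationError("pgs vector length does not match cohort")

    # disturbance covariance so that total factor correlations are honoured
    D = config.factor_correlations - np.outer(a, a)
    evals = np.linalg.eigvalsh(D)
    if evals[0] < -1e-10:
        raise SimulationError(
            "factor disturbance covariance not PSD given PGS paths "
            f"(smallest eigenvalue {evals[0]:.3e})"
        )
    L = np.linalg.cholesky(D + 1e-12 * np.eye(k))
    disturb = rng.standard_normal((n, k)) @ L.T
    F = pgs[:, None] * a[None, :] + disturb

    covars = pd.DataFrame({
        "sex": rng.integers(0, 2, size=n).astype(float),
        "age": rng.normal(4.78, 0.07, size=n),
    })
    for i in range(1, N_PCS + 1):
        covars[f"PC{i}"] = rng.standard_normal(n)

    fidx = {f: i for i, f in enumerate(config.factor_names)}
    data = {}
    meta_rows = []
    for m, (f, lam) in config.loading_matrix.items():
        resid_var = 1.0 - lam ** 2
        y = lam * F[:, fidx[f]] + rng.normal(0, np.sqrt(resid_var), size=n)
        for cov_name, beta in config.covariate_effects.get(m, {}).items():
            y = y + beta * covars[cov_name].to_numpy()
        scale = "continuous"
        if m in config.ordinal_specs:
            y = ordinalize(y, config.ordinal_specs[m])
            scale = "ordinal"
        data[m] = y
        meta_rows.append({
            "measure": m,
            "role": config.measure_roles.get(m, "outcome"),
            "scale": scale,
            "factor": f,
            "loading": lam,
            "composite": False,
        })

    df = pd.DataFrame(data)
    df = pd.concat([df, covars], axis=1)
    df["pgs_true"] = pgs
    df.index = pd.RangeIndex(n, name="individual_id")
    meta = pd.DataFrame(meta_rows).set_index("measure")
    cohort = CohortTable(data=df, metadata=meta)
    if config.missing_rates:
        cohort = apply_missingness(cohort, config.missing_rates,
                                   seed=int(rng.integers(2**31)))
    return cohort


def apply_missingness(cohort: CohortTable, missing_rates: dict[str, float],
                      seed: int) -> CohortTable:
    """Mask each measure completely at random at its configured rate."""
    for m, r in missing_rates.items():
        if not 0.0 <= r < 1.0:
            raise SimulationError(f"missing rate for {m!r} outside [0, 1)")
    rng = np.random.default_rng(seed)
    df = cohort.data.copy()
    for m, r in missing_rates.items():
        if r == 0.0 or m not in df.columns:
            continue
        mask = rng.random(len(df)) < r
        df.loc[mask, m] = np.nan
    return CohortTable(data=df, metadata=cohort.metadata.copy())


def generate_genotypes_pgs(
    n: int, n_snps: int, target_incremental_r2: float, seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Simulate linkage-equilibrium genotypes and a calibrated score.

    Dosages are Binomial(2, maf); per-SNP weights are rescaled so the
    raw score variance equals ``target_incremental_r2``, hence pairing
    the Z-standardised score with a factor built as
    ``sqrt(r2) * score + noise`` yields the target incremental R^2 in
    expectation.  Returns (GenotypeMatrix, weight table in 6-column
    CHR/SNP/BP/A1/A2/BETA layout, Z-standardised score).
    """
    if n_snps < 1:
        raise SimulationError("n_snps must be >= 1: no score definable")
    if not 0.0 <= target_incremental_r2 < 1.0:
        raise SimulationError("target incremental R2 must be in [0, 1)")
    lo, hi = maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise SimulationError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, maf, size=(n, n_snps)).astype(float)
    snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), size=n_snps)
    a1 = np.array([_UNAMBIGUOUS_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_UNAMBIGUOUS_PAIRS[i][1] for i in pair_idx])

    w = rng.standard_normal(n_snps)
    gvar = 2.0 * maf * (1.0 - maf)
    raw_var = float(np.sum(w ** 2 * gvar))
    if raw_var <= 0:
        raise SimulationError("degenerate weights: zero raw score variance")
    if target_incremental_r2 > 0:
        w = w * np.sqrt(target_incremental_r2 / raw_var)

    geno = GenotypeMatrix(
        dosages=pd.DataFrame(dosages, columns=snp_ids,
                             index=pd.RangeIndex(n, name="individual_id")),
        snps=pd.DataFrame({
            "chr": rng.integers(1, 23, size=n_snps),
            "bp": np.arange(1, n_snps + 1) * 1000,
            "effect_allele": a1, "other_allele": a2, "maf": maf,
        }, index=pd.Index(snp_ids, name="snp_id")),
    )
    weights = pd.DataFrame({
        "CHR": geno.snps["chr"].to_numpy(), "SNP": snp_ids,
        "BP": geno.snps["bp"].to_numpy(), "A1": a1, "A2": a2, "BETA": w,
    })
    raw = dosages @ w
    sd = raw.std(ddof=1)
    if sd <= 1e-12:
        raise SimulationError("degenerate score: zero variance, cannot "
                              "Z-standardise")
    score = (raw - raw.mean()) / sd
    return geno, weights, score


def generate_sumstats_pair(
    n_snps: int, genetic_cov: np.ndarray, seed: int,
    n_confounder: int = 100_000, n_trait: int = 100_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired GWAS summary statistics with a known effect covariance.

    Per-SNP standardised effects for (confounder, focal trait) are drawn
    bivariate normal with across-SNP covariance ``genetic_cov``; SEs
    follow the standardised-trait formula 1/sqrt(2 p (1-p) N).  Both
    tables share SNP ids and alleles, i.e. arrive pre-harmonised.
    """
    S = np.asarray(genetic_cov, dtype=float)
    if S.shape != (2, 2) or not np.allclose(S, S.T):
        raise SimulationError("genetic_cov must be symmetric 2x2")
    if np.linalg.eigvalsh(S)[0] < -1e-12:
        raise SimulationError("genetic_cov must be positive semi-definite")
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    maf = rng.uniform(lo, hi, size=n_snps)
    L = np.linalg.cholesky(S + 1e-14 * np.eye(2))
    betas = rng.standard_normal((n_snps, 2)) @ L.T
    snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), size=n_snps)
    a1 = [_UNAMBIGUOUS_PAIRS[i][0] for i in pair_idx]
    a2 = [_UNAMBIGUOUS_PAIRS[i][1] for i in pair_idx]

    def table(col: int, n_gwas: int) -> pd.DataFrame:
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_gwas)
        return pd.DataFrame({
            "SNP": snp_ids, "A1": a1, "A2": a2, "FRQ": maf,
            "BETA": betas[:, col], "SE": se,
            "N": np.full(n_snps, n_gwas),
        })

    return table(0, n_confounder), table(1, n_trait)
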