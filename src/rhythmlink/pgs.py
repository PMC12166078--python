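"""Polygenic scoring and GWAS-by-subtraction.

A polygenic score is the weighted sum of effect-allele dosages over the
SNPs shared between a weight table and the genotype panel, after allele
harmonisation (sign flips for swapped alleles, removal of strand-
ambiguous A/T and C/G variants), Z-standardised across individuals.

GWAS-by-subtraction removes the genetic component a focal trait shares
with a confounder trait (here educational attainment) from its summary
statistics.  Given the 2x2 genetic covariance S (confounder first) and
its Cholesky factor L (S = L L^T), the confounder loads on latent 1
with l11 and the focal trait loads on latent 1 (l21) and latent 2
(l22).  Per SNP the latent effects solve

    b1 = beta_conf / l11
    b2 = (beta_trait - l21 * b1) / l22

and the subtracted effect is l22 * b2 = beta_trait - (l21/l11) *
beta_conf, with the SE propagated by the delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizeReport:
    n_shared: int
    n_flipped: int
    n_ambiguous_removed: int
    n_mismatch_removed: int


def harmonize(a: pd.DataFrame, b: pd.DataFrame,
              effect_col: str = "BETA"
              ) -> tuple[pd.DataFrame, pd.DataFrame, HarmonizeReport]:
    """Align two SNP tables on shared ids and effect alleles.

    Both tables need SNP/A1/A2 plus an effect column; ``b`` is flipped
    (effect sign, FRQ -> 1-FRQ if present) where its alleles are swapped
    relative to ``a``.  Strand-ambiguous (A/T, C/G) and unresolvable
    allele pairs are removed and counted.
    """
    shared = a[a["SNP"].isin(set(b["SNP"]))].copy()
    if shared.empty:
        raise ValueError("no shared SNPs between the two tables")
    a_idx = shared.set_index("SNP")
    b_idx = b.set_index("SNP").loc[a_idx.index].copy()

    amb = np.array([_is_ambiguous(x, y)
                    for x, y in zip(a_idx["A1"], a_idx["A2"])])
    # an unknown other allele ('N', e.g. from a .raw export) matches
    # anything; the effect allele still decides orientation
    b_a2_known = b_idx["A2"].values != "N"
    same = (a_idx["A1"].values == b_idx["A1"].values) & \
           ((a_idx["A2"].values == b_idx["A2"].values) | ~b_a2_known)
    swapped = ~same & (a_idx["A1"].values == b_idx["A2"].values) & \
              (a_idx["A2"].values == b_idx["A1"].values)
    swapped |= (~b_a2_known & ~same &
                (a_idx["A2"].values == b_idx["A1"].values))
    keep = ~amb & (same | swapped)

    flip = swapped & keep
    b_idx.loc[flip, effect_col] = -b_idx.loc[flip, effect_col]
    if "FRQ" in b_idx.columns:
        b_idx.loc[flip, "FRQ"] = 1.0 - b_idx.loc[flip, "FRQ"]
    b_idx.loc[flip, ["A1", "A2"]] = b_idx.loc[flip, ["A2", "A1"]].values

    report = HarmonizeReport(
        n_shared=int(keep.sum()), n_flipped=int(flip.sum()),
        n_ambiguous_removed=int(amb.sum()),
        n_mismatch_removed=int((~amb & ~(same | swapped)).sum()),
    )
    log.info("harmonise: %s", report)
    if report.n_shared == 0:
        raise ValueError("no SNPs left after harmonisation")
    return (a_idx[keep].reset_index(), b_idx[keep].reset_index(), report)


def score(genotypes: GenotypeMatrix, weights: pd.DataFrame,
          standardise: bool = True) -> pd.Series:
    """Per-individual polygenic score from a CHR/SNP/BP/A1/A2/BETA table.

    Genotype allele coding is harmonised to the weight table's effect
    allele; missing dosages are mean-imputed to 2*MAF per SNP.
    """
    geno_tab = genotypes.snps.reset_index().rename(columns={
        "snp_id": "SNP", "effect_allele": "A1", "other_allele": "A2"})
    geno_tab["BETA"] = 0.0
    w_al, g_al, report = harmonize(weights, geno_tab)
    snps = g_al["SNP"].tolist()
    D = genotypes.dosages[snps].to_numpy(dtype=float).copy()
    # flip dosage where the genotype effect allele was swapped relative
    # to the weight table (harmonize flipped the zero-beta side; detect
    # by comparing alleles)
    flipped = (g_al["A1"].values !=
               genotypes.snps.loc[snps, "effect_allele"].values)
    D[:, flipped] = 2.0 - D[:, flipped]
    maf = genotypes.snps.loc[snps, "maf"].to_numpy(dtype=float)
    fill = 2.0 * np.where(flipped, 1.0 - maf, maf)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D = np.where(nan_mask, np.broadcast_to(fill, D.shape), D)
    raw = D @ w_al["BETA"].to_numpy(dtype=float)
    s = pd.Series(raw, index=genotypes.dosages.index, name="pgs")
    if standardise:
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd <= 1e-12:
            raise ValueError("zero-variance raw score; cannot Z-standardise")
        s = (s - s.mean()) / sd
    return s


def subtract_cholesky(S_genetic: np.ndarray, ss_confounder: pd.DataFrame,
                      ss_trait: pd.DataFrame,
                      effective_n_value: float | None = None
                      ) -> pd.DataFrame:
    """Subtract the confounder-shared genetic component from a trait GWAS.

    ``S_genetic`` is the 2x2 genetic covariance with the confounder
    trait first.  Inputs must already be harmonised (shared SNPs,
    matching alleles); use :func:`harmonize` first otherwise.  Returns a
    summary-statistics table for the subtracted trait with delta-method
    SEs; N is set to ``effective_n_value`` when given.
    """
    S = np.asarray(S_genetic, dtype=float)
    if S.shape != (2, 2) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S_genetic must be symmetric 2x2")
    evals = np.linalg.eigvalsh(S)
    if evals[0] < -1e-12:
        raise ValueError("S_genetic must be positive semi-definite")
    # the subtraction only needs the shared-path ratio l21/l11 = S12/S11;
    # a vanishing l22 (trait fully explained by the confounder) merely
    # sends every subtracted beta to ~0 and is legitimate here, unlike in
    # latent_effects where it would divide by zero
    l11 = np.sqrt(S[0, 0])
    l21 = S[0, 1] / l11
    c = ss_confounder.set_index("SNP")
    t = ss_trait.set_index("SNP")
    if not c.index.equals(t.index):
        raise ValueError("summary statistics are not harmonised "
                         "(SNP sets differ); run harmonize() first")
    if not (c["A1"].values == t["A1"].values).all():
        raise ValueError("effect alleles differ; run harmonize() first")
    ratio = l21 / l11
    beta_sub = t["BETA"].to_numpy() - ratio * c["BETA"].to_numpy()
    se_sub = np.sqrt(t["SE"].to_numpy() ** 2 +
                     ratio ** 2 * c["SE"].to_numpy() ** 2)
    out = t.reset_index()[["SNP", "A1", "A2", "FRQ"]].copy()
    out["BETA"] = beta_sub
    out["SE"] = se_sub
    out["N"] = (effective_n_value if effective_n_value is not None
                else t["N"].to_numpy())
    return out


def latent_effects(S_genetic: np.ndarray, beta_conf: np.ndarray,
                   beta_trait: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP latent-path effects (b1, b2) of the Cholesky model.

    Satisfies the reconstruction identity
    ``l21 * b1 + l22 * b2 == beta_trait`` exactly.  Raises when the
    focal trait is fully explained by the confounder (l22 ~ 0).
    """
    S = np.asarray(S_genetic, float)
    if S[1, 1] - S[0, 1] ** 2 / S[0, 0] < 1e-10:
        raise ValueError("focal trait fully explained by confounder "
                         "(lambda_22 ~ 0); latent effects undefined")
    L = np.linalg.cholesky(S + 1e-15 * np.eye(2))
    b1 = np.asarray(beta_conf, float) / L[0, 0]
    b2 = (np.asarray(beta_trait, float) - L[1, 0] * b1) / L[1, 1]
    return b1, b2


def effective_n(ss: pd.DataFrame,
                maf_window: tuple[float, float] = (0.1, 0.4)) -> float:
    """Effective GWAS sample size for a standardised trait.

    Per SNP, N_j = 1 / (2 p_j (1 - p_j) se_j^2); the estimate is the
    mean over SNPs whose MAF falls inside ``maf_window``.
    """
    frq = ss["FRQ"].to_numpy(dtype=float)
    maf = np.minimum(frq, 1.0 - frq)
    lo, hi = maf_window
    inside = (maf >= lo) & (maf <= hi)
    if not inside.any():
        raise ValueError(f"no SNPs with MAF inside {maf_window}")
    p = frq[inside]
    se = ss["SE"].to_numpy(dtype=float)[inside]
    return float(np.mean(1.0 / (2.0 * p * (1.0 - p) * se ** 2)))


def naive_weights(ss: pd.DataFrame, h2: float = 1.0) -> pd.DataFrame:
    """LD-agnostic fallback weights from summary statistics.

    Scales raw betas so the expected score variance under linkage
    equilibrium equals ``h2``.  A stand-in for externally shrunk weight
    files in synthetic runs only; makes no attempt at LD adjustment.
    """
    frq = ss["FRQ"].to_numpy(dtype=float)
    beta = ss["BETA"].to_numpy(dtype=float)
    var = float(np.sum(beta ** 2 * 2.0 * frq * (1.0 - frq)))
    scale = np.sqrt(h2 / var) if var > 0 else 0.0
    out = pd.DataFrame({
        "CHR": ss["CHR"] if "CHR" in ss.columns else 0,
        "SNP": ss["SNP"],
        "BP": ss["BP"] if "BP" in ss.columns else 0,
        "A1": ss["A1"], "A2": ss["A2"], "BETA": beta * scale,
    })
    return out
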