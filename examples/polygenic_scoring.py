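"""Polygenic scoring and its association with an ordinal musicality item.

Simulated linkage-equilibrium genotypes and a weight table calibrated so
the Z-standardised score explains ~0.8% of a latent factor's variance;
the score-item association is quantified by incremental Nagelkerke
pseudo-R2 from proportional-odds models, the statistic used for ordinal
phenotypes throughout the pipeline.
"""

import numpy as np

from rhythmlink import simulate
from rhythmlink.pgs import score
from rhythmlink.screen import incremental_nagelkerke
from rhythmlink.simulate import COVARIATE_COLS

n = 6000
geno, weights, pgs_truth = simulate.generate_genotypes_pgs(
    n, n_snps=500, target_incremental_r2=0.008, seed=10)

pgs = score(geno, weights)  # harmonised, mean-imputed, Z-standardised
print(f"score over {geno.dosages.shape[1]} SNPs: mean {pgs.mean():.2e}, "
      f"SD {pgs.std(ddof=1):.3f}")
print(f"agreement with the generator's own score: "
      f"r = {np.corrcoef(pgs, pgs_truth)[0, 1]:.4f}")

cfg = simulate.default_config(n, pgs_paths={"musicality": np.sqrt(0.008)})
cohort = simulate.generate_cohort(cfg, seed=11, pgs=pgs.to_numpy())
data = cohort.data.copy()
data["pgs"] = pgs.to_numpy()

res = incremental_nagelkerke(data, "clap_5y", "pgs", COVARIATE_COLS)
print(f"\nPGS vs clap-to-a-beat (3 categories, n = {res.n}):")
print(f"  beta = {res.beta:.3f} (SE {res.se:.3f}), p = {res.p_value:.2e}")
print(f"  incremental Nagelkerke-R2 = {res.incremental_r2:.4f}")
print("a latent effect of 0.8% on this skewed 3-category item yields "
      "increments averaging ~0.006; single cohorts scatter roughly "
      "between 0.002 and 0.011")
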