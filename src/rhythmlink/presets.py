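"""Published model parameterisations and descriptive constants.

These are the standardised estimates of the confirmed three-factor model
linking preschool musicality (parent-reported singing, humming, clapping
at age 5) to school-age verbal cognition (nonword repetition, verbal IQ
at 9, appropriate initiation at 10) and speech-related communication
(CCC intelligibility/fluency, syntax, conversational rapport at 10), and
the ordinal category counts of the preschool musicality items.  They
serve as default generating values for the synthetic cohort and as the
canonical worked example of the pipeline.
"""

from __future__ import annotations

# standardised loadings of the confirmed three-factor model, by factor
STAGE3_LOADINGS: dict[str, dict[str, float]] = {
    "musicality": {
        "sing_5y": 0.55,
        "hum_5y": 0.74,
        "clap_5y": 0.54,
    },
    "cognition": {
        "nonword_9y": 0.61,
        "verbal_iq_9y": 0.64,
        "initiation_10y": 0.20,
    },
    "speech": {
        "intelligibility_10y": 0.55,
        "syntax_10y": 0.59,
        "rapport_10y": 0.40,
    },
}

# standardised factor correlations of the same model
STAGE3_FACTOR_CORRELATIONS: dict[tuple[str, str], float] = {
    ("musicality", "cognition"): 0.31,
    ("musicality", "speech"): 0.42,
    ("cognition", "speech"): 0.56,
}

STAGE3_N = 5873  # analysis sample of the confirmed model

# mediation-model generating paths used in the worked examples:
# a: PGS -> musicality factor, b: PGS -> outcome factor,
# c: musicality factor -> outcome factor (all standardised)
MEDIATION_PATHS = {"a": 0.09, "b": 0.06, "c": 0.45}

# ordinal category counts (lowest ability first after reverse coding is
# undone: category 1 = "has not yet done", 3 = "can do well") for the
# preschool musicality items
PRESCHOOL_CATEGORY_COUNTS: dict[str, tuple[int, int, int]] = {
    "sing_5y": (89, 358, 5596),
    "hum_5y": (241, 511, 5270),
    "clap_5y": (403, 1003, 4562),
}

# multiple-testing constants of the screening stages
N_STAGE1_TESTS = 154          # 11 predictors x 14 outcomes
N_INDEPENDENT_PHENOTYPES = 20  # spectral-decomposition estimate from 25

# calibration band for the polygenic-score incremental pseudo-R2 on
# ordinal musicality items
PGS_NAGELKERKE_BAND = (0.006, 0.011)


def stage3_spec():
    """The confirmed three-factor CFA with its published values as starts.

    Residual variances are 1 - loading^2, so the start vector is the
    standardised generating parameterisation (unit-variance measures)
    and the implied covariance at the start vector is the population
    covariance to simulate from.
    """
    from .sem import FactorModelSpec

    residuals = {item: 1.0 - lam ** 2
                 for items in STAGE3_LOADINGS.values()
                 for item, lam in items.items()}
    return FactorModelSpec.cfa(
        STAGE3_LOADINGS,
        factor_correlations=STAGE3_FACTOR_CORRELATIONS,
        residuals=residuals,
    )


def category_probs(item: str) -> tuple[float, float, float]:
    """Category probabilities of a preschool musicality item."""
    counts = PRESCHOOL_CATEGORY_COUNTS[item]
    n = sum(counts)
    return tuple(c / n for c in counts)
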