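"""Stage orchestration: run the full analysis from a YAML config.

A run directory accumulates inter-stage artefacts on disk (cohort and
genotype exports, screen tables, the chosen factor-model spec, mediation
tables) plus a manifest recording the package version, master seed,
per-stage seeds, thresholds, sample sizes and every exclusion decision.
Stages check for the artefacts they depend on and fail naming the
missing one.  All randomness derives from the single master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, presets
from .discovery import discover
from .mediation import build_mediation_spec, estimate_effects
from .pgs import effective_n, harmonize, score, subtract_cholesky
from .screen import (bonferroni, filter_predictors, incremental_nagelkerke,
                     incremental_r2, meff_spectral, residualize, screen_table)
from .sem import fit_ml
from .simulate import (COVARIATE_COLS, default_config, generate_cohort,
                       generate_genotypes_pgs, generate_sumstats_pair)

log = logging.getLogger(__name__)

STAGES = ["simulate", "screen", "discover", "pgs-assoc", "subtract",
          "mediate", "report"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": STAGES,
    "simulate": {
        "n_individuals": presets.STAGE3_N,
        "n_snps": 1000,
        "target_r2": 0.008,
        "pgs_paths": {"musicality": presets.MEDIATION_PATHS["a"],
                      "cognition": presets.MEDIATION_PATHS["b"],
                      "speech": presets.MEDIATION_PATHS["b"]},
    },
    "thresholds": {
        "retain": 0.1,
        "meaningful": 0.3,
        "alpha": 0.05,
        "min_max_r2": 0.01,
        "meff_method": "li_ji",
    },
    "subtract": {
        "n_snps": 20000,
        "genetic_cov": [[0.12, 0.02], [0.02, 0.05]],
        "n_confounder": 750000,
        "n_trait": 600000,
    },
    "bootstrap": 0,
    "mediation_se": "delta",
}


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and \
            isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """One pipeline execution rooted at ``outdir``."""

    def __init__(self, config: dict, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config["seed"])
        ss = np.random.SeedSequence(self.seed)
        self.stage_seeds = {s: int(c.generate_state(1)[0] % 2**31)
                            for s, c in zip(STAGES, ss.spawn(len(STAGES)))}
        self.manifest: dict = {
            "version": __version__, "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "thresholds": config["thresholds"],
            "stages_run": [], "exclusions": [], "n": {}, "hashes": {},
        }

    # -- helpers -------------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, name: str, stage: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"stage {stage!r} requires artefact {name!r}; run its "
                "upstream stage first"
            )
        return p

    def _record(self, *names: str) -> None:
        for name in names:
            self.manifest["hashes"][name] = _sha256(self._path(name))

    def _covariates(self, cohort) -> list[str]:
        return [c for c in COVARIATE_COLS if c in cohort.data.columns]

    # -- stages --------------------------------------------------------
    def stage_simulate(self) -> None:
        seed = self.stage_seeds["simulate"]
        sim = self.config["simulate"]
        geno, weights, pgs_vec = generate_genotypes_pgs(
            sim["n_individuals"], sim["n_snps"], sim["target_r2"], seed)
        cfg = default_config(sim["n_individuals"],
                             pgs_paths=dict(sim["pgs_paths"]))
        cohort = generate_cohort(cfg, seed=seed + 1, pgs=pgs_vec)
        io.write_cohort(cohort, self._path("cohort.tsv"))
        io.write_genotypes_raw(geno, self._path("genotypes.raw"))
        io.write_weights(weights, self._path("weights.tsv"))
        self.manifest["n"]["cohort"] = cohort.n
        self._record("cohort.tsv", "genotypes.raw", "weights.tsv")

    def stage_screen(self) -> None:
        cohort = io.read_cohort(self._require("cohort.tsv", "screen"))
        covs = self._covariates(cohort)
        meta = cohort.metadata
        predictors = [m for m in cohort.measures
                      if meta.loc[m, "role"] == "predictor"]
        outcomes = [m for m in cohort.measures
                    if meta.loc[m, "role"] == "outcome"]
        results = [incremental_r2(cohort.data, out, pred, covs)
                   for pred in predictors for out in outcomes]
        n_tests = len(results)
        thr = bonferroni(n_tests, self.config["thresholds"]["alpha"])
        tab = screen_table(results, {"bonferroni": thr})
        tab.to_csv(self._path("screen.tsv"), sep="\t", index=False)
        kept = filter_predictors(
            results, self.config["thresholds"]["min_max_r2"])
        for p in predictors:
            if p not in kept:
                self.manifest["exclusions"].append(
                    f"predictor {p} dropped: max incremental R2 below "
                    f"{self.config['thresholds']['min_max_r2']}")
        (self._path("retained_predictors.txt")).write_text(
            "\n".join(kept) + "\n")
        self.manifest["n"]["screen_tests"] = n_tests
        self.manifest["thresholds"]["bonferroni_stage1"] = thr
        self._record("screen.tsv", "retained_predictors.txt")

    def stage_discover(self) -> None:
        cohort = io.read_cohort(self._require("cohort.tsv", "discover"))
        retained_path = self._path("retained_predictors.txt")
        if retained_path.exists():
            kept = set(retained_path.read_text().split())
            drop = [m for m in cohort.measures
                    if cohort.metadata.loc[m, "role"] == "predictor"
                    and m not in kept]
            if drop:
                cohort.metadata = cohort.metadata.drop(index=drop)
                self.manifest["exclusions"].append(
                    f"predictors excluded from modelling: {drop}")
        covs = self._covariates(cohort)
        resid = residualize(cohort.data, cohort.measures, covs)
        result = discover(cohort, resid, seed=self.stage_seeds["discover"],
                          retain_threshold=self.config["thresholds"]["retain"],
                          b_boot=self.config["bootstrap"])
        io.spec_to_yaml(result.spec, self._path("model_spec.yaml"))
        result.interpretation.to_csv(self._path("cfa_table.tsv"), sep="\t",
                                     index=False)
        resid.to_csv(self._path("residualized.tsv"), sep="\t", na_rep="NA")
        fitrow = {"model": "cfa_full", "n": result.full_fit.n,
                  "statistic": result.full_fit.statistic,
                  "df": result.full_fit.df, **result.full_fit.indices}
        pd.DataFrame([fitrow]).to_csv(self._path("fit_indices.tsv"),
                                      sep="\t", index=False)
        self.manifest["n"]["cfa_full"] = result.full_fit.n
        self.manifest["chosen_rotation"] = result.chosen_rotation
        self._record("model_spec.yaml", "cfa_table.tsv", "fit_indices.tsv")

    def stage_pgs_assoc(self) -> None:
        cohort = io.read_cohort(self._require("cohort.tsv", "pgs-assoc"))
        geno = io.read_genotypes_raw(self._require("genotypes.raw",
                                                   "pgs-assoc"))
        weights = io.read_weights(self._require("weights.tsv", "pgs-assoc"))
        pgs_col = score(geno, weights)
        data = cohort.data.copy()
        data["pgs"] = pgs_col.reindex(data.index).to_numpy()
        covs = self._covariates(cohort)
        meta = cohort.metadata
        results = []
        for m in cohort.measures:
            if meta.loc[m, "scale"] == "ordinal":
                results.append(incremental_nagelkerke(data, m, "pgs", covs))
            else:
                results.append(incremental_r2(data, m, "pgs", covs))
        R = data[cohort.measures].corr(method="pearson").to_numpy()
        raw, meff = meff_spectral(
            R, self.config["thresholds"]["meff_method"])
        thr = bonferroni(meff, self.config["thresholds"]["alpha"])
        tab = screen_table(results, {"meff": thr})
        tab.to_csv(self._path("pgs_assoc.tsv"), sep="\t", index=False)
        data[["pgs"]].to_csv(self._path("pgs.tsv"), sep="\t")
        self.manifest["thresholds"]["meff_raw"] = raw
        self.manifest["thresholds"]["meff"] = meff
        self.manifest["thresholds"]["bonferroni_meff"] = thr
        self._record("pgs_assoc.tsv", "pgs.tsv")

    def stage_subtract(self) -> None:
        sub = self.config["subtract"]
        S = np.asarray(sub["genetic_cov"], dtype=float)
        ss_conf, ss_trait = generate_sumstats_pair(
            sub["n_snps"], S, seed=self.stage_seeds["subtract"],
            n_confounder=sub["n_confounder"], n_trait=sub["n_trait"])
        ss_conf, ss_trait, rep = harmonize(ss_conf, ss_trait)
        n_eff_inputs = effective_n(ss_trait)
        out = subtract_cholesky(S, ss_conf, ss_trait)
        out["N"] = round(effective_n(out))
        io.write_sumstats(out, self._path("subtracted_sumstats.tsv"))
        self.manifest["n"]["sumstats_snps"] = int(rep.n_shared)
        self.manifest["n"]["subtracted_effective_n"] = float(out["N"].iloc[0])
        self.manifest["n"]["trait_effective_n"] = float(n_eff_inputs)
        self.manifest["exclusions"].append(
            f"{rep.n_ambiguous_removed} strand-ambiguous and "
            f"{rep.n_mismatch_removed} mismatched SNPs removed in "
            "harmonisation")
        self._record("subtracted_sumstats.tsv")

    def stage_mediate(self) -> None:
        spec_path = self._require("model_spec.yaml", "mediate")
        resid_path = self._require("residualized.tsv", "mediate")
        pgs_path = self._require("pgs.tsv", "mediate")
        cfa_spec = io.spec_from_yaml(spec_path)
        resid = pd.read_csv(resid_path, sep="\t", index_col="individual_id",
                            na_values=["NA"])
        pgs_col = pd.read_csv(pgs_path, sep="\t", index_col="individual_id")

        cohort = io.read_cohort(self._path("cohort.tsv"))
        meta = cohort.metadata
        pred_factors = [f for f in cfa_spec.factors
                        if any(meta.loc[m, "role"] == "predictor"
                               for m in _factor_items(cfa_spec, f))]
        out_factors = [f for f in cfa_spec.factors if f not in pred_factors]
        if len(pred_factors) != 1:
            raise RuntimeError(
                f"expected one predictor factor, found {pred_factors}")
        data = resid.copy()
        data["pgs"] = pgs_col["pgs"].reindex(data.index).to_numpy()
        S_cols = cfa_spec.manifest
        d0 = data[S_cols].dropna()
        cfa_fit = fit_ml(cfa_spec, np.cov(d0.to_numpy(), rowvar=False, ddof=1),
                         len(d0), seed=self.stage_seeds["mediate"])
        med_spec = build_mediation_spec(cfa_spec, "pgs", pred_factors[0],
                                        out_factors)
        result = estimate_effects(
            med_spec, data, "pgs", pred_factors[0], out_factors,
            seed=self.stage_seeds["mediate"],
            se_method=self.config["mediation_se"],
            cfa_fit=cfa_fit)
        result.table().to_csv(self._path("mediation.tsv"), sep="\t",
                              index=False)
        if result.loading_shift is not None:
            result.loading_shift.to_csv(self._path("loading_shift.tsv"),
                                        sep="\t", index=False)
        fitrow = {"model": "mediation", "n": result.fit.n,
                  "statistic": result.fit.statistic, "df": result.fit.df,
                  **result.fit.indices}
        fi_path = self._path("fit_indices.tsv")
        if fi_path.exists():
            fi = pd.read_csv(fi_path, sep="\t")
            fi = pd.concat([fi, pd.DataFrame([fitrow])], ignore_index=True)
        else:
            fi = pd.DataFrame([fitrow])
        fi.to_csv(fi_path, sep="\t", index=False)
        self.manifest["n"]["mediation"] = result.fit.n
        self._record("mediation.tsv", "fit_indices.tsv")

    def stage_report(self) -> None:
        report: dict = {"tables": {}}
        for name in ["screen.tsv", "pgs_assoc.tsv", "cfa_table.tsv",
                     "mediation.tsv", "fit_indices.tsv"]:
            p = self._path(name)
            if p.exists():
                report["tables"][name] = pd.read_csv(p, sep="\t").to_dict(
                    orient="records")
        if not report["tables"]:
            raise FileNotFoundError("empty run directory: no stage outputs "
                                    "to report")
        with open(self._path("report.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        self._record("report.json")

    # -- driver --------------------------------------------------------
    def run(self) -> Path:
        dispatch = {
            "simulate": self.stage_simulate, "screen": self.stage_screen,
            "discover": self.stage_discover,
            "pgs-assoc": self.stage_pgs_assoc,
            "subtract": self.stage_subtract, "mediate": self.stage_mediate,
            "report": self.stage_report,
        }
        for stage in self.config["stages"]:
            if stage not in dispatch:
                raise ValueError(f"unknown stage {stage!r}")
            log.info("running stage %s", stage)
            dispatch[stage]()
            self.manifest["stages_run"].append(stage)
            self._write_manifest()
        return self.outdir

    def _write_manifest(self) -> None:
        with open(self._path("manifest.yaml"), "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.manifest, default=str)),
                           fh, sort_keys=False)


def _factor_items(spec, factor: str) -> list[str]:
    return [c.row for c in spec.cells
            if c.matrix == "A" and c.col == factor and c.row in spec.observed]


def run(config_path: str | Path | None, outdir: str | Path,
        seed: int | None = None) -> Path:
    """Execute the configured stages; returns the run directory."""
    config = load_config(config_path)
    if seed is not None:
        config["seed"] = int(seed)
    return PipelineRun(config, outdir).run()
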