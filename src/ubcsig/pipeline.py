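"""End-to-end orchestration: synthesize -> normalize -> adjust -> classify ->
survival -> IHC, with per-stage seeds derived deterministically from one
global seed and a JSON run report tying every metric to a written artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import combat as cb
from . import ihc as ihc_mod
from . import normalization as norm
from . import survival as surv_mod
from . import synthetic as syn

__all__ = ["StageError", "default_demo_config", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def default_demo_config(seed: int = 0) -> dict:
    """A fully synthetic demo configuration sized to run in minutes."""
    return {
        "seed": seed,
        "stages": ["synthesize", "normalize", "batch_adjust", "classify",
                   "survival", "ihc"],
        "cohort": {
            "n_samples": 240,
            "n_genes": 300,
            "n_signature_genes": 13,
            "basal_fraction": 0.5,
            "log2_effect": 2.0,
            "n_batches": 2,
            "batch_shift": 1.0,
            "batch_scale": 1.5,
            "cox_betas": {f"G{i:04d}": 0.5 for i in range(5)},
            "target_censoring": 0.6,
        },
        "classify": {"n_folds": 10, "alpha_grid": [0.0, 0.25, 0.5, 0.75, 1.0],
                     "n_lambda": 50, "proportion": 0.7,
                     "pi_threshold": 0.8, "pcer": 0.1, "n_subsamples": 100},
        "survival": {"t_max": 3.0, "n_folds": 10, "boot_B": 25,
                     "retain_fraction": 0.5, "span": 0.25,
                     "epsilon": [0.1, 0.9]},
        "ihc": {"n_cases": 200},
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _validate(config: dict) -> None:
    stages = config.get("stages", [])
    known = {"synthesize", "normalize", "batch_adjust", "classify", "survival",
             "ihc"}
    unknown = set(stages) - known
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    needs = {"normalize": "synthesize", "batch_adjust": "normalize",
             "classify": "normalize", "survival": "normalize"}
    for stage, dep in needs.items():
        if stage in stages and dep not in stages and "counts_tsv" not in config:
            raise ValueError(
                f"stage {stage!r} requires {dep!r} or an input counts_tsv"
            )


def run_pipeline(config: dict, outdir) -> dict:
    """Run the enabled stages in dependency order; returns the run report."""
    from . import __version__

    try:
        _validate(config)
    except ValueError:
        raise
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", [])
    report: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seeds": {},
        "stages": {},
    }
    state: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - report which stage failed
            logger.error("stage %s failed on input: %s", name, exc)
            raise StageError(name, exc) from exc
        report["stages"][name] = out or {}
        report["stages"][name]["wall_seconds"] = round(
            time.perf_counter() - t0, 3
        )

    if "synthesize" in stages:
        def _synthesize():
            s = stage_seed(seed, "synthesize")
            report["seeds"]["synthesize"] = s
            cfg = syn.SyntheticConfig(seed=s, **config.get("cohort", {}))
            cohort = syn.generate_cohort(cfg)
            cohort.write(outdir / "cohort")
            state["cohort"] = cohort
            return {"n_samples": cohort.counts.n_samples,
                    "n_genes": cohort.counts.n_genes,
                    "artifacts": str(outdir / "cohort")}
        run_stage("synthesize", _synthesize)
    elif "counts_tsv" in config:
        state["cohort"] = syn.SyntheticCohort(
            counts=norm.CountMatrix.read_tsv(config["counts_tsv"]),
            annotation=pd.read_csv(config["clinical_tsv"], sep="\t"),
        )

    if "normalize" in stages:
        def _normalize():
            cohort = state["cohort"]
            counts = cohort.counts
            ann = cohort.annotation
            if "ffpe" in ann:
                keep = ~ann["ffpe"].astype(bool)
                counts = counts.subset_samples(ann.loc[keep, "sample_id"])
                ann = ann[keep].reset_index(drop=True)
                state["cohort"] = syn.SyntheticCohort(counts, ann, cohort.truth)
            tmm = norm.tmm_factors(counts)
            expr = norm.log2_rpkm(counts, tmm)
            expr.write_tsv(outdir / "expression.tsv")
            state["expr"] = expr
            return {"reference_sample": str(tmm.reference_sample),
                    "artifacts": str(outdir / "expression.tsv")}
        run_stage("normalize", _normalize)

    if "batch_adjust" in stages:
        def _batch_adjust():
            ann = state["cohort"].annotation
            if ann["batch"].nunique() < 2:
                state["expr_adj"] = state["expr"]
                return {"skipped": "single batch"}
            adj, params = cb.combat_adjust(state["expr"], ann["batch"].to_numpy())
            adj.write_tsv(outdir / "expression_combat.tsv")
            with open(outdir / "combat_params.json", "w") as fh:
                json.dump(params.to_dict(), fh)
            state["expr_adj"] = adj
            return {"n_batches": int(ann["batch"].nunique()),
                    "artifacts": str(outdir / "expression_combat.tsv")}
        run_stage("batch_adjust", _batch_adjust)

    expr_for_models = lambda: state.get("expr_adj", state.get("expr"))  # noqa: E731

    if "classify" in stages:
        def _classify():
            p = config.get("classify", {})
            s = stage_seed(seed, "classify")
            report["seeds"]["classify"] = s
            cohort = state["cohort"]
            expr = expr_for_models()
            sig = cohort.truth.get(
                "signature_genes", list(expr.gene_ids[:13])
            )
            X = expr.to_frame().T.loc[:, sig]
            y = cohort.annotation.set_index("sample_id").loc[X.index, "subtype"]
            plan = cls.split_train_test(
                X.index.to_numpy(), y.to_numpy(),
                proportion=p.get("proportion", 0.7), seed=s,
            )
            model = cls.fit_elastic_net_logistic(
                X.loc[plan.train_ids], y.loc[plan.train_ids],
                alpha_grid=tuple(p.get("alpha_grid", cls.DEFAULT_ALPHA_GRID)),
                n_folds=p.get("n_folds", 10),
                n_lambda=p.get("n_lambda", 100), seed=s,
            )
            metrics = cls.evaluate_classifier(
                model, X.loc[plan.test_ids], y.loc[plan.test_ids]
            )
            stab = cls.stability_path_select(
                X.loc[plan.train_ids], y.loc[plan.train_ids],
                pi_threshold=p.get("pi_threshold", 0.8),
                pcer=p.get("pcer", 0.1),
                n_subsamples=p.get("n_subsamples", 100), seed=s,
            )
            with open(outdir / "classifier.json", "w") as fh:
                json.dump({"model": model.to_dict(),
                           "metrics": metrics.to_dict(),
                           "stable_set": stab.stable_set,
                           "q": stab.q_per_subsample}, fh, indent=2)
            state["model"] = model
            state["signature"] = sig
            return {"accuracy": metrics.accuracy,
                    "accuracy_ci": list(metrics.accuracy_ci),
                    "sensitivity": metrics.sensitivity,
                    "specificity": metrics.specificity,
                    "alpha": model.alpha, "lambda": model.lam,
                    "stable_set": stab.stable_set,
                    "artifacts": str(outdir / "classifier.json")}
        run_stage("classify", _classify)

    if "survival" in stages:
        def _survival():
            p = config.get("survival", {})
            s = stage_seed(seed, "survival")
            report["seeds"]["survival"] = s
            cohort = state["cohort"]
            expr = expr_for_models()
            sig = state.get("signature") or cohort.truth.get(
                "signature_genes", list(expr.gene_ids[:13])
            )
            X = expr.to_frame().T.loc[:, sig]
            sd = surv_mod.SurvivalData.from_annotation(cohort.annotation)
            t_max = p.get("t_max", 3.0)

            ridge = surv_mod.fit_ridge_cox(X, sd, n_folds=p.get("n_folds", 10),
                                           seed=s)
            boot = surv_mod.boot_lasso_cox(
                X, sd, B=p.get("boot_B", 200),
                retain_fraction=p.get("retain_fraction", 0.5), seed=s,
            )
            curves = []
            ibs = {}
            for label, spec in (("null", "null"), ("full_signature", "ridge")):
                pec = surv_mod.cv_prediction_error(
                    spec, X, sd, n_folds=p.get("n_folds", 10), seed=s,
                    t_max=t_max, model_label=label,
                )
                ibs[label] = pec.ibs
                curves.append(pec.to_frame())
            pd.concat(curves).to_csv(outdir / "prediction_error.tsv",
                                     sep="\t", index=False)

            eta = ridge.linear_predictor(X)
            km = surv_mod.conditional_km(eta, sd, span=p.get("span", 0.25))
            pd.concat(
                [df.assign(group=g) for g, df in km.items()]
            ).to_csv(outdir / "conditional_km.tsv", sep="\t", index=False)
            cut = surv_mod.maxstat_cutpoint(
                eta, sd, epsilon=tuple(p.get("epsilon", (0.1, 0.9)))
            )
            with open(outdir / "survival.json", "w") as fh:
                json.dump({"ridge": ridge.to_dict(),
                           "boot_lasso": {
                               "retained_set": boot.retained_set,
                               "B": boot.B, "empty": boot.empty},
                           "ibs": ibs,
                           "cutpoint": {
                               "value": cut.cut_value,
                               "quantile": cut.cut_quantile,
                               "max_statistic": cut.max_statistic,
                               "adjusted_p": cut.adjusted_p}}, fh, indent=2)
            return {"ibs": ibs,
                    "boot_lasso_retained": boot.retained_set,
                    "cut_quantile": cut.cut_quantile,
                    "cut_adjusted_p": cut.adjusted_p,
                    "artifacts": str(outdir / "survival.json")}
        run_stage("survival", _survival)

    if "ihc" in stages:
        def _ihc():
            p = config.get("ihc", {})
            s = stage_seed(seed, "ihc")
            report["seeds"]["ihc"] = s
            panel = syn.generate_ihc_cohort(p.get("n_cases", 200), seed=s)
            calls = ihc_mod.call_cohort(panel)
            calls.to_csv(outdir / "ihc_calls.tsv", sep="\t", index=False)
            known = calls[calls["call"] != "non-type"]
            agree = float(
                (known["call"] == known["true_subtype"]).mean()
            ) if len(known) else float("nan")
            # subtype x pSTAT3-high contingency among called cases
            tab = pd.crosstab(
                known["call"],
                known["pSTAT3"].map(
                    lambda v: ihc_mod.dichotomize(
                        ihc_mod.quantize_score(v, "pSTAT3"))
                ),
            ).reindex(index=["basal", "luminal"], columns=["high", "low"],
                      fill_value=0)
            chi2, pval = ihc_mod.contingency_test(tab.to_numpy())
            return {"n_called": int(len(known)),
                    "agreement_with_truth": agree,
                    "pstat3_chi2": chi2, "pstat3_p": pval,
                    "artifacts": str(outdir / "ihc_calls.tsv")}
        run_stage("ihc", _ihc)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
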