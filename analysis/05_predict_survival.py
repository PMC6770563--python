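#!/usr/bin/env python
"""Predict overall survival from the gene signature.

Univariate Cox screen, ridge Cox on the full signature, Boot Lasso
(B = 200 bootstrap lasso selections, >= 50% retention, ridge refit),
10-fold cross-validated Brier curves over three years (null vs full
signature vs Boot Lasso), conditional Kaplan-Meier curves at the low /
median / high signature values, and the maximally selected log-rank cut
point.  Writes prediction-error and KM tables plus survival.json.
"""

import json
from pathlib import Path

import pandas as pd

from ubcsig import survival as sv
from ubcsig.normalization import ExpressionMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
T_MAX = 3.0


def main() -> None:
    expr = ExpressionMatrix.read_tsv(ROOT / "expression_combat.tsv")
    ann = pd.read_csv(ROOT / "cohort" / "annotation.tsv", sep="\t")
    truth = json.load(open(ROOT / "cohort" / "truth.json"))
    signature = truth["signature_genes"]

    X = expr.to_frame().T.loc[:, signature]
    surv = sv.SurvivalData.from_annotation(ann)

    screen = sv.univariate_cox_screen(X, surv)
    screen.to_csv(ROOT / "univariate_cox.tsv", sep="\t", index=False)
    hits = screen[screen["wald_p"] < 0.05]["gene"].tolist()
    print(f"univariate Cox: {len(hits)}/{len(signature)} genes at p<0.05: "
          f"{hits}")

    ridge = sv.fit_ridge_cox(X, surv, n_folds=10, seed=SEED)
    boot = sv.boot_lasso_cox(X, surv, B=200, retain_fraction=0.5, seed=SEED)
    print(f"ridge lambda {ridge.lam:.3g}; Boot Lasso retained "
          f"{boot.retained_set}")

    curves, ibs = [], {}
    for label, spec, kwargs in (
        ("null", "null", {}),
        ("full_signature", "ridge", {}),
        ("boot_lasso", "bootlasso", {"B": 50}),
    ):
        pec = sv.cv_prediction_error(spec, X, surv, n_folds=10, seed=SEED,
                                     t_max=T_MAX, model_label=label, **kwargs)
        ibs[label] = pec.ibs
        curves.append(pec.to_frame())
    pd.concat(curves).to_csv(ROOT / "prediction_error.tsv", sep="\t",
                             index=False)
    print("cross-validated IBS over 3 years: "
          + ", ".join(f"{k}={v:.3f}" for k, v in ibs.items()))

    eta = ridge.linear_predictor(X)
    km = sv.conditional_km(eta, surv, span=0.25)
    pd.concat([df.assign(group=g) for g, df in km.items()]).to_csv(
        ROOT / "conditional_km.tsv", sep="\t", index=False
    )
    cut = sv.maxstat_cutpoint(eta, surv, epsilon=(0.1, 0.9))
    print(f"maxstat cut point at the {100 * cut.cut_quantile:.0f}th quantile "
          f"(M = {cut.max_statistic:.2f}, adjusted p = {cut.adjusted_p:.3g})")

    with open(ROOT / "survival.json", "w") as fh:
        json.dump({
            "ridge": ridge.to_dict(),
            "boot_lasso": {"B": boot.B, "retained_set": boot.retained_set,
                           "empty": boot.empty},
            "ibs": ibs,
            "cutpoint": {
                "value": cut.cut_value,
                "quantile": cut.cut_quantile,
                "max_statistic": cut.max_statistic,
                "adjusted_p": cut.adjusted_p,
            },
        }, fh, indent=2)


if __name__ == "__main__":
    main()
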