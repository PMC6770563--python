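#!/usr/bin/env python
"""Classify basal vs luminal tumors from the gene signature.

Balanced 70-30 split, elastic-net logistic regression with joint
(alpha, lambda) 10-fold cross-validation, held-out accuracy with an exact
binomial interval, and stability-path selection (pi = 0.8, PCER = 0.1) of
the most reliable signature genes.  Writes results/classifier.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ubcsig import classify as cls
from ubcsig.normalization import ExpressionMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    expr = ExpressionMatrix.read_tsv(ROOT / "expression_combat.tsv")
    ann = pd.read_csv(ROOT / "cohort" / "annotation.tsv", sep="\t")
    truth = json.load(open(ROOT / "cohort" / "truth.json"))
    signature = truth["signature_genes"]

    X = expr.to_frame().T.loc[:, signature]
    y = ann.set_index("sample_id").loc[X.index, "subtype"]

    plan = cls.split_train_test(X.index.to_numpy(), y.to_numpy(), 0.7,
                                seed=SEED)
    model = cls.fit_elastic_net_logistic(
        X.loc[plan.train_ids], y.loc[plan.train_ids],
        n_folds=10, seed=SEED, n_lambda=50,
    )
    metrics = cls.evaluate_classifier(model, X.loc[plan.test_ids],
                                      y.loc[plan.test_ids])
    stab = cls.stability_path_select(
        X.loc[plan.train_ids], y.loc[plan.train_ids], seed=SEED
    )

    with open(ROOT / "classifier.json", "w") as fh:
        json.dump({
            "split": plan.stratum_counts,
            "model": model.to_dict(),
            "metrics": metrics.to_dict(),
            "stability": {
                "q_per_subsample": stab.q_per_subsample,
                "stable_set": stab.stable_set,
                "selection_frequency": {
                    str(g): float(f)
                    for g, f in stab.selection_frequency.items()
                },
            },
        }, fh, indent=2)

    nnz = int(np.sum(model.coefficients != 0))
    lo, hi = metrics.accuracy_ci
    print(f"selected alpha={model.alpha}, lambda={model.lam:.4g}, "
          f"{nnz}/{len(signature)} genes with nonzero coefficients")
    print(f"test accuracy {metrics.accuracy:.3f} "
          f"(95% CI {lo:.3f}-{hi:.3f}), "
          f"sensitivity {metrics.sensitivity:.3f}, "
          f"specificity {metrics.specificity:.3f}")
    print(f"stability path (q={stab.q_per_subsample}): "
          f"stable set {stab.stable_set}")


if __name__ == "__main__":
    main()
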