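#!/usr/bin/env python
"""Call tumor subtypes from the four-marker IHC panel.

Quantizes percent-positive staining to the four-tier score, applies the
basal/luminal decision rule, compares calls against the generating truth,
and cross-tabulates pSTAT3/MYC/FOSL1 high-vs-low status by subtype with
chi-square tests.  Writes results/ihc_calls.tsv and ihc_contingency.json.
"""

import json
from pathlib import Path

import pandas as pd

from ubcsig.ihc import call_cohort, contingency_test, dichotomize, quantize_score

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = pd.read_csv(ROOT / "cohort" / "ihc_panel.tsv", sep="\t")
    calls = call_cohort(panel)
    calls.to_csv(ROOT / "ihc_calls.tsv", sep="\t", index=False)

    agree = (calls["call"] == calls["true_subtype"]).mean()
    counts = calls["call"].value_counts().to_dict()
    print(f"calls: {counts}; agreement with truth {agree:.3f}")

    tables = {}
    called = calls[calls["call"].isin(["basal", "luminal"])]
    for marker in ("pSTAT3", "MYC", "FOSL1"):
        level = called[marker].map(
            lambda v, m=marker: dichotomize(quantize_score(v, m))
        )
        tab = pd.crosstab(called["call"], level).reindex(
            index=["basal", "luminal"], columns=["high", "low"], fill_value=0
        )
        chi2, p = contingency_test(tab.to_numpy())
        tables[marker] = {"table": tab.to_numpy().tolist(),
                          "chi2": chi2, "p": p}
        high_b = tab.loc["basal", "high"] / tab.loc["basal"].sum()
        high_l = tab.loc["luminal", "high"] / tab.loc["luminal"].sum()
        print(f"{marker}: {100 * high_b:.1f}% vs {100 * high_l:.1f}% high "
              f"(basal vs luminal), chi2 = {chi2:.1f}, p = {p:.2g}")

    with open(ROOT / "ihc_contingency.json", "w") as fh:
        json.dump(tables, fh, indent=2)


if __name__ == "__main__":
    main()
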