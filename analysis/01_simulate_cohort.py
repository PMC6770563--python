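#!/usr/bin/env python
"""Simulate the study cohort stand-ins.

Draws a 388-sample bladder-cancer RNA-seq cohort (negative-binomial counts,
a 13-gene basal/luminal signature at +2 log2 units, two pseudo-dataset
batches, Weibull overall survival driven by five signature genes, ~60%
censoring) and a 200-case IHC marker panel.  Writes counts, clinical
annotation, generating truth and the IHC panel under results/cohort/.
"""

import json
from pathlib import Path

from ubcsig.synthetic import SyntheticConfig, generate_cohort, generate_ihc_cohort

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = SyntheticConfig(
        n_samples=388,
        n_genes=500,
        n_signature_genes=13,
        log2_effect=2.0,
        n_batches=2,
        batch_shift=1.0,
        batch_scale=1.5,
        cox_betas={f"G{i:04d}": 0.5 for i in range(5)},
        target_censoring=0.6,
        seed=SEED,
    )
    cohort = generate_cohort(cfg)
    cohort.write(OUT)
    panel = generate_ihc_cohort(200, seed=SEED)
    panel.to_csv(OUT / "ihc_panel.tsv", sep="\t", index=False)

    ann = cohort.annotation
    print(f"cohort: {cohort.counts.n_genes} genes x {cohort.counts.n_samples} samples")
    print(f"basal fraction: {(ann['subtype'] == 'basal').mean():.2f}")
    print(f"censoring: {1 - ann['os_event'].mean():.2f}")
    print(f"IHC panel: {len(panel)} cases -> {OUT}")
    with open(OUT / "config.json", "w") as fh:
        json.dump({"seed": SEED}, fh)


if __name__ == "__main__":
    main()
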