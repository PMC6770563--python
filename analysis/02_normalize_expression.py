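#!/usr/bin/env python
"""Normalize the simulated counts.

TMM library-size factors followed by log2-RPKM; prints the factor range and
writes results/expression.tsv.
"""

from pathlib import Path

import numpy as np

from ubcsig.normalization import CountMatrix, log2_rpkm, tmm_factors

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = CountMatrix.read_tsv(ROOT / "cohort" / "counts.tsv")
    tmm = tmm_factors(counts)
    expr = log2_rpkm(counts, tmm)
    expr.write_tsv(ROOT / "expression.tsv")
    print(f"reference sample: {tmm.reference_sample}")
    print(f"TMM factors: min {tmm.factors.min():.3f}, "
          f"max {tmm.factors.max():.3f}, "
          f"geometric mean {np.exp(np.mean(np.log(tmm.factors))):.6f}")
    print(f"expression written: {ROOT / 'expression.tsv'}")


if __name__ == "__main__":
    main()
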