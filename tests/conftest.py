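import numpy as np
import pandas as pd
import pytest

from ubcsig.normalization import CountMatrix
from ubcsig.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def signal_cohort():
    """Moderate cohort with a strong basal/luminal signature (13 genes)."""
    return generate_cohort(
        SyntheticConfig(
            n_samples=200, n_genes=100, n_signature_genes=13,
            log2_effect=2.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def prognostic_cohort():
    """Cohort whose survival depends on five signature genes (beta = 0.5)."""
    return generate_cohort(
        SyntheticConfig(
            n_samples=250, n_genes=40, n_signature_genes=10,
            cox_betas={f"G{i:04d}": 0.6 for i in range(5)},
            target_censoring=0.4, seed=21,
        )
    )


@pytest.fixture()
def toy_counts():
    """Five genes, two hand-sized samples for normalization arithmetic."""
    return CountMatrix(
        gene_ids=np.array(["g1", "g2", "g3", "g4", "g5"], dtype=object),
        gene_length_bp=np.array([500, 1000, 1500, 2000, 2500]),
        sample_ids=np.array(["s1", "s2"], dtype=object),
        counts=np.array([[100, 120], [200, 230], [300, 310],
                         [400, 410], [500, 2500]]),
    )


@pytest.fixture()
def mixed_censoring_surv():
    """n = 8 fixture with events and censoring interleaved."""
    from ubcsig.survival import SurvivalData

    return SurvivalData(
        time=np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]),
        event=np.array([1, 0, 1, 1, 0, 1, 0, 1]),
    )


@pytest.fixture(scope="session")
def expr_and_labels(signal_cohort):
    """log2-RPKM signature submatrix and subtype labels for the classifier."""
    from ubcsig.normalization import log2_rpkm, tmm_factors

    expr = log2_rpkm(signal_cohort.counts, tmm_factors(signal_cohort.counts))
    X = expr.to_frame().T.loc[:, signal_cohort.truth["signature_genes"]]
    y = signal_cohort.annotation.set_index("sample_id").loc[X.index, "subtype"]
    return X, y
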