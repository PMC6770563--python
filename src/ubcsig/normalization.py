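"""Count-matrix container, duplicate averaging, TMM factors and log transforms.

RNA-seq counts are held in a :class:`CountMatrix` (genes x samples, with
per-gene lengths).  Library-size normalization uses the trimmed mean of
M-values (TMM): sample-vs-reference log-ratios of count fractions are doubly
trimmed (30% on M, 5% on A by default) and averaged with inverse
delta-method-variance weights; the resulting factors are rescaled to
geometric mean 1.  Expression is reported as log2-RPKM (reads per kilobase
per million, on TMM-effective library sizes) or log-CPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "TMMResult",
    "ExpressionMatrix",
    "average_duplicates",
    "tmm_factors",
    "log2_rpkm",
    "log_cpm",
]


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix with gene lengths in bp."""

    gene_ids: np.ndarray
    gene_length_bp: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.gene_length_bp = np.asarray(self.gene_length_bp, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.gene_length_bp <= 0):
            raise ValueError("gene lengths must be strictly positive")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.insert(0, "length_bp", self.gene_length_bp)
        df.index.name = "gene_id"
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length_bp").to_numpy()
        return cls(
            gene_ids=df.index.to_numpy(dtype=object),
            gene_length_bp=lengths,
            sample_ids=df.columns.to_numpy(dtype=object),
            counts=df.to_numpy(),
        )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(
            gene_ids=self.gene_ids.copy(),
            gene_length_bp=self.gene_length_bp.copy(),
            sample_ids=np.asarray(list(sample_ids), dtype=object),
            counts=self.counts[:, cols].copy(),
        )


@dataclass
class TMMResult:
    factors: np.ndarray
    sample_ids: np.ndarray
    reference_sample: str
    m_values: dict
    a_values: dict
    trim_m: float
    trim_a: float


@dataclass
class ExpressionMatrix:
    """Log-scale expression values with transform provenance."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    transform: str
    pseudocount: float
    effective_libsizes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# transform={self.transform} pseudocount={self.pseudocount}\n")
            self.to_frame().to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            df = pd.read_csv(fh, sep="\t", index_col="gene_id")
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        return cls(
            gene_ids=df.index.to_numpy(dtype=object),
            sample_ids=df.columns.to_numpy(dtype=object),
            values=df.to_numpy(),
            transform=meta.get("transform", "unknown"),
            pseudocount=float(meta.get("pseudocount", "nan")),
        )


def average_duplicates(matrix: CountMatrix, case_of: Mapping[str, str]) -> CountMatrix:
    """Collapse technical duplicates: one column per case.

    Duplicated cases are replaced by the arithmetic mean of their columns,
    rounded half-to-even back to integers; singleton cases pass through
    unchanged.  Case order follows first appearance in the sample order.
    """
    missing = [s for s in matrix.sample_ids if s not in case_of]
    if missing:
        raise KeyError(f"samples without a case id: {missing}")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for j, s in enumerate(matrix.sample_ids):
        c = case_of[s]
        if c not in members:
            members[c] = []
            order.append(c)
        members[c].append(j)
    out = np.empty((matrix.n_genes, len(order)), dtype=matrix.counts.dtype)
    for k, c in enumerate(order):
        cols = members[c]
        if len(cols) == 1:
            out[:, k] = matrix.counts[:, cols[0]]
        else:
            # numpy rint rounds half to even, preserving integer count semantics
            out[:, k] = np.rint(matrix.counts[:, cols].mean(axis=1)).astype(
                matrix.counts.dtype
            )
    return CountMatrix(
        gene_ids=matrix.gene_ids.copy(),
        gene_length_bp=matrix.gene_length_bp.copy(),
        sample_ids=np.asarray(order, dtype=object),
        counts=out,
    )


def _choose_reference(fractions: np.ndarray) -> int:
    # sample whose 75th-percentile count fraction is closest to the mean of those
    q75 = np.quantile(fractions, 0.75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def tmm_factors(
    matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> TMMResult:
    """Trimmed-mean-of-M-values library-size normalization factors.

    For each sample vs the reference, M_g = log2 ratio of count fractions and
    A_g = half the log2 product; genes with a zero count in either sample are
    excluded.  The top/bottom ``trim_m`` of M and ``trim_a`` of A are trimmed
    (rank-based, double trimming) and the factor is 2**(weighted mean of the
    surviving M_g), weights the inverse binomial delta-method variances.
    Factors are rescaled to geometric mean 1.
    """
    if matrix.n_samples < 2:
        raise ValueError("TMM requires at least 2 samples")
    counts = matrix.counts.astype(float)
    libsize = counts.sum(axis=0)
    if np.any(libsize <= 0):
        bad = matrix.sample_ids[libsize <= 0]
        raise ValueError(f"zero library size for sample(s): {list(bad)}")
    frac = counts / libsize
    ref = _choose_reference(frac)

    log_factors = np.zeros(matrix.n_samples)
    m_store: dict = {}
    a_store: dict = {}
    for j in range(matrix.n_samples):
        if j == ref:
            continue
        keep = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if not np.any(keep):
            raise ValueError(
                f"sample {matrix.sample_ids[j]!r} shares no positive genes "
                f"with reference {matrix.sample_ids[ref]!r}"
            )
        y, yr = counts[keep, j], counts[keep, ref]
        n, nr = libsize[j], libsize[ref]
        m = np.log2((y / n) / (yr / nr))
        a = 0.5 * np.log2((y / n) * (yr / nr))
        # inverse delta-method (binomial) variances as precision weights
        w = 1.0 / ((n - y) / (n * y) + (nr - yr) / (nr * yr))

        k = len(m)
        m_rank = m.argsort().argsort()
        a_rank = a.argsort().argsort()
        lo_m, hi_m = np.floor(k * trim_m), k - np.floor(k * trim_m)
        lo_a, hi_a = np.floor(k * trim_a), k - np.floor(k * trim_a)
        kept = (
            (m_rank >= lo_m)
            & (m_rank < hi_m)
            & (a_rank >= lo_a)
            & (a_rank < hi_a)
        )
        if not np.any(kept):
            raise ValueError(
                f"trimming removed every gene for sample {matrix.sample_ids[j]!r}"
            )
        log_factors[j] = np.sum(w[kept] * m[kept]) / np.sum(w[kept])
        m_store[matrix.sample_ids[j]] = m[kept]
        a_store[matrix.sample_ids[j]] = a[kept]

    factors = 2.0 ** (log_factors - log_factors.mean())
    return TMMResult(
        factors=factors,
        sample_ids=matrix.sample_ids.copy(),
        reference_sample=matrix.sample_ids[ref],
        m_values=m_store,
        a_values=a_store,
        trim_m=trim_m,
        trim_a=trim_a,
    )


def log2_rpkm(
    matrix: CountMatrix, tmm: TMMResult, pseudocount: float = 0.5
) -> ExpressionMatrix:
    """log2 reads-per-kilobase-per-million on TMM-effective library sizes."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if not np.array_equal(tmm.sample_ids, matrix.sample_ids):
        raise ValueError("TMM factors do not align with the count matrix samples")
    libsize = matrix.library_sizes
    if np.any(libsize <= 0):
        raise ValueError("zero library size")
    eff = libsize * tmm.factors
    denom = (eff / 1e6)[None, :] * (matrix.gene_length_bp / 1e3)[:, None]
    values = np.log2((matrix.counts + pseudocount) / denom)
    return ExpressionMatrix(
        gene_ids=matrix.gene_ids.copy(),
        sample_ids=matrix.sample_ids.copy(),
        values=values,
        transform="log2_rpkm",
        pseudocount=pseudocount,
        effective_libsizes=eff,
    )


def log_cpm(matrix: CountMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a prior count (limma-style +2*prior on lib)."""
    if prior < 0:
        raise ValueError("prior must be non-negative")
    libsize = matrix.library_sizes
    if np.any(libsize <= 0):
        raise ValueError("zero library size")
    values = np.log2((matrix.counts + prior) / (libsize + 2 * prior)[None, :] * 1e6)
    return ExpressionMatrix(
        gene_ids=matrix.gene_ids.copy(),
        sample_ids=matrix.sample_ids.copy(),
        values=values,
        transform="log_cpm",
        pseudocount=prior,
        effective_libsizes=libsize,
    )
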