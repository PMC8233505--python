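"""Shared-variation statistics over accessions x CNS indicator matrices.

The central object is the variation matrix: rows are accessions, columns are
CNS, entries indicate whether the CNS shows a given variation status (PAV or
PosV) in that accession. From it come the independence expectation for the
number of distinct variable CNS, the shared-event fraction, rarefaction
curves, hypergeometric set-overlap tests, count correlations, a binary PCA
and a population-structure regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def variation_matrix(calls: pd.DataFrame, status: str) -> pd.DataFrame:
    """Accessions x CNS binary indicator frame for one status from calls.tsv rows."""
    if status not in {"pav", "posv"}:
        raise ValueError("status must be 'pav' or 'posv'")
    ind = (calls["status"] == status).astype(int)
    return (
        calls.assign(ind=ind)
        .pivot_table(index="accession", columns="cns_id", values="ind", fill_value=0)
        .astype(int)
    )


def expected_distinct(k, N: int) -> float:
    """Expected number of distinct variable CNS under independent accessions.

    Each accession i draws its k_i variable CNS uniformly without replacement
    from a universe of N; accessions are independent. The expectation is
    N * (1 - prod_i (1 - k_i / N)), exact under this model.
    """
    k = np.asarray(k, dtype=float)
    if N <= 0:
        raise ValueError("universe size must be positive")
    if (k < 0).any() or (k > N).any():
        raise ValueError("per-accession counts must satisfy 0 <= k_i <= N")
    return float(N * (1 - np.prod(1 - k / N)))


def shared_event_fraction(matrix: pd.DataFrame | np.ndarray) -> float:
    """Fraction of variable CNS that are variable in two or more accessions."""
    m = np.asarray(matrix)
    col = m.sum(axis=0)
    variable = int((col >= 1).sum())
    if variable == 0:
        raise ValueError("no variable CNS: shared fraction undefined")
    return float((col >= 2).sum() / variable)


@dataclass
class HypergeomResult:
    p: float
    tail: str          # 'ge' (inclusive upper), 'gt' (exclusive upper)
    N: int
    nA: int
    nB: int
    n_overlap: int


def hypergeom_overlap_test(
    N: int, nA: int, nB: int, n_overlap: int, tail: str = "gt"
) -> HypergeomResult:
    """Exact hypergeometric overlap probability of two sets in a universe.

    Models the overlap X of a fixed set of size nA with a uniform draw of nB
    from N. ``tail='gt'`` (default, the survival-function idiom) returns
    P[X > n_overlap]; ``tail='ge'`` returns P[X >= n_overlap]. Computed by
    direct summation of the log-pmf over the support, no normal approximation.
    """
    if not (0 <= nA <= N and 0 <= nB <= N):
        raise ValueError("set sizes must lie within the universe")
    if not (0 <= n_overlap <= min(nA, nB)):
        raise ValueError("overlap must lie in [0, min(nA, nB)]")
    if tail not in {"ge", "gt"}:
        raise ValueError("tail must be 'ge' or 'gt'")
    lo = n_overlap if tail == "ge" else n_overlap + 1
    hi = min(nA, nB)
    if lo > hi:
        return HypergeomResult(0.0, tail, N, nA, nB, n_overlap)
    ks = np.arange(max(lo, max(0, nA + nB - N)), hi + 1)
    p = float(hypergeom_pmf(ks, N, nA, nB).sum())
    return HypergeomResult(min(p, 1.0), tail, N, nA, nB, n_overlap)


def hypergeom_pmf(k: np.ndarray, N: int, nA: int, nB: int) -> np.ndarray:
    """Probability mass of overlap counts ``k`` for a draw of nB from N
    containing nA marked items."""
    return sps.hypergeom(N, nA, nB).pmf(k)


def kmer_expected(genome_length: int, k: int, both_strands: bool = False) -> float:
    """Expected chance occurrences of one fixed k-mer in a genome.

    Uniform-base model, one strand: (L - k + 1) / 4**k; doubled when
    ``both_strands`` is set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > genome_length:
        raise ValueError("k exceeds the genome length")
    e = (genome_length - k + 1) * 4.0 ** (-k)
    return 2 * e if both_strands else e


def rarefaction(matrix: pd.DataFrame | np.ndarray, n_draws: int, seed: int) -> pd.DataFrame:
    """Distinct-variable-CNS rarefaction over accession subsamples.

    For every subsample size s = 1..n_accessions, draws ``n_draws`` random
    accession subsets without replacement and reports the mean and sd of the
    number of CNS variable in at least one sampled accession.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    m = np.asarray(matrix, dtype=bool)
    n_acc = m.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_acc + 1):
        counts = np.empty(n_draws)
        for d in range(n_draws):
            idx = rng.choice(n_acc, s, replace=False)
            counts[d] = m[idx].any(axis=0).sum()
        rows.append((s, counts.mean(), counts.std(ddof=0)))
    return pd.DataFrame(rows, columns=["subsample_size", "mean_distinct", "sd_distinct"])


def count_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation between two per-accession count vectors with its
    two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of at least 3 accessions")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a count vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class PcaResult:
    scores: pd.DataFrame       # accessions x components
    percent_variance: np.ndarray


def binary_pca(matrix: pd.DataFrame) -> PcaResult:
    """PCA of the binary indicator matrix (columns centered, not scaled)."""
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 accessions and 2 variable CNS")
    centered = m - m.mean(axis=0)
    if not centered.any():
        raise ValueError("constant matrix has no principal components")
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    pct = 100 * s**2 / (s**2).sum()
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(m.shape[0])
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(pd.DataFrame(scores, index=idx, columns=cols), pct)


@dataclass
class StructureR2:
    r2_base: float
    r2_with_covariate: float | None
    increment: float | None


def structure_r2(neutral_axes, response, covariate=None) -> StructureR2:
    """How much of a CNS-variation axis population structure explains.

    Ordinary least squares of the response axis (e.g. PC1 of the CNS PAV
    matrix) on the neutral axes (e.g. the first three whole-genome SNP PCA
    axes), optionally adding one covariate; reports R-squared with and
    without it.
    """
    import statsmodels.api as sm

    X = np.asarray(neutral_axes, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    n_pred = p + (1 if covariate is not None else 0)
    if n <= n_pred + 1:
        raise ValueError("need more accessions than predictors + 1")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design")
    r2_base = float(sm.OLS(y, design).fit().rsquared)
    if covariate is None:
        return StructureR2(r2_base, None, None)
    design2 = np.column_stack([design, np.asarray(covariate, dtype=float)])
    if np.linalg.matrix_rank(design2) < design2.shape[1]:
        raise ValueError("rank-deficient design with covariate")
    r2_cov = float(sm.OLS(y, design2).fit().rsquared)
    return StructureR2(r2_base, r2_cov, r2_cov - r2_base)
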