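"""Overlap of CNS classes with accessible-chromatin (ATAC) peaks.

Fold enrichment is the observed number of peak-overlapping intervals divided
by the mean overlap count across length-preserving random placements of the
same intervals; the empirical p-value counts permutations reaching the
observed overlap. A length-matched control subsamples a reference interval
class to the query's length histogram, addressing the concern that shorter
elements overlap peaks less for purely geometric reasons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context import PermutationParams, permute_intervals
from .intervals import merge_intervals, overlaps_any


def overlap_summary(intervals: pd.DataFrame, peaks: pd.DataFrame) -> tuple[int, float]:
    """(number, percent) of intervals sharing >= 1 bp with any peak.

    Peaks are merged (union) first; half-open semantics, so an interval
    ending where a peak starts does not overlap it.
    """
    if not len(intervals):
        raise ValueError("empty interval set")
    hit = overlaps_any(intervals.reset_index(drop=True), peaks)
    n = int(hit.sum())
    return n, 100.0 * n / len(intervals)


@dataclass
class EnrichmentResult:
    label: str
    n_intervals: int
    n_overlapping: int
    percent_overlap: float
    fold_enrichment: float
    p_value: float
    n_perm: int
    length_matched: bool = False
    perm_mean: float = float("nan")
    perm_sd: float = float("nan")


def fold_enrichment(
    intervals: pd.DataFrame,
    peaks: pd.DataFrame,
    chrom_lengths: dict[str, int],
    params: PermutationParams,
    label: str = "",
) -> EnrichmentResult:
    """Peak-overlap enrichment of an interval set against random placement."""
    n_obs, pct = overlap_summary(intervals, peaks)
    merged = merge_intervals(peaks)
    perms = permute_intervals(intervals, chrom_lengths, params)
    counts = np.array([overlaps_any(p, merged).sum() for p in perms], dtype=float)
    mean_perm = counts.mean()
    if mean_perm == 0:
        if n_obs == 0:
            fold = 0.0
        else:
            warnings.warn("no permuted interval overlapped a peak; fold is infinite")
            fold = float("inf")
    else:
        fold = n_obs / mean_perm
    p = (1 + int((counts >= n_obs).sum())) / (params.n_perm + 1)
    return EnrichmentResult(
        label, len(intervals), n_obs, pct, float(fold), float(p), params.n_perm,
        params.length_match, float(mean_perm), float(counts.std(ddof=1)),
    )


def length_matched_subsample(
    reference: pd.DataFrame,
    query_lengths: np.ndarray,
    seed: int,
    bin_width: int = 5,
) -> pd.DataFrame:
    """Subsample ``reference`` intervals to match a query length histogram.

    Sampling is without replacement within ``bin_width``-bp length bins, so
    the subsample reproduces the query's binned length histogram exactly;
    raises when a bin of the reference is too shallow.
    """
    rng = np.random.default_rng(seed)
    ref_len = (reference["end"] - reference["start"]).to_numpy()
    q_bins = np.asarray(query_lengths) // bin_width
    r_bins = ref_len // bin_width
    picks: list[int] = []
    for b, need in zip(*np.unique(q_bins, return_counts=True)):
        pool = np.flatnonzero(r_bins == b)
        if len(pool) < need:
            raise ValueError(
                f"reference has only {len(pool)} intervals in length bin "
                f"[{b * bin_width},{(b + 1) * bin_width}) but {need} are needed"
            )
        picks.extend(rng.choice(pool, need, replace=False).tolist())
    return reference.iloc[sorted(picks)].reset_index(drop=True)


def length_matched_enrichment(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    peaks: pd.DataFrame,
    chrom_lengths: dict[str, int],
    params: PermutationParams,
    bin_width: int = 5,
    label: str = "",
) -> EnrichmentResult:
    """Enrichment of a reference-class subsample matched to the query lengths.

    Answers: would the reference class, if it had the query's length
    distribution, still show its overlap? Useful when the query class (e.g.
    PosV CNS) is systematically shorter.
    """
    q_len = (query["end"] - query["start"]).to_numpy()
    matched = length_matched_subsample(reference, q_len, params.seed, bin_width)
    res = fold_enrichment(matched, peaks, chrom_lengths, params, label=label)
    res.length_matched = True
    return res
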