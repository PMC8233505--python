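"""Genomic context of CNS classes: distances to genes and repeats,
permutation nulls and duplicate-class summaries.

The permutation null places each interval uniformly over all valid
(chromosome, start) positions — "random movement across the genome" — while
preserving interval lengths, so observed distance distributions can be
compared against what random relocation would produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import nearest_gap, signed_gene_distances


@dataclass
class PermutationParams:
    n_perm: int = 1000
    seed: int = 0
    placement: str = "genome-wide"   # or "same-chromosome"
    length_match: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.placement not in {"genome-wide", "same-chromosome"}:
            raise ValueError("placement must be 'genome-wide' or 'same-chromosome'")


def distance_distribution(
    intervals: pd.DataFrame, genes: pd.DataFrame, window: int
) -> tuple[np.ndarray, float]:
    """Signed nearest-gene distance per interval and the fraction within
    +/- ``window`` bp of a gene boundary (overlaps count as within)."""
    if not len(genes):
        raise ValueError("gene annotation is empty")
    _, dists = signed_gene_distances(intervals, genes)
    frac = float(np.mean(np.abs(dists) <= window)) if len(dists) else float("nan")
    return dists, frac


def permute_intervals(
    intervals: pd.DataFrame,
    chrom_lengths: dict[str, int],
    params: PermutationParams,
) -> list[pd.DataFrame]:
    """Length-preserving random placements of an interval set.

    Genome-wide placement draws each interval's start uniformly over every
    valid position on every chromosome long enough to hold it (so chromosome
    assignment is proportional to length); same-chromosome placement keeps
    each interval on its own chromosome. Replicate r is a deterministic
    function of (seed, r).
    """
    lens = (intervals["end"] - intervals["start"]).to_numpy()
    chroms = list(chrom_lengths)
    L = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    if len(lens) and lens.max() > L.max():
        raise ValueError("an interval is longer than every chromosome")
    out = []
    for rep in range(params.n_perm):
        rng = np.random.default_rng([params.seed, rep])
        if params.placement == "genome-wide":
            # valid starts per chromosome for each interval length
            valid = np.maximum(L[None, :] - lens[:, None] + 1, 0)  # n x n_chrom
            total = valid.sum(axis=1)
            u = (rng.random(len(lens)) * total).astype(np.int64)
            cum = np.cumsum(valid, axis=1)
            ci = (u[:, None] >= cum).sum(axis=1)
            prev = np.where(ci > 0, np.take_along_axis(cum, np.maximum(ci - 1, 0)[:, None], 1)[:, 0], 0)
            starts = u - prev
            df = pd.DataFrame(
                {
                    "chrom": [chroms[i] for i in ci],
                    "start": starts,
                    "end": starts + lens,
                }
            )
        else:
            starts = np.empty(len(lens), dtype=np.int64)
            for i, (c, ln) in enumerate(zip(intervals["chrom"], lens)):
                starts[i] = rng.integers(0, chrom_lengths[c] - ln + 1)
            df = pd.DataFrame(
                {"chrom": intervals["chrom"].to_numpy(), "start": starts, "end": starts + lens}
            )
        out.append(df)
    return out


def _ks_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov statistic (no p-value machinery)."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.abs(fa - fb).max())


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    direction: str     # 'closer' | 'farther' | 'none'
    n_perm: int


def distance_permutation_test(
    intervals: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int],
    params: PermutationParams,
) -> PermutationTestResult:
    """Are the observed nearest-gene distances unlike random placement?

    Two-sample Kolmogorov–Smirnov statistic of the observed absolute
    distances against the pooled distances of ``n_perm`` random placements;
    the p-value is empirical, p = (1 + #{permutation D >= observed D}) /
    (n_perm + 1), with each permutation replicate scored against the pool of
    the remaining replicates (leave-one-out) so the null reference is
    exchangeable with the observed set.
    """
    if len(intervals) < 10:
        raise ValueError("need at least 10 intervals")
    obs, _ = distance_distribution(intervals, genes, 0)
    obs = np.abs(obs)
    # gene distances are undefined on unannotated chromosomes: keep the
    # permutation domain to chromosomes carrying at least one gene
    domain = {c: L for c, L in chrom_lengths.items() if c in set(genes["chrom"])}
    reps = permute_intervals(intervals, domain, params)
    rep_d = [np.abs(distance_distribution(r, genes, 0)[0]) for r in reps]
    pooled = np.concatenate(rep_d)
    if np.ptp(pooled) == 0 and np.ptp(obs) == 0:
        raise ValueError("degenerate distance vectors")
    d_obs = _ks_stat(obs, pooled)
    # leave-one-out pool per replicate keeps replicates exchangeable with obs
    sizes = np.array([len(d) for d in rep_d])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    count = 0
    for i, d in enumerate(rep_d):
        rest = np.concatenate([pooled[: offsets[i]], pooled[offsets[i + 1] :]])
        if _ks_stat(d, rest) >= d_obs:
            count += 1
    p = (1 + count) / (params.n_perm + 1)
    med_obs, med_null = np.median(obs), np.median(pooled)
    direction = "closer" if med_obs < med_null else "farther" if med_obs > med_null else "none"
    return PermutationTestResult(float(d_obs), float(p), direction, params.n_perm)


def nearest_repeat_distance(
    intervals: pd.DataFrame,
    repeats: pd.DataFrame,
    classes: pd.Series | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Unsigned distance from each interval to its nearest repeat.

    Overlapping intervals score 0; intervals on chromosomes with no repeat
    get an infinite sentinel and are excluded from the per-class medians
    (with a warning). ``classes`` aligns positionally with ``intervals``.
    """
    if not len(repeats):
        raise ValueError("repeat set is empty")
    d = nearest_gap(intervals.reset_index(drop=True), repeats)
    if np.isinf(d).any():
        warnings.warn(
            f"{int(np.isinf(d).sum())} interval(s) on chromosomes without repeats "
            "excluded from medians",
            stacklevel=2,
        )
    medians: dict[str, float] = {}
    if classes is None:
        finite = d[np.isfinite(d)]
        medians["all"] = float(np.median(finite)) if len(finite) else float("nan")
    else:
        cl = np.asarray(classes)
        for c in pd.unique(cl):
            sub = d[(cl == c) & np.isfinite(d)]
            medians[str(c)] = float(np.median(sub)) if len(sub) else float("nan")
    return d, medians


def repeat_proximity_permutation_test(
    intervals: pd.DataFrame,
    repeats: pd.DataFrame,
    chrom_lengths: dict[str, int],
    params: PermutationParams,
) -> PermutationTestResult:
    """Do the intervals sit closer to repeats than random placement would?

    One-sided permutation test on the median nearest-repeat distance:
    p = (1 + #{permutation median <= observed median}) / (n_perm + 1).
    Infinite distances (chromosomes without repeats) are excluded from the
    medians.
    """
    obs, _ = nearest_repeat_distance(intervals, repeats)
    obs_med = float(np.median(obs[np.isfinite(obs)]))
    reps = permute_intervals(intervals, chrom_lengths, params)
    count = 0
    meds = []
    for r in reps:
        d = nearest_gap(r, repeats)
        med = float(np.median(d[np.isfinite(d)]))
        meds.append(med)
        if med <= obs_med:
            count += 1
    p = (1 + count) / (params.n_perm + 1)
    direction = "closer" if obs_med < np.median(meds) else "farther"
    return PermutationTestResult(obs_med, float(p), direction, params.n_perm)


DUPLICATE_CLASSES = {"tandem", "singleton", "wgd"}


def cns_by_duplicate_class(
    gene_classes: pd.Series,
    cns_counts: pd.Series,
    only_genes_with_cns: bool = True,
) -> pd.Series:
    """Mean CNS count per gene within each gene-duplication class.

    ``gene_classes`` maps gene id -> class (tandem | singleton | wgd);
    ``cns_counts`` maps gene id -> number of associated CNS (genes absent
    from it count 0). By default the mean is restricted to genes with at
    least one associated CNS; classes with no genes are reported missing.
    """
    bad = set(gene_classes.unique()) - DUPLICATE_CLASSES
    if bad:
        raise ValueError(f"unknown duplicate class label(s): {sorted(bad)}")
    counts = cns_counts.reindex(gene_classes.index).fillna(0)
    if only_genes_with_cns:
        keep = counts > 0
        counts, gene_classes = counts[keep], gene_classes[keep]
    out = counts.groupby(gene_classes).mean()
    return out.reindex(sorted(gene_classes.unique()))
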