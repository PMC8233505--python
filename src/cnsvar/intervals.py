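"""Lightweight genomic-interval utilities on pandas frames.

Coordinates are 0-based half-open throughout. Interval frames carry at least
``chrom``, ``start`` and ``end`` columns; an :class:`IntervalSet` additionally
declares chromosome lengths so permutation and placement operations know the
valid domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


@dataclass
class IntervalSet:
    """Stranded genomic intervals plus the chromosome-length table they live on."""

    df: pd.DataFrame
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in INTERVAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"interval frame lacks columns {missing}")
        if len(self.df):
            if (self.df["start"] >= self.df["end"]).any():
                raise ValueError("intervals must satisfy start < end")
            unknown = set(self.df["chrom"]) - set(self.chrom_lengths)
            if unknown:
                raise ValueError(f"chromosomes absent from length table: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.df)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or adjacent intervals are merged per chromosome."""
    if not len(df):
        return df.loc[:, INTERVAL_COLUMNS].copy()
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it share >=1 bp with any subject interval?

    Half-open semantics: [10,20) and [20,30) do not overlap.
    """
    result = np.zeros(len(query), dtype=bool)
    if not len(query) or not len(subject):
        return result
    merged = merge_intervals(subject)
    by_chrom = {c: g for c, g in merged.groupby("chrom")}
    for chrom, sub in query.groupby("chrom"):
        block = by_chrom.get(chrom)
        if block is None:
            continue
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        # merged intervals are sorted and disjoint: the only candidate overlapping
        # [qs,qe) is the last interval with start < qe; it overlaps iff its end > qs.
        idx = np.searchsorted(starts, qe, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[ok] = ends[idx[ok]] > qs[ok]
        result[query.index.get_indexer(sub.index)] = hit
    return result


def nearest_gap(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Unsigned gap (bp) from each query interval to the nearest subject interval.

    0 when overlapping; ``inf`` for query intervals on chromosomes with no
    subject interval.
    """
    out = np.full(len(query), np.inf)
    if not len(query) or not len(subject):
        return out
    merged = merge_intervals(subject)
    by_chrom = {c: g for c, g in merged.groupby("chrom")}
    for chrom, sub in query.groupby("chrom"):
        block = by_chrom.get(chrom)
        if block is None:
            continue
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        # predecessor (last interval starting before query end) and successor
        idx = np.searchsorted(starts, qe, side="left") - 1
        left = np.full(len(sub), np.inf)
        ok = idx >= 0
        left[ok] = np.maximum(qs[ok] - ends[idx[ok]], 0)
        overlap = ok & (ends[np.maximum(idx, 0)] > qs) if len(sub) else ok
        nxt = idx + 1
        right = np.full(len(sub), np.inf)
        ok2 = nxt < len(starts)
        right[ok2] = np.maximum(starts[nxt[ok2]] - qe[ok2], 0)
        d = np.minimum(left, right)
        d[overlap] = 0.0
        out[query.index.get_indexer(sub.index)] = d
    return out


def signed_gene_distances(
    query: pd.DataFrame, genes: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Signed distance to, and identity of, the nearest gene per query interval.

    Distance is 0 when the interval overlaps the gene extent; otherwise the
    boundary gap, negative when the interval lies 5' of the gene start in
    genomic coordinates and positive when it lies 3' of the gene end.
    Equidistant genes tie-break to the smaller gene start. Raises if a query
    chromosome has no annotated gene.
    """
    if not len(genes):
        raise ValueError("gene annotation is empty")
    dist = np.zeros(len(query))
    names = np.empty(len(query), dtype=object)
    by_chrom = {c: g.sort_values(["start", "end"]) for c, g in genes.groupby("chrom")}
    for chrom, sub in query.groupby("chrom"):
        block = by_chrom.get(chrom)
        if block is None or not len(block):
            raise ValueError(f"no genes annotated on chromosome {chrom!r}")
        gs = block["start"].to_numpy()
        ge = block["end"].to_numpy()
        gid = block["gene_id"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        sub_d = np.empty(len(sub))
        sub_g = np.empty(len(sub), dtype=object)
        for i, (s, e) in enumerate(zip(qs, qe)):
            # exhaustive scan: gene counts per chromosome are small, and genes
            # may overlap each other, which defeats bisection shortcuts
            gaps = np.where(
                (gs < e) & (ge > s), 0.0, np.where(ge <= s, s - ge, gs - e)
            )
            absg = np.abs(gaps)
            tied = np.flatnonzero(absg == absg.min())
            j = tied[np.argmin(gs[tied])]
            gap = gaps[j]
            # sign: negative 5' of gene start, positive 3' of gene end
            sub_d[i] = -gap if (gap > 0 and e <= gs[j]) else gap
            sub_g[i] = gid[j]
        pos = query.index.get_indexer(sub.index)
        dist[pos] = sub_d
        names[pos] = sub_g
    return names, dist
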