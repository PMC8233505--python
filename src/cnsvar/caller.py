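"""Locate reference CNS in accession assemblies and classify their variation.

Each conserved noncoding sequence (CNS) annotated on the reference genome is
searched for in an accession assembly by exact k-mer seeding followed by
semi-global alignment of the full element against a window around each seeded
candidate. A found CNS is *collinear* when the gene nearest its match maps,
through the ortholog table, back to the gene the CNS is associated with in the
reference; it is *positionally variable* (PosV) when it is found only in a
different gene context; it is *presence–absence variable* (PAV) when no match
passes the identity/coverage thresholds anywhere in the assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .intervals import signed_gene_distances

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class CnsRecord:
    """One reference CNS: coordinates, sequence and its associated gene."""

    cns_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    assoc_gene: str

    def __post_init__(self) -> None:
        if self.end - self.start < 15:
            raise ValueError(f"{self.cns_id}: CNS shorter than the 15 bp floor")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"{self.cns_id}: sequence length != end - start")


@dataclass
class CnsMatch:
    cns_id: str
    accession: str
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float

    @property
    def score(self) -> float:
        return self.identity * self.coverage


@dataclass
class CnsCall:
    cns_id: str
    accession: str
    status: str  # collinear | posv | pav
    best_match: CnsMatch | None = None
    acc_proximate_gene: str | None = None
    secondary_matches: list[CnsMatch] = field(default_factory=list)


@dataclass
class CallerParams:
    """Search thresholds.

    ``min_identity``/``min_coverage`` default to 0.90: permissive enough for
    intraspecific SNP divergence (~0.5%/bp) yet strict enough that chance hits
    of 15-mers in a ~100 Mb genome stay rare. ``seed_k`` = 11 < 15 guarantees
    every verbatim occurrence of a minimum-length CNS contains an exact seed.
    """

    min_identity: float = 0.90
    min_coverage: float = 0.90
    seed_k: int = 11
    max_candidates: int = 50

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.seed_k < 1:
            raise ValueError("seed_k must be positive")


class KmerIndex:
    """Sorted index of all exact k-mers of a genome (forward strand).

    k-mers are 2-bit packed into int64 keys; lookups are binary searches, so
    the index costs O(L log L) to build and O(log L) per probe.
    """

    def __init__(self, genome: dict[str, str], k: int):
        self.k = k
        self.genome = genome
        self.chroms = list(genome)
        codes = []
        offsets = [0]
        for name in self.chroms:
            codes.append(_CODE[np.frombuffer(genome[name].encode(), dtype=np.uint8)])
            offsets.append(offsets[-1] + len(codes[-1]))
        self.offsets = np.array(offsets, dtype=np.int64)
        cat = np.concatenate(codes) if codes else np.zeros(0, dtype=np.uint8)
        n = len(cat) - k + 1
        if n <= 0:
            self._keys = np.zeros(0, dtype=np.int64)
            self._pos = np.zeros(0, dtype=np.int64)
            return
        keys = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            c = cat[j : n + j].astype(np.int64)
            keys = (keys << 2) | (c & 3)
            valid &= c != 255
        # drop windows containing non-ACGT bases and windows spanning a
        # chromosome boundary
        for b in self.offsets[1:-1]:
            valid[max(0, b - k + 1) : b] = False
        pos = np.flatnonzero(valid)
        keys = keys[pos]
        order = np.argsort(keys, kind="stable")
        self._keys = keys[order]
        self._pos = pos[order]

    @staticmethod
    def encode(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(keys, query offsets) for every valid k-mer of ``seq``."""
        c = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        n = len(c) - k + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        keys = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            x = c[j : n + j].astype(np.int64)
            keys = (keys << 2) | (x & 3)
            valid &= x != 255
        off = np.flatnonzero(valid)
        return keys[off], off

    def hits(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Global genome positions sharing an exact k-mer with ``seq``.

        Returns (global candidate diagonal starts, seed-hit counts are implied
        by repetition).
        """
        keys, qoff = self.encode(seq, self.k)
        if not len(keys):
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        lo = np.searchsorted(self._keys, keys, side="left")
        hi = np.searchsorted(self._keys, keys, side="right")
        total = int((hi - lo).sum())
        gpos = np.empty(total, dtype=np.int64)
        goff = np.empty(total, dtype=np.int64)
        at = 0
        for l, h, o in zip(lo, hi, qoff):
            m = h - l
            if m:
                gpos[at : at + m] = self._pos[l:h]
                goff[at : at + m] = o
                at += m
        return gpos, goff

    def to_chrom(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return self.chroms[i], int(gpos - self.offsets[i])


def _align_window(query: str, window: str) -> tuple[int, int, int]:
    """Best semi-global alignment of ``query`` inside ``window``.

    Returns (edit distance, target start, target end) of the best location;
    end gaps on the window are free, the query is consumed in full.
    """
    res = edlib.align(query, window, mode="HW", task="locations")
    s, e = res["locations"][0]
    if s is None:  # edlib omits the start for some degenerate alignments
        s = max(0, e + 1 - len(query))
    return res["editDistance"], s, e + 1


def locate_cns(
    cns: CnsRecord, index: KmerIndex, params: CallerParams | None = None, accession: str = ""
) -> list[CnsMatch]:
    """Seed-and-extend search for one CNS across an indexed assembly.

    Every genomic position sharing at least one exact ``seed_k``-mer with the
    CNS (either strand) nominates a candidate diagonal; candidates are merged
    when closer than the element length, and each surviving candidate window
    is aligned semi-globally against the full element. Matches below
    ``min_identity`` or ``min_coverage`` are discarded; the list is sorted by
    score descending, ties broken by (chrom, start).
    """
    params = params or CallerParams()
    m = len(cns.sequence)
    if m < params.seed_k:
        raise ValueError(f"{cns.cns_id}: CNS shorter than seed_k={params.seed_k}")
    pad = max(8, m // 8)
    matches: list[CnsMatch] = []
    for strand, q in (("+", cns.sequence.upper()), ("-", revcomp(cns.sequence.upper()))):
        gpos, goff = index.hits(q)
        if not len(gpos):
            continue
        diag = np.sort(gpos - goff)
        # cluster candidate starts closer than the element length, weight by
        # seed support so repetitive junk cannot crowd out the true site; a
        # cluster's window spans all its member diagonals (internal repeats
        # inside an element spread seeds across nearby diagonals)
        clusters: list[tuple[int, int, int]] = []  # (min start, max start, support)
        lo = hi = int(diag[0])
        support = 1
        for d in diag[1:]:
            if d - hi < m:
                hi = int(d)
                support += 1
            else:
                clusters.append((lo, hi, support))
                lo = hi = int(d)
                support = 1
        clusters.append((lo, hi, support))
        clusters.sort(key=lambda t: -t[2])
        for start, last, _support in clusters[: params.max_candidates]:
            chrom, pos = index.to_chrom(start)
            seq = index.genome[chrom]
            ws = max(0, pos - pad)
            we = min(len(seq), pos + (last - start) + m + pad)
            dist, ts, te = _align_window(q, seq[ws:we])
            if dist < 0:
                continue
            identity = max(0.0, 1.0 - dist / m)
            coverage = min(1.0, (te - ts) / m)
            if identity >= params.min_identity and coverage >= params.min_coverage:
                matches.append(
                    CnsMatch(
                        cns.cns_id, accession, chrom, ws + ts, ws + te, strand, identity, coverage
                    )
                )
    # deduplicate overlapping reports of the same site (e.g. adjacent clusters)
    matches.sort(key=lambda x: (-x.score, x.chrom, x.start))
    kept: list[CnsMatch] = []
    for cand in matches:
        dup = any(
            k.chrom == cand.chrom and cand.start < k.end and k.start < cand.end for k in kept
        )
        if not dup:
            kept.append(cand)
    return kept


def proximate_gene(
    chrom: str, start: int, end: int, genes: pd.DataFrame
) -> tuple[str, int]:
    """Nearest gene to an interval with a signed boundary distance.

    Distance 0 when the interval overlaps the gene extent; otherwise the
    minimal boundary gap, negative 5' of the gene start (genomic coordinates),
    positive 3' of the gene end. Ties break to the smaller gene start.
    """
    q = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
    names, dists = signed_gene_distances(q, genes)
    return str(names[0]), int(dists[0])


def classify_cns(
    cns: CnsRecord,
    matches: list[CnsMatch],
    acc_to_ref: dict[str, str],
    acc_genes: pd.DataFrame,
    accession: str = "",
) -> CnsCall:
    """Assign collinear / posv / pav from the matches of one CNS.

    Collinearity takes priority over positional variation: if any qualifying
    match sits next to the orthologous associated gene, the CNS is collinear
    there and any other occurrences become secondary matches.
    """
    if not matches:
        return CnsCall(cns.cns_id, accession, "pav")
    genes_by_chrom = set(acc_genes["chrom"]) if len(acc_genes) else set()
    annotated: list[tuple[CnsMatch, str | None]] = []
    for match in matches:
        if match.chrom not in genes_by_chrom:
            annotated.append((match, None))  # no genes there: non-syntenic
            continue
        gene, _dist = proximate_gene(match.chrom, match.start, match.end, acc_genes)
        annotated.append((match, gene))
    for match, gene in annotated:
        if gene is None:
            continue
        ref_gene = acc_to_ref.get(gene)
        if ref_gene is None:
            logger.warning(
                "accession gene %s absent from ortholog table; treated as non-syntenic", gene
            )
            continue
        if ref_gene == cns.assoc_gene:
            others = [m for m, _ in annotated if m is not match]
            return CnsCall(cns.cns_id, accession, "collinear", match, gene, others)
    best, best_gene = annotated[0]
    others = [m for m, _ in annotated[1:]]
    return CnsCall(cns.cns_id, accession, "posv", best, best_gene, others)


def call_accession(
    cns_records: list[CnsRecord],
    genome: dict[str, str],
    acc_genes: pd.DataFrame,
    orthologs: pd.DataFrame,
    params: CallerParams | None = None,
    accession: str = "acc",
) -> tuple[list[CnsCall], dict[str, int]]:
    """Call every reference CNS against one accession assembly.

    Returns the calls plus a summary ``{n_pav, n_posv, n_collinear}``; the
    three counts always partition the CNS set.
    """
    params = params or CallerParams()
    ids = [c.cns_id for c in cns_records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cns_id in input CNS set")
    acc_to_ref = dict(zip(orthologs["acc_gene_id"], orthologs["ref_gene_id"]))
    index = KmerIndex(genome, params.seed_k)
    calls = []
    for cns in cns_records:
        matches = locate_cns(cns, index, params, accession)
        calls.append(classify_cns(cns, matches, acc_to_ref, acc_genes, accession))
    summary = {
        "n_pav": sum(c.status == "pav" for c in calls),
        "n_posv": sum(c.status == "posv" for c in calls),
        "n_collinear": sum(c.status == "collinear" for c in calls),
    }
    return calls, summary


def calls_to_frame(calls: list[CnsCall]) -> pd.DataFrame:
    """Flatten calls into the calls.tsv layout."""
    rows = []
    for c in calls:
        m = c.best_match
        rows.append(
            (
                c.accession,
                c.cns_id,
                c.status,
                m.chrom if m else "",
                m.start if m else -1,
                m.end if m else -1,
                m.strand if m else ".",
                round(m.identity, 6) if m else float("nan"),
                round(m.coverage, 6) if m else float("nan"),
                c.acc_proximate_gene or "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "cns_id", "status", "chrom", "start", "end",
            "strand", "identity", "coverage", "acc_proximate_gene",
        ],
    )


def phastcons_filter(scores) -> bool:
    """Conservation-profile gate for candidate elements.

    True iff the per-base score window contains a run of at least seven
    consecutive positions scoring above 0.82 and no run longer than twelve
    consecutive positions scoring below 0.55.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score window")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("scores must lie in [0, 1]")

    def longest_run(mask: np.ndarray) -> int:
        best = run = 0
        for v in mask:
            run = run + 1 if v else 0
            best = max(best, run)
        return best

    return longest_run(s > 0.82) >= 7 and longest_run(s < 0.55) <= 12
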