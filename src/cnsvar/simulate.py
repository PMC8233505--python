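"""Synthetic genomes with planted CNS variation.

The generator emulates the study design the package analyses: a multi-
chromosome reference carrying genes and short (15–150 bp) conserved noncoding
sequences placed in intergenic space near genes, plus accession assemblies
derived from the reference by background SNPs/indels, planted CNS deletions
(presence–absence variation, PAV) and planted CNS relocations (positional
variation, PosV), optionally biased to land near annotated repeats. Auxiliary
tracks — accessible-chromatin peaks covering a configurable CNS fraction,
differential-expression labels with configurable odds conditioned on per-gene
CNS gain/loss, and codon alignments with target synonymous/nonsynonymous
diversity — make every downstream statistic testable against known truth.

All randomness flows from ``SynthConfig.seed`` through independent
``numpy.random.Generator`` streams, so outputs are byte-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genome_io
from .caller import CallerParams, CnsRecord, KmerIndex, locate_cns, revcomp
from .intervals import signed_gene_distances

BASES = np.array(list("ACGT"))

# stream labels keeping accession / peaks / labels / alignments independent
_S_REF, _S_ACC, _S_PEAK, _S_DE, _S_ALN = 11, 13, 17, 19, 23


@dataclass
class SynthConfig:
    """Study-condition knobs for the synthetic genomes.

    Defaults follow the scaled-down desk conditions used throughout the test
    suite: a 2 x 1 Mb reference with 500 genes and 2,000 CNS, five accessions
    each carrying 50 planted PAV and 100 planted PosV events, background SNP
    rate 0.005/bp outside CNS bodies, and untouched CNS bodies
    (``cns_snp_rate`` = 0) so recovery tests isolate the caller's thresholds.
    """

    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_genes: int = 500
    gene_len: int = 1_000
    n_cns: int = 2_000
    cns_len_range: tuple[int, int] = (15, 150)
    n_accessions: int = 5
    snp_rate: float = 0.005
    indel_rate: float = 5e-4
    cns_snp_rate: float = 0.0
    pav_per_accession: int = 50
    posv_per_accession: int = 100
    te_bias: float = 0.0
    te_window: int = 500
    n_repeats: int = 200
    repeat_len_range: tuple[int, int] = (100, 500)
    n_peaks: int = 350
    peak_len_range: tuple[int, int] = (150, 350)
    peak_cover_collinear: float = 0.14
    peak_cover_posv: float = 0.067
    de_base_rate: float = 0.10
    de_odds_gain_up: float = 4.0
    de_odds_loss_down: float = 4.0
    screen_identity: float = 0.90
    assoc_margin: int = 100
    max_retries: int = 100
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_chroms=self.n_chroms, chrom_len=self.chrom_len, n_genes=self.n_genes,
            gene_len=self.gene_len, n_cns=self.n_cns, n_accessions=self.n_accessions,
            pav_per_accession=self.pav_per_accession,
            posv_per_accession=self.posv_per_accession, te_window=self.te_window,
            n_repeats=self.n_repeats, n_peaks=self.n_peaks,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        rates = dict(
            snp_rate=self.snp_rate, indel_rate=self.indel_rate,
            cns_snp_rate=self.cns_snp_rate, te_bias=self.te_bias,
            peak_cover_collinear=self.peak_cover_collinear,
            peak_cover_posv=self.peak_cover_posv, de_base_rate=self.de_base_rate,
        )
        for name, v in rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cns_len_range[0] < 15:
            raise ValueError("minimum CNS length is 15 bp")
        if self.cns_len_range[0] > self.cns_len_range[1]:
            raise ValueError("cns_len_range must be (min, max) with min <= max")
        if self.pav_per_accession + self.posv_per_accession > self.n_cns:
            raise ValueError("planted variant counts exceed the CNS universe")
        if self.de_odds_gain_up <= 0 or self.de_odds_loss_down <= 0:
            raise ValueError("odds ratios must be positive")
        footprint = self.n_genes * self.gene_len + self.n_cns * self.cns_len_range[1]
        if footprint > 0.9 * self.n_chroms * self.chrom_len:
            raise ValueError("infeasible packing: features exceed chromosome space")


@dataclass
class ReferenceBundle:
    config: SynthConfig
    genome: dict[str, str]
    genes: pd.DataFrame       # chrom, start, end, strand, gene_id
    cns: pd.DataFrame         # chrom, start, end, strand, cns_id, gene_id, sequence
    repeats: pd.DataFrame     # chrom, start, end, name

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def cns_records(self) -> list[CnsRecord]:
        return [
            CnsRecord(r.cns_id, r.chrom, r.start, r.end, r.sequence, r.gene_id)
            for r in self.cns.itertuples(index=False)
        ]


@dataclass
class AccessionBundle:
    name: str
    index: int
    genome: dict[str, str]
    genes: pd.DataFrame       # chrom, start, end, strand, gene_id (accession ids)
    orthologs: pd.DataFrame   # ref_gene_id, acc_gene_id
    truth: pd.DataFrame       # accession, cns_id, true_status, new_chrom, new_start
    cns_acc: pd.DataFrame     # accession coordinates of surviving CNS + status
    repeats: pd.DataFrame = None  # repeat annotation lifted to accession coordinates
    config: SynthConfig = field(repr=False, default=None)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


def _split_counts(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across weighted bins."""
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_reference(config: SynthConfig) -> ReferenceBundle:
    """Build the reference: genome, genes, CNS (with nearest-gene assignment),
    repeats.

    Genes are placed uniformly without overlap; each CNS is anchored near a
    random gene at a geometric(mean 300 bp) boundary gap on either side and
    never overlaps genes, repeats or other CNS. After placement every CNS is
    screened for spurious second occurrences (>= ``screen_identity`` identity
    elsewhere in the reference); colliding loci are re-randomised so the
    planted truth labels are unambiguous.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _S_REF])
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    lengths = {c: config.chrom_len for c in chroms}
    codes = {c: _random_seq(rng, config.chrom_len) for c in chroms}
    occupied = {c: np.zeros(config.chrom_len, dtype=bool) for c in chroms}

    # genes: largest-remainder split across chromosomes, uniform non-overlapping
    per_chrom = _split_counts(config.n_genes, np.array([lengths[c] for c in chroms], float))
    gene_rows = []
    gid = 0
    for c, n in zip(chroms, per_chrom):
        free = lengths[c] - n * config.gene_len
        if free < 0:
            raise ValueError("infeasible packing: genes exceed chromosome space")
        offs = np.sort(rng.integers(0, free + 1, n))
        starts = offs + np.arange(n) * config.gene_len
        for s in starts:
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((c, int(s), int(s) + config.gene_len, strand, f"g{gid:05d}"))
            occupied[c][s : s + config.gene_len] = True
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"])

    gene_arrays = {
        c: (g["start"].to_numpy(), g["end"].to_numpy(), g["gene_id"].to_numpy())
        for c, g in genes.groupby("chrom")
    }

    def margin_ok(chrom: str, start: int, end: int) -> tuple[bool, str]:
        """Nearest gene must beat the runner-up by ``assoc_margin`` bp, so
        background indels cannot flip the proximate-gene assignment."""
        gs, ge, gid = gene_arrays[chrom]
        gaps = np.where((gs < end) & (ge > start), 0, np.where(ge <= start, start - ge, gs - end))
        absg = np.abs(gaps)
        order = np.argsort(absg, kind="stable")
        nearest = gid[order[0]]
        if len(order) > 1 and absg[order[1]] - absg[order[0]] < config.assoc_margin:
            return False, nearest
        return True, nearest

    # CNS: anchored near genes, non-overlapping with everything placed so far
    cns_rows = []
    for i in range(config.n_cns):
        length = int(rng.integers(config.cns_len_range[0], config.cns_len_range[1] + 1))
        placed = False
        for _ in range(config.max_retries):
            g = genes.iloc[int(rng.integers(0, len(genes)))]
            gap = int(rng.geometric(1 / 300))
            if rng.random() < 0.5:
                start = int(g.end) + gap
            else:
                start = int(g.start) - gap - length
            end = start + length
            if start < 0 or end > lengths[g.chrom]:
                continue
            if occupied[g.chrom][start:end].any():
                continue
            if not margin_ok(g.chrom, start, end)[0]:
                continue
            occupied[g.chrom][start:end] = True
            strand = "+" if rng.random() < 0.5 else "-"
            cns_rows.append((g.chrom, start, end, strand, f"cns{i:05d}"))
            placed = True
            break
        if not placed:
            raise ValueError("infeasible packing: could not place CNS without overlap")
    cns = pd.DataFrame(cns_rows, columns=["chrom", "start", "end", "strand", "cns_id"])

    # repeats: anywhere outside genes and CNS
    rep_rows = []
    for i in range(config.n_repeats):
        length = int(rng.integers(config.repeat_len_range[0], config.repeat_len_range[1] + 1))
        for _ in range(config.max_retries):
            c = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, lengths[c] - length + 1))
            if occupied[c][start : start + length].any():
                continue
            occupied[c][start : start + length] = True
            rep_rows.append((c, start, start + length, f"rep{i:04d}"))
            break
        else:
            raise ValueError("infeasible packing: could not place repeat")
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "name"])

    genome = {c: _codes_to_str(codes[c]) for c in chroms}
    if len(cns):
        cns["sequence"] = [
            genome[r.chrom][r.start : r.end] for r in cns.itertuples(index=False)
        ]
        _screen_cns_uniqueness(genome, codes, cns, config, rng)
        names, _ = signed_gene_distances(cns, genes)
        cns.insert(5, "gene_id", names)
    else:
        cns = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "cns_id", "gene_id", "sequence"]
        )
    return ReferenceBundle(replace(config), genome, genes, cns, repeats)


def _screen_cns_uniqueness(
    genome: dict[str, str],
    codes: dict[str, np.ndarray],
    cns: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
) -> None:
    """Re-randomise CNS loci whose sequence recurs elsewhere in the reference.

    A planted-absence truth label is only meaningful if the excised element
    has no second copy the caller would accept; loci with a second occurrence
    at >= ``screen_identity`` identity (default: the caller's acceptance
    threshold) are rewritten with fresh random bases until unique (bounded
    passes). Mutates ``genome``/``codes``/``cns``. Screening much below the
    caller threshold is infeasible for 15 bp elements: near-matches two edits
    away are expected by chance in megabase genomes.
    """
    params = CallerParams(min_identity=config.screen_identity, min_coverage=0.5)
    for _pass in range(15):
        index = KmerIndex(genome, params.seed_k)
        colliding = []
        for pos, row in enumerate(cns.itertuples(index=False)):
            rec = CnsRecord(row.cns_id, row.chrom, row.start, row.end, row.sequence, "na")
            hits = locate_cns(rec, index, params)
            extra = [
                h for h in hits
                if not (h.chrom == row.chrom and h.start < row.end and row.start < h.end)
            ]
            if extra:
                colliding.append(pos)
        if not colliding:
            return
        for pos in colliding:
            row = cns.iloc[pos]
            fresh = _random_seq(rng, row.end - row.start)
            codes[row.chrom][row.start : row.end] = fresh
            genome[row.chrom] = _codes_to_str(codes[row.chrom])
            cns.iat[pos, cns.columns.get_loc("sequence")] = genome[row.chrom][
                row.start : row.end
            ]
    raise RuntimeError("could not make all CNS sequences unique within retry budget")


def reference_score_track(ref: ReferenceBundle, flank: int = 10) -> pd.DataFrame:
    """Per-base conservation scores over CNS bodies (+ flanks).

    Scores inside each CNS body are drawn above the 0.82 element threshold;
    flanking bases score low. Positions not listed carry background score.
    """
    rng = np.random.default_rng([ref.config.seed, _S_REF, 2])
    scores: dict[tuple[str, int], float] = {}
    body: dict[tuple[str, int], bool] = {}
    for r in ref.cns.itertuples(index=False):
        lo = max(0, r.start - flank)
        hi = min(ref.chrom_lengths[r.chrom], r.end + flank)
        for p in range(lo, hi):
            inside = r.start <= p < r.end
            if body.get((r.chrom, p)):
                continue  # body score of a neighbouring element wins over flank
            if inside:
                scores[(r.chrom, p)] = round(0.83 + 0.16 * rng.random(), 4)
                body[(r.chrom, p)] = True
            elif (r.chrom, p) not in scores:
                scores[(r.chrom, p)] = round(0.5 * rng.random(), 4)
    rows = [(c, p, s) for (c, p), s in sorted(scores.items())]
    return pd.DataFrame(rows, columns=["chrom", "pos", "score"])


class _EditList:
    """Ordered edits on one chromosome with reference->accession coordinate maps."""

    def __init__(self) -> None:
        self.ops: list[tuple[int, int, str]] = []  # (pos, ref_len, alt)

    def add(self, pos: int, ref_len: int, alt: str) -> None:
        self.ops.append((pos, ref_len, alt))

    def finalize(self) -> None:
        self.ops.sort(key=lambda t: (t[0], t[1]))
        self._pos = np.array([o[0] for o in self.ops], dtype=np.int64)
        self._rl = np.array([o[1] for o in self.ops], dtype=np.int64)
        deltas = np.array([len(o[2]) - o[1] for o in self.ops], dtype=np.int64)
        self._cum = np.concatenate([[0], np.cumsum(deltas)])

    def apply(self, seq: str) -> str:
        parts = []
        last = 0
        for pos, rl, alt in self.ops:
            parts.append(seq[last:pos])
            parts.append(alt)
            last = pos + rl
        parts.append(seq[last:])
        return "".join(parts)

    def map_coord(self, x: int, before_insertions: bool = False) -> int:
        """Accession image of reference coordinate ``x``.

        Insertions at exactly ``x`` land before its image (so the image of an
        interval *start* follows them) unless ``before_insertions`` is set
        (appropriate for interval *ends* and for the start of an inserted
        element itself). A coordinate inside a deleted span collapses to the
        span's image.
        """
        i = int(np.searchsorted(self._pos, x, side="left"))
        out = x + int(self._cum[i])
        if not before_insertions:
            j = i
            while j < len(self._pos) and self._pos[j] == x and self._rl[j] == 0:
                out += int(self._cum[j + 1] - self._cum[j])
                j += 1
        # collapse if x lies inside the previous op's deleted span
        if i > 0:
            p, rl = int(self._pos[i - 1]), int(self._rl[i - 1])
            if rl and p + rl > x:
                out = p + int(self._cum[i - 1])
        return out


class _GeometryFlip(Exception):
    """A planted edit changed some element's proximate-gene assignment."""


def derive_accession(
    ref: ReferenceBundle, config: SynthConfig, accession_index: int
) -> AccessionBundle:
    """Derive one accession genome from the reference.

    PAV CNS are excised; PosV CNS are excised and reinserted at a resampled
    intergenic site (within ``te_window`` of a repeat with probability
    ``te_bias``, never at a site whose nearest gene is the element's own
    associated gene); background SNPs and short indels are applied outside
    CNS bodies; ``cns_snp_rate`` optionally mutates surviving CNS copies.

    The coordinate distortion of excised elements can flip a nearby CNS's
    proximate-gene assignment, which would make the planted truth label
    wrong; draws producing such a flip are rejected and resampled so every
    truth label agrees with the accession's final geometry.
    """
    config.validate()
    for attempt in range(config.max_retries):
        rng = np.random.default_rng([config.seed, _S_ACC, accession_index, attempt])
        try:
            return _derive_attempt(ref, config, accession_index, rng)
        except _GeometryFlip:
            continue
    raise RuntimeError(
        f"could not derive accession {accession_index} without a proximate-gene flip"
    )


def _derive_attempt(
    ref: ReferenceBundle,
    config: SynthConfig,
    accession_index: int,
    rng: np.random.Generator,
) -> AccessionBundle:
    name = f"acc{accession_index:02d}"
    chroms = list(ref.genome)
    lengths = ref.chrom_lengths
    n_cns = len(ref.cns)
    n_var = config.pav_per_accession + config.posv_per_accession
    if n_var > n_cns:
        raise ValueError("planted variant counts exceed the CNS universe")
    var = rng.choice(n_cns, n_var, replace=False) if n_var else np.array([], dtype=int)
    pav_idx = set(var[: config.pav_per_accession].tolist())
    posv_idx = set(var[config.pav_per_accession :].tolist())

    cns_mask = {c: np.zeros(lengths[c], dtype=bool) for c in chroms}
    for r in ref.cns.itertuples(index=False):
        cns_mask[r.chrom][r.start : r.end] = True
    claim = {c: m.copy() for c, m in cns_mask.items()}
    gene_mask = {c: np.zeros(lengths[c], dtype=bool) for c in chroms}
    for r in ref.genes.itertuples(index=False):
        gene_mask[r.chrom][r.start : r.end] = True

    edits = {c: _EditList() for c in chroms}
    truth_rows = []

    # --- planted deletions (PAV)
    for pos in sorted(pav_idx):
        r = ref.cns.iloc[pos]
        edits[r.chrom].add(int(r.start), int(r.end - r.start), "")
        truth_rows.append((name, r.cns_id, "pav", "", -1))

    # --- planted relocations (PosV)
    landing_mask = {c: np.zeros(lengths[c], dtype=bool) for c in chroms}
    landings = []  # (cns row position, chrom, start, inserted sequence)
    chrom_w = np.array([lengths[c] for c in chroms], float)
    gene_arrays = {
        c: (g["start"].to_numpy(), g["end"].to_numpy(), g["gene_id"].to_numpy())
        for c, g in ref.genes.groupby("chrom")
    }
    for pos in sorted(posv_idx):
        r = ref.cns.iloc[pos]
        length = int(r.end - r.start)
        site = None
        for _ in range(config.max_retries):
            # a landing is an insertion at a reference point: it consumes no
            # reference space, so all distances are measured from that point
            corridor = None
            if len(ref.repeats) and rng.random() < config.te_bias:
                rep = ref.repeats.iloc[int(rng.integers(0, len(ref.repeats)))]
                gap = int(rng.integers(0, config.te_window + 1))
                if rng.random() < 0.5:
                    p = int(rep.end) + gap
                    corridor = (int(rep.end), p)
                else:
                    p = int(rep.start) - gap
                    corridor = (p, int(rep.start))
                chrom = rep.chrom
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=chrom_w / chrom_w.sum()))]
                p = int(rng.integers(1, lengths[chrom]))
            if not 1 <= p <= lengths[chrom] - 1:
                continue
            blocked = (
                gene_mask[chrom][p - 1 : p + 1].any()   # would split a gene
                or cns_mask[chrom][p - 1 : p + 1].any()  # or another element
                or landing_mask[chrom][p - 1 : p + 1].any()
            )
            if corridor is not None and landing_mask[chrom][corridor[0] : corridor[1]].any():
                blocked = True  # an earlier insertion already sits in the gap
            if blocked:
                continue
            gs = gene_arrays[chrom]
            gaps = np.where(gs[1] <= p, p - gs[1], gs[0] - p)
            absg = np.abs(gaps)
            order = np.argsort(absg, kind="stable")
            if len(order) > 1 and absg[order[1]] - absg[order[0]] < config.assoc_margin:
                continue  # ambiguous proximate gene; resample
            if gs[2][order[0]] == r.gene_id:
                continue  # would still look collinear; resample
            site = (chrom, p)
            break
        if site is None:
            raise RuntimeError(f"could not place PosV landing for {r.cns_id}")
        chrom, start = site
        landing_mask[chrom][start] = True
        if corridor is not None:
            # reserve the gap to the anchoring repeat so no later insertion
            # stretches the planted repeat proximity
            landing_mask[chrom][corridor[0] : corridor[1]] = True
        claim[chrom][start] = True
        seq = str(r.sequence)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        edits[r.chrom].add(int(r.start), length, "")
        landings.append((pos, chrom, start, seq))
        truth_rows.append((name, r.cns_id, "posv", chrom, start))

    # --- optional mutation of surviving CNS copies
    mutated_landing_seq = {}
    if config.cns_snp_rate > 0:
        for i, (pos, chrom, start, seq) in enumerate(landings):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = np.flatnonzero(rng.random(len(arr)) < config.cns_snp_rate)
            for h in hit:
                arr[h] = ord(_other_base(chr(arr[h]), rng))
            mutated_landing_seq[i] = arr.tobytes().decode()
        for pos, r in enumerate(ref.cns.itertuples(index=False)):
            if pos in pav_idx or pos in posv_idx:
                continue
            body = ref.genome[r.chrom][r.start : r.end]
            hit = np.flatnonzero(rng.random(len(body)) < config.cns_snp_rate)
            for h in hit:
                p = int(r.start + h)
                edits[r.chrom].add(p, 1, _other_base(body[h], rng))
                claim[r.chrom][p] = True
    for i, (pos, chrom, start, seq) in enumerate(landings):
        edits[chrom].add(start, 0, mutated_landing_seq.get(i, seq))

    # --- background SNPs and indels outside CNS bodies
    for c in chroms:
        free = ~claim[c]
        snp_pos = np.flatnonzero((rng.random(lengths[c]) < config.snp_rate) & free)
        seq = ref.genome[c]
        for p in snp_pos:
            edits[c].add(int(p), 1, _other_base(seq[p], rng))
        claim[c][snp_pos] = True
        if config.indel_rate > 0:
            ind_pos = np.flatnonzero((rng.random(lengths[c]) < config.indel_rate) & ~claim[c])
            for p in ind_pos:
                ilen = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # insertion before p
                    edits[c].add(int(p), 0, _codes_to_str(_random_seq(rng, ilen)))
                else:
                    if p + ilen > lengths[c] or claim[c][p : p + ilen].any():
                        continue
                    edits[c].add(int(p), ilen, "")
                    claim[c][p : p + ilen] = True

    genome = {}
    for c in chroms:
        edits[c].finalize()
        genome[c] = edits[c].apply(ref.genome[c])

    acc_genes = ref.genes.copy()
    acc_genes["start"] = [
        edits[r.chrom].map_coord(int(r.start)) for r in ref.genes.itertuples(index=False)
    ]
    acc_genes["end"] = [
        edits[r.chrom].map_coord(int(r.end), before_insertions=True)
        for r in ref.genes.itertuples(index=False)
    ]
    acc_genes["gene_id"] = [f"{name}_{g}" for g in ref.genes["gene_id"]]
    orthologs = pd.DataFrame(
        {"ref_gene_id": ref.genes["gene_id"].to_numpy(), "acc_gene_id": acc_genes["gene_id"].to_numpy()}
    )

    # accession coordinates of surviving CNS copies
    acc_rows = []
    landing_by_pos = {pos: (chrom, start, seq) for pos, chrom, start, seq in landings}
    for pos, r in enumerate(ref.cns.itertuples(index=False)):
        if pos in pav_idx:
            continue
        if pos in posv_idx:
            chrom, start, seq = landing_by_pos[pos]
            s = edits[chrom].map_coord(start, before_insertions=True)
            acc_rows.append((r.cns_id, chrom, s, s + len(seq), "posv"))
        else:
            s = edits[r.chrom].map_coord(int(r.start))
            e = edits[r.chrom].map_coord(int(r.end), before_insertions=True)
            acc_rows.append((r.cns_id, r.chrom, s, e, "collinear"))
    cns_acc = pd.DataFrame(acc_rows, columns=["cns_id", "chrom", "start", "end", "status"])

    truth = pd.DataFrame(
        truth_rows, columns=["accession", "cns_id", "true_status", "new_chrom", "new_start"]
    )
    # report landing coordinates in the accession frame
    if len(truth):
        mapped = []
        for r in truth.itertuples(index=False):
            if r.true_status == "posv":
                mapped.append(
                    edits[r.new_chrom].map_coord(int(r.new_start), before_insertions=True)
                )
            else:
                mapped.append(-1)
        truth["new_start"] = mapped
    acc_repeats = ref.repeats.copy()
    if len(acc_repeats):
        acc_repeats["start"] = [
            edits[r.chrom].map_coord(int(r.start)) for r in ref.repeats.itertuples(index=False)
        ]
        acc_repeats["end"] = [
            edits[r.chrom].map_coord(int(r.end), before_insertions=True)
            for r in ref.repeats.itertuples(index=False)
        ]
    bundle = AccessionBundle(
        name, accession_index, genome, acc_genes, orthologs, truth, cns_acc,
        acc_repeats, config,
    )
    _validate_geometry(ref, bundle)
    return bundle


def _validate_geometry(ref: ReferenceBundle, acc: AccessionBundle) -> None:
    """Planted truth must agree with the accession's final geometry.

    Every retained (collinear) CNS must still have its associated gene as
    proximate gene in accession coordinates; every PosV landing must not.
    """
    if not len(acc.cns_acc):
        return
    assoc = ref.cns.set_index("cns_id")["gene_id"]
    acc_to_ref = dict(zip(acc.orthologs["acc_gene_id"], acc.orthologs["ref_gene_id"]))
    names, _ = signed_gene_distances(acc.cns_acc, acc.genes)
    for (row, nearest) in zip(acc.cns_acc.itertuples(index=False), names):
        ref_gene = acc_to_ref[nearest]
        if row.status == "collinear" and ref_gene != assoc[row.cns_id]:
            raise _GeometryFlip(row.cns_id)
        if row.status == "posv" and ref_gene == assoc[row.cns_id]:
            raise _GeometryFlip(row.cns_id)


def _other_base(base: str, rng: np.random.Generator) -> str:
    alts = [b for b in "ACGT" if b != base.upper()]
    return alts[int(rng.integers(0, 3))]


def truth_status(truth: pd.DataFrame, cns_ids, accession: str) -> pd.Series:
    """Full per-CNS status vector for one accession (implicit collinear)."""
    sub = truth[truth["accession"] == accession]
    s = pd.Series("collinear", index=pd.Index(cns_ids, name="cns_id"))
    s.loc[sub["cns_id"].to_numpy()] = sub["true_status"].to_numpy()
    return s


def generate_peaks(acc: AccessionBundle, config: SynthConfig) -> pd.DataFrame:
    """Accessible-chromatin peaks on one accession genome.

    Exactly ``round(peak_cover_collinear * n_collinear)`` collinear CNS and
    ``round(peak_cover_posv * n_posv)`` PosV CNS are covered by a dedicated
    peak (clipped so it touches no other CNS); the remaining peaks up to
    ``n_peaks`` are placed uniformly, avoiding every CNS, so the planted
    coverage fractions are exact.
    """
    for f in (config.peak_cover_collinear, config.peak_cover_posv):
        if not 0 <= f <= 1:
            raise ValueError("peak coverage fractions must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, _S_PEAK, acc.index])
    lengths = acc.chrom_lengths
    cns_sorted = acc.cns_acc.sort_values(["chrom", "start"])
    starts_by_chrom = {
        c: (g["start"].to_numpy(), g["end"].to_numpy())
        for c, g in cns_sorted.groupby("chrom")
    }
    rows = []

    def cover(sub: pd.DataFrame, fraction: float) -> None:
        n_cov = int(round(fraction * len(sub)))
        if n_cov == 0:
            return
        chosen = sub.iloc[rng.choice(len(sub), n_cov, replace=False)]
        for r in chosen.itertuples(index=False):
            a = int(rng.integers(20, 151))
            b = int(rng.integers(20, 151))
            ss, ee = starts_by_chrom[r.chrom]
            # clip so the peak touches no other CNS
            i = np.searchsorted(ss, r.start)
            left_lim = ee[i - 1] if i > 0 else 0
            j = np.searchsorted(ss, r.end, side="left")
            right_lim = ss[j] if j < len(ss) else lengths[r.chrom]
            start = max(int(r.start) - a, int(left_lim), 0)
            end = min(int(r.end) + b, int(right_lim), lengths[r.chrom])
            rows.append((r.chrom, start, end))

    cover(acc.cns_acc[acc.cns_acc["status"] == "collinear"], config.peak_cover_collinear)
    cover(acc.cns_acc[acc.cns_acc["status"] == "posv"], config.peak_cover_posv)

    n_bg = max(0, config.n_peaks - len(rows))
    chroms = list(lengths)
    w = np.array([lengths[c] for c in chroms], float)
    for _ in range(n_bg):
        for _try in range(config.max_retries):
            plen = int(rng.integers(config.peak_len_range[0], config.peak_len_range[1] + 1))
            c = chroms[int(rng.choice(len(chroms), p=w / w.sum()))]
            start = int(rng.integers(0, lengths[c] - plen + 1))
            end = start + plen
            ss, ee = starts_by_chrom.get(c, (np.array([]), np.array([])))
            i = np.searchsorted(ss, end, side="left") - 1
            if i >= 0 and ee[i] > start:
                continue  # would touch a CNS
            rows.append((c, start, end))
            break
        else:
            raise RuntimeError("could not place background peak avoiding CNS")
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )
    peaks["name"] = [f"peak{i:04d}" for i in range(len(peaks))]
    return peaks


def generate_expression_labels(
    deltas: pd.DataFrame, config: SynthConfig, stream: int = 0
) -> pd.DataFrame:
    """Differential-expression labels conditioned on per-gene CNS change.

    Genes in the ``gain`` category are upregulated with odds
    ``de_odds_gain_up`` times the baseline odds (``de_base_rate``); ``loss``
    genes analogously for downregulation. Returns (gene_id, label) with
    label in {up, down, ns}.
    """
    rng = np.random.default_rng([config.seed, _S_DE, stream])
    q = config.de_base_rate
    base_odds = q / (1 - q)

    def rate(odds_ratio: float) -> float:
        o = odds_ratio * base_odds
        return o / (1 + o)

    labels = []
    u = rng.random(len(deltas))
    for x, r in zip(u, deltas.itertuples(index=False)):
        p_up = rate(config.de_odds_gain_up) if r.category == "gain" else q
        p_down = rate(config.de_odds_loss_down) if r.category == "loss" else q
        if p_up + p_down > 1:
            raise ValueError("de label probabilities exceed 1; lower odds or base rate")
        labels.append("up" if x < p_up else "down" if x < p_up + p_down else "ns")
    return pd.DataFrame({"gene_id": deltas["gene_id"].to_numpy(), "label": labels})


def planted_gene_deltas(ref: ReferenceBundle, acc: AccessionBundle) -> pd.DataFrame:
    """Per-gene CNS gain/loss category implied by the planted truth.

    Reference counts come from the reference CNS-to-gene assignment; accession
    counts drop excised (PAV) elements, move PosV elements to the nearest gene
    of their landing site and keep everything else in place.
    """
    ref_counts = ref.cns.groupby("gene_id").size()
    acc_counts = ref_counts.copy().astype(int)
    assoc = ref.cns.set_index("cns_id")["gene_id"]
    acc_to_ref = dict(zip(acc.orthologs["acc_gene_id"], acc.orthologs["ref_gene_id"]))
    posv_sites = acc.cns_acc.set_index("cns_id")
    for row in acc.truth.itertuples(index=False):
        if row.true_status == "pav":
            acc_counts[assoc[row.cns_id]] -= 1
        elif row.true_status == "posv":
            acc_counts[assoc[row.cns_id]] -= 1
            site = posv_sites.loc[row.cns_id]
            q = pd.DataFrame(
                {"chrom": [site.chrom], "start": [site.start], "end": [site.end]}
            )
            # nearest gene of the landing site, in accession coordinates
            names, _ = signed_gene_distances(q, acc.genes)
            ref_gene = acc_to_ref[names[0]]
            acc_counts[ref_gene] = acc_counts.get(ref_gene, 0) + 1
    all_genes = ref.genes["gene_id"]
    n_ref = ref_counts.reindex(all_genes).fillna(0).astype(int)
    n_acc = acc_counts.reindex(all_genes).fillna(0).astype(int)
    cat = np.where(n_acc > n_ref, "gain", np.where(n_acc < n_ref, "loss", "no_change"))
    return pd.DataFrame(
        {"accession": acc.name, "gene_id": all_genes.to_numpy(),
         "n_cns_ref": n_ref.to_numpy(), "n_cns_acc": n_acc.to_numpy(), "category": cat}
    )


def generate_coding_alignments(
    pi_n: float, pi_s: float, n_seq: int, n_codons: int, seed: int
):
    """Codon alignment whose realized synonymous/nonsynonymous pairwise
    diversity converges to (``pi_s``, ``pi_n``) as ``n_codons`` grows.

    Each sequence independently mutates each ancestral codon with a
    synonymous (nonsynonymous) single-nucleotide change at a per-codon
    probability proportional to its synonymous (nonsynonymous) site count,
    calibrated so the expected pairwise diversity hits the targets. No stop
    codons are ever introduced and the alignment is gap-free.
    """
    from .selection import SENSE_CODONS, CodonAlignment, codon_neighbors, ng_sites

    if n_seq < 2:
        raise ValueError("diversity is undefined for fewer than two sequences")
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if pi_n < 0 or pi_s < 0:
        raise ValueError("diversity targets must be non-negative")
    rng = np.random.default_rng([seed, _S_ALN])
    anc = rng.choice(len(SENSE_CODONS), n_codons)
    sites = np.array([ng_sites(c) for c in SENSE_CODONS])
    q_s = pi_s * sites[anc, 0] / 2
    q_n = pi_n * sites[anc, 1] / 2
    if np.any(q_s + q_n > 0.95):
        raise ValueError("diversity targets unreachable for this codon composition")
    syn_nb, nonsyn_nb = codon_neighbors()
    seqs = []
    for _ in range(n_seq):
        u = rng.random(n_codons)
        codons = []
        for i, a in enumerate(anc):
            codon = SENSE_CODONS[a]
            if u[i] < q_s[i] and syn_nb[codon]:
                codon = syn_nb[codon][int(rng.integers(0, len(syn_nb[codon])))]
            elif q_s[i] <= u[i] < q_s[i] + q_n[i] and nonsyn_nb[codon]:
                codon = nonsyn_nb[codon][int(rng.integers(0, len(nonsyn_nb[codon])))]
            codons.append(codon)
        seqs.append("".join(codons))
    return CodonAlignment([f"seq{i}" for i in range(n_seq)], seqs)


def write_reference(ref: ReferenceBundle, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    genome_io.write_fasta(ref.genome, os.path.join(outdir, "genome.fa"))
    genome_io.write_gff3(ref.genes, os.path.join(outdir, "genes.gff3"))
    genome_io.write_bed(ref.cns, os.path.join(outdir, "cns.bed"), extra=["gene_id"])
    genome_io.write_bed(ref.repeats, os.path.join(outdir, "repeats.bed"))
    genome_io.write_tsv(reference_score_track(ref), os.path.join(outdir, "phastcons.tsv"))


def write_accession(acc: AccessionBundle, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    genome_io.write_fasta(acc.genome, os.path.join(outdir, "genome.fa"))
    genome_io.write_gff3(acc.genes, os.path.join(outdir, "genes.gff3"))
    genome_io.write_tsv(acc.orthologs, os.path.join(outdir, "orthologs.tsv"))
    genome_io.write_tsv(acc.truth, os.path.join(outdir, "truth.tsv"))
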