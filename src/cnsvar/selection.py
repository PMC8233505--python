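"""Synonymous/nonsynonymous diversity (piN/piS) and nucleotide diversity.

Site counting and difference counting follow the Nei–Gojobori (1986)
unweighted scheme: a codon's synonymous site count is the fraction of its
nine single-nucleotide mutants that preserve the amino acid (changes to stop
codons count as nonsynonymous), codon differences are averaged over all
minimal mutational pathways with equal weights, and pathways passing through
a stop codon are excluded (unless every pathway does, in which case all are
used). Proportions are raw p-distances without multiple-hit correction,
appropriate at intraspecific divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _CODON_TABLE[_b1 + _b2 + _b3] = ""
# standard genetic code
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _codon in enumerate(_CODON_TABLE):
    _CODON_TABLE[_codon] = _AA[_i]

STOP_CODONS = tuple(c for c, a in _CODON_TABLE.items() if a == "*")
SENSE_CODONS = tuple(c for c, a in _CODON_TABLE.items() if a != "*")


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def ng_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each of the three positions contributes the fraction of its three
    single-nucleotide changes that are synonymous; mutations to stop codons
    count as nonsynonymous. S + N = 3 always.
    """
    codon = codon.upper()
    aa = _CODON_TABLE.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TABLE[mut] == aa:
                s += 1 / 3
    return s, 3.0 - s


@lru_cache(maxsize=1)
def codon_neighbors() -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Single-nucleotide neighbours of every sense codon, split into
    synonymous and nonsynonymous (stop codons excluded from both)."""
    syn: dict[str, list[str]] = {}
    nonsyn: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        syn[codon], nonsyn[codon] = [], []
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if _CODON_TABLE[mut] == "*":
                    continue
                (syn if _CODON_TABLE[mut] == _CODON_TABLE[codon] else nonsyn)[codon].append(mut)
    return syn, nonsyn


@lru_cache(maxsize=None)
def codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged with equal weight over minimal mutational pathways.

    Pathways whose intermediate codons are stops are excluded; if every
    pathway is blocked, all are used (rare fallback, keeps the count
    defined).
    """
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if _CODON_TABLE.get(c, "*") == "*":
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                blocked = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    usable = [(s, n) for b, s, n in paths if not b]
    if not usable:
        usable = [(s, n) for _b, s, n in paths]
    sd = float(np.mean([s for s, _ in usable]))
    nd = float(np.mean([n for _, n in usable]))
    return sd, nd


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment: equal-length sequences, length % 3 == 0."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in number")
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length must be divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from Bio import SeqIO

        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq) for r in recs])


def _usable_codon(codon: str) -> bool:
    return all(b in "TCAG" for b in codon) and _CODON_TABLE[codon] != "*"


def pin_pis(alignment: CodonAlignment) -> tuple[float, float, float | None]:
    """(piN, piS, piN/piS) over all sequence pairs.

    Per pair: sum Nei–Gojobori path-averaged differences over codons, divide
    by the pair-averaged nonsynonymous and synonymous site totals, then
    average the per-pair proportions. Codons with gaps, ambiguity or a stop
    in either sequence are excluded pairwise (a stop triggers a warning).
    The ratio is None when piS is zero.
    """
    seqs = alignment.sequences
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    n_codons = alignment.n_codons
    warned = False
    pn_vals, ps_vals = [], []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            S = N = sd = nd = 0.0
            for c in range(n_codons):
                c1 = seqs[i][3 * c : 3 * c + 3]
                c2 = seqs[j][3 * c : 3 * c + 3]
                ok1, ok2 = _usable_codon(c1), _usable_codon(c2)
                if not (ok1 and ok2):
                    if not warned and (
                        (set(c1) <= set("TCAG") and _CODON_TABLE[c1] == "*")
                        or (set(c2) <= set("TCAG") and _CODON_TABLE[c2] == "*")
                    ):
                        warnings.warn("internal stop codon excluded from piN/piS")
                        warned = True
                    continue
                s1, n1 = ng_sites(c1)
                s2, n2 = ng_sites(c2)
                S += (s1 + s2) / 2
                N += (n1 + n2) / 2
                ds, dn = codon_path_diffs(c1, c2)
                sd += ds
                nd += dn
            if S == 0 or N == 0:
                continue
            pn_vals.append(nd / N)
            ps_vals.append(sd / S)
    if not pn_vals:
        raise ValueError("no comparable codons in any pair")
    pi_n = float(np.mean(pn_vals))
    pi_s = float(np.mean(ps_vals))
    ratio = pi_n / pi_s if pi_s > 0 else None
    return pi_n, pi_s, ratio


def nucleotide_diversity(alignment: CodonAlignment) -> float:
    """Mean pairwise per-site difference proportion (pi), pairwise deletion.

    For each sequence pair, sites where either member carries a gap or an
    ambiguous base are excluded for that pair only.
    """
    seqs = alignment.sequences
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    good = [np.isin(a, np.array([b"A", b"C", b"G", b"T"])) for a in arrs]
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            both = good[i] & good[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                continue
            diffs = int(((arrs[i] != arrs[j]) & both).sum())
            vals.append(diffs / n_sites)
    if not vals:
        raise ValueError("no comparable sites in any pair")
    return float(np.mean(vals))


def filter_groups(groups, min_per_class: int = 2):
    """Keep genes whose every CNS-change class has >= ``min_per_class``
    accessions.

    ``groups`` is a frame with columns (gene_id, accession, category).
    """
    ok = []
    for gene, sub in groups.groupby("gene_id"):
        counts = sub.groupby("category")["accession"].nunique()
        if len(counts) and (counts >= min_per_class).all():
            ok.append(gene)
    return groups[groups["gene_id"].isin(ok)]


def grouped_selection_stats(alignments: dict, groups) -> "object":
    """piN, piS, their ratio and pi per (gene, category) group alignment.

    ``alignments`` maps (gene_id, category) or gene_id to a
    :class:`CodonAlignment` containing the member sequences (reference
    included). Returns a tidy frame.
    """
    import pandas as pd

    rows = []
    keys = groups[["gene_id", "category"]].drop_duplicates().itertuples(index=False)
    for gene, cat in keys:
        aln = alignments.get((gene, cat), alignments.get(gene))
        if aln is None or len(aln.sequences) < 2:
            continue
        pn, ps, ratio = pin_pis(aln)
        rows.append((gene, cat, pn, ps, ratio if ratio is not None else np.nan,
                     nucleotide_diversity(aln)))
    return pd.DataFrame(
        rows, columns=["gene_id", "category", "pi_n", "pi_s", "pin_pis", "pi"]
    )
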