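"""Variation caller: search, identity oracle, classification and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnsvar.caller import (
    CallerParams,
    CnsRecord,
    KmerIndex,
    call_accession,
    classify_cns,
    locate_cns,
    phastcons_filter,
    proximate_gene,
    revcomp,
)


def semiglobal_edit_distance(query: str, target: str) -> int:
    """Independent dynamic-programming oracle: minimal edit distance of the
    full query against any substring of the target (end gaps on the target
    free)."""
    m, n = len(query), len(target)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        qc = query[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (qc != target[j - 1]),
            )
        prev = cur
    return min(prev)


def _random_genome(rng, n) -> str:
    return "".join(rng.choice(list("ACGT"), n))


class TestLocate:
    def test_verbatim_planted_cns_found_once_with_perfect_identity(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": _random_genome(rng, 5000)}
        seq = genome["chr1"][2000:2040]
        cns = CnsRecord("c1", "chr1", 2000, 2040, seq, "g1")
        matches = locate_cns(cns, KmerIndex(genome, 11))
        assert len(matches) == 1
        m = matches[0]
        assert (m.start, m.end, m.identity, m.coverage) == (2000, 2040, 1.0, 1.0)

    def test_excised_cns_yields_no_match(self):
        rng = np.random.default_rng(1)
        full = _random_genome(rng, 5000)
        seq = full[2000:2040]
        genome = {"chr1": full[:2000] + full[2040:]}
        cns = CnsRecord("c1", "chr1", 2000, 2040, seq, "g1")
        assert locate_cns(cns, KmerIndex(genome, 11)) == []

    def test_reported_identity_matches_dp_oracle_for_planted_mismatches(self):
        rng = np.random.default_rng(2)
        full = list(_random_genome(rng, 1000))
        seq = "".join(full[400:430])
        # plant two mismatches inside the genomic copy
        for pos in (405, 417):
            full[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[full[pos]]
        genome = {"chr1": "".join(full)}
        cns = CnsRecord("c1", "chr1", 400, 430, seq, "g1")
        matches = locate_cns(cns, KmerIndex(genome, 11))
        assert len(matches) == 1
        window = genome["chr1"][200:630]
        oracle = 1 - semiglobal_edit_distance(seq, window) / len(seq)
        assert matches[0].identity == pytest.approx(28 / 30)
        assert matches[0].identity == pytest.approx(oracle)

    def test_reverse_strand_occurrence_found(self):
        rng = np.random.default_rng(3)
        g = _random_genome(rng, 3000)
        seq = revcomp(g[1000:1050])
        cns = CnsRecord("c1", "chr1", 0, 50, seq, "g1")
        matches = locate_cns(cns, KmerIndex({"chr1": g}, 11))
        assert matches and matches[0].strand == "-"
        assert (matches[0].start, matches[0].end) == (1000, 1050)

    def test_cns_shorter_than_seed_errors(self):
        cns = CnsRecord("c1", "chr1", 0, 15, "A" * 15, "g1")
        with pytest.raises(ValueError, match="seed_k"):
            locate_cns(cns, KmerIndex({"chr1": "A" * 100}, 11), CallerParams(seed_k=16))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(35, 60), st.integers(0, 2))
    def test_best_identity_equals_dp_oracle(self, seed, qlen, n_mut):
        """Property: the reported best identity equals the semi-global DP
        oracle over the genome. With <= 2 mutations in a >= 35 bp element an
        intact 11-mer seed is guaranteed, so the caller must find the site.
        """
        rng = np.random.default_rng(seed)
        g = list(_random_genome(rng, 600))
        start = int(rng.integers(100, 400))
        query = "".join(g[start : start + qlen])
        for _ in range(n_mut):
            p = int(rng.integers(start, start + qlen))
            g[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[g[p]]
        genome = {"chr1": "".join(g)}
        cns = CnsRecord("c1", "chr1", 0, qlen, query, "g1")
        matches = locate_cns(
            cns, KmerIndex(genome, 11), CallerParams(min_identity=0.5, min_coverage=0.5)
        )
        oracle = 1 - semiglobal_edit_distance(query, genome["chr1"]) / qlen
        assert matches, "a seeded near-identical site must be found"
        assert matches[0].identity == pytest.approx(oracle)


GENES = pd.DataFrame(
    {
        "chrom": ["chr1", "chr1"],
        "start": [1000, 3000],
        "end": [2000, 4000],
        "strand": ["+", "+"],
        "gene_id": ["gA", "gB"],
    }
)


class TestProximateGene:
    def test_interval_inside_gene_has_distance_zero(self):
        assert proximate_gene("chr1", 1200, 1300, GENES) == ("gA", 0)

    def test_upstream_interval_signed_negative(self):
        assert proximate_gene("chr1", 700, 730, GENES) == ("gA", -270)

    def test_downstream_interval_signed_positive(self):
        assert proximate_gene("chr1", 2100, 2150, GENES) == ("gA", 100)

    def test_equidistant_tie_breaks_to_smaller_gene_start(self):
        # midpoint between gA end (2000) and gB start (3000)
        gene, d = proximate_gene("chr1", 2450, 2550, GENES)
        assert gene == "gA"
        assert abs(d) == 450

    def test_missing_chromosome_errors(self):
        with pytest.raises(ValueError):
            proximate_gene("chrX", 0, 10, GENES)


ORTH = pd.DataFrame({"ref_gene_id": ["gA", "gB"], "acc_gene_id": ["aA", "aB"]})
ACC_GENES = GENES.assign(gene_id=["aA", "aB"])


def _match(start, end, identity=1.0):
    from cnsvar.caller import CnsMatch

    return CnsMatch("c1", "acc", "chr1", start, end, "+", identity, 1.0)


class TestClassify:
    CNS = CnsRecord("c1", "chr1", 500, 540, "A" * 40, "gA")

    def test_no_match_is_pav(self):
        call = classify_cns(self.CNS, [], dict(zip(ORTH.acc_gene_id, ORTH.ref_gene_id)), ACC_GENES)
        assert call.status == "pav" and call.best_match is None

    def test_match_near_orthologous_gene_is_collinear(self):
        call = classify_cns(
            self.CNS, [_match(600, 640)],
            dict(zip(ORTH.acc_gene_id, ORTH.ref_gene_id)), ACC_GENES,
        )
        assert call.status == "collinear"
        assert call.acc_proximate_gene == "aA"

    def test_match_near_other_gene_is_posv(self):
        call = classify_cns(
            self.CNS, [_match(3500, 3540)],
            dict(zip(ORTH.acc_gene_id, ORTH.ref_gene_id)), ACC_GENES,
        )
        assert call.status == "posv"
        assert call.acc_proximate_gene == "aB"

    def test_collinear_has_priority_over_posv(self):
        """A duplicated occurrence elsewhere does not displace the syntenic site."""
        call = classify_cns(
            self.CNS,
            [_match(3500, 3540), _match(600, 640, identity=0.95)],
            dict(zip(ORTH.acc_gene_id, ORTH.ref_gene_id)),
            ACC_GENES,
        )
        assert call.status == "collinear"
        assert len(call.secondary_matches) == 1

    def test_gene_without_ortholog_treated_as_non_syntenic(self):
        call = classify_cns(
            self.CNS, [_match(600, 640)], {"aB": "gB"}, ACC_GENES
        )
        assert call.status == "posv"


class TestCallAccession:
    def test_statuses_partition_the_cns_set(self, small_ref, small_calls):
        calls, summary = small_calls
        assert len(calls) == len(small_ref.cns)
        assert summary["n_pav"] + summary["n_posv"] + summary["n_collinear"] == len(calls)

    def test_planted_statuses_recovered_exactly(self, small_ref, small_acc, small_calls):
        from cnsvar.simulate import truth_status

        calls, _ = small_calls
        truth = truth_status(small_acc.truth, small_ref.cns["cns_id"], small_acc.name)
        predicted = pd.Series({c.cns_id: c.status for c in calls})
        assert (truth.loc[predicted.index] == predicted).all()

    def test_reference_against_itself_is_all_collinear(self, small_ref):
        orth = pd.DataFrame(
            {"ref_gene_id": small_ref.genes["gene_id"], "acc_gene_id": small_ref.genes["gene_id"]}
        )
        _, summary = call_accession(
            small_ref.cns_records(), small_ref.genome, small_ref.genes, orth
        )
        assert summary == {"n_pav": 0, "n_posv": 0, "n_collinear": len(small_ref.cns)}

    def test_duplicate_cns_id_rejected(self, small_ref):
        recs = small_ref.cns_records()[:2]
        recs.append(recs[0])
        with pytest.raises(ValueError, match="duplicate"):
            call_accession(recs, small_ref.genome, small_ref.genes, pd.DataFrame(
                {"ref_gene_id": [], "acc_gene_id": []}))

    def test_status_calls_invariant_under_reverse_complement(self, small_ref, small_acc, small_calls):
        """Reverse-complementing the accession assembly (and flipping its
        annotation) must not change any status."""
        calls, _ = small_calls
        L = {c: len(s) for c, s in small_acc.genome.items()}
        rc_genome = {c: revcomp(s) for c, s in small_acc.genome.items()}
        genes = small_acc.genes.copy()
        genes["start"], genes["end"] = (
            [L[r.chrom] - r.end for r in small_acc.genes.itertuples(index=False)],
            [L[r.chrom] - r.start for r in small_acc.genes.itertuples(index=False)],
        )
        genes["strand"] = genes["strand"].map({"+": "-", "-": "+"})
        rc_calls, _ = call_accession(
            small_ref.cns_records(), rc_genome, genes, small_acc.orthologs,
            accession=small_acc.name,
        )
        fwd = {c.cns_id: c.status for c in calls}
        rev = {c.cns_id: c.status for c in rc_calls}
        assert fwd == rev


class TestPhastconsFilter:
    def test_seven_high_positions_pass(self):
        assert phastcons_filter([0.9] * 7) is True

    def test_six_high_positions_fail(self):
        assert phastcons_filter([0.9] * 6) is False

    def test_long_low_run_disqualifies(self):
        assert phastcons_filter([0.9] * 7 + [0.50] * 13) is False

    def test_twelve_low_positions_tolerated(self):
        assert phastcons_filter([0.9] * 7 + [0.50] * 12) is True

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            phastcons_filter([0.9, 1.2])
        with pytest.raises(ValueError):
            phastcons_filter([])
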