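"""Synthetic-genome generator: determinism, planted-event contracts,
conservation invariants and auxiliary tracks."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnsvar import (
    SynthConfig,
    derive_accession,
    generate_coding_alignments,
    generate_expression_labels,
    generate_peaks,
    generate_reference,
)
from cnsvar.caller import revcomp
from cnsvar.chromatin import overlap_summary
from cnsvar.intervals import nearest_gap
from cnsvar.simulate import reference_score_track, write_accession, write_reference

from conftest import small_config


def test_reference_cns_lengths_within_configured_range(small_ref, small_cfg):
    lengths = (small_ref.cns["end"] - small_ref.cns["start"]).to_numpy()
    lo, hi = small_cfg.cns_len_range
    assert lengths.min() >= max(lo, 15)
    assert lengths.max() <= hi
    seqs = small_ref.cns["sequence"]
    assert all(
        small_ref.genome[r.chrom][r.start : r.end] == r.sequence
        for r in small_ref.cns.itertuples(index=False)
    )
    del seqs


def test_empty_cns_request_gives_valid_genome():
    cfg = small_config(n_cns=0, pav_per_accession=0, posv_per_accession=0)
    ref = generate_reference(cfg)
    assert len(ref.cns) == 0
    assert len(ref.genome["chr1"]) == cfg.chrom_len


def test_file_level_determinism(tmp_path, small_cfg):
    for d in ("a", "b"):
        ref = generate_reference(small_cfg)
        write_reference(ref, tmp_path / d)
        write_accession(derive_accession(ref, small_cfg, 0), tmp_path / d / "acc")
    for name in ("genome.fa", "genes.gff3", "cns.bed", "repeats.bed", "phastcons.tsv"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)
    for name in ("genome.fa", "genes.gff3", "orthologs.tsv", "truth.tsv"):
        assert filecmp.cmp(
            tmp_path / "a" / "acc" / name, tmp_path / "b" / "acc" / name, shallow=False
        )


def test_no_mutation_accession_identical_to_reference():
    cfg = small_config(
        snp_rate=0.0, indel_rate=0.0, pav_per_accession=0, posv_per_accession=0
    )
    ref = generate_reference(cfg)
    acc = derive_accession(ref, cfg, 0)
    assert acc.genome == ref.genome
    assert (acc.genes["start"] == ref.genes["start"]).all()


def test_truth_table_has_exactly_the_planted_event_counts(small_acc, small_cfg):
    counts = small_acc.truth["true_status"].value_counts()
    assert counts.get("pav", 0) == small_cfg.pav_per_accession
    assert counts.get("posv", 0) == small_cfg.posv_per_accession


def test_genome_length_conservation_without_indels():
    cfg = small_config(indel_rate=0.0)
    ref = generate_reference(cfg)
    acc = derive_accession(ref, cfg, 0)
    excised = 0
    cns = ref.cns.set_index("cns_id")
    for r in acc.truth.itertuples(index=False):
        if r.true_status == "pav":
            row = cns.loc[r.cns_id]
            excised += int(row.end - row.start)
    diff = sum(len(s) for s in ref.genome.values()) - sum(
        len(s) for s in acc.genome.values()
    )
    assert diff == excised


def test_posv_sequences_planted_verbatim_without_snps(clean_ref, clean_acc):
    cns = clean_ref.cns.set_index("cns_id")
    posv = clean_acc.truth[clean_acc.truth["true_status"] == "posv"]
    assert len(posv) > 0
    for r in posv.itertuples(index=False):
        seq = cns.loc[r.cns_id, "sequence"]
        planted = clean_acc.genome[r.new_chrom][r.new_start : r.new_start + len(seq)]
        assert planted in (seq, revcomp(seq))


def test_te_bias_places_every_posv_landing_near_a_repeat(clean_acc, clean_cfg):
    posv = clean_acc.cns_acc[clean_acc.cns_acc["status"] == "posv"]
    assert len(posv) == clean_cfg.posv_per_accession
    d = nearest_gap(posv[["chrom", "start", "end"]], clean_acc.repeats)
    assert (d <= clean_cfg.te_window).all()


def test_score_track_exceeds_element_threshold_over_cns_bodies(small_ref):
    track = reference_score_track(small_ref)
    track = track.set_index(["chrom", "pos"])["score"]
    for r in small_ref.cns.head(20).itertuples(index=False):
        body = [track[(r.chrom, p)] for p in range(r.start, r.end)]
        assert min(body) > 0.82


def test_infeasible_packing_raises():
    with pytest.raises(ValueError, match="packing"):
        SynthConfig(
            n_chroms=1, chrom_len=10_000, n_genes=50, n_cns=100,
            pav_per_accession=0, posv_per_accession=0,
        ).validate()


@pytest.mark.parametrize("bad", [dict(snp_rate=1.5), dict(cns_len_range=(10, 100)), dict(n_genes=-1)])
def test_config_validation_rejects_bad_values(bad):
    with pytest.raises(ValueError):
        small_config(**bad).validate()


def test_peak_coverage_fractions_are_exact(clean_ref, clean_cfg):
    cfg = small_config(
        snp_rate=0.0, indel_rate=0.0, peak_cover_collinear=0.2, peak_cover_posv=0.0
    )
    ref = generate_reference(cfg)
    acc = derive_accession(ref, cfg, 0)
    peaks = generate_peaks(acc, cfg)
    coll = acc.cns_acc[acc.cns_acc["status"] == "collinear"][["chrom", "start", "end"]]
    posv = acc.cns_acc[acc.cns_acc["status"] == "posv"][["chrom", "start", "end"]]
    n, pct = overlap_summary(coll, peaks)
    assert n == round(0.2 * len(coll))
    n_posv, _ = overlap_summary(posv, peaks)
    assert n_posv == 0
    assert pct == pytest.approx(100 * n / len(coll))


def test_full_peak_coverage(clean_ref, clean_cfg):
    cfg = small_config(snp_rate=0.0, indel_rate=0.0, peak_cover_collinear=1.0)
    ref = generate_reference(cfg)
    acc = derive_accession(ref, cfg, 0)
    peaks = generate_peaks(acc, cfg)
    coll = acc.cns_acc[acc.cns_acc["status"] == "collinear"][["chrom", "start", "end"]]
    n, pct = overlap_summary(coll, peaks)
    assert pct == 100.0


def _deltas(n_gain, n_loss, n_none):
    cats = ["gain"] * n_gain + ["loss"] * n_loss + ["no_change"] * n_none
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(cats))], "category": cats})


def test_de_labels_null_odds_independent_of_category():
    cfg = small_config(de_odds_gain_up=1.0, de_odds_loss_down=1.0)
    deltas = _deltas(3000, 3000, 4000)
    labels = generate_expression_labels(deltas, cfg)
    table = pd.crosstab(deltas["category"], labels["label"] == "up")
    _, p, *_ = sps.chi2_contingency(table)
    assert p > 0.01


def test_de_labels_recover_planted_odds_ratio():
    cfg = small_config(de_odds_gain_up=4.0)
    deltas = _deltas(5000, 0, 5000)
    labels = generate_expression_labels(deltas, cfg)
    merged = deltas.merge(labels, on="gene_id")
    gain_up = ((merged["category"] == "gain") & (merged["label"] == "up")).sum()
    gain_no = ((merged["category"] == "gain") & (merged["label"] != "up")).sum()
    none_up = ((merged["category"] == "no_change") & (merged["label"] == "up")).sum()
    none_no = ((merged["category"] == "no_change") & (merged["label"] != "up")).sum()
    odds = (gain_up / gain_no) / (none_up / none_no)
    assert 3.0 <= odds <= 5.0


def test_de_labels_cover_exactly_the_input_genes():
    cfg = small_config()
    deltas = _deltas(0, 5, 10)
    labels = generate_expression_labels(deltas, cfg)
    assert list(labels["gene_id"]) == list(deltas["gene_id"])
    assert set(labels["label"]) <= {"up", "down", "ns"}


class TestCodingAlignmentGenerator:
    def test_zero_diversity_gives_identical_sequences(self):
        aln = generate_coding_alignments(0.0, 0.0, 5, 50, seed=1)
        assert len(set(aln.sequences)) == 1

    def test_alignment_is_clean(self):
        aln = generate_coding_alignments(0.01, 0.03, 6, 300, seed=2)
        from cnsvar.selection import STOP_CODONS

        for s in aln.sequences:
            assert len(s) % 3 == 0
            assert "-" not in s
            codons = {s[i : i + 3] for i in range(0, len(s), 3)}
            assert not (codons & set(STOP_CODONS))

    def test_single_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            generate_coding_alignments(0.01, 0.03, 1, 100, seed=3)

    def test_unreachable_targets_raise(self):
        with pytest.raises(ValueError):
            generate_coding_alignments(0.0, 2.5, 4, 100, seed=4)
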