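"""Read extraction: indexing, seed-and-extend mapping, histograms, SAM repair."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from ssuflash import extract, refdb, synth
from ssuflash.extract import ReadPair

from conftest import make_record, random_dna


# --------------------------------------------------------------------------
# Reference index
# --------------------------------------------------------------------------

def test_index_posting_count(rng):
    rec = make_record("r", random_dna(rng, 100))
    idx = extract.build_ref_index([rec], k=13)
    assert idx.n_postings() == 100 - 13 + 1


def test_fully_masked_reference_contributes_nothing():
    rec = make_record("r", "N" * 100)
    idx = extract.build_ref_index([rec], k=13)
    assert idx.n_postings() == 0


def test_identical_references_double_postings(rng):
    seq = random_dna(rng, 100)
    idx = extract.build_ref_index(
        [make_record("a", seq), make_record("b", seq)], k=13)
    for postings in idx.postings.values():
        assert len(postings) == 2


def test_index_rejects_even_k_and_oversized_k(rng):
    rec = make_record("r", random_dna(rng, 50))
    with pytest.raises(ValueError):
        extract.build_ref_index([rec], k=12)
    with pytest.raises(ValueError):
        extract.build_ref_index([rec], k=51)


# --------------------------------------------------------------------------
# extract_reads
# --------------------------------------------------------------------------

@pytest.fixture
def two_refs(rng):
    return [make_record("refA", random_dna(rng, 800), ("Bacteria", "PA", "CA")),
            make_record("refB", random_dna(rng, 800), ("Bacteria", "PB", "CB"))]


def test_verbatim_read_full_identity(two_refs):
    idx = extract.build_ref_index(two_refs)
    pair = ReadPair("p1", two_refs[0].seq[100:200], two_refs[0].seq[400:500])
    hits, retained = extract.extract_reads([pair], idx)
    assert retained == [pair]
    assert all(h.identity == pytest.approx(1.0) for h in hits)
    assert {h.ref_id for h in hits} == {"refA"}
    by_mate = {h.mate: h for h in hits}
    assert by_mate[1].ref_start == 100 and by_mate[2].ref_start == 400


def test_reverse_complement_read_found(two_refs):
    idx = extract.build_ref_index(two_refs)
    rc = refdb.revcomp(two_refs[1].seq[300:400])
    hits, retained = extract.extract_reads(
        [ReadPair("p1", rc, two_refs[1].seq[50:150])], idx)
    assert len(retained) == 1
    m1 = [h for h in hits if h.mate == 1]
    assert m1 and m1[0].strand == "-" and m1[0].identity == pytest.approx(1.0)


def test_dissimilar_read_not_reported(two_refs, rng):
    idx = extract.build_ref_index(two_refs)
    pair = ReadPair("p1", random_dna(rng, 100), random_dna(rng, 100))
    hits, retained = extract.extract_reads([pair], idx, min_identity=0.70)
    assert hits == [] and retained == []


def test_pair_retained_when_only_one_mate_aligns(two_refs, rng):
    idx = extract.build_ref_index(two_refs)
    pair = ReadPair("p1", two_refs[0].seq[0:100], random_dna(rng, 100))
    hits, retained = extract.extract_reads([pair], idx)
    assert retained == [pair]  # the whole pair, both mates, is retained
    assert {h.mate for h in hits} == {1}


def test_tied_best_hits_all_reported(rng):
    seq = random_dna(rng, 800)
    refs = [make_record("a", seq), make_record("b", seq)]
    idx = extract.build_ref_index(refs)
    hits, _ = extract.extract_reads(
        [ReadPair("p", seq[100:200], seq[300:400])], idx)
    assert {(h.mate, h.ref_id) for h in hits} == {
        (1, "a"), (1, "b"), (2, "a"), (2, "b")}
    assert all(h.is_best for h in hits)


def test_identity_rescoring_oracle(small_hits, small_reads, small_db):
    """Stored identities equal identities recomputed from a fresh
    alignment of the read against the reported reference window."""
    import edlib
    hits, _ = small_hits
    pairs, _ = small_reads
    by_id = {p.read_id: p for p in pairs}
    refs = {r.id: r.seq for r in small_db[0]}
    for h in hits[:200]:
        read = by_id[h.read_id].seq1 if h.mate == 1 else by_id[h.read_id].seq2
        if h.strand == "-":
            read = refdb.revcomp(read)
        window = refs[h.ref_id][max(0, h.ref_start - 20):
                                h.ref_start + len(read) + 20]
        res = edlib.align(read, window, mode="HW", task="path")
        ident, _, _ = extract._cigar_identity(res["cigar"])
        assert ident == pytest.approx(h.identity, abs=1e-9)


def test_retention_rule_consistency(small_hits, small_reads):
    hits, retained = small_hits
    pairs, _ = small_reads
    with_hits = {h.read_id for h in hits}
    retained_ids = {p.read_id for p in retained}
    assert retained_ids == with_hits  # no hitless pair kept, none dropped


def test_sensitivity_and_false_positives_monotone_in_identity(small_reads,
                                                              small_index,
                                                              small_db):
    pairs, truth = small_reads
    truth_ssu = set(truth[truth.is_ssu].read_id)
    sens, fps = [], []
    for min_id in (0.70, 0.80, 0.90, 0.97):
        _, retained = extract.extract_reads(pairs, small_index,
                                            min_identity=min_id)
        got = {p.read_id for p in retained}
        sens.append(len(got & truth_ssu) / len(truth_ssu))
        fps.append(len(got - truth_ssu))
    assert sens == sorted(sens, reverse=True)
    assert fps == sorted(fps, reverse=True)


# --------------------------------------------------------------------------
# Histograms
# --------------------------------------------------------------------------

def test_identity_histogram_counts(two_refs):
    idx = extract.build_ref_index(two_refs)
    pairs = [ReadPair(f"p{i}", two_refs[0].seq[i * 50:i * 50 + 100],
                      two_refs[0].seq[400:500]) for i in range(3)]
    hits, _ = extract.extract_reads(pairs, idx)
    ident, ins = extract.alignment_histograms(hits)
    assert ident.loc[100] == 6  # 3 pairs x 2 mates, all at identity 1.0
    assert ident.sum() == 6


def test_empty_insert_histogram_when_no_same_ref_pairs(two_refs, rng):
    idx = extract.build_ref_index(two_refs)
    pair = ReadPair("p1", two_refs[0].seq[0:100], random_dna(rng, 100))
    hits, _ = extract.extract_reads([pair], idx)
    _, ins = extract.alignment_histograms(hits)
    assert ins.empty


def test_fixed_insert_yields_single_bin():
    spec = synth.FixtureSpec(seed=31, n_taxa=4, n_reads=50, fraction_ssu=1.0,
                             insert_mean=300.0, insert_sd=0.0, error_rate=0.0)
    records, _, _, _ = synth.gen_reference_db(spec)
    pairs, _ = synth.gen_reads(spec, records)
    idx = extract.build_ref_index(records)
    hits, _ = extract.extract_reads(pairs, idx)
    _, ins = extract.alignment_histograms(hits)
    assert list(ins.index) == [300]
    assert ins.sum() == 50


# --------------------------------------------------------------------------
# SAM pairing repair
# --------------------------------------------------------------------------

def _segment(header, name, flag=0, tid=0, pos=0):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "ACGT" * 10
    a.flag = flag
    a.reference_id = tid
    a.reference_start = pos
    if tid >= 0:
        a.cigartuples = [(0, 40)]
    return a


@pytest.fixture
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": 1000}]})


def test_repair_fixes_inconsistent_mate_unmapped(header):
    a = _segment(header, "r1", flag=0x1 | 0x40 | 0x8, pos=10)
    b = _segment(header, "r1", flag=0x1 | 0x80, pos=200)
    out = extract.repair_sam_pairing([a, b])
    assert not out[0].mate_is_unmapped and not out[1].mate_is_unmapped
    assert out[0].next_reference_start == 200
    assert out[1].next_reference_start == 10
    assert out[0].is_proper_pair and out[1].is_proper_pair


def test_repair_strips_mate_suffixes(header):
    a = _segment(header, "r1/1", flag=0x1, pos=10)
    b = _segment(header, "r1/2", flag=0x1, pos=50)
    out = extract.repair_sam_pairing([a, b])
    assert out[0].query_name == out[1].query_name == "r1"
    assert out[0].is_read1 and out[1].is_read2
    assert out[0].flag & 0x40 and out[1].flag & 0x80


def test_repair_idempotent(header):
    a = _segment(header, "r1/1", flag=0x1 | 0x8, pos=10)
    b = _segment(header, "r1/2", flag=0x1, pos=50)
    once = extract.repair_sam_pairing([a, b])
    flags = [(r.flag, r.next_reference_start) for r in once]
    twice = extract.repair_sam_pairing(once)
    assert [(r.flag, r.next_reference_start) for r in twice] == flags


def test_repair_keeps_orphans(header):
    a = _segment(header, "solo/1", flag=0x1, pos=10)
    out = extract.repair_sam_pairing([a])
    assert len(out) == 1
    assert out[0].is_paired and out[0].mate_is_unmapped


# --------------------------------------------------------------------------
# SAM round-trip
# --------------------------------------------------------------------------

def test_sam_output_valid_and_paired(tmp_path, small_hits, small_reads, small_db):
    hits, retained = small_hits
    pairs, _ = small_reads
    path = tmp_path / "out.sam"
    extract.write_sam(hits, retained, small_db[0], path)
    with pysam.AlignmentFile(path) as sam:
        recs = list(sam)
    assert len(recs) == 2 * len(retained)
    for r in recs:
        assert r.is_paired
        assert r.is_read1 != r.is_read2
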