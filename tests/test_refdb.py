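"""Reference curation: LSU removal, masking, vector screening, clustering."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from ssuflash import refdb
from ssuflash.refdb import FeatureHit, ReferenceRecord, VectorIndex

from conftest import make_record, random_dna


# --------------------------------------------------------------------------
# LSU fragment removal
# --------------------------------------------------------------------------

@pytest.mark.parametrize("evalue,fraction,dropped", [
    (1e-12, 0.15, True),   # both thresholds satisfied
    (1e-8, 0.15, False),   # E-value fails cutoff
    (1e-12, 0.08, False),  # model fraction at/below 10%
])
def test_lsu_removal_thresholds(evalue, fraction, dropped):
    rec = make_record("X", "ACGT" * 300)
    hit = FeatureHit("X", "lsu", evalue, fraction, 0, 100)
    out = refdb.remove_lsu_fragments([rec], [hit])
    assert out[0].kept is (not dropped)
    assert out[0].drop_reason == (refdb.DROP_LSU if dropped else refdb.DROP_NONE)
    assert out[0].seq == rec.seq  # flags only, never sequence content


def test_lsu_removal_unknown_id_errors():
    rec = make_record("X", "ACGT" * 300)
    with pytest.raises(ValueError, match="unknown record"):
        refdb.remove_lsu_fragments(
            [rec], [FeatureHit("nope", "lsu", 1e-20, 0.5, 0, 10)])


def test_non_lsu_hits_ignored():
    rec = make_record("X", "ACGT" * 300)
    hit = FeatureHit("X", "ssu_bac", 1e-200, 1.0, 0, 100)
    assert refdb.remove_lsu_fragments([rec], [hit])[0].kept


# --------------------------------------------------------------------------
# Low-complexity masking vs exhaustive oracle
# --------------------------------------------------------------------------

def oracle_flagged(seq: str, kmin: int, kmax: int, cutoff: float,
                   window: int) -> np.ndarray:
    """Exhaustive per-window restatement of the masking rule."""
    L = len(seq)
    w = min(window, L)
    flagged = np.zeros(L, dtype=bool)
    for k in range(kmin, kmax + 1):
        if w <= k:
            continue
        for start in range(L - w + 1):
            win = seq[start:start + w]
            kmers = [win[i:i + k] for i in range(len(win) - k + 1)]
            counts = Counter(km for km in kmers if set(km) <= set("ACGT"))
            total = sum(counts.values())
            if total < 2:
                continue
            h = -sum((c / total) * math.log2(c / total)
                     for c in counts.values())
            if h / math.log2(min(4 ** k, total)) < cutoff:
                thresh = max(3, math.ceil(max(counts.values()) / 2))
                for i, km in enumerate(kmers):
                    if set(km) <= set("ACGT") and counts[km] >= thresh:
                        flagged[start + i:start + i + k] = True
    return flagged


def test_random_sequence_not_masked(rng):
    seq = random_dna(rng, 100)
    rec = make_record("r", seq)
    out = refdb.mask_low_complexity(rec)
    assert out.masked_intervals == []
    assert out.seq == seq
    assert not oracle_flagged(seq, 4, 8, 0.7, 100).any()


def test_homopolymer_masked_with_bounded_slack(rng):
    flank = random_dna(rng, 75)
    flank2 = random_dna(rng, 75)
    seq = flank + "A" * 50 + flank2
    out = refdb.mask_low_complexity(make_record("r", seq))
    assert len(out.masked_intervals) == 1
    a, b = out.masked_intervals[0]
    # interval covers the homopolymer with window-edge slack <= kmax
    assert a >= 75 - 8 and b <= 125 + 8
    assert b - a >= 50 - 8
    assert set(out.seq[a:b]) == {"N"}


def test_short_homopolymer_not_masked(rng):
    seq = random_dna(rng, 95) + "A" * 10 + random_dna(rng, 95)
    out = refdb.mask_low_complexity(make_record("r", seq))
    assert out.masked_intervals == []


@pytest.mark.parametrize("case", range(4))
def test_masking_agrees_with_exhaustive_oracle(case, rng):
    """Flagged-position agreement with the brute-force window oracle on
    sequences up to 500 bp, for all k in [4, 8]."""
    specials = {
        0: random_dna(rng, 300),
        1: random_dna(rng, 140) + "A" * 40 + random_dna(rng, 120),
        2: random_dna(rng, 100) + "ACAC" * 15 + random_dna(rng, 200),
        3: random_dna(rng, 60) + "TTTTTTTTTTGGGGGGGGGGG" * 3 + random_dna(rng, 90),
    }
    seq = specials[case]
    flagged = oracle_flagged(seq, 4, 8, 0.7, 100)
    out = refdb.mask_low_complexity(make_record("r", seq))
    expected = [(a, b) for a, b in refdb._runs(flagged) if b - a >= 20]
    assert out.masked_intervals == expected


def test_masking_rejects_degenerate_input():
    with pytest.raises(ValueError):
        refdb.mask_low_complexity(make_record("r", "ACGTACGT"))


# --------------------------------------------------------------------------
# Vector screening
# --------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_vector_scan(seq: str, vectors: list[str], k: int = 27,
                            max_h: int = 1) -> bool:
    """Any window of seq within Hamming distance 1 of any vector k-mer?"""
    pool = set()
    for v in vectors:
        for src in (v, refdb.revcomp(v)):
            for i in range(len(src) - k + 1):
                pool.add(src[i:i + k])
    for i in range(len(seq) - k + 1):
        win = seq[i:i + k]
        if any(hamming(win, p) <= max_h for p in pool):
            return True
    return False


@pytest.fixture(scope="module")
def vector():
    r = np.random.default_rng(77)
    return random_dna(r, 500)


def test_internal_vector_hit_trims_longest_fragment(rng):
    # a standalone 27-bp vector: the only match is the planted k-mer itself
    vec = random_dna(np.random.default_rng(78), 27)
    body = random_dna(rng, 1000)
    seq = body[:10] + vec + body[37:]
    rec = make_record("r", seq)
    out = refdb.screen_vector(rec, VectorIndex([vec]))
    assert out.kept
    assert len(out.seq) == 963  # longest retained fragment
    assert not brute_force_vector_scan(out.seq, [vec])


def test_mid_vector_hit_drops_short_record(rng):
    vec = random_dna(np.random.default_rng(79), 27)
    body = random_dna(rng, 850)
    seq = body[:411] + vec + body[438:]
    out = refdb.screen_vector(make_record("r", seq), VectorIndex([vec]))
    assert not out.kept
    assert out.drop_reason == refdb.DROP_SHORT


def test_no_vector_match_identity(rng, vector):
    seq = random_dna(rng, 1000)
    assert not brute_force_vector_scan(seq, [vector])  # sanity of fixture
    out = refdb.screen_vector(make_record("r", seq), VectorIndex([vector]))
    assert out.seq == seq and out.kept


def test_hamming_one_neighbour_also_trimmed(rng, vector):
    kmer = list(vector[50:77])
    kmer[13] = {"A": "C"}.get(kmer[13], "A")  # one substitution
    seq = random_dna(rng, 900) + "".join(kmer) + random_dna(rng, 900)
    out = refdb.screen_vector(make_record("r", seq), VectorIndex([vector]))
    assert len(out.seq) < len(seq)
    assert not brute_force_vector_scan(out.seq, [vector])


def test_end_anchored_short_kmer_trimmed(rng, vector):
    # an 11-mer of vector at the very start is below the primary k but
    # matches because it is anchored at the sequence end
    seq = vector[30:41] + random_dna(rng, 1000)
    out = refdb.screen_vector(make_record("r", seq), VectorIndex([vector]))
    assert len(out.seq) <= 1000


def test_vector_index_rejects_bad_k():
    with pytest.raises(ValueError):
        VectorIndex(["ACGT" * 20], k=11, k_end=27)


# --------------------------------------------------------------------------
# Alphabet normalisation
# --------------------------------------------------------------------------

def test_rna_to_dna():
    out = refdb.normalize_alphabet(make_record("r", "ACGU"), seed=1)
    assert out.seq == "ACGT"


def test_ambiguity_replacement_reproducible():
    outs = {refdb.normalize_alphabet(make_record("r", "R"), seed=9).seq
            for _ in range(5)}
    assert len(outs) == 1 and outs.pop() in {"A", "G"}


def test_plain_dna_unchanged():
    assert refdb.normalize_alphabet(make_record("r", "ACGT"), seed=1).seq == "ACGT"


def test_non_iupac_character_rejected():
    with pytest.raises(ValueError, match="non-IUPAC"):
        refdb.normalize_alphabet(make_record("r", "ACXG"), seed=1)


def test_masked_positions_stay_hard_masked():
    rec = ReferenceRecord("r", ("B",), "ACNNNNGT",
                          masked_intervals=[(2, 6)])
    out = refdb.normalize_alphabet(rec, seed=3)
    assert out.seq[2:6] == "NNNN"
    assert set(out.seq) <= set("ACGTN")


# --------------------------------------------------------------------------
# Greedy clustering
# --------------------------------------------------------------------------

def mutate_at(seq: str, positions: list[int]) -> str:
    s = list(seq)
    for p in positions:
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


def test_identical_sequences_one_cluster(rng):
    seq = random_dna(rng, 600)
    asg = refdb.greedy_cluster(
        [make_record("a", seq), make_record("b", seq)], 0.99)
    centroids = {x.centroid_id for x in asg}
    assert centroids == {"a"}
    member = next(x for x in asg if x.member_id == "b")
    assert member.identity_to_centroid == pytest.approx(1.0)


def test_cluster_partition_by_identity(rng):
    s1 = random_dna(rng, 1500)
    s2 = mutate_at(s1, list(range(0, 1500, 300)))       # 5 subs, ~99.7%
    s3 = mutate_at(s1, list(range(0, 1500, 20)))        # 75 subs, ~95%
    for a, b, expected in [(s1, s2, 0.996), (s1, s3, 0.95)]:
        assert refdb.global_identity(a, b) == pytest.approx(expected, abs=0.005)
    asg = refdb.greedy_cluster(
        [make_record("s1", s1), make_record("s2", s2), make_record("s3", s3)],
        0.99)
    by_member = {x.member_id: x.centroid_id for x in asg}
    assert by_member["s2"] == by_member["s1"]
    assert by_member["s3"] == "s3"


def test_noncentroid_identity_meets_threshold(small_db):
    records = small_db[0]
    for thr in (0.99, 0.90):
        for a in refdb.greedy_cluster(records, thr):
            if a.member_id != a.centroid_id:
                assert a.identity_to_centroid >= thr
            else:
                assert a.identity_to_centroid == 1.0


def test_cluster_count_monotone_in_threshold(small_db):
    records = small_db[0][:8]
    counts = [len({a.centroid_id for a in refdb.greedy_cluster(records, t)})
              for t in (0.80, 0.90, 0.96, 0.99)]
    assert counts == sorted(counts)


def test_empty_input_empty_output():
    assert refdb.greedy_cluster([], 0.99) == []


# --------------------------------------------------------------------------
# Full curation pass
# --------------------------------------------------------------------------

def test_curation_idempotent(small_db):
    records, lsu_hits, vectors, _truth = small_db
    vidx = VectorIndex(vectors)
    once = refdb.curate(records, lsu_hits, vidx, seed=5)
    twice = refdb.curate(once, [], vidx, seed=5)
    for a, b in zip(once, twice):
        assert a.seq == b.seq
        assert a.masked_intervals == b.masked_intervals
        assert a.kept == b.kept


def test_curation_flags_planted_artifacts():
    from ssuflash import synth
    spec = synth.FixtureSpec(seed=21, n_taxa=10, lsu_fraction=0.2,
                             low_complexity_fraction=0.2,
                             vector_insert_fraction=0.1)
    records, lsu_hits, vectors, truth = synth.gen_reference_db(spec)
    assert truth["has_vector"].sum() == 1  # deterministic allocation
    curated = refdb.curate(records, lsu_hits, VectorIndex(vectors), seed=5)
    by_id = {r.id: r for r in curated}
    for _, row in truth.iterrows():
        rec = by_id[row["id"]]
        if row["has_lsu"]:
            assert rec.drop_reason == refdb.DROP_LSU
        elif row["has_low_complexity"]:
            # at least 50 of the 60 planted positions are hard-masked
            assert sum(b - a for a, b in rec.masked_intervals) >= 50
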