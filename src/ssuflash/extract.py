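"""SSU rRNA read extraction by identity-cutoff mapping.

Aligns paired-end shotgun reads against the curated reference set with a
seed-and-extend strategy (shared canonical k-mers, banded extension via
edlib around the seed diagonal) and reports every hit at or above a
minimum identity (70% by default).  A pair is retained when at least
one mate aligns, and both mates of a retained pair are written out, so
downstream assembly sees complete pairs.  Also provides identity /
insert-size histograms and SAM pairing-flag repair for mappers that
emit incomplete pair information.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from ssuflash import config
from ssuflash.refdb import ReferenceRecord, revcomp


@dataclass(frozen=True)
class AlignmentHit:
    """One read-to-reference alignment."""

    read_id: str
    mate: int  # 1 or 2
    ref_id: str
    identity: float  # matches / alignment columns
    ref_start: int  # 0-based
    strand: str  # "+" or "-"
    aln_len: int = 0  # reference bases consumed
    insert_size: int | None = None
    is_best: bool = False
    taxonomy: tuple[str, ...] = ()


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    truth_origin: str | None = None  # fixture-only ground-truth label


# --------------------------------------------------------------------------
# Reference k-mer index
# --------------------------------------------------------------------------

def _canonical(kmer: str) -> tuple[str, bool]:
    """Canonical form of a k-mer and whether it equals the forward form."""
    rc = revcomp(kmer)
    return (kmer, True) if kmer <= rc else (rc, False)


class ReferenceIndex:
    """Canonical k-mer index over curated references.

    Maps each unmasked canonical k-mer to ``(ref index, position,
    forward)`` postings; k-mers overlapping masked (N) positions
    contribute nothing.
    """

    def __init__(self, records: Sequence[ReferenceRecord], k: int = config.EXTRACT_SEED_K):
        if k % 2 == 0:
            raise ValueError("seed k must be odd (avoids palindromic k-mers)")
        kept = [r for r in records if r.kept]
        if kept and k > min(len(r.seq) for r in kept):
            raise ValueError("k larger than the shortest reference")
        self.k = k
        self.records = kept
        self.postings: dict[str, list[tuple[int, int, bool]]] = defaultdict(list)
        for ri, rec in enumerate(kept):
            s = rec.seq
            for i in range(len(s) - k + 1):
                kmer = s[i:i + k]
                if "N" in kmer:
                    continue
                canon, fwd = _canonical(kmer)
                self.postings[canon].append((ri, i, fwd))

    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())


def build_ref_index(records: Sequence[ReferenceRecord],
                    k: int = config.EXTRACT_SEED_K) -> ReferenceIndex:
    """Build the canonical k-mer seeding index over curated references."""
    return ReferenceIndex(records, k=k)


# --------------------------------------------------------------------------
# Seed-and-extend alignment
# --------------------------------------------------------------------------

def _cigar_identity(cigar: str) -> tuple[float, int, int]:
    """(identity, alignment columns, reference bases) from an extended CIGAR."""
    matches = cols = ref_bases = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            matches += n
            ref_bases += n
        elif ch == "X":
            ref_bases += n
        elif ch == "D":
            ref_bases += n
        # "I": query-only columns
    return (matches / cols if cols else 0.0), cols, ref_bases


def _align_read(read: str, ref_seq: str, diag: int, band: int,
                ) -> tuple[float, int, int] | None:
    """Banded extension: align read to the reference window around ``diag``.

    Returns (identity, ref_start, ref_aln_len) or None when edlib finds
    no alignment.  Infix alignment of the read inside the window plays
    the role of a banded global alignment around the seed diagonal.
    """
    lo = max(0, diag - band)
    hi = min(len(ref_seq), diag + len(read) + band)
    window = ref_seq[lo:hi]
    if not window:
        return None
    res = edlib.align(read, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    identity, _cols, ref_bases = _cigar_identity(res["cigar"])
    start = lo + res["locations"][0][0]
    return identity, start, ref_bases


def _read_hits(seq: str, index: ReferenceIndex, min_identity: float,
               min_seeds: int, band: int) -> list[tuple[int, float, int, int, str]]:
    """All hits of one read: (ref index, identity, ref_start, aln_len, strand)."""
    k = index.k
    if len(seq) < k:
        return []
    # candidate (ref, strand) -> diagonal -> seed count
    diags: dict[tuple[int, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if not set(kmer) <= set("ACGT"):
            continue
        canon, read_fwd = _canonical(kmer)
        for ri, pos, ref_fwd in index.postings.get(canon, ()):
            if read_fwd == ref_fwd:  # read forward matches reference
                diags[(ri, "+")][(pos - i) // band] += 1
            else:  # read reverse-complement matches reference
                rc_i = len(seq) - k - i
                diags[(ri, "-")][(pos - rc_i) // band] += 1
    hits = []
    for (ri, strand), bands in diags.items():
        best_diag_count = 0
        best_diag = None
        for b, n in bands.items():
            # neighbouring bands can split co-linear seeds; pool them
            n_pooled = n + bands.get(b - 1, 0)
            if n_pooled > best_diag_count:
                best_diag_count = n_pooled
                best_diag = b * band
        if best_diag is None or best_diag_count < min_seeds:
            continue
        query = seq if strand == "+" else revcomp(seq)
        res = _align_read(query, index.records[ri].seq, best_diag, 2 * band)
        if res is None:
            continue
        identity, start, ref_bases = res
        if identity >= min_identity:
            hits.append((ri, identity, start, ref_bases, strand))
    return hits


def extract_reads(
    pairs: Sequence[ReadPair],
    index: ReferenceIndex,
    min_identity: float = config.EXTRACT_MIN_IDENTITY,
    min_seeds: int = config.EXTRACT_MIN_SEEDS,
    band: int = config.EXTRACT_BAND,
    best_only: bool = True,
) -> tuple[list[AlignmentHit], list[ReadPair]]:
    """Map read pairs to the reference index and retain SSU candidates.

    Alignments below ``min_identity`` are never reported.  By default
    each read reports its best-scoring placement and every placement
    tied with it (all ambiguous best-scoring hits are kept), mirroring
    mapper semantics; ``best_only=False`` additionally reports
    sub-optimal placements above the identity floor.  A pair is
    retained iff at least one mate has at least one hit; both mates of
    retained pairs appear in the output.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    all_hits: list[AlignmentHit] = []
    retained: list[ReadPair] = []
    for pair in pairs:
        per_pair: list[AlignmentHit] = []
        mate_best: dict[int, list[AlignmentHit]] = {}
        for mate, seq in ((1, pair.seq1), (2, pair.seq2)):
            raw = _read_hits(seq.upper(), index, min_identity, min_seeds, band)
            if not raw:
                continue
            best_ident = max(h[1] for h in raw)
            mate_hits = []
            for ri, identity, start, ref_bases, strand in sorted(
                    raw, key=lambda h: index.records[h[0]].id):
                rec = index.records[ri]
                mate_hits.append(AlignmentHit(
                    read_id=pair.read_id, mate=mate, ref_id=rec.id,
                    identity=identity, ref_start=start, strand=strand,
                    aln_len=ref_bases,
                    is_best=np.isclose(identity, best_ident),
                    taxonomy=rec.taxonomy,
                ))
            mate_best[mate] = [h for h in mate_hits if h.is_best]
            per_pair.extend(mate_best[mate] if best_only else mate_hits)
        if not per_pair:
            continue
        # insert size when both mates place best on the same reference
        if 1 in mate_best and 2 in mate_best:
            by_ref1 = {h.ref_id: h for h in mate_best[1]}
            insert_by_ref = {}
            for h2 in mate_best[2]:
                h1 = by_ref1.get(h2.ref_id)
                if h1 is None:
                    continue
                left = min(h1.ref_start, h2.ref_start)
                right = max(h1.ref_start + h1.aln_len,
                            h2.ref_start + h2.aln_len)
                insert_by_ref[h2.ref_id] = right - left
            if insert_by_ref:
                per_pair = [
                    h if h.insert_size is not None or h.ref_id not in insert_by_ref
                    or not h.is_best
                    else AlignmentHit(**{**h.__dict__,
                                         "insert_size": insert_by_ref[h.ref_id]})
                    for h in per_pair
                ]
        all_hits.extend(per_pair)
        retained.append(pair)
    return all_hits, retained


# --------------------------------------------------------------------------
# Histograms
# --------------------------------------------------------------------------

def alignment_histograms(
    hits: Sequence[AlignmentHit],
    min_identity: float = config.EXTRACT_MIN_IDENTITY,
) -> tuple[pd.Series, pd.Series]:
    """Identity (1% bins) and insert-size (10-bp bins) histograms.

    Identity uses each read's best hits; the insert histogram counts one
    entry per pair with a defined insert.  Counts conserve the number of
    contributing reads / pairs.
    """
    lo = int(np.floor(min_identity * 100))
    ident_bins = {b: 0 for b in range(lo, 101)}
    seen_reads = set()
    inserts: dict[str, int] = {}
    for h in hits:
        key = (h.read_id, h.mate)
        if h.is_best and key not in seen_reads:
            seen_reads.add(key)
            b = min(100, max(lo, int(np.floor(h.identity * 100))))
            ident_bins[b] += 1
        if h.insert_size is not None and h.read_id not in inserts:
            inserts[h.read_id] = h.insert_size
    ident = pd.Series(ident_bins, name="count").sort_index()
    ident.index.name = "identity_pct"
    if inserts:
        vals = np.array(list(inserts.values()))
        binned = (vals // 10) * 10
        ins = pd.Series(binned).value_counts().sort_index()
    else:
        ins = pd.Series(dtype=int)
    ins.name = "count"
    ins.index.name = "insert_bp"
    return ident, ins


# --------------------------------------------------------------------------
# FASTQ / SAM I/O
# --------------------------------------------------------------------------

def read_fastq_pairs(r1: str | Path, r2: str | Path | None = None) -> list[ReadPair]:
    """Load read pairs from two FASTQ files or one interleaved file."""
    if r2 is not None:
        it1 = SeqIO.parse(str(r1), "fastq")
        it2 = SeqIO.parse(str(r2), "fastq")
        out = []
        for a, b in zip(it1, it2):
            out.append(ReadPair(strip_mate_suffix(a.id), str(a.seq), str(b.seq)))
        return out
    recs = list(SeqIO.parse(str(r1), "fastq"))
    if len(recs) % 2:
        raise ValueError("interleaved FASTQ has an odd number of records")
    return [
        ReadPair(strip_mate_suffix(recs[i].id),
                 str(recs[i].seq), str(recs[i + 1].seq))
        for i in range(0, len(recs), 2)
    ]


def write_fastq_pairs(pairs: Iterable[ReadPair], r1: str | Path,
                      r2: str | Path) -> None:
    with open(r1, "w") as f1, open(r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


def sam_header(records: Sequence[ReferenceRecord]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.id, "LN": len(r.seq)} for r in records if r.kept],
    })


def write_sam(
    hits: Sequence[AlignmentHit],
    pairs: Sequence[ReadPair],
    records: Sequence[ReferenceRecord],
    path: str | Path,
) -> None:
    """Write retained pairs with their best hits as a valid SAM file.

    Each mate gets one primary line (its lexicographically first best
    hit, or an unmapped-but-retained line when only the other mate
    aligned); pairing flags are set consistently.
    """
    header = sam_header(records)
    best: dict[tuple[str, int], AlignmentHit] = {}
    for h in hits:
        key = (h.read_id, h.mate)
        if h.is_best and key not in best:
            best[key] = h
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in pairs:
            lines = []
            for mate, seq in ((1, pair.seq1), (2, pair.seq2)):
                a = pysam.AlignedSegment(header)
                a.query_name = pair.read_id
                a.query_sequence = seq
                a.flag = 0x1 | (0x40 if mate == 1 else 0x80)
                h = best.get((pair.read_id, mate))
                if h is None:
                    a.is_unmapped = True
                else:
                    a.reference_id = header.get_tid(h.ref_id)
                    a.reference_start = h.ref_start
                    a.is_reverse = h.strand == "-"
                    if h.strand == "-":
                        a.query_sequence = revcomp(seq)
                    a.cigartuples = [(0, len(seq))]
                    a.mapping_quality = 40
                    a.set_tag("XI", round(h.identity, 4))
                lines.append(a)
            for a, b in ((lines[0], lines[1]), (lines[1], lines[0])):
                _set_mate_fields(a, b)
            for a in lines:
                out.write(a)


def _set_mate_fields(a: pysam.AlignedSegment, b: pysam.AlignedSegment) -> None:
    a.is_paired = True
    a.mate_is_unmapped = b.is_unmapped
    a.mate_is_reverse = bool(b.is_reverse) and not b.is_unmapped
    if b.is_unmapped:
        a.next_reference_id = a.reference_id if not a.is_unmapped else -1
        a.next_reference_start = a.reference_start if not a.is_unmapped else -1
    else:
        a.next_reference_id = b.reference_id
        a.next_reference_start = b.reference_start
    a.is_proper_pair = (not a.is_unmapped and not b.is_unmapped
                        and a.reference_id == b.reference_id)


MATE_SUFFIXES = ("/1", "/2", ".1", ".2")


def strip_mate_suffix(name: str) -> str:
    for suf in MATE_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)]
    return name


def repair_sam_pairing(
    records: Iterable[pysam.AlignedSegment],
) -> list[pysam.AlignedSegment]:
    """Make pairing flags and mate fields mutually consistent per pair.

    Strips ``/1`` / ``/2`` read-name suffixes, sets read1/read2 bits,
    and rewrites mate-unmapped / mate-strand flags and mate reference /
    position fields from the partner record.  Orphan mates (one record
    only) are kept and flagged paired with an unmapped mate.  Idempotent.
    """
    records = list(records)
    groups: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    for rec in records:
        name = strip_mate_suffix(rec.query_name)
        if rec.query_name != name:
            mate = 1 if rec.query_name.endswith("1") else 2
            rec.query_name = name
            rec.is_read1 = mate == 1
            rec.is_read2 = mate == 2
        groups[name].append(rec)
    for name, recs in groups.items():
        if len(recs) == 1:
            a = recs[0]
            a.is_paired = True
            if not a.is_read1 and not a.is_read2:
                a.is_read1 = True
            a.mate_is_unmapped = True
            a.mate_is_reverse = False
            a.is_proper_pair = False
            a.next_reference_id = a.reference_id if not a.is_unmapped else -1
            a.next_reference_start = a.reference_start if not a.is_unmapped else -1
            continue
        a, b = recs[0], recs[1]
        if not (a.is_read1 or a.is_read2):
            a.is_read1, b.is_read2 = True, True
        _set_mate_fields(a, b)
        _set_mate_fields(b, a)
    return records
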