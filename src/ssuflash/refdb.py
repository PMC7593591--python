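"""Reference database curation.

Curates a raw SSU rRNA reference set carrying SILVA-style semicolon
taxonomy headers: removes entries contaminated by large-subunit (LSU)
rRNA fragments, screens cloning/sequencing vector k-mers, normalises
the alphabet to DNA with seeded ambiguity replacement, hard-masks
low-complexity / repeat regions by sliding-window k-mer entropy, and
de-replicates the survivors by greedy identity clustering (NR99/NR96).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ssuflash import config

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

#: curation drop reasons
DROP_NONE = "none"
DROP_LSU = "lsu_fragment"
DROP_SHORT = "too_short_after_trim"

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceRecord:
    """One reference SSU sequence with its taxonomy path and curation state.

    ``masked_intervals`` are 0-based half-open, disjoint and sorted;
    ``kept`` is False iff ``drop_reason`` is set.
    """

    id: str
    taxonomy: tuple[str, ...]
    seq: str
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)
    kept: bool = True
    drop_reason: str = DROP_NONE

    def __post_init__(self) -> None:
        if (self.drop_reason == DROP_NONE) != self.kept:
            raise ValueError("kept must be False iff drop_reason is set")


@dataclass(frozen=True)
class FeatureHit:
    """One rRNA-model hit on a target sequence (0-based half-open)."""

    target_id: str
    model: str  # ssu_bac | ssu_arc | ssu_euk | lsu
    evalue: float
    model_fraction: float
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"hit on {self.target_id}: start must be < end")
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")
        if not 0.0 <= self.model_fraction <= 1.0:
            raise ValueError("model_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ClusterAssignment:
    member_id: str
    centroid_id: str
    identity_to_centroid: float


# --------------------------------------------------------------------------
# FASTA / hit-table I/O
# --------------------------------------------------------------------------

def parse_taxonomy(description: str) -> tuple[str, ...]:
    """Parse the semicolon-delimited taxonomy path from a SILVA-style header."""
    parts = description.split(None, 1)
    if len(parts) < 2:
        return ()
    return tuple(x.strip() for x in parts[1].split(";") if x.strip())


def read_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Read references from FASTA with ``>accession Dom;Phy;...`` headers."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(ReferenceRecord(
            id=rec.id,
            taxonomy=parse_taxonomy(rec.description),
            seq=str(rec.seq).upper(),
        ))
    return out


def write_reference_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=";".join(r.taxonomy))
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_feature_hits(path: str | Path) -> list[FeatureHit]:
    """Read rRNA-model hits from a 9-column GFF-like TSV.

    Coordinates are 1-based inclusive on disk (GFF convention) and
    converted to 0-based half-open in memory.  The attribute column
    carries ``model=...;model_fraction=...``.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"expected 9 columns in hit table, got {len(f)}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            hits.append(FeatureHit(
                target_id=f[0],
                model=attrs.get("model", f[2]),
                evalue=float(f[5]),
                model_fraction=float(attrs["model_fraction"]),
                start=int(f[3]) - 1,
                end=int(f[4]),
                strand=f[6],
            ))
    return hits


def write_feature_hits(hits: Iterable[FeatureHit], path: str | Path,
                       source: str = "ssuflash") -> None:
    with open(path, "w") as fh:
        for h in hits:
            attrs = f"model={h.model};model_fraction={h.model_fraction:g}"
            fh.write("\t".join([
                h.target_id, source, "rRNA", str(h.start + 1), str(h.end),
                f"{h.evalue:g}", h.strand, ".", attrs,
            ]) + "\n")


def write_cluster_table(assignments: Iterable[ClusterAssignment],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("member\tcentroid\tidentity\n")
        for a in assignments:
            fh.write(f"{a.member_id}\t{a.centroid_id}\t{a.identity_to_centroid:.4f}\n")


# --------------------------------------------------------------------------
# LSU fragment removal
# --------------------------------------------------------------------------

def remove_lsu_fragments(
    records: list[ReferenceRecord],
    hits: list[FeatureHit],
    evalue_cutoff: float = config.LSU_EVALUE_CUTOFF,
    min_model_fraction: float = config.LSU_MIN_MODEL_FRACTION,
) -> list[ReferenceRecord]:
    """Flag references carrying a significant LSU-model hit as dropped.

    A record is dropped when any LSU hit has E-value <= ``evalue_cutoff``
    and covers strictly more than ``min_model_fraction`` of the model.
    Sequence content is never altered, only curation flags.
    """
    known = {r.id for r in records}
    contaminated = set()
    for h in hits:
        if h.target_id not in known:
            raise ValueError(f"hit references unknown record id {h.target_id!r}")
        if (h.model == "lsu" and h.evalue <= evalue_cutoff
                and h.model_fraction > min_model_fraction):
            contaminated.add(h.target_id)
    out = []
    for r in records:
        if r.id in contaminated and r.kept:
            out.append(replace(r, kept=False, drop_reason=DROP_LSU))
        else:
            out.append(r)
    return out


# --------------------------------------------------------------------------
# Low-complexity masking
# --------------------------------------------------------------------------

_UNAMBIGUOUS = frozenset("ACGT")


def _window_normalized_entropy(window: str, k: int) -> float | None:
    """Shannon entropy of the window's k-mer profile over its attainable max.

    k-mers containing characters outside {A,C,G,T} (masked or ambiguous
    positions) are excluded from counting; returns None when fewer than
    two countable k-mers remain (the window cannot be assessed).
    """
    n = len(window) - k + 1
    counts = Counter(
        window[i:i + k] for i in range(n)
        if _UNAMBIGUOUS.issuperset(window[i:i + k])
    )
    total = sum(counts.values())
    if total < 2:
        return None
    h = -sum((c / total) * math.log2(c / total) for c in counts.values())
    attainable = min(4 ** k, total)
    return h / math.log2(attainable)


def _flag_low_entropy_positions(seq: str, kmin: int, kmax: int,
                                cutoff: float, window: int) -> np.ndarray:
    """Boolean mask of positions covered by a low-entropy window for any k.

    Rolling-count implementation of the per-window statistic; agrees
    with :func:`_window_normalized_entropy` window by window.  k-mers
    containing non-ACGT characters never contribute, so already-masked
    regions cannot re-trigger masking.
    """
    L = len(seq)
    w = min(window, L)
    flagged = np.zeros(L, dtype=bool)
    for k in range(kmin, kmax + 1):
        if w <= k:
            continue
        kmers = [seq[i:i + k] for i in range(L - k + 1)]
        valid = [_UNAMBIGUOUS.issuperset(km) for km in kmers]
        nk = w - k + 1  # k-mer start positions per window
        counts: Counter = Counter(
            km for km, v in zip(kmers[:nk], valid[:nk]) if v)
        total = sum(counts.values())
        for start in range(0, L - w + 1):
            if start > 0:
                old, new = start - 1, start + nk - 1
                if valid[old]:
                    counts[kmers[old]] -= 1
                    total -= 1
                    if counts[kmers[old]] == 0:
                        del counts[kmers[old]]
                if valid[new]:
                    counts[kmers[new]] += 1
                    total += 1
            if total < 2:
                continue
            h = -sum((c / total) * math.log2(c / total)
                     for c in counts.values())
            attainable = min(4 ** k, total)
            if h / math.log2(attainable) < cutoff:
                # Flag only positions covered by k-mers that dominate this
                # window: the repeated/low-complexity content itself, not
                # the high-entropy flanks the window happens to span and
                # not chance duplicates.
                thresh = max(3, -(-max(counts.values()) // 2))
                for p in range(start, start + nk):
                    if valid[p] and counts[kmers[p]] >= thresh:
                        flagged[p:p + k] = True
    return flagged


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based half-open runs of True in a boolean array."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def mask_low_complexity(
    record: ReferenceRecord,
    kmin: int = config.MASK_KMIN,
    kmax: int = config.MASK_KMAX,
    entropy_cutoff: float = config.MASK_ENTROPY_CUTOFF,
    min_masked_len: int = config.MASK_MIN_LEN,
    window: int = config.MASK_WINDOW,
) -> ReferenceRecord:
    """Hard-mask low-complexity / repeat regions by k-mer entropy.

    Slides a window (length ``window``, step 1) along the sequence and,
    for every k in ``[kmin, kmax]``, finds windows whose k-mer entropy
    normalised by its maximum attainable value falls below
    ``entropy_cutoff``.  Within each such window, positions covered by
    k-mers that occur more than once in the window (the repeated /
    low-complexity content) are flagged.  Flagged positions are merged
    into runs; runs of at least ``min_masked_len`` bp are replaced by N
    and recorded in ``masked_intervals``.  Masking is hard (N) so that
    downstream seeding cannot start inside masked regions.
    """
    if kmin > kmax:
        raise ValueError("kmin must be <= kmax")
    if not record.seq:
        raise ValueError("cannot mask an empty sequence")
    if len(record.seq) <= kmax:
        raise ValueError("sequence must be longer than kmax")
    flagged = _flag_low_entropy_positions(
        record.seq, kmin, kmax, entropy_cutoff, window)
    intervals = [(a, b) for a, b in _runs(flagged) if b - a >= min_masked_len]
    if not intervals:
        return record
    seq = list(record.seq)
    for a, b in intervals:
        seq[a:b] = "N" * (b - a)
    merged = _merge_intervals(list(record.masked_intervals) + intervals)
    return replace(record, seq="".join(seq), masked_intervals=merged)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [ivs[0]]
    for a, b in ivs[1:]:
        pa, pb = out[-1]
        if a <= pb:
            out[-1] = (pa, max(pb, b))
        else:
            out.append((a, b))
    return out


# --------------------------------------------------------------------------
# Vector screening
# --------------------------------------------------------------------------

class VectorIndex:
    """k-mer index over vector sequences for contamination screening.

    Stores all k-mers (both strands) at the primary length ``k`` and, to
    support matches anchored at reference termini, all substrings of the
    vectors down to ``k_end``.
    """

    def __init__(self, vector_seqs: Sequence[str],
                 k: int = config.VECTOR_K, k_end: int = config.VECTOR_K_END):
        if k_end > k:
            raise ValueError("k_end must be <= k")
        self.k = k
        self.k_end = k_end
        self.kmer_sets: dict[int, set[str]] = {}
        for kk in range(k_end, k + 1):
            s: set[str] = set()
            for v in vector_seqs:
                v = v.upper()
                rc = revcomp(v)
                for src in (v, rc):
                    for i in range(len(src) - kk + 1):
                        s.add(src[i:i + kk])
            self.kmer_sets[kk] = s

    def matches(self, query: str, kk: int, max_hamming: int) -> bool:
        """True if ``query`` is within ``max_hamming`` of any indexed kk-mer."""
        pool = self.kmer_sets.get(kk)
        if not pool:
            return False
        if query in pool:
            return True
        if max_hamming >= 1:
            q = list(query)
            for i in range(len(q)):
                orig = q[i]
                for b in "ACGT":
                    if b == orig:
                        continue
                    q[i] = b
                    if "".join(q) in pool:
                        return True
                q[i] = orig
        return False


def build_vector_index(vector_fasta: str | Path,
                       k: int = config.VECTOR_K,
                       k_end: int = config.VECTOR_K_END) -> VectorIndex:
    seqs = [str(r.seq) for r in SeqIO.parse(str(vector_fasta), "fasta")]
    return VectorIndex(seqs, k=k, k_end=k_end)


def screen_vector(
    record: ReferenceRecord,
    vector_index: VectorIndex,
    max_hamming: int = config.VECTOR_MAX_HAMMING,
    min_len_after: int = config.VECTOR_MIN_LEN_AFTER,
) -> ReferenceRecord:
    """Trim vector-matching regions; drop the record if too short after.

    Full-length ``k``-mers are matched anywhere in the sequence;
    shortened k-mers (down to ``k_end``) only when anchored at either
    sequence end.  Matched positions are trimmed and the longest
    retained fragment kept; records whose longest fragment is below
    ``min_len_after`` are dropped with reason ``too_short_after_trim``.
    """
    seq = record.seq
    L = len(seq)
    k = vector_index.k
    covered = np.zeros(L, dtype=bool)
    for i in range(L - k + 1):
        if vector_index.matches(seq[i:i + k], k, max_hamming):
            covered[i:i + k] = True
    for kk in range(vector_index.k_end, k):
        if kk > L:
            continue
        if vector_index.matches(seq[:kk], kk, max_hamming):
            covered[:kk] = True
        if vector_index.matches(seq[L - kk:], kk, max_hamming):
            covered[L - kk:] = True
    if not covered.any():
        return record
    fragments = _runs(~covered)
    best = max(fragments, key=lambda ab: (ab[1] - ab[0], -ab[0]), default=(0, 0))
    if best[1] - best[0] < min_len_after:
        return replace(record, kept=False, drop_reason=DROP_SHORT)
    return replace(record, seq=seq[best[0]:best[1]], masked_intervals=[])


# --------------------------------------------------------------------------
# Alphabet normalisation
# --------------------------------------------------------------------------

def normalize_alphabet(record: ReferenceRecord, seed: int) -> ReferenceRecord:
    """RNA→DNA conversion plus seeded random replacement of ambiguity codes.

    U becomes T; every other IUPAC ambiguity code is replaced by a base
    drawn uniformly from the set it denotes, using a generator seeded
    with ``seed`` (reproducible).  Positions inside ``masked_intervals``
    stay N.
    """
    rng = np.random.default_rng(seed)
    masked = np.zeros(len(record.seq), dtype=bool)
    for a, b in record.masked_intervals:
        masked[a:b] = True
    out = []
    for i, c in enumerate(record.seq.upper()):
        if c == "U":
            c = "T"
        if masked[i]:
            out.append("N")
            continue
        if c in "ACGT":
            out.append(c)
        elif c in IUPAC_DNA:
            choices = IUPAC_DNA[c]
            out.append(choices[rng.integers(len(choices))])
        else:
            raise ValueError(f"non-IUPAC character {c!r} in {record.id}")
    return replace(record, seq="".join(out))


# --------------------------------------------------------------------------
# Greedy identity clustering (NR99 / NR96)
# --------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.ALIGN_MATCH
    aligner.mismatch_score = config.ALIGN_MISMATCH
    aligner.open_gap_score = config.ALIGN_GAP_OPEN
    aligner.extend_gap_score = config.ALIGN_GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def global_identity(a: str, b: str) -> float:
    """Matching columns / alignment length of an affine-gap global alignment."""
    if not a or not b:
        return 0.0
    aln = _ALIGNER.align(a, b)[0]
    c = aln.counts()
    total = c.identities + c.mismatches + c.gaps
    return c.identities / total if total else 0.0


def greedy_cluster(
    records: list[ReferenceRecord],
    identity_threshold: float,
) -> list[ClusterAssignment]:
    """Greedy length-sorted centroid clustering at a global-identity threshold.

    Records are processed in order of decreasing length (ties broken by
    id, ascending); each joins the first existing centroid whose global
    pairwise identity is at least the threshold, otherwise it founds a
    new cluster.  Mirrors greedy centroid clustering as used for NR99 /
    NR96 reference de-replication.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    centroids: list[ReferenceRecord] = []
    out: list[ClusterAssignment] = []
    for rec in ordered:
        placed = False
        for c in centroids:
            ident = global_identity(rec.seq, c.seq)
            if ident >= identity_threshold:
                out.append(ClusterAssignment(rec.id, c.id, ident))
                placed = True
                break
        if not placed:
            centroids.append(rec)
            out.append(ClusterAssignment(rec.id, rec.id, 1.0))
    return out


# --------------------------------------------------------------------------
# Full curation pass
# --------------------------------------------------------------------------

def curate(
    records: list[ReferenceRecord],
    lsu_hits: list[FeatureHit],
    vector_index: VectorIndex | None,
    seed: int,
    lsu_evalue_cutoff: float = config.LSU_EVALUE_CUTOFF,
    lsu_min_model_fraction: float = config.LSU_MIN_MODEL_FRACTION,
    entropy_cutoff: float = config.MASK_ENTROPY_CUTOFF,
    min_masked_len: int = config.MASK_MIN_LEN,
    min_len_after: int = config.VECTOR_MIN_LEN_AFTER,
) -> list[ReferenceRecord]:
    """Run the whole curation pass: LSU removal, vector screening,
    alphabet normalisation, then low-complexity masking.

    Dropped records are retained in the output with their flags so the
    curation is auditable; callers filter on ``kept``.  The pass is
    idempotent: applying it twice yields identical output.
    """
    recs = remove_lsu_fragments(records, lsu_hits, lsu_evalue_cutoff,
                                lsu_min_model_fraction)
    out = []
    for r in recs:
        if not r.kept:
            out.append(r)
            continue
        if vector_index is not None:
            r = screen_vector(r, vector_index, min_len_after=min_len_after)
            if not r.kept:
                out.append(r)
                continue
        r = normalize_alphabet(r, seed=seed)
        r = mask_low_complexity(r, entropy_cutoff=entropy_cutoff,
                                min_masked_len=min_masked_len)
        out.append(r)
    return out
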