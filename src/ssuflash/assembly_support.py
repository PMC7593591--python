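"""Targeted-assembly support: parameter rules, SSU-region extraction,
assembled-fraction accounting, and closest-reference assignment.

Assembler invocation itself is out of scope; these are the pure rules a
thin wrapper needs to drive a de Bruijn assembler (k-mer ladder from
read length) or an EM reconstructor (paired/single mode, minimum insert
size), plus the post-assembly accounting steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ssuflash import config
from ssuflash.extract import ReadPair, ReferenceIndex, extract_reads
from ssuflash.refdb import FeatureHit, ReferenceRecord, global_identity, revcomp


@dataclass(frozen=True)
class AssemblyParams:
    kmers: tuple[int, ...]
    emirge_mode: str  # "paired" | "single"
    emirge_insert: float | None
    iterations: int = config.EMIRGE_ITERATIONS

    def to_json(self) -> str:
        return json.dumps({
            "kmers": list(self.kmers),
            "emirge_mode": self.emirge_mode,
            "emirge_insert": self.emirge_insert,
            "iterations": self.iterations,
        })


@dataclass(frozen=True)
class SSURegion:
    """An SSU rRNA region extracted from an assembled contig."""

    contig_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    model: str
    evalue: float
    model_fraction: float
    seq: str

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}:{self.strand}:{self.model}"


def _next_lower_odd(x: int) -> int:
    return x if x % 2 else x - 1


def choose_kmers(read_len: int) -> tuple[int, ...]:
    """k-mer ladder for de Bruijn assembly, chosen from read length.

    Reads of at least 134 bp use the fixed ladder (99, 111, 127);
    shorter reads use the next lower odd numbers to the read length
    minus 27, 17, and 7 bp.
    """
    if read_len < 40:
        raise ValueError("read length below 40 bp is not supported")
    if read_len >= 134:
        return (99, 111, 127)
    return tuple(_next_lower_odd(read_len - d) for d in (27, 17, 7))


def emirge_insert_rule(
    read_len: int,
    observed_insert_mean: float | None = None,
) -> tuple[str, float | None]:
    """Paired/single mode and minimum insert size for EM reconstruction.

    Reads longer than 152 bp run single-ended.  Paired runs use the
    observed mean insert when it exceeds 2.2x the read length, else the
    floor of 2.2x read length + 0.5.
    """
    if read_len <= 0:
        raise ValueError("read length must be positive")
    if observed_insert_mean is not None and observed_insert_mean < 0:
        raise ValueError("insert size cannot be negative")
    if read_len > config.EMIRGE_MAX_PAIRED_READ_LEN:
        return "single", None
    floor = config.EMIRGE_INSERT_FACTOR * read_len
    if observed_insert_mean is not None and observed_insert_mean > floor:
        return "paired", float(observed_insert_mean)
    return "paired", floor + 0.5


def assembly_params(read_len: int,
                    observed_insert_mean: float | None = None) -> AssemblyParams:
    mode, insert = emirge_insert_rule(read_len, observed_insert_mean)
    return AssemblyParams(kmers=choose_kmers(read_len),
                         emirge_mode=mode, emirge_insert=insert)


# --------------------------------------------------------------------------
# SSU-region extraction from contigs
# --------------------------------------------------------------------------

def _overlap_frac(a: FeatureHit, b: FeatureHit) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / min(a.end - a.start, b.end - b.start)


def extract_ssu_regions(
    contigs: dict[str, str],
    hits: Sequence[FeatureHit],
    evalue_cutoff: float = config.SSU_REGION_EVALUE,
    min_model_fraction: float = config.SSU_REGION_MIN_MODEL_FRACTION,
) -> list[SSURegion]:
    """Extract SSU rRNA regions passing the significance thresholds.

    Hits must satisfy E-value <= ``evalue_cutoff`` and model coverage
    >= ``min_model_fraction``; minus-strand regions are emitted
    reverse-complemented.  When passing hits on the same contig and
    model overlap by at least half the shorter hit, only the lowest
    E-value hit is kept.
    """
    passing = []
    for h in hits:
        if h.target_id not in contigs:
            raise ValueError(f"hit on unknown contig {h.target_id!r}")
        if h.end > len(contigs[h.target_id]):
            raise ValueError(f"hit coordinates exceed contig {h.target_id!r}")
        if h.evalue <= evalue_cutoff and h.model_fraction >= min_model_fraction:
            passing.append(h)
    # overlap de-duplication: best (lowest E-value) hit wins
    kept: list[FeatureHit] = []
    for h in sorted(passing, key=lambda x: (x.evalue, x.target_id, x.start)):
        if any(k.target_id == h.target_id and k.model == h.model
               and _overlap_frac(k, h) >= 0.5 for k in kept):
            continue
        kept.append(h)
    regions = []
    for h in sorted(kept, key=lambda x: (x.target_id, x.start)):
        sub = contigs[h.target_id][h.start:h.end]
        if h.strand == "-":
            sub = revcomp(sub)
        regions.append(SSURegion(
            contig_id=h.target_id, start=h.start, end=h.end,
            strand=h.strand, model=h.model, evalue=h.evalue,
            model_fraction=h.model_fraction, seq=sub,
        ))
    return regions


def write_regions_fasta(regions: Sequence[SSURegion], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in regions],
        str(path), "fasta")


# --------------------------------------------------------------------------
# Post-assembly accounting
# --------------------------------------------------------------------------

def assembled_fraction(
    extracted: Sequence[ReadPair],
    assembled: Sequence[str],
    min_identity: float = config.REMAP_MIN_IDENTITY,
) -> float | None:
    """Fraction of extracted reads that remap to the assembled sequences.

    Re-runs the extraction aligner against the assembled sequences at a
    stringent identity (98% by default); returns mapped reads / total
    extracted reads, or None when there are no extracted reads.
    """
    n_reads = 2 * len(extracted)
    if n_reads == 0:
        return None
    if not assembled:
        return 0.0
    refs = [ReferenceRecord(id=f"asm{i}", taxonomy=(), seq=s.upper())
            for i, s in enumerate(assembled)]
    k = min(config.EXTRACT_SEED_K, min(len(s) for s in assembled))
    if k % 2 == 0:
        k -= 1
    index = ReferenceIndex(refs, k=k)
    hits, _ = extract_reads(extracted, index, min_identity=min_identity)
    mapped = {(h.read_id, h.mate) for h in hits}
    return len(mapped) / n_reads


def closest_reference(
    region: SSURegion,
    db: Sequence[ReferenceRecord],
    min_identity: float = config.CLOSEST_REF_MIN_IDENTITY,
) -> tuple[str, float] | None:
    """Highest-identity database reference for an assembled region.

    Global-alignment identity; ties broken by reference id
    (lexicographically first); None when no reference reaches the
    identity floor.
    """
    best: tuple[str, float] | None = None
    for ref in sorted((r for r in db if r.kept), key=lambda r: r.id):
        ident = global_identity(region.seq, ref.seq)
        if ident < min_identity:
            continue
        if best is None or ident > best[1] + 1e-12:
            best = (ref.id, ident)
    return best
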