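"""Seeded synthetic fixtures for every input the pipeline consumes.

Generates a SILVA-style reference database along a random taxonomy tree
(with optional planted LSU fragments, low-complexity runs, and vector
k-mer insertions), paired-end read libraries with ground-truth origins
and truth alignments, and planted-genome Fastg assembly graphs with bin
tables.  The generator emulates short-read shotgun libraries of the
kind the workflow targets: 100-bp paired reads at 220 +/- 110 bp insert
size with uniform substitution errors, a ~1,500-bp SSU gene, and a
background of non-rRNA genomic sequence.  One global seed fans out to
independent per-generator streams, so adding a generator never perturbs
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ssuflash.extract import ReadPair
from ssuflash.refdb import FeatureHit, ReferenceRecord

BASES = np.array(list("ACGT"))

RANK_NAMES = ("Domain", "Phylum", "Class", "Order", "Family", "Genus", "Species")


@dataclass
class FixtureSpec:
    """Study conditions for fixture generation.

    Defaults mirror the short-read libraries the workflow is designed
    for: 100-bp paired-end reads with 220 +/- 110 bp inserts, 1%
    substitution error, a full-length (~1,500 bp) SSU gene per taxon,
    and one tenth of the pairs drawn from SSU genes against a genomic
    background.
    """

    seed: int = 42
    n_taxa: int = 10
    tree_depth: int = 7
    ssu_length: int = 1500
    divergence: float = 0.02  # tip-level substitution rate (taxon from its group)
    domain_divergence: float = 0.15  # domain ancestor from the root sequence
    group_divergence: float = 0.05  # class-level group from its domain ancestor
    n_reads: int = 10_000  # read pairs
    read_len: int = 100
    insert_mean: float = 220.0
    insert_sd: float = 110.0
    error_rate: float = 0.01
    fraction_ssu: float = 0.1
    low_complexity_fraction: float = 0.0
    vector_insert_fraction: float = 0.0
    lsu_fraction: float = 0.0
    background_len: int = 100_000
    contigs_per_genome: int = 5
    contig_len: int = 2_000

    def __post_init__(self) -> None:
        for name in ("divergence", "error_rate", "fraction_ssu",
                     "low_complexity_fraction", "vector_insert_fraction",
                     "lsu_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _streams(spec: FixtureSpec) -> dict[str, np.random.Generator]:
    """Independent per-generator RNG streams fanned out from one seed."""
    root = np.random.SeedSequence(spec.seed)
    names = ("refdb", "reads", "fastg", "vector", "misc")
    return {n: np.random.default_rng(s)
            for n, s in zip(names, root.spawn(len(names)))}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# --------------------------------------------------------------------------
# Reference database
# --------------------------------------------------------------------------

def gen_reference_db(
    spec: FixtureSpec,
) -> tuple[list[ReferenceRecord], list[FeatureHit], list[str], pd.DataFrame]:
    """Simulate a reference database with SILVA-style taxonomy paths.

    A root SSU sequence is mutated along a random taxonomy tree of
    ``tree_depth`` ranks; designated records receive planted LSU
    fragments (with matching model hits), low-complexity homopolymer
    runs, or vector 27-mers, truth-flagged in the returned table.

    Returns ``(records, lsu_hits, vector_seqs, truth)`` where ``truth``
    has one row per record with boolean columns ``has_lsu``,
    ``has_low_complexity``, ``has_vector``.
    """
    if spec.n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = _streams(spec)["refdb"]
    vrng = _streams(spec)["vector"]
    root_seq = _random_seq(rng, spec.ssu_length)
    vector = _random_seq(vrng, 3000)
    lsu_core = _random_seq(rng, 600)

    # random taxonomy tree with hierarchical divergence: domains are deeply
    # diverged, class-level groups moderately, tips shallowly -- mirroring
    # how SSU rRNA identity scales with taxonomic rank
    n_groups = max(2, spec.n_taxa // 3)
    domain_seqs = {d: _mutate(rng, root_seq, spec.domain_divergence)
                   for d in range(2)}
    records = []
    seqs_by_group: dict[int, str] = {}
    for t in range(spec.n_taxa):
        g = t % n_groups  # round-robin keeps every group populated
        if g not in seqs_by_group:
            seqs_by_group[g] = _mutate(rng, domain_seqs[g % 2],
                                       spec.group_divergence)
        seq = _mutate(rng, seqs_by_group[g], spec.divergence)
        path = [f"Domain_{g % 2}", f"Phylum_{g}", f"Class_{g}"]
        for depth in range(3, spec.tree_depth):
            path.append(f"{RANK_NAMES[depth]}_{g}_{t}")
        records.append(ReferenceRecord(
            id=f"REF{t:04d}", taxonomy=tuple(path[:spec.tree_depth]), seq=seq))

    n = spec.n_taxa
    n_lsu = round(spec.lsu_fraction * n)
    n_lc = round(spec.low_complexity_fraction * n)
    n_vec = round(spec.vector_insert_fraction * n)
    order = rng.permutation(n)
    lsu_ids = set(order[:n_lsu])
    lc_ids = set(order[n_lsu:n_lsu + n_lc])
    vec_ids = set(order[n_lsu + n_lc:n_lsu + n_lc + n_vec])

    lsu_hits: list[FeatureHit] = []
    truth_rows = []
    for t, rec in enumerate(records):
        seq = rec.seq
        if t in lsu_ids:
            frag = _mutate(rng, lsu_core, 0.01)
            start = len(seq)
            seq = seq + frag
            lsu_hits.append(FeatureHit(
                target_id=rec.id, model="lsu", evalue=1e-50,
                model_fraction=0.2, start=start, end=len(seq), strand="+"))
        if t in lc_ids:
            pos = int(rng.integers(100, len(seq) - 100))
            seq = seq[:pos] + "A" * 60 + seq[pos + 60:]
        if t in vec_ids:
            vstart = int(rng.integers(0, len(vector) - 27))
            pos = int(rng.integers(50, len(seq) - 50))
            seq = seq[:pos] + vector[vstart:vstart + 27] + seq[pos + 27:]
        records[t] = ReferenceRecord(id=rec.id, taxonomy=rec.taxonomy, seq=seq)
        truth_rows.append({
            "id": rec.id, "has_lsu": t in lsu_ids,
            "has_low_complexity": t in lc_ids, "has_vector": t in vec_ids,
        })
    return records, lsu_hits, [vector], pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# Read libraries
# --------------------------------------------------------------------------

def gen_reads(
    spec: FixtureSpec,
    references: Sequence[ReferenceRecord],
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate a paired-end library with ground-truth origins.

    ``fraction_ssu`` of the pairs are drawn from the given SSU
    references, the rest from a random background genome; substitution
    errors at ``error_rate``.  The truth table records, per pair, its
    origin label (reference id or ``background``), fragment start and
    strandedness, sufficient to reproduce the error-free read from the
    reference (truth-alignment contract).
    """
    if not references:
        raise ValueError("references must be non-empty")
    if any(spec.read_len > len(r.seq) for r in references):
        raise ValueError("read length exceeds a reference length")
    rng = _streams(spec)["reads"]
    background = _random_seq(rng, spec.background_len)
    refs = [r for r in references if r.kept]
    n_ssu = round(spec.fraction_ssu * spec.n_reads)
    pairs: list[ReadPair] = []
    rows = []
    rl = spec.read_len
    for i in range(spec.n_reads):
        is_ssu = i < n_ssu
        if is_ssu:
            src = refs[int(rng.integers(len(refs)))]
            template, origin = src.seq, src.id
        else:
            template, origin = background, "background"
        frag = int(np.clip(rng.normal(spec.insert_mean, spec.insert_sd),
                           rl, len(template)))
        start = int(rng.integers(0, len(template) - frag + 1))
        fwd = template[start:start + rl]
        rev_start = start + frag - rl
        rev = _revcomp(template[rev_start:rev_start + rl])
        flip = bool(rng.integers(2))
        seq1, seq2 = (rev, fwd) if flip else (fwd, rev)
        read_id = f"read{i:06d}"
        pairs.append(ReadPair(
            read_id=read_id,
            seq1=_mutate(rng, seq1, spec.error_rate),
            seq2=_mutate(rng, seq2, spec.error_rate),
            truth_origin=origin,
        ))
        rows.append({
            "read_id": read_id, "origin": origin, "is_ssu": is_ssu,
            "frag_start": start, "frag_len": frag, "flipped": flip,
        })
    return pairs, pd.DataFrame(rows)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def truth_read(spec: FixtureSpec, references: Sequence[ReferenceRecord],
               row: pd.Series, mate: int) -> str:
    """Reconstruct the error-free sequence of one mate from the truth table."""
    if row["origin"] == "background":
        raise ValueError("background reads have no reference coordinates")
    template = next(r.seq for r in references if r.id == row["origin"])
    rl = spec.read_len
    fwd = template[row["frag_start"]:row["frag_start"] + rl]
    rev_start = row["frag_start"] + row["frag_len"] - rl
    rev = _revcomp(template[rev_start:rev_start + rl])
    first, second = (rev, fwd) if row["flipped"] else (fwd, rev)
    return first if mate == 1 else second


# --------------------------------------------------------------------------
# Assembly graphs
# --------------------------------------------------------------------------

def gen_fastg(
    spec: FixtureSpec,
    references: Sequence[ReferenceRecord] | None = None,
    n_bin_errors: int = 0,
) -> tuple[str, list[FeatureHit], pd.DataFrame, dict[str, set[str]]]:
    """Plant one connected contig graph ("genome") per taxon.

    Each genome is a random connected graph over ``contigs_per_genome``
    contigs, one of which carries an embedded SSU gene (with a matching
    passing model hit).  No inter-genome edges exist, so the connected
    components are exactly the planted genomes.  Returns the Fastg text,
    the SSU hits, a bin table (with ``n_bin_errors`` contigs reassigned
    to a wrong bin), and the ground-truth membership mapping
    ``genome id -> set of contig ids``.
    """
    if spec.n_taxa < 1:
        raise ValueError("need at least one taxon")
    rng = _streams(spec)["fastg"]
    lines = []
    hits: list[FeatureHit] = []
    bin_rows = []
    truth: dict[str, set[str]] = {}
    adjacency: dict[str, set[str]] = {}
    seqs: dict[str, str] = {}
    for g in range(spec.n_taxa):
        genome = f"g{g}"
        ids = [f"EDGE_{g}_{c}_length_{spec.contig_len}_cov_{10 + g}.0"
               for c in range(spec.contigs_per_genome)]
        truth[genome] = set(ids)
        for c, cid in enumerate(ids):
            seq = _random_seq(rng, spec.contig_len)
            if c == 0:
                gene = (references[g % len(references)].seq if references
                        else _random_seq(rng, spec.ssu_length))
                gene = gene[:spec.contig_len - 100]
                seq = seq[:50] + gene + seq[50 + len(gene):]
                hits.append(FeatureHit(
                    target_id=cid, model="ssu_bac", evalue=1e-150,
                    model_fraction=min(1.0, len(gene) / 1500),
                    start=50, end=50 + len(gene), strand="+"))
            seqs[cid] = seq
            adjacency[cid] = set()
        # random spanning tree keeps the genome connected
        for c in range(1, len(ids)):
            p = int(rng.integers(0, c))
            adjacency[ids[c]].add(ids[p])
        # a few extra intra-genome edges for branching structure
        for _ in range(max(0, spec.contigs_per_genome // 2 - 1)):
            a, b = rng.integers(0, len(ids), size=2)
            if a != b:
                adjacency[ids[int(a)]].add(ids[int(b)])
        for c, cid in enumerate(ids):
            bin_rows.append({"contig": cid, "bin": f"bin_{g}"})
    # orientation markers on some adjacency mentions exercise collapsing
    for cid in sorted(adjacency):
        nbrs = sorted(adjacency[cid])
        decorated = [n + "'" if rng.random() < 0.3 else n for n in nbrs]
        header = f">{cid}:{','.join(decorated)};" if decorated else f">{cid};"
        lines.append(header)
        lines.append(seqs[cid])
    bins = pd.DataFrame(bin_rows)
    if n_bin_errors:
        idx = rng.choice(len(bins), size=n_bin_errors, replace=False)
        all_bins = sorted(bins["bin"].unique())
        for i in idx:
            wrong = [b for b in all_bins if b != bins.loc[i, "bin"]]
            bins.loc[i, "bin"] = wrong[int(rng.integers(len(wrong)))]
    return "\n".join(lines) + "\n", hits, bins, truth
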