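"""Assembly-graph "fishing": linking SSU rRNA sequences to genome bins.

SSU rRNA genes routinely assemble into their own contigs and are missed
by composition- or coverage-based binning.  The assembly graph (Fastg)
retains the adjacencies that linear scaffolds lose; starting from an
SSU-bearing contig, the connected component collects the contigs of the
genome it belongs to, which can then be reconciled with a binning table
and with targeted-assembly SSU sequences.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import networkx as nx
import pandas as pd

from ssuflash import config
from ssuflash.refdb import FeatureHit

_SPADES_HEADER = re.compile(
    r"^(?:NODE|EDGE)_(?P<num>\w+?)_length_(?P<len>\d+)_cov_(?P<cov>[\d.eE+-]+)")


@dataclass
class Contig:
    id: str
    length: int | None = None
    coverage: float | None = None
    seq: str | None = None

    @property
    def size_bp(self) -> int:
        if self.seq is not None:
            return len(self.seq)
        return self.length or 0


@dataclass
class AssemblyGraph:
    """Contigs plus undirected, orientation-blind adjacency."""

    contigs: dict[str, Contig] = field(default_factory=dict)
    graph: nx.Graph = field(default_factory=nx.Graph)


def _strip_orientation(name: str) -> str:
    return name[:-1] if name.endswith("'") else name


def parse_fastg(path: str | Path) -> AssemblyGraph:
    """Parse a (SPAdes-dialect) Fastg file into an undirected graph.

    Header records ``>u[:v1,v2,...];`` encode adjacencies; a trailing
    ``'`` marks reverse-complement orientation and is collapsed, so u
    and u' become one node and every adjacency one undirected edge.
    SPAdes-style ``EDGE_n_length_L_cov_C`` names yield length and
    coverage; unknown header styles fall back to the raw id.
    """
    ag = AssemblyGraph()
    adjacencies: list[tuple[str, str, str]] = []  # (record, u, v)
    current: Contig | None = None
    chunks: list[str] = []

    def finish() -> None:
        if current is not None:
            current.seq = "".join(chunks) or None
            if current.length is None and current.seq:
                current.length = len(current.seq)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not line.startswith(">"):
                chunks.append(line)
                continue
            finish()
            chunks = []
            record = line[1:].rstrip(";")
            head, _, adj = record.partition(":")
            u = _strip_orientation(head)
            m = _SPADES_HEADER.match(u)
            meta = {}
            if m:
                meta = {"length": int(m.group("len")),
                        "coverage": float(m.group("cov"))}
            if u not in ag.contigs:
                current = Contig(id=u, **meta)
                ag.contigs[u] = current
                ag.graph.add_node(u)
            else:
                current = ag.contigs[u]
                for k, v in meta.items():
                    setattr(current, k, v)
            if adj:
                for v in adj.split(","):
                    adjacencies.append((record, u, _strip_orientation(v.strip())))
    finish()
    for record, u, v in adjacencies:
        if v not in ag.contigs:
            raise ValueError(
                f"Fastg record {record!r}: adjacency target {v!r} "
                "does not exist")
        if u != v:
            ag.graph.add_edge(u, v)
    return ag


def write_fastg(ag: AssemblyGraph, path: str | Path) -> None:
    """Serialise the graph back to Fastg (one record per contig)."""
    with open(path, "w") as fh:
        for cid in sorted(ag.contigs):
            nbrs = sorted(ag.graph.neighbors(cid))
            header = f">{cid}:{','.join(nbrs)};" if nbrs else f">{cid};"
            fh.write(header + "\n")
            seq = ag.contigs[cid].seq
            if seq:
                fh.write(seq + "\n")


@dataclass
class FishedCluster:
    """One seed-containing connected component of the assembly graph."""

    seed_contigs: tuple[str, ...]
    members: tuple[str, ...]
    total_bp: int
    below_min_size: bool = False
    bin_overlap: dict[str, int] = field(default_factory=dict)
    majority_bin: str | None = None
    majority_fraction: float | None = None
    ambiguous_bin: bool = False
    matched_ssu: dict[str, tuple[str, float]] = field(default_factory=dict)


def fish(
    ag: AssemblyGraph,
    ssu_hits: Sequence[FeatureHit],
    min_cluster_size_bp: int = 0,
) -> list[FishedCluster]:
    """Collect the connected component of every SSU-bearing contig.

    One cluster per component containing at least one seed contig;
    clusters whose total contig length falls below
    ``min_cluster_size_bp`` are flagged, not dropped.
    """
    seeds = {h.target_id for h in ssu_hits}
    missing = seeds - set(ag.contigs)
    if missing:
        raise ValueError(f"SSU hits on contigs absent from graph: {sorted(missing)}")
    if not seeds:
        warnings.warn("no SSU seed contigs; nothing to fish", stacklevel=2)
        return []
    clusters = []
    for comp in nx.connected_components(ag.graph):
        comp_seeds = sorted(seeds & comp)
        if not comp_seeds:
            continue
        members = tuple(sorted(comp))
        total = sum(ag.contigs[c].size_bp for c in members)
        clusters.append(FishedCluster(
            seed_contigs=tuple(comp_seeds), members=members, total_bp=total,
            below_min_size=total < min_cluster_size_bp,
        ))
    return sorted(clusters, key=lambda c: c.seed_contigs)


def read_bin_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "bin"],
                     dtype=str, comment="#")
    return dict(zip(df["contig"], df["bin"]))


def link_bins(
    clusters: Sequence[FishedCluster],
    bin_table: dict[str, str],
    known_contigs: set[str] | None = None,
) -> list[FishedCluster]:
    """Annotate clusters with per-bin member counts and the majority bin.

    Ties between bins are reported (both bins keep their counts) and the
    cluster flagged ambiguous.  Binned contigs absent from the graph are
    warned about and ignored.
    """
    if known_contigs is not None:
        unknown = set(bin_table) - known_contigs
        if unknown:
            warnings.warn(
                f"{len(unknown)} binned contig(s) absent from graph ignored",
                stacklevel=2)
    for cl in clusters:
        counts = Counter(bin_table[c] for c in cl.members if c in bin_table)
        cl.bin_overlap = dict(counts)
        if not counts:
            cl.majority_bin = None
            cl.majority_fraction = None
            continue
        top = counts.most_common()
        best_n = top[0][1]
        tied = sorted(b for b, n in top if n == best_n)
        cl.ambiguous_bin = len(tied) > 1
        cl.majority_bin = tied[0]
        cl.majority_fraction = best_n / len(cl.members)
    return list(clusters)


def _glocal_identity(query: str, target: str) -> float:
    """Identity of the best infix alignment of query within target."""
    if not query or not target:
        return 0.0
    if len(query) > len(target):
        query, target = target, query
    res = edlib.align(query.upper(), target.upper(), mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return 0.0
    matches = cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n, num = int(num), ""
        cols += n
        if ch == "=":
            matches += n
    return matches / cols if cols else 0.0


def match_targeted_ssu(
    clusters: Sequence[FishedCluster],
    targeted: dict[str, str],
    ag: AssemblyGraph,
    min_identity: float = config.REMAP_MIN_IDENTITY,
) -> list[FishedCluster]:
    """Match each seed contig against targeted-assembly SSU sequences.

    Records the best match at or above ``min_identity`` per seed; ties
    go to the lexicographically first targeted-sequence id.
    """
    for cl in clusters:
        for seed in cl.seed_contigs:
            seq = ag.contigs[seed].seq
            if not seq:
                continue
            best: tuple[str, float] | None = None
            for tid in sorted(targeted):
                ident = _glocal_identity(targeted[tid], seq)
                if ident < min_identity:
                    continue
                if best is None or ident > best[1] + 1e-12:
                    best = (tid, ident)
            if best is not None:
                cl.matched_ssu[seed] = best
    return list(clusters)


def write_clusters_tsv(clusters: Sequence[FishedCluster], path: str | Path) -> None:
    rows = []
    for i, cl in enumerate(clusters):
        rows.append({
            "cluster": i,
            "seeds": ",".join(cl.seed_contigs),
            "n_members": len(cl.members),
            "members": ",".join(cl.members),
            "total_bp": cl.total_bp,
            "below_min_size": cl.below_min_size,
            "majority_bin": cl.majority_bin or "",
            "majority_fraction": ("" if cl.majority_fraction is None
                                  else f"{cl.majority_fraction:.3f}"),
            "ambiguous_bin": cl.ambiguous_bin,
            "matched_ssu": ";".join(
                f"{s}={t}:{i:.3f}" for s, (t, i) in sorted(cl.matched_ssu.items())),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
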