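"""LCA-consensus taxonomic profiling of extracted read pairs.

Each read pair is assigned the last common ancestor (longest common
prefix) of the SILVA-style taxonomy paths of all its database hits,
both mates pooled.  Assignments are then summarised at a chosen rank
(1 = domain ... 7 = species; class by default), with pairs classified
above the requested rank reported as ``(unclassified) <last rank>``.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ssuflash import config
from ssuflash.extract import AlignmentHit

#: a taxonomy path is an ordered tuple of rank labels, domain first
TaxPath = tuple[str, ...]

ROOT: TaxPath = ()
ROOT_LABEL = "Unclassified"


def lca(paths: Sequence[TaxPath]) -> TaxPath:
    """Longest common prefix of taxonomy paths (case-sensitive exact match).

    Disjoint paths reduce to the root (empty path, rendered as
    ``Unclassified``).
    """
    if not paths:
        raise ValueError("LCA of an empty path set is undefined")
    first = paths[0]
    depth = min(len(p) for p in paths)
    out = []
    for i in range(depth):
        label = first[i]
        if all(p[i] == label for p in paths):
            out.append(label)
        else:
            break
    return tuple(out)


def classify_pairs(
    hits: Sequence[AlignmentHit],
) -> dict[str, TaxPath]:
    """Per-pair LCA over the taxonomy paths of all hits (mates pooled).

    Pairs with no hits simply do not appear (they were never extracted).
    """
    by_pair: dict[str, list[TaxPath]] = defaultdict(list)
    for h in hits:
        by_pair[h.read_id].append(tuple(h.taxonomy))
    return {read_id: lca(paths) for read_id, paths in by_pair.items()}


@dataclass
class TaxProfile:
    """Per-sample counts of LCA-consensus taxa at one summarised level."""

    sample_id: str
    level: int
    counts: dict[TaxPath, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[TaxPath, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()} if t else {}


def render_label(path: TaxPath, level: int) -> str:
    """Human-readable taxon label; truncated paths get an
    ``(unclassified)`` annotation mirroring report style."""
    if not path:
        return ROOT_LABEL
    label = ";".join(path)
    if len(path) < level:
        return f"(unclassified) {path[-1]}"
    return label


def summarize(
    assignments: Mapping[str, TaxPath],
    level: int = config.TAX_LEVEL_DEFAULT,
    sample_id: str = "sample",
) -> TaxProfile:
    """Summarise per-pair assignments at a taxonomic level.

    Paths are truncated to ``level``; paths shorter than the level are
    counted at their own (maximal) depth and later rendered with the
    ``(unclassified)`` annotation.  Counts conserve the number of
    classified pairs.
    """
    if not 1 <= level <= 7:
        raise ValueError("level must be between 1 (domain) and 7 (species)")
    counts: Counter = Counter()
    for path in assignments.values():
        counts[tuple(path[:level])] += 1
    return TaxProfile(sample_id=sample_id, level=level, counts=dict(counts))


# --------------------------------------------------------------------------
# I/O ("NTU table")
# --------------------------------------------------------------------------

def write_profile_tsv(profile: TaxProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tcount\n")
        for tax, n in sorted(profile.counts.items(),
                             key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{render_label(tax, profile.level)}\t{n}\n")


def write_profile_json(profile: TaxProfile, path: str | Path) -> None:
    payload = {
        "sample_id": profile.sample_id,
        "level": profile.level,
        "total": profile.total,
        "counts": [{"path": list(k), "count": v}
                   for k, v in sorted(profile.counts.items())],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_profile_json(path: str | Path) -> TaxProfile:
    payload = json.loads(Path(path).read_text())
    return TaxProfile(
        sample_id=payload["sample_id"],
        level=payload["level"],
        counts={tuple(e["path"]): e["count"] for e in payload["counts"]},
    )
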