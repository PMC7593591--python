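"""Per-sequence k-mer entropy and informational redundancy.

Low-complexity artifacts among extracted rRNA reads show up as
sequences with unusually low k-mer entropy.  For a sequence of length
``L`` and k-mer length ``k``, k-mers are counted in a sliding window of
width ``k``; with occurrence counts ``w_i`` and probabilities
``p_i = w_i / (L - k + 1)``, the entropy is ``H = -sum p_i log2 p_i``.
The informational redundancy ``R = 1 - H / log2(A)``, where the
attainable alphabet size ``A`` is ``4**k`` unless the sequence is too
short to realise it, in which case ``A = L - k + 1``.  R lies in
[0, 1]: 0 at maximum entropy, 1 for a homopolymer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from ssuflash import config


@dataclass(frozen=True)
class EntropyStats:
    read_id: str
    k: int
    L: int  # countable window total (ambiguous windows excluded)
    H: float  # bits
    A: int  # attainable alphabet size
    R: float  # redundancy in [0, 1]


def compute_entropy(seq: str, k: int = config.ENTROPY_K,
                    read_id: str = "") -> EntropyStats:
    """Entropy and redundancy of one sequence's k-mer profile.

    Windows containing characters outside {A,C,G,T} are skipped and the
    window total adjusted accordingly.
    """
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    counts: Counter = Counter()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) <= set("ACGT"):
            counts[kmer] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous k-mer windows in sequence")
    p = np.array(list(counts.values()), dtype=float) / total
    H = float(-(p * np.log2(p)).sum())
    A = 4 ** k if total > 4 ** k else total
    R = 1.0 if A <= 1 else 1.0 - H / np.log2(A)
    return EntropyStats(read_id=read_id, k=k, L=total, H=H, A=A,
                        R=float(min(max(R, 0.0), 1.0)))


def redundancy_summary(stats: Sequence[EntropyStats]) -> dict:
    """Mean / median / 0.01-bin histogram of redundancy over reads."""
    if not stats:
        raise ValueError("empty statistics list")
    r = np.array([s.R for s in stats])
    edges = np.arange(0, 1.01 + 1e-9, 0.01)
    hist, _ = np.histogram(r, bins=edges)
    return {
        "n": len(stats),
        "mean_R": float(r.mean()),
        "median_R": float(np.median(r)),
        "histogram": pd.Series(hist, index=np.round(edges[:-1], 2),
                               name="count"),
    }


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def entropy_from_fastq(path: str | Path, k: int = config.ENTROPY_K) -> list[EntropyStats]:
    return [compute_entropy(str(r.seq), k=k, read_id=r.id)
            for r in SeqIO.parse(str(path), "fastq")]


def entropy_from_sam(path: str | Path, k: int = config.ENTROPY_K) -> list[EntropyStats]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.query_sequence and len(rec.query_sequence) >= k:
                out.append(compute_entropy(rec.query_sequence, k=k,
                                           read_id=rec.query_name))
    return out


def write_entropy_tsv(stats: Iterable[EntropyStats], path: str | Path) -> None:
    df = pd.DataFrame([s.__dict__ for s in stats])
    df.to_csv(path, sep="\t", index=False)
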