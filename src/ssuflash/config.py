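"""Pipeline-wide default parameters.

Every stage default lives here under one name so that a run can be
reproduced from its configuration alone.  Values are the workflow's
published operating points; functions take them as keyword defaults and
the CLI exposes each as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: Reference curation ------------------------------------------------------
LSU_EVALUE_CUTOFF: float = 1e-10  #: drop entries with LSU hits at E <= this
LSU_MIN_MODEL_FRACTION: float = 0.10  #: ... covering > this fraction of the LSU model
MASK_KMIN: int = 4  #: smallest k for low-complexity entropy masking
MASK_KMAX: int = 8  #: largest k for low-complexity entropy masking
MASK_ENTROPY_CUTOFF: float = 0.7  #: normalised entropy below which a window is flagged
MASK_MIN_LEN: int = 20  #: minimum length (bp) of a masked run
MASK_WINDOW: int = 100  #: sliding-window length for masking
VECTOR_K: int = 27  #: primary vector-screening k-mer length
VECTOR_K_END: int = 11  #: shortest k-mer allowed at sequence termini
VECTOR_MAX_HAMMING: int = 1  #: maximum Hamming distance for a vector k-mer match
VECTOR_MIN_LEN_AFTER: int = 800  #: discard references shorter than this after trimming
CLUSTER_ID_NR99: float = 0.99  #: primary de-replication identity ("NR99")
CLUSTER_ID_NR96: float = 0.96  #: secondary de-replication identity ("NR96")

#: Read extraction ---------------------------------------------------------
EXTRACT_MIN_IDENTITY: float = 0.70  #: minimum mapping identity for a reported hit
EXTRACT_SEED_K: int = 13  #: seeding k-mer length (odd; canonical k-mers)
EXTRACT_MIN_SEEDS: int = 2  #: co-linear seeds required per candidate
EXTRACT_BAND: int = 16  #: diagonal band width for seed grouping / extension

#: Entropy QC --------------------------------------------------------------
ENTROPY_K: int = 5  #: k-mer length for informational redundancy

#: Taxonomic summary -------------------------------------------------------
TAX_LEVEL_DEFAULT: int = 3  #: class level (1=domain ... 7=species)
TAX_RANK_NAMES: Sequence[str] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

#: Targeted-assembly support ----------------------------------------------
SSU_REGION_EVALUE: float = 1e-100  #: E-value cutoff for SSU regions on contigs
SSU_REGION_MIN_MODEL_FRACTION: float = 0.6  #: minimum model coverage for a region
REMAP_MIN_IDENTITY: float = 0.98  #: identity for remapping reads to assemblies
CLOSEST_REF_MIN_IDENTITY: float = 0.70  #: identity floor for closest-database-hit
EMIRGE_MAX_PAIRED_READ_LEN: int = 152  #: above this, run reads as single-ended
EMIRGE_INSERT_FACTOR: float = 2.2  #: minimum insert = factor * read length (+0.5)
EMIRGE_ITERATIONS: int = 40

#: Multi-sample comparison -------------------------------------------------
COMPARE_TOP_N: int = 30  #: taxa kept individually in heatmaps; rest pooled as "Other"

#: Global-alignment scoring used for clustering / closest-reference identity
ALIGN_MATCH: int = 1
ALIGN_MISMATCH: int = -2
ALIGN_GAP_OPEN: int = -5
ALIGN_GAP_EXTEND: int = -2


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (one sample)."""

    sample_id: str = "sample"
    min_identity: float = EXTRACT_MIN_IDENTITY
    tax_level: int = TAX_LEVEL_DEFAULT
    entropy_k: int = ENTROPY_K
    seed: int = 42
    out_prefix: str = "ssuflash_out"
    html: bool = False
    zip_archive: bool = False
    extra: dict = field(default_factory=dict)


def defaults() -> dict:
    """All shipped defaults as one flat mapping (for reports and parity checks)."""
    return {
        "lsu_evalue_cutoff": LSU_EVALUE_CUTOFF,
        "lsu_min_model_fraction": LSU_MIN_MODEL_FRACTION,
        "mask_kmin": MASK_KMIN,
        "mask_kmax": MASK_KMAX,
        "mask_entropy_cutoff": MASK_ENTROPY_CUTOFF,
        "mask_min_len": MASK_MIN_LEN,
        "vector_k": VECTOR_K,
        "vector_k_end": VECTOR_K_END,
        "vector_max_hamming": VECTOR_MAX_HAMMING,
        "vector_min_len_after": VECTOR_MIN_LEN_AFTER,
        "cluster_id_nr99": CLUSTER_ID_NR99,
        "cluster_id_nr96": CLUSTER_ID_NR96,
        "extract_min_identity": EXTRACT_MIN_IDENTITY,
        "entropy_k": ENTROPY_K,
        "tax_level_default": TAX_LEVEL_DEFAULT,
        "ssu_region_evalue": SSU_REGION_EVALUE,
        "ssu_region_min_model_fraction": SSU_REGION_MIN_MODEL_FRACTION,
        "remap_min_identity": REMAP_MIN_IDENTITY,
        "closest_ref_min_identity": CLOSEST_REF_MIN_IDENTITY,
        "emirge_max_paired_read_len": EMIRGE_MAX_PAIRED_READ_LEN,
        "emirge_iterations": EMIRGE_ITERATIONS,
    }
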