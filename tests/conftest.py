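"""Shared fixtures: small seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ssuflash import extract, refdb, synth


@pytest.fixture(scope="session")
def small_spec() -> synth.FixtureSpec:
    return synth.FixtureSpec(seed=11, n_taxa=10, n_reads=400, fraction_ssu=0.5)


@pytest.fixture(scope="session")
def small_db(small_spec):
    records, lsu_hits, vectors, truth = synth.gen_reference_db(small_spec)
    return records, lsu_hits, vectors, truth


@pytest.fixture(scope="session")
def small_reads(small_spec, small_db):
    records = small_db[0]
    return synth.gen_reads(small_spec, records)


@pytest.fixture(scope="session")
def small_index(small_db):
    return extract.build_ref_index(small_db[0])


@pytest.fixture(scope="session")
def small_hits(small_reads, small_index):
    pairs, _truth = small_reads
    return extract.extract_reads(pairs, small_index)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_record(id: str, seq: str, taxonomy=("Bacteria", "P", "C")) -> refdb.ReferenceRecord:
    return refdb.ReferenceRecord(id=id, taxonomy=tuple(taxonomy), seq=seq)
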