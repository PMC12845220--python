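"""Shared fixtures: tiny hand-built datasets for exact-value tests."""

from __future__ import annotations

import numpy as np
import pytest

from dinpop.datamodel import (
    BinaryMarkerMatrix,
    GenotypeTable,
    HaplotypeAlignment,
    Individual,
)


def make_table(rows, loci):
    """Build a GenotypeTable from [(id, pop, ploidy, [call, ...]), ...].

    Calls are tuples of allele labels (already at full ploidy) or None.
    """
    individuals = [Individual(r[0], r[1], r[2]) for r in rows]
    calls = [[tuple(sorted(c)) if c is not None else None for c in r[3]]
             for r in rows]
    return GenotypeTable(individuals, list(loci), calls)


@pytest.fixture
def diploid_two_pops():
    """2 populations x 10 diploids, 1 locus; hand-checkable W-C fixture."""
    rows = []
    # P1: 6 x (a,a), 4 x (a,b)   P2: 2 x (a,b), 8 x (b,b)
    for i in range(6):
        rows.append((f"p1_{i}", "P1", 2, [("a", "a")]))
    for i in range(4):
        rows.append((f"p1h_{i}", "P1", 2, [("a", "b")]))
    for i in range(2):
        rows.append((f"p2h_{i}", "P2", 2, [("a", "b")]))
    for i in range(8):
        rows.append((f"p2_{i}", "P2", 2, [("b", "b")]))
    return make_table(rows, ["L1"])


@pytest.fixture
def small_alignment():
    """4 sequences x 12 columns with one gapped and one N column."""
    seqs = np.array([
        list("ACGTACGTACGT"),
        list("ACGAACGTACGT"),   # differs at col 4
        list("ACGTAC-TACGT"),   # gap at col 7
        list("ACGTACGTNCGT"),   # N at col 9
    ])
    labels = [("s1", "P1"), ("s2", "P1"), ("s3", "P2"), ("s4", "P2")]
    return HaplotypeAlignment(seqs, labels, [("r1", 1, 12)])


def make_binary(values, groups=None, pops=None, sizes=None):
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    return BinaryMarkerMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        population_ids=pops or ["P1"] * n,
        replicate_groups=groups or [f"g{i}" for i in range(n)],
        fragment_ids=[f"f{j}" for j in range(m)],
        fragment_sizes=sizes or [100 + j for j in range(m)],
        values=values,
    )
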