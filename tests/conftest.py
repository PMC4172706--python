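"""Shared fixtures: one session-scoped reference build plus small helpers."""

from __future__ import annotations

import pytest

from ibismhc import amplify, simulate_lanes, simulate_southern
from ibismhc.sim import build_reference_set

#: fixture seed for the session-scoped reference; every constraint asserted
#: in the tests must hold for any seed, this one just keeps the suite fast.
SEED = 11

GENOTYPES = [("hp1", "hp1"), ("hp1", "hp2"), ("hp1", "hp3"),
             ("hp2", "hp2"), ("hp2", "hp3"), ("hp3", "hp3")]


@pytest.fixture(scope="session")
def reference():
    return build_reference_set(SEED)


@pytest.fixture(scope="session")
def family(reference):
    return reference.exon2_family


@pytest.fixture(scope="session")
def amplicons_for(reference):
    """genotype pair -> pooled amplicon sequences of the diploid."""

    def _get(pair):
        return [
            a.sequence
            for h in pair
            for a in amplify(reference.haplotypes[h].seq,
                             reference.fwd_primer, reference.rev_primer)
        ]

    return _get


@pytest.fixture(scope="session")
def lanes_for(amplicons_for):
    def _get(pair):
        return simulate_lanes(amplicons_for(pair))

    return _get


@pytest.fixture(scope="session")
def southern_for(reference):
    def _get(pair):
        seqs = [reference.haplotypes[h].seq for h in pair]
        return simulate_southern(seqs, list(reference.probes.values()))

    return _get
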