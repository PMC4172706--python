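"""Digestion engine: site scanning, fragmenting, and the gel model."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ibismhc import (Enzyme, default_enzymes, digest, find_sites, revcomp,
                     to_gel_lane)
from ibismhc.enzymes import IUPAC

ENZ = default_enzymes()

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


def brute_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Naive O(n*m) sliding-window oracle, IUPAC-aware, both strands."""
    rec = enzyme.recognition.upper()
    size = len(rec)

    def hits(pattern):
        return [
            p for p in range(len(seq) - size + 1)
            if all(seq[p + i] in IUPAC[pattern[i]] for i in range(size))
        ]

    cuts = {p + enzyme.cut_offset for p in hits(rec)}
    if rec != revcomp(rec):
        cuts.update(p + size - enzyme.cut_offset for p in hits(revcomp(rec)))
    return sorted(c for c in cuts if 0 < c < len(seq))


def test_toy_bamhi_cuts():
    assert find_sites("GGATCCAAGGATCC", ENZ["BamHI"]) == [1, 9]


def test_typed_amplicon_sites(family):
    assert find_sites(family["II"], ENZ["RsaI"]) == []
    assert find_sites(family["I"], ENZ["RsaI"]) == [124, 178]
    assert find_sites(family["III"], ENZ["SalI"]) == [201]
    assert find_sites(family["IV"], ENZ["PstI"]) == [168]


@pytest.mark.parametrize("enzyme_name",
                         ["BamHI", "EcoRI", "PstI", "RsaI", "SalI", "Sau3AI"])
def test_find_sites_against_biopython(enzyme_name):
    """Cross-check against Bio.Restriction on 100 random sequences.

    Bio.Restriction reports the 1-based first base downstream of the cut,
    i.e. our 0-based cut position plus one.
    """
    from Bio import Restriction
    from Bio.Seq import Seq

    bio_enz = getattr(Restriction, enzyme_name)
    rng = np.random.default_rng(0)
    for _ in range(100):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        expected = sorted(p - 1 for p in bio_enz.search(Seq(seq))
                          if 0 < p - 1 < len(seq))
        assert find_sites(seq, ENZ[enzyme_name]) == expected


@given(seq=dna)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_sites_match_bruteforce_oracle(seq):
    for enzyme in (ENZ["RsaI"], ENZ["BamHI"],
                   Enzyme("DegPal", "CCWGG", 2),
                   Enzyme("NonPal", "GGTCTC", 1)):
        assert find_sites(seq, enzyme) == brute_sites(seq, enzyme)


def test_nonpalindromic_reverse_strand_site():
    # GGTCTC with cut offset 1; its reverse-strand occurrence GAGACC at
    # position 2 maps to a top-strand cut at 2 + 6 - 1 = 7.
    enz = Enzyme("NonPal", "GGTCTC", 1)
    assert find_sites("AAGAGACCAA", enz) == [7]
    assert find_sites("AAGGTCTCAA", enz) == [3]


@given(seq=dna, which=st.sets(st.sampled_from(sorted(ENZ)), min_size=1, max_size=4))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_digest_conserves_length_and_tiles(seq, which):
    res = digest(seq, [ENZ[n] for n in which])
    assert sum(res.lengths) == len(seq)
    assert len(res.fragments) == len(res.cut_positions) + 1
    # fragments tile the input exactly
    pos = 0
    for start, end, length in res.fragments:
        assert start == pos and end - start == length
        pos = end
    assert pos == len(seq)


@given(seq=dna)
@settings(max_examples=40, derandomize=True, deadline=None)
def test_adding_enzymes_never_decreases_cuts(seq):
    single = digest(seq, ENZ["RsaI"])
    double = digest(seq, [ENZ["RsaI"], ENZ["Sau3AI"]])
    assert set(single.cut_positions) <= set(double.cut_positions)


def test_gel_lane_collapses_duplicates():
    lane = to_gel_lane([279, 279, 124], relative_tolerance=0.02)
    assert lane.bands == (124, 279)


def test_gel_lane_merges_comigrating_sizes():
    lane = to_gel_lane([8000, 8100], relative_tolerance=0.05, min_detectable=500)
    assert len(lane.bands) == 1
    assert lane.matches(8000)


def test_gel_lane_detection_threshold():
    assert to_gel_lane([54], min_detectable=40).bands == (54,)
    assert to_gel_lane([30], min_detectable=40).bands == ()


def test_gel_lane_idempotent():
    lane = to_gel_lane([100, 104, 300, 990, 1000], relative_tolerance=0.05)
    again = to_gel_lane(lane.bands, relative_tolerance=0.05)
    assert again.bands == lane.bands


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        find_sites("ACGTX", ENZ["RsaI"])
    with pytest.raises(ValueError):
        Enzyme("bad", "GZTC", 1)
    with pytest.raises(ValueError):
        Enzyme("bad", "GATC", 9)
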