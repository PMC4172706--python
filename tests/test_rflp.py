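"""PCR-RFLP typing: profiles, type assignment, lane simulation and decoding."""

from __future__ import annotations

from itertools import combinations

import pytest

from ibismhc import (assign_type, decode_lanes, default_profile_table,
                     profile_of_amplicon, simulate_lanes)
from ibismhc.rflp import TableError, TypeProfileTable
from tests.conftest import GENOTYPES

TABLE = default_profile_table()

#: the published typing scheme: fragment lists in positional order
EXPECTED_PROFILES = {
    "I": {"PstI": (279,), "RsaI": (124, 54, 101), "SalI": (279,)},
    "II": {"PstI": (279,), "RsaI": (279,), "SalI": (279,)},
    "III": {"PstI": (279,), "RsaI": (124, 54, 101), "SalI": (201, 78)},
    "IV": {"PstI": (168, 111), "RsaI": (279,), "SalI": (279,)},
}


@pytest.mark.parametrize("type_id", sorted(EXPECTED_PROFILES))
def test_amplicon_profiles_match_reference_table(family, type_id):
    assert profile_of_amplicon(family[type_id]) == EXPECTED_PROFILES[type_id]


@pytest.mark.parametrize("type_id", sorted(EXPECTED_PROFILES))
def test_typing_round_trip(family, type_id):
    call = assign_type(profile_of_amplicon(family[type_id]))
    assert call.type_id == type_id


def test_assign_type_examples():
    assert assign_type({"PstI": (168, 111), "RsaI": (279,), "SalI": (279,)}).type_id == "IV"
    assert assign_type({"PstI": (279,), "RsaI": (279,), "SalI": (279,)}).type_id == "II"
    miss = assign_type({"PstI": (200, 79), "RsaI": (279,), "SalI": (279,)})
    assert miss.type_id is None
    assert miss.nearest in TABLE.profiles


def test_short_amplicon_warns_and_yields_whole_fragment():
    with pytest.warns(UserWarning):
        profile = profile_of_amplicon("GGGGGGGGGG")
    assert profile == {"PstI": (10,), "RsaI": (10,), "SalI": (10,)}


def test_lanes_of_homozygous_hp1_show_only_279(lanes_for):
    obs = lanes_for(("hp1", "hp1"))
    assert all(lane.bands == (279,) for lane in obs.lanes.values())


def test_lanes_of_hp2_hp3_pool_all_three_types(lanes_for):
    obs = lanes_for(("hp2", "hp3"))
    bands = obs.band_sets()
    assert bands["PstI"] == {279, 168, 111}
    assert bands["RsaI"] == {279, 124, 54, 101}
    assert bands["SalI"] == {279, 201, 78}


def test_single_amplicon_lanes_equal_its_profile(family):
    obs = simulate_lanes([family["I"]])
    assert obs.band_sets() == {
        "PstI": {279}, "RsaI": {124, 54, 101}, "SalI": {279}
    }


def test_empty_pool_is_an_error():
    with pytest.raises(ValueError, match="no product"):
        simulate_lanes([])


def test_decode_undigested_lanes_forces_type_ii(lanes_for):
    assert decode_lanes(lanes_for(("hp1", "hp1"))) == [frozenset({"II"})]


def test_decode_hp1_hp2_lanes_masks_type_ii(lanes_for):
    sets = decode_lanes(lanes_for(("hp1", "hp2")))
    assert sets == [frozenset({"I", "IV"}), frozenset({"I", "II", "IV"})]


def test_decode_hp3_homozygote(lanes_for):
    assert decode_lanes(lanes_for(("hp3", "hp3"))) == [frozenset({"I", "III"})]


def test_decoding_always_contains_the_true_type_union(reference, lanes_for):
    for pair in GENOTYPES:
        truth = frozenset().union(
            *(reference.haplotypes[h].exon2_types for h in pair)
        )
        assert truth in decode_lanes(lanes_for(pair))


def test_exactly_one_lane_ambiguous_genotype_pair(lanes_for):
    """hp1/2 vs hp2/2 share lanes; every other genotype pair differs."""
    observations = {pair: lanes_for(pair).band_sets() for pair in GENOTYPES}
    same = [
        (a, b) for a, b in combinations(GENOTYPES, 2)
        if observations[a] == observations[b]
    ]
    assert same == [(("hp1", "hp2"), ("hp2", "hp2"))]


def test_inconsistent_lanes_raise():
    from ibismhc.enzymes import GelLane
    from ibismhc.rflp import LaneObservation

    weird = LaneObservation(lanes={
        "PstI": GelLane((250,)), "RsaI": GelLane((279,)), "SalI": GelLane((279,)),
    })
    with pytest.raises(ValueError, match="consistent"):
        decode_lanes(weird)


def test_malformed_table_rejected(tmp_path):
    bad = tmp_path / "bad.tsv"
    rows = ["type\tenzyme\tfragments_bp"]
    for t in ("I", "II"):
        for e in ("PstI", "RsaI", "SalI"):
            rows.append(f"{t}\t{e}\t279")  # identical rows: indistinguishable
    bad.write_text("\n".join(rows) + "\n")
    with pytest.raises(TableError, match="indistinguishable"):
        TypeProfileTable.from_tsv(bad)

    off = tmp_path / "off.tsv"
    rows = ["type\tenzyme\tfragments_bp",
            "I\tPstI\t280", "I\tRsaI\t279", "I\tSalI\t279"]
    off.write_text("\n".join(rows) + "\n")
    with pytest.raises(TableError, match="sum"):
        TypeProfileTable.from_tsv(off)
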