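"""Synthetic-data generator: structural constraints and reproducibility."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from ibismhc import (amplify, assign_type, default_enzymes, digest,
                     find_sites, profile_of_amplicon)
from ibismhc.sim import (EXON2_SPECS, FOUNDER_GENOTYPES, GenerationError,
                         HAPLOTYPE_DEFS, PopulationSpec, build_exon2_allele,
                         build_exon2_family, build_reference_set,
                         default_population, simulate_population)
from ibismhc.sim._scrub import STOP_CODONS
from tests.conftest import SEED

ENZ = default_enzymes()


def has_stop(seq: str) -> bool:
    return any(seq[i:i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


@pytest.mark.parametrize("type_id", ["I", "II", "III", "IV"])
def test_single_allele_builder_satisfies_spec(type_id):
    spec = EXON2_SPECS[type_id]
    seq = build_exon2_allele(spec, seed=123)
    assert len(seq) == 279
    for enzyme_name, cuts in spec.required_sites.items():
        assert find_sites(seq, ENZ[enzyme_name]) == sorted(cuts)
    for enzyme_name in spec.forbidden_enzymes:
        assert find_sites(seq, ENZ[enzyme_name]) == []
    # no catalogued enzyme cuts anywhere it should not
    for name, enz in ENZ.items():
        sites = find_sites(seq, enz)
        assert sites == sorted(spec.required_sites.get(name, ()))
    assert not has_stop(seq)


def test_allele_builder_deterministic_and_seed_sensitive():
    spec = EXON2_SPECS["I"]
    a1 = build_exon2_allele(spec, seed=5)
    a2 = build_exon2_allele(spec, seed=5)
    b = build_exon2_allele(spec, seed=6)
    assert a1 == a2
    assert a1 != b
    # both seeds satisfy the constraints; they differ outside them
    for seq in (a1, b):
        assert find_sites(seq, ENZ["RsaI"]) == [124, 178]


@pytest.mark.parametrize("type_id", ["I", "II", "III", "IV"])
@pytest.mark.parametrize("enzyme_name", ["PstI", "RsaI", "SalI"])
def test_every_family_member_reproduces_its_table_row(family, type_id, enzyme_name):
    from ibismhc.rflp import default_profile_table

    expected = default_profile_table().profiles[type_id][enzyme_name]
    assert digest(family[type_id], ENZ[enzyme_name]).lengths == expected


def test_family_cross_type_constraints(family):
    seqs = family.sequences
    assert {s[:36] for s in seqs.values()} == {seqs["II"][:36]}
    assert {s[-21:] for s in seqs.values()} == {seqs["II"][-21:]}
    diff = [i for i, (x, y) in enumerate(zip(seqs["I"], seqs["III"])) if x != y]
    assert diff and all(200 <= i < 206 for i in diff)
    assert not any(has_stop(s) for s in seqs.values())


def test_translated_gene_exons_are_stop_free(reference):
    for gene in reference.genes.values():
        for kind, ordv, s, e in gene.parts:
            if kind == "exon":
                assert not has_stop(gene.seq[s:e]), (gene.allele_id, ordv)


def test_haplotype_architecture(reference):
    for name, hap in reference.haplotypes.items():
        n_pairs = len(HAPLOTYPE_DEFS[name]["pairs"])
        genes = [f for f in hap.features if f.type == "gene"
                 and f.attrs.get("ID") not in ("COL11A2", "BRD2")]
        daa = [f for f in genes if f.attrs["ID"].startswith("DAA")]
        dab = [f for f in genes if f.attrs["ID"].startswith("DAB")]
        assert len(daa) == len(dab) == n_pairs
        assert all(f.strand == "-" for f in daa)
        assert all(f.strand == "+" for f in dab)
        # the class II cluster lies between COL11A2 and BRD2
        col = next(f for f in hap.features if f.attrs.get("ID") == "COL11A2")
        brd = next(f for f in hap.features if f.attrs.get("ID") == "BRD2")
        assert col.end < min(f.start for f in genes)
        assert max(f.end for f in genes) < brd.start


def test_single_exact_bamhi_interval_and_no_ecori(reference):
    for name, hap in reference.haplotypes.items():
        cuts = find_sites(hap.seq, ENZ["BamHI"])
        assert len(cuts) == 2
        assert cuts[1] - cuts[0] == HAPLOTYPE_DEFS[name]["bamhi"]
        assert (cuts[0], cuts[1]) == hap.bamhi_interval
        assert find_sites(hap.seq, ENZ["EcoRI"]) == []


def test_rescanned_exon2_types_match_declared_composition(reference):
    for name, hap in reference.haplotypes.items():
        amps = amplify(hap.seq, reference.fwd_primer, reference.rev_primer)
        called = tuple(
            assign_type(profile_of_amplicon(a.sequence)).type_id for a in amps
        )
        assert called == hap.exon2_types
    assert reference.haplotypes["hp2"].exon2_types == ("IV", "I")
    assert reference.haplotypes["hp3"].exon2_types == ("III", "I", "I")


def test_reference_build_is_bit_reproducible():
    a = build_reference_set(SEED)
    b = build_reference_set(SEED)
    for name in a.haplotypes:
        assert a.haplotypes[name].seq == b.haplotypes[name].seq
    c = build_exon2_family(seed=SEED + 1)
    assert c.sequences != a.exon2_family.sequences


def test_founder_type_unions():
    _, truth = simulate_population(default_population(n_progeny=0))
    expected = {
        "A": {"I", "II", "IV"}, "B": {"I", "II", "III"}, "C": {"I", "II", "III"},
        "D": {"II"}, "E": {"I", "III", "IV"},
    }
    for ind, types in expected.items():
        assert truth.type_union(ind) == frozenset(types)


def test_forced_inheritance_from_homozygous_cross():
    spec = PopulationSpec(founders={"D": ("hp1", "hp1")},
                          pedigree=(("c1", "D", "D"),), seed=0)
    for seed in range(5):
        individuals, _ = simulate_population(spec, rng=np.random.default_rng(seed))
        assert individuals["c1"].genotype == ("hp1", "hp1")


def test_unknown_parent_rejected():
    spec = PopulationSpec(founders=dict(FOUNDER_GENOTYPES),
                          pedigree=(("c1", "D", "Z"),))
    with pytest.raises(KeyError, match="Z"):
        simulate_population(spec)


def test_progeny_genotype_frequencies_follow_mendel():
    """hp1/2 x hp1/2 cross: 1:2:1 genotype law within 4 sigma at n=1000."""
    n = 1000
    spec = PopulationSpec(
        founders={"A1": ("hp1", "hp2"), "A2": ("hp1", "hp2")},
        pedigree=tuple((f"c{i}", "A1", "A2") for i in range(n)),
        seed=SEED,
    )
    individuals, _ = simulate_population(spec)
    counts = Counter(individuals[f"c{i}"].genotype for i in range(n))
    for pair, p in {("hp1", "hp1"): 0.25, ("hp1", "hp2"): 0.5,
                    ("hp2", "hp2"): 0.25}.items():
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(counts[pair] - n * p) <= 4 * sigma


def test_truth_table_spot_check_against_sequences(reference):
    """Re-scanning an individual's sequences reproduces its truth row."""
    _, truth = simulate_population(default_population(n_progeny=0))
    for ind, pair in truth.genotypes.items():
        amps = [
            a.sequence for h in pair
            for a in amplify(reference.haplotypes[h].seq,
                             reference.fwd_primer, reference.rev_primer)
        ]
        called = sorted(
            assign_type(profile_of_amplicon(a)).type_id for a in amps
        )
        assert tuple(called) == truth.exon2_types[ind]


def test_impossible_architecture_is_a_generation_error(reference):
    from ibismhc.sim.genome import build_haplotype

    HAPLOTYPE_DEFS["tmp"] = dict(pairs=HAPLOTYPE_DEFS["hp3"]["pairs"],
                                 bamhi=2000, total=30000)
    try:
        with pytest.raises(GenerationError, match="fit"):
            build_haplotype("tmp", reference.components, np.random.default_rng(0))
    finally:
        del HAPLOTYPE_DEFS["tmp"]
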