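"""Founder genotypes and Mendelian sampling of progeny.

The five founders (A-E) carry the genotypes inferred for the real founder
population: hp1/2, hp1/3, hp1/3, hp1/1 and hp2/3.  The pedigree linking the
progeny to founders is not published, so the generator accepts any pedigree
and defaults to a D x E cross; each child receives one haplotype drawn
uniformly from each parent's pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import HAPLOTYPE_DEFS

__all__ = [
    "FOUNDER_GENOTYPES",
    "PopulationSpec",
    "Individual",
    "TruthTable",
    "default_population",
    "simulate_population",
]

FOUNDER_GENOTYPES: dict[str, tuple[str, str]] = {
    "A": ("hp1", "hp2"),
    "B": ("hp1", "hp3"),
    "C": ("hp1", "hp3"),
    "D": ("hp1", "hp1"),
    "E": ("hp2", "hp3"),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Founders with fixed genotypes plus a pedigree of progeny."""

    founders: Mapping[str, tuple[str, str]]
    pedigree: tuple[tuple[str, str, str], ...]  # (child, dam, sire)
    seed: int = 0

    def validate(self) -> None:
        known = set(self.founders)
        for child, dam, sire in self.pedigree:
            for parent in (dam, sire):
                if parent not in known:
                    raise KeyError(f"unknown parent {parent!r} for {child!r}")
            known.add(child)
        for name, pair in self.founders.items():
            for h in pair:
                if h not in HAPLOTYPE_DEFS:
                    raise ValueError(f"founder {name}: unknown haplotype {h!r}")


@dataclass(frozen=True)
class Individual:
    id: str
    haplotypes: tuple[str, str]  # catalogue names, unordered pair

    @property
    def genotype(self) -> tuple[str, str]:
        return tuple(sorted(self.haplotypes))


@dataclass(frozen=True)
class TruthTable:
    """Generator-side ground truth for round-trip testing."""

    genotypes: Mapping[str, tuple[str, str]]
    locus_alleles: Mapping[str, tuple[str, ...]]
    exon2_types: Mapping[str, tuple[str, ...]]  # multiset, sorted

    def type_union(self, individual_id: str) -> frozenset[str]:
        return frozenset(self.exon2_types[individual_id])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, pair in self.genotypes.items():
            rows.append({
                "individual": ind,
                "genotype": "/".join(pair),
                "alleles": ";".join(self.locus_alleles[ind]),
                "exon2_types": ",".join(self.exon2_types[ind]),
            })
        return pd.DataFrame(rows)


def default_population(n_progeny: int = 20, dam: str = "D", sire: str = "E",
                       seed: int = 0) -> PopulationSpec:
    pedigree = tuple(
        (f"P{i + 1:02d}", dam, sire) for i in range(n_progeny)
    )
    return PopulationSpec(founders=dict(FOUNDER_GENOTYPES), pedigree=pedigree,
                          seed=seed)


def _truth_for(pair: tuple[str, str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    alleles: list[str] = []
    types: list[str] = []
    for h in pair:
        for daa_id, dab_id, _ in HAPLOTYPE_DEFS[h]["pairs"]:
            alleles.extend([daa_id, dab_id])
        spec_types = [t for t in _haplotype_types(h)]
        types.extend(spec_types)
    return tuple(alleles), tuple(sorted(types))


def _haplotype_types(name: str) -> list[str]:
    from .genome import _DAB_SPECS

    return [_DAB_SPECS[dab_id][1] for _, dab_id, _ in HAPLOTYPE_DEFS[name]["pairs"]]


def simulate_population(
    spec: PopulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Individual], TruthTable]:
    """Founders verbatim plus Mendelian progeny, in pedigree order."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    individuals: dict[str, Individual] = {}
    for name, pair in spec.founders.items():
        individuals[name] = Individual(id=name, haplotypes=tuple(pair))
    for child, dam, sire in spec.pedigree:
        inherited = tuple(
            individuals[parent].haplotypes[int(rng.integers(0, 2))]
            for parent in (dam, sire)
        )
        individuals[child] = Individual(id=child, haplotypes=inherited)
    genotypes = {i.id: i.genotype for i in individuals.values()}
    locus_alleles = {}
    exon2_types = {}
    for ind, pair in genotypes.items():
        alleles, types = _truth_for(pair)
        locus_alleles[ind] = alleles
        exon2_types[ind] = types
    truth = TruthTable(genotypes=genotypes, locus_alleles=locus_alleles,
                       exon2_types=exon2_types)
    return individuals, truth
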