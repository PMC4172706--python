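"""Diploid genotype inference for the MHC class II region.

Three evidence channels constrain an individual's unordered haplotype pair:

* the set of exon-2 types recovered by cloned-PCR sequencing,
* the PCR-RFLP lane pattern (pooled amplicon digests), and
* the Southern-blot band sizes of a BamHI+EcoRI digest probed with class II
  probes, where each reference haplotype contributes one diagnostic band.

Each channel yields a candidate set of haplotype pairs drawn from a
closed-world catalogue; :func:`integrate_evidence` intersects the channels.
Presence/absence data cannot distinguish a homozygote from a hemizygote, so
pairs are unordered with replacement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

from .enzymes import Enzyme, GelLane, default_enzymes, digest, revcomp, to_gel_lane
from .rflp import LaneObservation, TypeProfileTable, default_profile_table

__all__ = [
    "HaplotypeCatalog",
    "SouthernObservation",
    "GenotypeCall",
    "PopulationSummary",
    "genotypes_from_typeset",
    "genotypes_from_lanes",
    "simulate_southern",
    "genotypes_from_southern",
    "integrate_evidence",
    "population_summary",
]

Pair = tuple[str, str]  # unordered; stored sorted


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    exon2_types: tuple[str, ...]  # multiset, one entry per IIB locus
    southern_bp: int


@dataclass(frozen=True)
class HaplotypeCatalog:
    """The closed-world set of reference haplotypes."""

    entries: Mapping[str, CatalogEntry]

    def __post_init__(self) -> None:
        sizes = [e.southern_bp for e in self.entries.values()]
        if len(set(sizes)) != len(sizes):
            raise ValueError("diagnostic Southern sizes are not unique")
        if any(not e.exon2_types for e in self.entries.values()):
            raise ValueError("haplotype with empty exon-2 type multiset")

    @classmethod
    def from_yaml(cls, path=None) -> "HaplotypeCatalog":
        import yaml

        if path is None:
            with resources.as_file(
                resources.files("ibismhc.data") / "haplotype_catalog.yaml"
            ) as p:
                doc = yaml.safe_load(p.read_text())
        else:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
        entries = {
            name: CatalogEntry(
                name=name,
                exon2_types=tuple(spec["exon2_types"]),
                southern_bp=int(spec["southern_bp"]),
            )
            for name, spec in doc["haplotypes"].items()
        }
        return cls(entries=entries)

    def pairs(self) -> list[Pair]:
        """All unordered genotypes (with replacement) over the catalogue."""
        return [tuple(sorted(p)) for p in
                combinations_with_replacement(sorted(self.entries), 2)]

    def type_union(self, pair: Pair) -> frozenset[str]:
        a, b = pair
        return frozenset(self.entries[a].exon2_types) | frozenset(self.entries[b].exon2_types)

    def southern_sizes(self, pair: Pair) -> frozenset[int]:
        return frozenset(self.entries[h].southern_bp for h in pair)


_DEFAULT_CATALOG: HaplotypeCatalog | None = None


def default_catalog() -> HaplotypeCatalog:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = HaplotypeCatalog.from_yaml()
    return _DEFAULT_CATALOG


@dataclass(frozen=True)
class SouthernObservation:
    """Band sizes from a BamHI+EcoRI digest hybridized with class II probes."""

    lane: GelLane

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.lane.bands):
            raise ValueError("non-positive band size")


@dataclass(frozen=True)
class GenotypeCall:
    """Outcome of evidence integration for one individual."""

    individual_id: str
    candidates: tuple[Pair, ...]
    status: str  # "unique" | "ambiguous" | "inconsistent"
    evidence: Mapping[str, tuple[Pair, ...]] = field(default_factory=dict)

    @property
    def genotype(self) -> Pair | None:
        return self.candidates[0] if self.status == "unique" else None


def genotypes_from_typeset(
    observed: Iterable[str],
    catalog: HaplotypeCatalog | None = None,
) -> list[Pair]:
    """Pairs whose combined exon-2 type content equals the observed type set."""
    if catalog is None:
        catalog = default_catalog()
    observed = frozenset(observed)
    if not observed:
        raise ValueError("empty observed type set")
    known = set().union(*(e.exon2_types for e in catalog.entries.values()))
    if not observed <= known:
        raise ValueError(f"unknown exon-2 types: {sorted(observed - known)}")
    return [p for p in catalog.pairs() if catalog.type_union(p) == observed]


def genotypes_from_lanes(
    obs: LaneObservation,
    catalog: HaplotypeCatalog | None = None,
    table: TypeProfileTable | None = None,
    min_detectable: int = 40,
) -> list[Pair]:
    """Pairs whose predicted pooled-digest lanes equal the observation."""
    if catalog is None:
        catalog = default_catalog()
    if table is None:
        table = default_profile_table()
    observed = obs.band_sets()
    out = []
    for pair in catalog.pairs():
        types = catalog.type_union(pair)
        if all(
            table.band_set(types, e, min_detectable) == observed.get(e, frozenset())
            for e in table.enzymes
        ):
            out.append(pair)
    return out


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def simulate_southern(
    genomes: Sequence[str],
    probes: Sequence[str],
    enzymes: Mapping[str, Enzyme] | None = None,
    enzyme_names: Sequence[str] = ("BamHI", "EcoRI"),
    kmer: int = 18,
    relative_tolerance: float = 0.05,
    min_detectable: int = 500,
) -> SouthernObservation:
    """Predict the Southern-blot lane for one individual.

    Both haplotype sequences are digested to completion with BamHI+EcoRI; a
    fragment hybridizes iff it shares at least one perfect *kmer*-mer with a
    probe on either strand.  Hybridizing fragment sizes are collapsed by the
    proportional gel model (a 0.7% gel resolves kilobase-scale bands only
    approximately).
    """
    if not probes:
        raise ValueError("no probes supplied")
    if enzymes is None:
        enzymes = default_enzymes()
    probe_kmers: set[str] = set()
    for p in probes:
        p = p.upper()
        probe_kmers |= _kmers(p, kmer) | _kmers(revcomp(p), kmer)
    cutters = [enzymes[n] for n in enzyme_names]
    sizes: list[int] = []
    for genome in genomes:
        genome = genome.upper()
        for start, end, length in digest(genome, cutters).fragments:
            frag = genome[start:end]
            if any(frag[i : i + kmer] in probe_kmers for i in range(len(frag) - kmer + 1)):
                sizes.append(length)
    lane = to_gel_lane(sizes, relative_tolerance=relative_tolerance,
                       min_detectable=min_detectable)
    return SouthernObservation(lane=lane)


def genotypes_from_southern(
    obs: SouthernObservation,
    catalog: HaplotypeCatalog | None = None,
    relative_tolerance: float = 0.05,
) -> list[Pair]:
    """Pairs whose diagnostic band sizes match the observed lane.

    A pair matches when every observed band co-migrates with one of the
    pair's diagnostic sizes and every diagnostic size is observed.  A band
    matching no catalogued size at all means the sample carries something
    outside the closed-world catalogue and raises ``ValueError``.
    """
    if catalog is None:
        catalog = default_catalog()
    bands = obs.lane.bands
    if not bands:
        raise ValueError("empty Southern observation")
    all_sizes = [e.southern_bp for e in catalog.entries.values()]
    for b in bands:
        if not any(abs(b / s - 1.0) <= relative_tolerance for s in all_sizes):
            raise ValueError(f"band {b} matches no catalogued haplotype size")
    out = []
    for pair in catalog.pairs():
        expected = catalog.southern_sizes(pair)
        if len(bands) != len(expected):
            continue
        if all(
            any(abs(b / s - 1.0) <= relative_tolerance for b in bands)
            for s in expected
        ) and all(
            any(abs(b / s - 1.0) <= relative_tolerance for s in expected)
            for b in bands
        ):
            out.append(pair)
    return out


def integrate_evidence(
    individual_id: str,
    channels: Mapping[str, Iterable[Pair]],
) -> GenotypeCall:
    """Intersect candidate pairs across evidence channels."""
    if not channels:
        raise ValueError("no evidence channels supplied")
    normalized = {
        name: tuple(sorted({tuple(sorted(p)) for p in cands}))
        for name, cands in channels.items()
    }
    sets = [set(c) for c in normalized.values()]
    candidates = tuple(sorted(set.intersection(*sets)))
    if not candidates:
        status = "inconsistent"
    elif len(candidates) == 1:
        status = "unique"
    else:
        status = "ambiguous"
    return GenotypeCall(individual_id=individual_id, candidates=candidates,
                        status=status, evidence=normalized)


@dataclass(frozen=True)
class PopulationSummary:
    n_individuals: int
    n_called: int
    distinct_haplotypes: int
    haplotype_frequencies: Mapping[str, float]
    types_per_individual: Mapping[str, int]
    concordance: float | None = None  # fraction of calls matching truth


def population_summary(
    calls: Mapping[str, GenotypeCall],
    catalog: HaplotypeCatalog | None = None,
    truth: Mapping[str, Pair] | None = None,
) -> PopulationSummary:
    """Summarize haplotype diversity over uniquely called individuals."""
    if catalog is None:
        catalog = default_catalog()
    counts: Counter[str] = Counter()
    types_per: dict[str, int] = {}
    called = 0
    correct = 0
    for ind, call in calls.items():
        if call.status != "unique":
            continue
        called += 1
        pair = call.genotype
        counts.update(pair)
        types_per[ind] = len(catalog.type_union(pair))
        if truth is not None and tuple(sorted(truth[ind])) == pair:
            correct += 1
    total = sum(counts.values())
    freqs = {h: c / total for h, c in sorted(counts.items())} if total else {}
    return PopulationSummary(
        n_individuals=len(calls),
        n_called=called,
        distinct_haplotypes=len(counts),
        haplotype_frequencies=freqs,
        types_per_individual=types_per,
        concordance=(correct / called if truth is not None and called else None),
    )
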