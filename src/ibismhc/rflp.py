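"""PCR-RFLP typing of MHC-IIB exon-2 amplicons.

The 279-bp exon-2 amplicon is digested separately with PstI, RsaI and SalI;
the combination of the three fragment patterns assigns one of four allele
types (I-IV).  For a diploid individual all amplicons run pooled in each
enzyme lane, so a lane shows the *union* of the per-type band sets with no
copy-number information; :func:`decode_lanes` enumerates every type set
consistent with an observed lane pattern.

Band comparison for these amplicon-scale digests is exact integer equality
(the reference table is printed exact); the proportional gel tolerance only
matters at Southern scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

from .enzymes import Enzyme, GelLane, default_enzymes, digest, to_gel_lane

__all__ = [
    "AMPLICON_LENGTH",
    "TYPING_ENZYMES",
    "TypeProfileTable",
    "LaneObservation",
    "TypeCall",
    "profile_of_amplicon",
    "assign_type",
    "simulate_lanes",
    "decode_lanes",
]

AMPLICON_LENGTH = 279
TYPING_ENZYMES: tuple[str, ...] = ("PstI", "RsaI", "SalI")


class TableError(ValueError):
    """A malformed type-profile table."""


@dataclass(frozen=True)
class TypeProfileTable:
    """Reference digestion profiles: type -> enzyme -> fragment multiset."""

    enzymes: tuple[str, ...]
    profiles: Mapping[str, Mapping[str, tuple[int, ...]]]
    amplicon_length: int = AMPLICON_LENGTH

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when well-formed)."""
        problems: list[str] = []
        for type_id, by_enzyme in self.profiles.items():
            for enz in self.enzymes:
                if enz not in by_enzyme:
                    problems.append(f"type {type_id}: missing enzyme {enz}")
                    continue
                total = sum(by_enzyme[enz])
                if total != self.amplicon_length:
                    problems.append(
                        f"type {type_id}/{enz}: fragments sum to {total}, "
                        f"expected {self.amplicon_length}"
                    )
        type_ids = list(self.profiles)
        for a, b in combinations(type_ids, 2):
            if all(
                Counter(self.profiles[a].get(e, ())) == Counter(self.profiles[b].get(e, ()))
                for e in self.enzymes
            ):
                problems.append(f"types {a} and {b} are indistinguishable")
        return problems

    @classmethod
    def from_tsv(cls, path=None, enzymes: Sequence[str] = TYPING_ENZYMES) -> "TypeProfileTable":
        """Load from a TSV with columns type, enzyme, fragments_bp.

        With no *path* the packaged table (the published typing scheme for
        the 279-bp exon-2 amplicon) is used.
        """
        import pandas as pd

        if path is None:
            with resources.as_file(
                resources.files("ibismhc.data") / "exon2_profiles.tsv"
            ) as p:
                frame = pd.read_csv(p, sep="\t")
        else:
            frame = pd.read_csv(path, sep="\t")
        profiles: dict[str, dict[str, tuple[int, ...]]] = {}
        for row in frame.itertuples(index=False):
            frags = tuple(int(x) for x in str(row.fragments_bp).split(","))
            profiles.setdefault(str(row.type), {})[str(row.enzyme)] = frags
        table = cls(enzymes=tuple(enzymes), profiles=profiles)
        problems = table.validate()
        if problems:
            raise TableError("; ".join(problems))
        return table

    def band_set(self, type_ids: Iterable[str], enzyme: str,
                 min_detectable: int = 40) -> frozenset[int]:
        """Bands shown by the pooled amplicons of the given types."""
        bands: set[int] = set()
        for t in type_ids:
            bands.update(b for b in self.profiles[t][enzyme] if b >= min_detectable)
        return frozenset(bands)


_DEFAULT_TABLE: TypeProfileTable | None = None


def default_profile_table() -> TypeProfileTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = TypeProfileTable.from_tsv()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class LaneObservation:
    """One gel lane per typing enzyme for a single individual."""

    lanes: Mapping[str, GelLane]

    def band_sets(self) -> dict[str, frozenset[int]]:
        return {e: frozenset(int(b) for b in lane.bands) for e, lane in self.lanes.items()}


@dataclass(frozen=True)
class TypeCall:
    """Type assignment for a single amplicon."""

    amplicon_id: str | None
    type_id: str | None
    profile: Mapping[str, tuple[int, ...]]
    nearest: str | None = None  # closest table row when no exact match


def profile_of_amplicon(
    amplicon: str,
    enzymes: Mapping[str, Enzyme] | None = None,
    enzyme_names: Sequence[str] = TYPING_ENZYMES,
) -> dict[str, tuple[int, ...]]:
    """Per-enzyme complete-digest fragment lengths, in positional order."""
    import warnings

    if enzymes is None:
        enzymes = default_enzymes()
    if len(amplicon) != AMPLICON_LENGTH:
        warnings.warn(
            f"amplicon length {len(amplicon)} != expected {AMPLICON_LENGTH}",
            stacklevel=2,
        )
    return {name: digest(amplicon, enzymes[name]).lengths for name in enzyme_names}


def _profile_distance(a: Mapping[str, tuple[int, ...]],
                      b: Mapping[str, tuple[int, ...]],
                      enzymes: Sequence[str]) -> int:
    d = 0
    for e in enzymes:
        ca, cb = Counter(a.get(e, ())), Counter(b.get(e, ()))
        d += sum((ca - cb).values()) + sum((cb - ca).values())
    return d


def assign_type(
    profile: Mapping[str, tuple[int, ...]],
    table: TypeProfileTable | None = None,
    amplicon_id: str | None = None,
) -> TypeCall:
    """Assign an allele type by exact multiset match against the table.

    Returns a call with ``type_id=None`` (and the nearest row for
    diagnostics) when no row matches.  Two matching rows mean the table
    itself is malformed and raise :class:`TableError`.
    """
    if table is None:
        table = default_profile_table()
    matches = [
        t for t, ref in table.profiles.items()
        if all(Counter(profile.get(e, ())) == Counter(ref[e]) for e in table.enzymes)
    ]
    if len(matches) > 1:
        raise TableError(f"profile matches multiple types: {matches}")
    if matches:
        return TypeCall(amplicon_id, matches[0], dict(profile))
    nearest = min(
        table.profiles,
        key=lambda t: _profile_distance(profile, table.profiles[t], table.enzymes),
    )
    return TypeCall(amplicon_id, None, dict(profile), nearest=nearest)


def simulate_lanes(
    amplicons: Sequence[str],
    enzymes: Mapping[str, Enzyme] | None = None,
    table: TypeProfileTable | None = None,
    min_detectable: int = 40,
) -> LaneObservation:
    """Predict the three-enzyme gel lanes for a pool of amplicons.

    Each lane is the union of all amplicons' digest fragments, collapsed to
    distinct band sizes (no dosage).  Raises ``ValueError`` when the pool is
    empty (no PCR product: nothing to load on the gel).
    """
    if not amplicons:
        raise ValueError("no amplicons: PCR yielded no product")
    if enzymes is None:
        enzymes = default_enzymes()
    if table is None:
        table = default_profile_table()
    lanes: dict[str, GelLane] = {}
    for name in table.enzymes:
        fragments: list[int] = []
        for amp in amplicons:
            fragments.extend(digest(amp, enzymes[name]).lengths)
        lanes[name] = to_gel_lane(fragments, relative_tolerance=0.0,
                                  min_detectable=min_detectable)
    return LaneObservation(lanes=lanes)


def decode_lanes(
    obs: LaneObservation,
    table: TypeProfileTable | None = None,
    min_detectable: int = 40,
) -> list[frozenset[str]]:
    """All non-empty type sets whose pooled bands reproduce the observation.

    The search is exhaustive over the subsets of the table's types.  Raises
    ``ValueError`` when no subset is consistent (a pattern outside the
    reference table).
    """
    if table is None:
        table = default_profile_table()
    observed = obs.band_sets()
    type_ids = list(table.profiles)
    consistent: list[frozenset[str]] = []
    subsets = chain.from_iterable(
        combinations(type_ids, r) for r in range(1, len(type_ids) + 1)
    )
    for subset in subsets:
        if all(
            table.band_set(subset, e, min_detectable) == observed.get(e, frozenset())
            for e in table.enzymes
        ):
            consistent.append(frozenset(subset))
    if not consistent:
        raise ValueError("no type set is consistent with the observed lanes")
    return sorted(consistent, key=lambda s: (len(s), sorted(s)))
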