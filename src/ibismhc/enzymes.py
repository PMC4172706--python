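"""Restriction-site scanning, complete digestion of linear DNA, and a gel model.

This is the core engine behind PCR-RFLP typing and Southern-fragment
prediction.  Coordinates are 0-based half-open throughout; a *cut position*
counts the number of bases 5' of the cut on the top strand, so an enzyme
whose recognition sequence starts at position ``p`` cuts at
``p + cut_offset``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "IUPAC",
    "revcomp",
    "iupac_to_regex",
    "Enzyme",
    "DigestResult",
    "GelLane",
    "find_sites",
    "digest",
    "to_gel_lane",
    "load_enzymes",
    "default_enzymes",
]

#: IUPAC nucleotide ambiguity codes mapped to the concrete bases they cover.
IUPAC: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_ACGT_RE = re.compile(r"^[ACGT]*$")


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-ambiguous) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_to_regex(pattern: str) -> str:
    """Expand an IUPAC pattern into a plain regex over {A,C,G,T}."""
    parts = []
    for sym in pattern.upper():
        try:
            bases = IUPAC[sym]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in {pattern!r}") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease.

    Parameters
    ----------
    name:
        Display name, e.g. ``"PstI"``.
    recognition:
        Recognition sequence, 5'->3' top strand, IUPAC symbols allowed.
    cut_offset:
        Bases from the start of the recognition site to the top-strand cut
        (``G^GATCC`` has offset 1, ``CTGCA^G`` offset 5).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition sequence")
        for sym in self.recognition.upper():
            if sym not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {sym!r} in recognition")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition site")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition.upper() == revcomp(self.recognition.upper())


@dataclass(frozen=True)
class DigestResult:
    """Fragments of a complete digest of a linear sequence."""

    #: (start, end, length) in 0-based half-open template coordinates,
    #: in positional order from the 5' end.
    fragments: tuple[tuple[int, int, int], ...]
    cut_positions: tuple[int, ...]

    @property
    def lengths(self) -> tuple[int, ...]:
        """Fragment lengths in positional order."""
        return tuple(f[2] for f in self.fragments)


@dataclass(frozen=True)
class GelLane:
    """Bands visible in one electrophoresis lane (presence/absence only)."""

    bands: tuple[float, ...]
    relative_tolerance: float = 0.05
    min_detectable: int = 40

    def matches(self, size: float) -> bool:
        """True if *size* co-migrates with one of the lane's bands."""
        return any(abs(size / b - 1.0) <= self.relative_tolerance for b in self.bands)


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if not _ACGT_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
    return seq


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """All top-strand cut positions of *enzyme* in *seq*.

    Palindromic recognition sites are reported once.  Non-palindromic sites
    are also searched on the reverse strand, with the bottom-strand cut
    mapped to its top-strand coordinate.  Cuts falling exactly on a sequence
    boundary (which would produce an empty fragment) are dropped.
    """
    seq = _check_sequence(seq)
    pat = re.compile(f"(?=({iupac_to_regex(enzyme.recognition)}))")
    cuts = {m.start() + enzyme.cut_offset for m in pat.finditer(seq)}
    if not enzyme.is_palindromic:
        size = len(enzyme.recognition)
        rc = re.compile(f"(?=({iupac_to_regex(revcomp(enzyme.recognition))}))")
        # Recognition on the bottom strand at top interval [p, p+size):
        # the bottom-strand cut_offset counts from the bottom 5' end, i.e.
        # from top position p+size leftwards.
        cuts.update(m.start() + size - enzyme.cut_offset for m in rc.finditer(seq))
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(seq: str, enzymes: Enzyme | Iterable[Enzyme]) -> DigestResult:
    """Complete digest of a linear sequence with one or more enzymes."""
    if isinstance(enzymes, Enzyme):
        enzymes = [enzymes]
    cuts: set[int] = set()
    for enz in enzymes:
        cuts.update(find_sites(seq, enz))
    bounds = [0, *sorted(cuts), len(seq)]
    fragments = tuple(
        (s, e, e - s) for s, e in zip(bounds, bounds[1:])
    )
    return DigestResult(fragments=fragments, cut_positions=tuple(sorted(cuts)))


def to_gel_lane(
    lengths: Iterable[float],
    relative_tolerance: float = 0.05,
    min_detectable: int = 40,
) -> GelLane:
    """Collapse a fragment multiset into the bands a gel would show.

    Fragments shorter than *min_detectable* run off the gel.  Sizes whose
    ratio deviates by at most *relative_tolerance* co-migrate and are merged
    into a single band at their mean; merging is iterated to a fixed point,
    so the operation is idempotent.
    """
    sizes = sorted(float(x) for x in lengths if x >= min_detectable)
    merged = True
    while merged and len(sizes) > 1:
        merged = False
        for i in range(len(sizes) - 1):
            a, b = sizes[i], sizes[i + 1]
            if b / a - 1.0 <= relative_tolerance:
                sizes[i : i + 2] = [(a + b) / 2.0]
                merged = True
                break
    bands = tuple(int(s) if float(s).is_integer() else s for s in sizes)
    return GelLane(bands=bands, relative_tolerance=relative_tolerance,
                   min_detectable=min_detectable)


def load_enzymes(path=None) -> dict[str, Enzyme]:
    """Load an enzyme table (TSV: name, recognition, cut_offset).

    With no *path*, the catalogue shipped with the package is used; it holds
    standard recognition/cut definitions for the enzymes used in typing
    (PstI, RsaI, SalI), blotting (BamHI, EcoRI) and subcloning (KpnI, SacI,
    XhoI, Sau3AI).
    """
    import pandas as pd

    if path is None:
        with resources.as_file(
            resources.files("ibismhc.data") / "enzymes.tsv"
        ) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    enzymes: dict[str, Enzyme] = {}
    for row in frame.itertuples(index=False):
        enzymes[str(row.name)] = Enzyme(str(row.name), str(row.recognition),
                                        int(row.cut_offset))
    return enzymes


_DEFAULT: dict[str, Enzyme] | None = None


def default_enzymes() -> dict[str, Enzyme]:
    """The packaged enzyme catalogue (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_enzymes()
    return _DEFAULT
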