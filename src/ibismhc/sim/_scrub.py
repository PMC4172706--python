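"""Random-sequence primitives with constraint repair.

The generator samples padding and gene backbones uniformly over {A,C,G,T}
and then *scrubs* them: any occurrence of a banned motif (restriction site,
primer footprint, ...) outside a protected interval is destroyed by point
mutation, iterating until no violation remains.  Coding regions stay free of
stop codons throughout.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np

from ..enzymes import iupac_to_regex

__all__ = ["GenerationError", "random_dna", "random_codons", "scrub",
           "STOP_CODONS", "CODONS", "codon_aa"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASES = "ACGT"
CODONS = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in STOP_CODONS
)

_CODON_TABLE: dict[str, str] = {}


def codon_aa(codon: str) -> str:
    """Amino acid encoded by a codon (standard nuclear code)."""
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for a in _BASES:
            for b in _BASES:
                for c in _BASES:
                    cod = a + b + c
                    _CODON_TABLE[cod] = str(Seq(cod).translate())
    return _CODON_TABLE[codon]


class GenerationError(RuntimeError):
    """Constraint satisfaction failed after bounded retries."""


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def random_codons(n_codons: int, rng: np.random.Generator) -> str:
    """n_codons random codons, none of them a stop codon."""
    idx = rng.integers(0, len(CODONS), size=n_codons)
    return "".join(CODONS[i] for i in idx)


def _in_coding(pos: int, coding: Sequence[tuple[int, int]]) -> tuple[int, int] | None:
    for s, e in coding:
        if s <= pos < e:
            return (s, e)
    return None


def scrub(
    seq: str,
    banned: Iterable[str],
    rng: np.random.Generator,
    protected: Sequence[tuple[int, int]] = (),
    coding: Sequence[tuple[int, int]] = (),
    max_rounds: int = 2000,
) -> str:
    """Mutate *seq* until no banned motif survives outside protected spans.

    ``banned`` are IUPAC motifs (searched on the given strand only, so
    callers supply reverse complements for non-palindromic motifs).
    A match lying entirely inside a protected interval is taken to be a
    deliberately planted site and is left alone.  Mutations inside a
    ``coding`` interval (frame 0 relative to its start) never create a stop
    codon.
    """
    chars = list(seq.upper())
    prot: set[int] = set()
    for s, e in protected:
        prot.update(range(s, e))
    motifs = list(dict.fromkeys(banned))
    regexes = [(re.compile(f"(?=({iupac_to_regex(m)}))"), len(m)) for m in motifs]

    for _ in range(max_rounds):
        s = "".join(chars)
        mutable: list[int] | None = None
        for rx, mlen in regexes:
            start = 0
            while True:
                m = rx.search(s, start)
                if m is None:
                    break
                span = list(range(m.start(), m.start() + mlen))
                cand = [p for p in span if p not in prot]
                if cand:
                    mutable = cand
                    break
                start = m.start() + 1  # fully protected: planted site
            if mutable:
                break
        if mutable is None:
            return s
        pos = mutable[int(rng.integers(0, len(mutable)))]
        _mutate(chars, pos, rng, coding)
    raise GenerationError("scrub did not converge")


def _mutate(
    chars: list[str],
    pos: int,
    rng: np.random.Generator,
    coding: Sequence[tuple[int, int]],
) -> None:
    current = chars[pos]
    alternatives = [b for b in _BASES if b != current]
    rng.shuffle(alternatives)
    region = _in_coding(pos, coding)
    for base in alternatives:
        if region is not None:
            s, _ = region
            cstart = pos - (pos - s) % 3
            codon = "".join(chars[cstart:cstart + 3])
            codon = codon[: pos - cstart] + base + codon[pos - cstart + 1:]
            if codon in STOP_CODONS:
                continue
        chars[pos] = base
        return
    raise GenerationError(f"no stop-free substitution at position {pos}")
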