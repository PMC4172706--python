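"""Virtual PCR: primer binding-site search and amplicon prediction.

Primers may contain IUPAC ambiguity symbols (degenerate primers).  A primer
binds where its 3'-clamp bases match exactly and the remaining positions show
at most ``max_mismatches`` mismatches, an IUPAC symbol matching any base of
its expansion.  Amplification reports every convergent forward/reverse
binding combination whose product is short enough; no thermodynamics are
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .enzymes import IUPAC, revcomp

__all__ = ["Primer", "Amplicon", "match_primer", "amplify"]


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide primer, written 5'->3'."""

    name: str
    sequence: str
    max_mismatches: int = 0
    three_prime_clamp: int = 3

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 10:
            raise ValueError("primer shorter than 10 nt")
        if any(sym not in IUPAC for sym in seq):
            raise ValueError(f"invalid IUPAC symbol in primer {self.name!r}")
        if not 0 <= self.three_prime_clamp <= len(seq):
            raise ValueError("three_prime_clamp longer than primer")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the template top strand."""

    sequence: str
    template_id: str | None
    start: int
    end: int
    fwd_primer: str
    rev_primer: str

    def __len__(self) -> int:
        return self.end - self.start


_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _accept_matrix(primer_seq: str) -> np.ndarray:
    """(len(primer), 4) boolean table: does primer position i accept base j?"""
    acc = np.zeros((len(primer_seq), 4), dtype=bool)
    for i, sym in enumerate(primer_seq):
        for b in IUPAC[sym]:
            acc[i, _BASE_INDEX[b]] = True
    return acc


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    if (out < 0).any():
        raise ValueError("template contains non-ACGT symbols")
    return out


def match_primer(template: str, primer: Primer, strand: str = "+") -> list[int]:
    """Top-strand start positions of the primer footprint.

    ``strand="+"``: the primer anneals to the bottom strand and reads along
    the top strand (a forward primer).  ``strand="-"``: the primer anneals to
    the top strand; the footprint interval is still reported on the top
    strand, with the primer's 3' end at the interval start.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    template = template.upper()
    k = len(primer.sequence)
    n = len(template)
    if n < k:
        return []
    # On the minus strand the primer reads along the reverse complement, so
    # compare its reverse complement against the top strand directly.
    pseq = primer.sequence if strand == "+" else revcomp(primer.sequence)
    acc = _accept_matrix(pseq)
    enc = _encode(template)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    ok = acc[np.arange(k)[None, :], windows]  # (n-k+1, k) position-wise match
    clamp = primer.three_prime_clamp
    if strand == "+":
        clamp_ok = ok[:, k - clamp:].all(axis=1) if clamp else np.ones(len(ok), bool)
    else:
        clamp_ok = ok[:, :clamp].all(axis=1) if clamp else np.ones(len(ok), bool)
    mism = (~ok).sum(axis=1)
    # Clamp mismatches are disqualifying anyway; count the rest.
    if clamp:
        if strand == "+":
            mism = (~ok[:, : k - clamp]).sum(axis=1)
        else:
            mism = (~ok[:, clamp:]).sum(axis=1)
    hits = np.nonzero(clamp_ok & (mism <= primer.max_mismatches))[0]
    return [int(h) for h in hits]


def amplify(
    template: str,
    fwd: Primer,
    rev: Primer,
    max_product_length: int = 5000,
    template_id: str | None = None,
) -> list[Amplicon]:
    """Predict all products of a primer pair on a linear template.

    Every convergent combination — one primer on each strand, 3' ends facing
    each other, footprints non-overlapping, product no longer than
    *max_product_length* — is reported, sorted by template position.  PCR is
    strand-symmetric, so both role assignments are searched; each product is
    written 5'->3' starting with the forward primer's footprint, whichever
    template strand that lies on.
    """
    template = template.upper()
    out: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()
    for first, second, flip in ((fwd, rev, False), (rev, fwd, True)):
        for f in match_primer(template, first, "+"):
            for r in match_primer(template, second, "-"):
                start, end = f, r + len(second.sequence)
                if (r >= f + len(first.sequence)
                        and end - start <= max_product_length
                        and (start, end) not in seen):
                    seen.add((start, end))
                    seq = template[start:end]
                    out.append(
                        Amplicon(
                            sequence=revcomp(seq) if flip else seq,
                            template_id=template_id,
                            start=start,
                            end=end,
                            fwd_primer=fwd.name,
                            rev_primer=rev.name,
                        )
                    )
    out.sort(key=lambda a: (a.start, a.end))
    return out
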