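"""Dot-matrix comparison, polymorphism counting and breakpoint detection.

These are the ungapped sequence-comparison operations used to characterize
the class II haplotypes: windowed-identity dot plots between haplotype
sequences, counts of polymorphic alignment columns at the nucleotide and
amino-acid level, intron-length measurement from annotations, and
donor-assignment scanning that flags a hybrid (recombinant) allele and
localizes its breakpoint.

All operations assume ungapped, equal-length inputs where an alignment is
required; the synthetic alleles are constructed gap-free, so no aligner is
involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "DotMatrix",
    "BreakpointCall",
    "PolymorphismSummary",
    "dotplot",
    "count_polymorphic_sites",
    "count_polymorphic_residues",
    "measure_intron_length",
    "detect_breakpoint",
]


@dataclass(frozen=True)
class DotMatrix:
    """Anchors (posA, posB) of windows meeting the identity threshold."""

    window: int
    step: int
    identity_threshold: float
    shape: tuple[int, int]  # (len(seqA), len(seqB))
    anchors: tuple[tuple[int, int], ...]

    def transpose(self) -> "DotMatrix":
        return DotMatrix(
            window=self.window, step=self.step,
            identity_threshold=self.identity_threshold,
            shape=(self.shape[1], self.shape[0]),
            anchors=tuple(sorted((j, i) for i, j in self.anchors)),
        )


@dataclass(frozen=True)
class PolymorphismSummary:
    region_id: str | None
    n_sequences: int
    n_polymorphic: int
    positions: tuple[int, ...]


@dataclass(frozen=True)
class BreakpointCall:
    """Donor assignment of a query against two candidate donors."""

    verdict: str  # "hybrid" | "pure_a" | "pure_b" | "complex"
    breakpoint: tuple[int, int] | None  # half-open interval containing the switch
    assignments: tuple[str, ...]  # per-window: "A" or "B"
    anchors: tuple[int, ...]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def dotplot(
    seq_a: str,
    seq_b: str,
    window: int = 20,
    step: int = 1,
    threshold: float = 0.9,
) -> DotMatrix:
    """Windowed-identity dot plot of two sequences.

    An anchor ``(i, j)`` is recorded when the *window*-length substrings at
    ``i`` in A and ``j`` in B agree at a fraction of positions >=
    *threshold*.  With ``step == 1`` every position pair is evaluated (by
    per-diagonal sliding sums); with larger steps anchors are evaluated on
    the ``step x step`` grid.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    a, b = _encode(seq_a), _encode(seq_b)
    la, lb = len(a), len(b)
    if window > la or window > lb:
        raise ValueError("window longer than a sequence")
    need = int(np.ceil(threshold * window - 1e-9))
    anchors: list[tuple[int, int]] = []
    kernel = np.ones(window, dtype=np.int32)
    if step == 1:
        for d in range(-(la - window), lb - window + 1):
            if d >= 0:
                eq = (a[: min(la, lb - d)] == b[d : d + min(la, lb - d)])
            else:
                eq = (a[-d : -d + min(la + d, lb)] == b[: min(la + d, lb)])
            if len(eq) < window:
                continue
            sums = np.convolve(eq.astype(np.int32), kernel, mode="valid")
            for k in np.nonzero(sums >= need)[0]:
                i = int(k) if d >= 0 else int(k) - d
                anchors.append((i, i + d))
    else:
        gi = np.arange(0, la - window + 1, step)
        gj = np.arange(0, lb - window + 1, step)
        bw = np.lib.stride_tricks.sliding_window_view(b, window)[gj]
        for i in gi:
            ident = (a[i : i + window][None, :] == bw).sum(axis=1)
            for j in gj[np.nonzero(ident >= need)[0]]:
                anchors.append((int(i), int(j)))
    return DotMatrix(window=window, step=step, identity_threshold=threshold,
                     shape=(la, lb), anchors=tuple(sorted(anchors)))


def _check_equal_lengths(seqs: Sequence[str]) -> int:
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return lengths.pop()


def count_polymorphic_sites(
    seqs: Sequence[str],
    region_id: str | None = None,
) -> PolymorphismSummary:
    """Count alignment columns where not all sequences agree."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    _check_equal_lengths(seqs)
    mat = np.vstack([_encode(s) for s in seqs])
    poly = np.nonzero((mat != mat[0]).any(axis=0))[0]
    return PolymorphismSummary(region_id=region_id, n_sequences=len(seqs),
                               n_polymorphic=len(poly),
                               positions=tuple(int(p) for p in poly))


def count_polymorphic_residues(
    seqs: Sequence[str],
    frame: int = 0,
    region_id: str | None = None,
) -> PolymorphismSummary:
    """Translate in-frame coding sequences and count polymorphic residues.

    *frame* is the annotated offset of the first complete codon; it is never
    inferred from the sequence.  An internal stop codon is an error: the
    reference alleles are all protein-coding.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    n = _check_equal_lengths(seqs)
    if (n - frame) % 3 != 0:
        raise ValueError("length minus frame offset not divisible by 3")
    proteins = []
    for s in seqs:
        aa = str(Seq(s[frame:]).translate())
        if "*" in aa:
            raise ValueError("internal stop codon in coding sequence")
        proteins.append(aa)
    mat = np.vstack([np.frombuffer(p.encode(), dtype=np.uint8) for p in proteins])
    poly = np.nonzero((mat != mat[0]).any(axis=0))[0]
    return PolymorphismSummary(region_id=region_id, n_sequences=len(seqs),
                               n_polymorphic=len(poly),
                               positions=tuple(int(p) for p in poly))


def measure_intron_length(features: Iterable, gene_id: str, ordinal: int) -> int:
    """Length of intron *ordinal* (1-based) of gene *gene_id*.

    *features* is any iterable of objects with ``type``, ``start``, ``end``
    attributes and an ``attrs``/``attributes`` mapping holding the parent
    gene id (both in-memory :class:`~ibismhc.io.Feature` records and
    gffutils features work).
    """
    introns = []
    for f in features:
        if getattr(f, "type", getattr(f, "featuretype", None)) != "intron":
            continue
        attrs = getattr(f, "attrs", None) or getattr(f, "attributes", {})
        parent = attrs.get("Parent")
        ordv = attrs.get("ordinal")
        if isinstance(parent, (list, tuple)):
            parent = parent[0]
        if isinstance(ordv, (list, tuple)):
            ordv = ordv[0]
        if parent == gene_id:
            introns.append((int(ordv), f))
    introns.sort(key=lambda x: x[0])
    for ordv, f in introns:
        if ordv == ordinal:
            start, end = int(f.start), int(f.end)
            # gffutils features are 1-based inclusive; in-memory ones are
            # 0-based half-open and carry a marker attribute.
            if getattr(f, "zero_based", False):
                return end - start
            return end - start + 1
    raise KeyError(f"gene {gene_id!r} has no intron {ordinal}")


def detect_breakpoint(
    query: str,
    donor_a: str,
    donor_b: str,
    window: int = 20,
    step: int = 1,
) -> BreakpointCall:
    """Assign windows of *query* to the closer donor and find the switch.

    Each window goes to the donor with fewer mismatches; ties inherit the
    previous window's assignment (the first window defaults to donor A).
    Exactly one A->B or B->A switch is a ``hybrid`` verdict with the
    breakpoint localized to the interval between the last window of the
    first donor and the end of the first window of the second; more than
    one switch is ``complex``; none is ``pure_a``/``pure_b``.
    """
    n = _check_equal_lengths([query, donor_a, donor_b])
    if window <= 0 or window > n:
        raise ValueError("bad window size")
    q, da, db = _encode(query), _encode(donor_a), _encode(donor_b)
    mism_a = np.concatenate([[0], np.cumsum(q != da)])
    mism_b = np.concatenate([[0], np.cumsum(q != db)])
    anchors = np.arange(0, n - window + 1, step)
    wa = mism_a[anchors + window] - mism_a[anchors]
    wb = mism_b[anchors + window] - mism_b[anchors]
    raw = [
        "A" if ca < cb else ("B" if cb < ca else None)
        for ca, cb in zip(wa, wb)
    ]
    # Ties inherit their neighbour's assignment; leading ties inherit the
    # first decided window (donor A when no window is decisive at all), so
    # an identical leading region never manufactures a switch.
    current = next((v for v in raw if v is not None), "A")
    assignments: list[str] = []
    for v in raw:
        if v is not None:
            current = v
        assignments.append(current)
    switches = [
        k for k in range(1, len(assignments))
        if assignments[k] != assignments[k - 1]
    ]
    if not switches:
        verdict = "pure_a" if assignments and assignments[0] == "A" else "pure_b"
        bp = None
    elif len(switches) == 1:
        verdict = "hybrid"
        k = switches[0]
        bp = (int(anchors[k - 1]), int(anchors[k]) + window)
    else:
        verdict = "complex"
        bp = None
    return BreakpointCall(verdict=verdict, breakpoint=bp,
                          assignments=tuple(assignments),
                          anchors=tuple(int(a) for a in anchors))
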