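"""Synthesis of the four 279-bp MHC-IIB exon-2 allele types.

Each type is defined by its PstI/RsaI/SalI digestion profile.  Interpreting
the published fragment lists in positional order from the amplicon 5' end
fixes the cut positions: RsaI at 124 and 178 (types I and III), SalI at 201
(type III), PstI at 168 (type IV).  Sequences are random stop-free codons
with the required recognition hexamers planted at those positions and every
other catalogued enzyme site scrubbed away.

:func:`build_exon2_family` builds the four types jointly off one backbone so
that downstream constraints hold by construction:

* the first 36 bp and last 21 bp are identical across types (primer
  footprints and probe anchor);
* type I equals type III except at the SalI hexamer (reverted to backbone);
* the three alleles of the DAB1 locus (types II, IV, III) differ at exactly
  12 amino-acid columns, engineered on top of the planted-site differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..enzymes import Enzyme, default_enzymes, digest, find_sites, revcomp
from ..pcr import Primer
from ._scrub import (CODONS, GenerationError, codon_aa, random_codons, scrub)

__all__ = [
    "EXON2_LENGTH",
    "Exon2AlleleSpec",
    "EXON2_SPECS",
    "Exon2Family",
    "build_exon2_allele",
    "build_exon2_family",
]

EXON2_LENGTH = 279
N_CODONS = EXON2_LENGTH // 3

#: region identical across all types: forward-primer footprint + probe anchor
PREFIX_END = 36
#: region identical across all types: reverse-primer footprint
SUFFIX_START = 258

PRIMER_LENGTH = 20

_TYPING_TRIO = ("PstI", "RsaI", "SalI")


@dataclass(frozen=True)
class Exon2AlleleSpec:
    """Digestion constraints defining one exon-2 allele type."""

    type_id: str
    required_sites: Mapping[str, tuple[int, ...]]  # enzyme -> cut positions
    forbidden_enzymes: tuple[str, ...]
    length: int = EXON2_LENGTH

    def implied_fragments(self, enzyme: str) -> tuple[int, ...]:
        cuts = sorted(self.required_sites.get(enzyme, ()))
        bounds = [0, *cuts, self.length]
        return tuple(e - s for s, e in zip(bounds, bounds[1:]))

    def validate(self, enzymes: Mapping[str, Enzyme] | None = None) -> None:
        if enzymes is None:
            enzymes = default_enzymes()
        intervals = []
        for name, cuts in self.required_sites.items():
            enz = enzymes[name]
            for cut in cuts:
                start = cut - enz.cut_offset
                end = start + len(enz.recognition)
                if start < 0 or end > self.length:
                    raise ValueError(f"site for {name} at cut {cut} out of bounds")
                intervals.append((start, end))
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError("required sites overlap")
        for name in self.required_sites:
            total = sum(self.implied_fragments(name))
            if total != self.length:
                raise ValueError("implied fragments do not tile the amplicon")


EXON2_SPECS: dict[str, Exon2AlleleSpec] = {
    "I": Exon2AlleleSpec("I", {"RsaI": (124, 178)}, ("PstI", "SalI")),
    "II": Exon2AlleleSpec("II", {}, ("PstI", "RsaI", "SalI")),
    "III": Exon2AlleleSpec("III", {"RsaI": (124, 178), "SalI": (201,)}, ("PstI",)),
    "IV": Exon2AlleleSpec("IV", {"PstI": (168,)}, ("RsaI", "SalI")),
}

#: codons overlapping any planted recognition hexamer across the four types
_PLANTED_CODONS = frozenset({40, 41, 54, 55, 56, 58, 59, 66, 67, 68})
#: codons eligible for engineered amino-acid differences: outside the shared
#: primer regions and at least one codon clear of every planted hexamer
_FREE_CODONS = tuple(
    c for c in range(PREFIX_END // 3, SUFFIX_START // 3)
    if not any(abs(c - p) <= 1 for p in _PLANTED_CODONS)
)

N_DAB1_AA_COLUMNS = 12  # polymorphic residues across the DAB1-locus alleles


def _plant(seq: str, spec: Exon2AlleleSpec,
           enzymes: Mapping[str, Enzyme]) -> tuple[str, list[tuple[int, int]]]:
    chars = list(seq)
    planted: list[tuple[int, int]] = []
    for name, cuts in spec.required_sites.items():
        enz = enzymes[name]
        for cut in cuts:
            start = cut - enz.cut_offset
            chars[start:start + len(enz.recognition)] = enz.recognition
            planted.append((start, start + len(enz.recognition)))
    return "".join(chars), planted


def _verify(seq: str, spec: Exon2AlleleSpec, enzymes: Mapping[str, Enzyme]) -> bool:
    for name in _TYPING_TRIO:
        sites = tuple(find_sites(seq, enzymes[name]))
        if name in spec.required_sites:
            if sites != tuple(sorted(spec.required_sites[name])):
                return False
        elif sites:
            return False
    return True


def _translate(seq: str) -> str:
    return "".join(codon_aa(seq[i:i + 3]) for i in range(0, len(seq), 3))


def build_exon2_allele(
    spec: Exon2AlleleSpec,
    seed: int | np.random.Generator,
    enzymes: Mapping[str, Enzyme] | None = None,
    attempts: int = 20,
) -> str:
    """A random 279-bp sequence realizing one type's digestion profile.

    The output carries every required cut exactly, no site of any other
    catalogued enzyme on either strand, and translates stop-free in frame 0.
    Deterministic for a given (spec, seed).
    """
    if enzymes is None:
        enzymes = default_enzymes()
    spec.validate(enzymes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    banned = [e.recognition for e in enzymes.values()]
    for _ in range(attempts):
        seq, planted = _plant(random_codons(N_CODONS, rng), spec, enzymes)
        try:
            seq = scrub(seq, banned, rng, protected=planted,
                        coding=[(0, spec.length)])
        except GenerationError:
            continue
        if _verify(seq, spec, enzymes) and "*" not in _translate(seq):
            return seq
    raise GenerationError(f"could not realize exon-2 type {spec.type_id}")


@dataclass(frozen=True)
class Exon2Family:
    """The four exon-2 types built off a common backbone, plus the primers."""

    sequences: Mapping[str, str]
    fwd_primer: Primer
    rev_primer: Primer
    engineered_codons: tuple[int, ...]  # codons carrying added AA differences

    def __getitem__(self, type_id: str) -> str:
        return self.sequences[type_id]


def _local_clean(seq: str, lo: int, hi: int, banned_res) -> bool:
    window = seq[max(0, lo - 8): hi + 8]
    return not any(rx.search(window) for rx in banned_res)


def build_exon2_family(
    seed: int | np.random.Generator,
    enzymes: Mapping[str, Enzyme] | None = None,
    attempts: int = 20,
) -> Exon2Family:
    """Jointly synthesize types I-IV with all cross-type constraints."""
    import re

    from ..enzymes import iupac_to_regex

    if enzymes is None:
        enzymes = default_enzymes()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    banned = [e.recognition for e in enzymes.values()]
    banned_res = [re.compile(iupac_to_regex(m)) for m in banned]

    for _ in range(attempts):
        try:
            backbone = scrub(random_codons(N_CODONS, rng), banned, rng,
                             coding=[(0, EXON2_LENGTH)])
        except GenerationError:
            continue
        seqs: dict[str, str] = {"II": backbone}
        ok = True
        for t in ("IV", "III"):
            planted_seq, planted = _plant(backbone, EXON2_SPECS[t], enzymes)
            try:
                planted_seq = scrub(planted_seq, banned, rng, protected=planted,
                                    coding=[(0, EXON2_LENGTH)])
            except GenerationError:
                ok = False
                break
            if not _verify(planted_seq, EXON2_SPECS[t], enzymes):
                ok = False
                break
            seqs[t] = planted_seq
        if not ok:
            continue

        # Engineer extra amino-acid columns so the three DAB1-locus alleles
        # (types II, IV, III) are polymorphic at exactly 12 residues.
        prots = {t: _translate(seqs[t]) for t in ("II", "IV", "III")}
        existing = {
            i for i in range(N_CODONS)
            if len({prots[t][i] for t in prots}) > 1
        }
        free = [c for c in _FREE_CODONS if c not in existing]
        need = N_DAB1_AA_COLUMNS - len(existing)
        if need < 0 or need > len(free):
            continue
        chosen = sorted(
            free[i] for i in rng.choice(len(free), size=need, replace=False)
        )
        targets = ("IV", "III", "II")
        engineered: list[int] = []
        for k, codon_idx in enumerate(chosen):
            target = targets[int(rng.integers(0, 3))]
            seq = seqs[target]
            lo, hi = codon_idx * 3, codon_idx * 3 + 3
            aa0 = codon_aa(seq[lo:hi])
            placed = False
            order = rng.permutation(len(CODONS))
            for ci in order:
                cod = CODONS[ci]
                if codon_aa(cod) == aa0:
                    continue
                trial = seq[:lo] + cod + seq[hi:]
                if _local_clean(trial, lo, hi, banned_res):
                    seqs[target] = trial
                    engineered.append(codon_idx)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue

        prots = {t: _translate(seqs[t]) for t in ("II", "IV", "III")}
        n_poly = sum(
            1 for i in range(N_CODONS) if len({p[i] for p in prots.values()}) > 1
        )
        if n_poly != N_DAB1_AA_COLUMNS:
            continue

        # Type I: type III with the SalI hexamer reverted to backbone bases.
        sal_start = 201 - enzymes["SalI"].cut_offset
        sal_end = sal_start + len(enzymes["SalI"].recognition)
        seq_i = seqs["III"][:sal_start] + backbone[sal_start:sal_end] + seqs["III"][sal_end:]
        seqs["I"] = seq_i

        if not all(_verify(seqs[t], EXON2_SPECS[t], enzymes) for t in seqs):
            continue
        if any("*" in _translate(s) for s in seqs.values()):
            continue
        prefixes = {s[:PREFIX_END] for s in seqs.values()}
        suffixes = {s[SUFFIX_START:] for s in seqs.values()}
        if len(prefixes) != 1 or len(suffixes) != 1:
            continue

        fwd = Primer("ex2F", backbone[:PRIMER_LENGTH])
        rev = Primer("ex2R", revcomp(backbone[-PRIMER_LENGTH:]))
        return Exon2Family(sequences=seqs, fwd_primer=fwd, rev_primer=rev,
                           engineered_codons=tuple(engineered))
    raise GenerationError("could not build a consistent exon-2 family")
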