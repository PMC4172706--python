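"""Assembly of synthetic class II haplotypes (hp1, hp2, hp3).

Each haplotype carries 1, 2 or 3 head-to-head MHC-IIA/IIB gene pairs between
a partial COL11A2 copy and BRD2.  The whole class II cluster sits inside a
single BamHI fragment of exactly 8000/13000/18000 bp with no internal EcoRI
site, so a BamHI+EcoRI Southern blot probed with class II probes shows one
diagnostic band per haplotype.

Gene parts are drawn from a shared component library so that the published
relationships hold by construction:

* the DAB1-lineage genes carry a 661-bp intron 1, the DAB3-lineage genes a
  285-bp intron 1;
* DAB1*01 is a hybrid: its 5' half (through the middle of intron 2) comes
  from the DAB1-lineage backbone, its 3' half from the DAB3 lineage;
* DAB2*03 differs from the DAB3 alleles by 1 amino acid in exon 1 and 7 in
  exon 3; DAB3*02 and DAB3*03 are identical;
* the three DAA1-locus alleles differ only at 2 intron-1 SNPs; the hp2 and
  hp3 copies of the DAA3-DAB3 promoter differ at 1 SNP.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..enzymes import default_enzymes, find_sites, iupac_to_regex, revcomp
from ..io import Feature
from ..pcr import Primer, amplify
from ._scrub import (CODONS, GenerationError, codon_aa, random_codons,
                     random_dna, scrub)
from .alleles import Exon2Family, build_exon2_family

__all__ = [
    "GeneModel",
    "Haplotype",
    "ReferenceSet",
    "HAPLOTYPE_DEFS",
    "build_components",
    "build_haplotype",
    "build_reference_set",
]

# Component lengths (bp).  Exons are codon-multiples so annotated frames are
# all zero; probe lengths (238/279/307) are sub-regions of their exons.
DAB_EXON1 = 75
DAB_INTRON1_LONG = 661   # DAB1 lineage
DAB_INTRON1_SHORT = 285  # DAB3 lineage
DAB_EXON2 = 279
DAB_INTRON2 = 400
DAB_BREAKPOINT = 200     # hybrid switch point within intron 2
DAB_EXON3 = 309
DAB_INTRON3 = 350
DAB_EXON4 = 120

DAA_EXON1 = 75
DAA_INTRON1 = 300
DAA_EXON2 = 270
DAA_INTRON2 = 300
DAA_EXON3 = 240
DAA_INTRON3 = 300
DAA_EXON4 = 90

PROMOTER = 300
BAMHI_SITE = "GGATCC"

PROBE_IIA_EX3 = 238
PROBE_IIB_EX2 = 279
PROBE_IIB_EX3 = 307

HYBRIDIZATION_KMER = 18

#: haplotype architecture: ordered (DAA allele, DAB allele, promoter key)
#: pairs, diagnostic BamHI fragment, and total haplotype length
HAPLOTYPE_DEFS: dict[str, dict] = {
    "hp1": dict(pairs=[("DAA1*01", "DAB1*01", "P1")],
                bamhi=8000, total=35000),
    "hp2": dict(pairs=[("DAA1*02", "DAB1*02", "P1"),
                       ("DAA3*02", "DAB3*02", "P23v")],
                bamhi=13000, total=35000),
    "hp3": dict(pairs=[("DAA1*03", "DAB1*03", "P1"),
                       ("DAA2*03", "DAB2*03", "P23"),
                       ("DAA3*03", "DAB3*03", "P23")],
                bamhi=18000, total=40000),
}

#: DAB allele -> (lineage, exon-2 type, hybrid?, DAB2 exon variants?)
_DAB_SPECS: dict[str, tuple[str, str, bool, bool]] = {
    "DAB1*01": ("DAB1-lineage", "II", True, False),
    "DAB1*02": ("DAB1-lineage", "IV", False, False),
    "DAB1*03": ("DAB1-lineage", "III", False, False),
    "DAB3*02": ("DAB3-lineage", "I", False, False),
    "DAB2*03": ("DAB3-lineage", "I", False, True),
    "DAB3*03": ("DAB3-lineage", "I", False, False),
}


@dataclass(frozen=True)
class GeneModel:
    """One assembled gene, in gene-forward orientation."""

    allele_id: str
    locus: str
    kind: str  # "DAA" | "DAB"
    lineage: str | None
    exon2_type: str | None
    seq: str
    #: ordered (part_kind, ordinal, start, end) in local coordinates
    parts: tuple[tuple[str, int, int, int], ...]
    breakpoint: int | None = None  # local coordinate, hybrid alleles only

    def part_interval(self, kind: str, ordinal: int) -> tuple[int, int]:
        for k, o, s, e in self.parts:
            if k == kind and o == ordinal:
                return (s, e)
        raise KeyError(f"{self.allele_id} has no {kind} {ordinal}")

    def part_seq(self, kind: str, ordinal: int) -> str:
        s, e = self.part_interval(kind, ordinal)
        return self.seq[s:e]


@dataclass(frozen=True)
class ClassIIComponents:
    """Shared sequence backbones all alleles are assembled from."""

    family: Exon2Family
    dab_ex1: str
    dab_ex1_dab2: str
    dab_in1_long: str
    dab_in1_short: str
    dab_in2_a: str       # DAB1-lineage intron 2
    dab_in2_b: str       # DAB3-lineage intron 2 (scattered substitutions)
    dab_ex3: str
    dab_ex3_dab2: str    # 7 nonsynonymous changes
    dab_in3: str
    dab_ex4: str
    daa_ex1: str
    daa_in1: Mapping[str, str]  # DAA1-locus intron-1 variants by allele suffix
    daa_ex2: str
    daa_in2: str
    daa_ex3: str
    daa_in3: str
    daa_ex4: str
    promoters: Mapping[str, str]  # P1, P23, P23v
    probes: Mapping[str, str]
    banned: tuple[str, ...]


def _scatter_snps(seq: str, positions: Sequence[int],
                  rng: np.random.Generator, banned_res) -> str:
    """Substitute one base at each position, never creating a banned motif."""
    chars = list(seq)
    for pos in positions:
        alts = [b for b in "ACGT" if b != chars[pos]]
        rng.shuffle(alts)
        for base in alts:
            old = chars[pos]
            chars[pos] = base
            window = "".join(chars[max(0, pos - 8): pos + 9])
            if not any(rx.search(window) for rx in banned_res):
                break
            chars[pos] = old
        else:
            raise GenerationError(f"no clean substitution at {pos}")
    return "".join(chars)


def _nonsyn_variant(seq: str, codon_indices: Sequence[int],
                    rng: np.random.Generator, banned_res) -> str:
    """Replace codons with different-amino-acid codons, motif-free."""
    out = seq
    for ci in codon_indices:
        lo, hi = ci * 3, ci * 3 + 3
        aa0 = codon_aa(out[lo:hi])
        for k in rng.permutation(len(CODONS)):
            cod = CODONS[k]
            if codon_aa(cod) == aa0:
                continue
            trial = out[:lo] + cod + out[hi:]
            window = trial[max(0, lo - 8): hi + 8]
            if not any(rx.search(window) for rx in banned_res):
                out = trial
                break
        else:
            raise GenerationError(f"no clean nonsynonymous codon at {ci}")
    return out


def build_dab_allele(allele_id: str, comp: ClassIIComponents) -> GeneModel:
    lineage, ex2_type, hybrid, dab2 = _DAB_SPECS[allele_id]
    ex1 = comp.dab_ex1_dab2 if dab2 else comp.dab_ex1
    in1 = comp.dab_in1_long if lineage == "DAB1-lineage" else comp.dab_in1_short
    ex2 = comp.family[ex2_type]
    if hybrid:
        in2 = comp.dab_in2_a[:DAB_BREAKPOINT] + comp.dab_in2_b[DAB_BREAKPOINT:]
    elif lineage == "DAB1-lineage":
        in2 = comp.dab_in2_a
    else:
        in2 = comp.dab_in2_b
    ex3 = comp.dab_ex3_dab2 if dab2 else comp.dab_ex3
    pieces = [("exon", 1, ex1), ("intron", 1, in1), ("exon", 2, ex2),
              ("intron", 2, in2), ("exon", 3, ex3), ("intron", 3, comp.dab_in3),
              ("exon", 4, comp.dab_ex4)]
    parts, chunks, pos = [], [], 0
    for kind, ordv, piece in pieces:
        parts.append((kind, ordv, pos, pos + len(piece)))
        chunks.append(piece)
        pos += len(piece)
    seq = "".join(chunks)
    bp = None
    if hybrid:
        bp = dict(parts_lookup(parts))["intron2"][0] + DAB_BREAKPOINT
    return GeneModel(allele_id=allele_id, locus=allele_id.split("*")[0],
                     kind="DAB", lineage=lineage, exon2_type=ex2_type,
                     seq=seq, parts=tuple(parts), breakpoint=bp)


def parts_lookup(parts) -> list[tuple[str, tuple[int, int]]]:
    return [(f"{k}{o}", (s, e)) for k, o, s, e in parts]


def build_daa_allele(allele_id: str, comp: ClassIIComponents) -> GeneModel:
    locus, suffix = allele_id.split("*")
    in1 = comp.daa_in1[f"*{suffix}"] if locus == "DAA1" else comp.daa_in1["*01"]
    pieces = [("exon", 1, comp.daa_ex1), ("intron", 1, in1),
              ("exon", 2, comp.daa_ex2), ("intron", 2, comp.daa_in2),
              ("exon", 3, comp.daa_ex3), ("intron", 3, comp.daa_in3),
              ("exon", 4, comp.daa_ex4)]
    parts, chunks, pos = [], [], 0
    for kind, ordv, piece in pieces:
        parts.append((kind, ordv, pos, pos + len(piece)))
        chunks.append(piece)
        pos += len(piece)
    return GeneModel(allele_id=allele_id, locus=locus, kind="DAA",
                     lineage=None, exon2_type=None,
                     seq="".join(chunks), parts=tuple(parts))


def _pair_block(daa: GeneModel, dab: GeneModel,
                promoter: str) -> tuple[str, list[Feature]]:
    """Head-to-head pair: reversed DAA, shared promoter, forward DAB."""
    la = len(daa.seq)
    block = revcomp(daa.seq) + promoter + dab.seq
    feats: list[Feature] = []

    def flip(s: int, e: int) -> tuple[int, int]:
        return (la - e, la - s)

    feats.append(Feature("", "gene", *flip(0, la), strand="-",
                         attrs={"ID": daa.allele_id, "locus": daa.locus,
                                "allele": daa.allele_id}))
    for kind, ordv, s, e in daa.parts:
        fs, fe = flip(s, e)
        feats.append(Feature("", kind, fs, fe, strand="-",
                             attrs={"Parent": daa.allele_id, "ordinal": str(ordv)}))
    s3, _ = daa.part_interval("exon", 3)
    fs, fe = flip(s3, s3 + PROBE_IIA_EX3)
    feats.append(Feature("", "probe_target", fs, fe, strand="-",
                         attrs={"Parent": daa.allele_id, "probe": "IIA_ex3"}))

    off = la + len(promoter)
    feats.append(Feature("", "promoter", la, off, strand=".",
                         attrs={"ID": f"promoter_{daa.locus}-{dab.locus}"}))
    feats.append(Feature("", "gene", off, off + len(dab.seq), strand="+",
                         attrs={"ID": dab.allele_id, "locus": dab.locus,
                                "allele": dab.allele_id,
                                "exon2_type": dab.exon2_type or "."}))
    for kind, ordv, s, e in dab.parts:
        feats.append(Feature("", kind, off + s, off + e, strand="+",
                             attrs={"Parent": dab.allele_id, "ordinal": str(ordv)}))
    e2s, _ = dab.part_interval("exon", 2)
    feats.append(Feature("", "probe_target", off + e2s, off + e2s + PROBE_IIB_EX2,
                         strand="+", attrs={"Parent": dab.allele_id,
                                            "probe": "IIB_ex2"}))
    e3s, _ = dab.part_interval("exon", 3)
    feats.append(Feature("", "probe_target", off + e3s, off + e3s + PROBE_IIB_EX3,
                         strand="+", attrs={"Parent": dab.allele_id,
                                            "probe": "IIB_ex3"}))
    return block, feats


def build_components(rng: np.random.Generator) -> ClassIIComponents:
    """Draw the shared component library and validate junction cleanliness."""
    family = build_exon2_family(rng)
    fwd = family.fwd_primer.sequence
    rev = family.rev_primer.sequence
    banned = tuple(dict.fromkeys(
        [BAMHI_SITE, "GAATTC", fwd, revcomp(fwd), rev, revcomp(rev)]
    ))
    banned_res = [re.compile(iupac_to_regex(m)) for m in banned]

    def pad(n: int) -> str:
        return scrub(random_dna(n, rng), banned, rng)

    def cds(n_codons: int) -> str:
        return scrub(random_codons(n_codons, rng), banned, rng,
                     coding=[(0, 3 * n_codons)])

    dab_ex1 = cds(DAB_EXON1 // 3)
    ex1_codon = int(rng.integers(2, DAB_EXON1 // 3 - 2))
    dab_ex1_dab2 = _nonsyn_variant(dab_ex1, [ex1_codon], rng, banned_res)

    dab_in2_a = pad(DAB_INTRON2)
    dab_in2_b = _scatter_snps(dab_in2_a, range(12, DAB_INTRON2, 25), rng, banned_res)

    dab_ex3 = cds(DAB_EXON3 // 3)
    # keep the first 12 codons shared so the exon-3 probe hybridizes with
    # every DAB allele
    ex3_codons = sorted(
        12 + int(i) for i in rng.choice(DAB_EXON3 // 3 - 14, size=7, replace=False)
    )
    dab_ex3_dab2 = _nonsyn_variant(dab_ex3, ex3_codons, rng, banned_res)

    daa_in1_base = pad(DAA_INTRON1)
    daa_in1 = {
        "*01": daa_in1_base,
        "*02": _scatter_snps(daa_in1_base, [100], rng, banned_res),
        "*03": _scatter_snps(daa_in1_base, [200], rng, banned_res),
    }

    prom_p23 = pad(PROMOTER)
    promoters = {
        "P1": pad(PROMOTER),
        "P23": prom_p23,
        "P23v": _scatter_snps(prom_p23, [150], rng, banned_res),
    }

    daa_ex3 = cds(DAA_EXON3 // 3)
    comp = ClassIIComponents(
        family=family,
        dab_ex1=dab_ex1, dab_ex1_dab2=dab_ex1_dab2,
        dab_in1_long=pad(DAB_INTRON1_LONG), dab_in1_short=pad(DAB_INTRON1_SHORT),
        dab_in2_a=dab_in2_a, dab_in2_b=dab_in2_b,
        dab_ex3=dab_ex3, dab_ex3_dab2=dab_ex3_dab2,
        dab_in3=pad(DAB_INTRON3), dab_ex4=cds(DAB_EXON4 // 3),
        daa_ex1=cds(DAA_EXON1 // 3), daa_in1=daa_in1,
        daa_ex2=cds(DAA_EXON2 // 3), daa_in2=pad(DAA_INTRON2),
        daa_ex3=daa_ex3, daa_in3=pad(DAA_INTRON3), daa_ex4=cds(DAA_EXON4 // 3),
        promoters=promoters,
        probes={
            "IIA_ex3": daa_ex3[:PROBE_IIA_EX3],
            "IIB_ex2": family["II"],
            "IIB_ex3": dab_ex3[:PROBE_IIB_EX3],
        },
        banned=banned,
    )
    _validate_junctions(comp, banned_res)
    return comp


def _validate_junctions(comp: ClassIIComponents, banned_res) -> None:
    """Reject component draws whose concatenation junctions create motifs.

    The only tolerated motif hits inside a pair block are the primer
    footprints within DAB exon 2.
    """
    for hap in HAPLOTYPE_DEFS.values():
        for daa_id, dab_id, prom_key in hap["pairs"]:
            daa = build_daa_allele(daa_id, comp)
            dab = build_dab_allele(dab_id, comp)
            block, feats = _pair_block(daa, dab, comp.promoters[prom_key])
            allowed = [
                (f.start, f.end) for f in feats
                if f.type == "exon" and f.strand == "+"
                and f.attrs.get("ordinal") == "2"
            ]
            for rx in banned_res:
                for m in rx.finditer(block):
                    span = (m.start(), m.end() if m.end() > m.start()
                            else m.start() + 1)
                    inside = any(s <= m.start() and m.start() < e
                                 for s, e in allowed)
                    if not inside:
                        raise GenerationError(
                            f"junction motif in pair {daa_id}/{dab_id}"
                        )


@dataclass(frozen=True)
class Haplotype:
    """One assembled haplotype sequence with annotations and truth."""

    name: str
    seq: str
    features: tuple[Feature, ...]
    bamhi_interval: tuple[int, int]
    bamhi_size: int
    pair_alleles: tuple[tuple[str, str], ...]
    exon2_types: tuple[str, ...]
    breakpoint: int | None  # haplotype coordinate of the DAB1*01 switch

    def __len__(self) -> int:
        return len(self.seq)


def build_haplotype(name: str, comp: ClassIIComponents,
                    rng: np.random.Generator) -> Haplotype:
    spec = HAPLOTYPE_DEFS[name]
    blocks: list[tuple[str, list[Feature], tuple[str, str], str | None, int | None]] = []
    for daa_id, dab_id, prom_key in spec["pairs"]:
        daa = build_daa_allele(daa_id, comp)
        dab = build_dab_allele(dab_id, comp)
        block, feats = _pair_block(daa, dab, comp.promoters[prom_key])
        bp = None
        if dab.breakpoint is not None:
            bp = len(daa.seq) + PROMOTER + dab.breakpoint
        blocks.append((block, feats, (daa_id, dab_id), dab.exon2_type, bp))

    interior_len = spec["bamhi"] - len(BAMHI_SITE)
    blocks_len = sum(len(b[0]) for b in blocks)
    pad_total = interior_len - blocks_len
    if pad_total < 0:
        raise GenerationError(f"pairs do not fit in the {name} BamHI fragment")
    n_pads = len(blocks) + 1
    pad_sizes = [pad_total // n_pads] * n_pads
    pad_sizes[0] += pad_total - sum(pad_sizes)

    banned = comp.banned

    def pad(n: int) -> str:
        return scrub(random_dna(n, rng), banned, rng)

    lf_pads = (1200, 1200)
    col11a2 = pad(1200)
    lf = pad(lf_pads[0]) + col11a2 + pad(lf_pads[1])
    lf_len = len(lf)

    chunks = [lf, BAMHI_SITE]
    features: list[Feature] = [
        Feature(name, "gene", lf_pads[0], lf_pads[0] + len(col11a2), strand="+",
                attrs={"ID": "COL11A2", "partial": "true"}),
        Feature(name, "restriction_site", lf_len, lf_len + 6, strand="+",
                attrs={"enzyme": "BamHI"}),
    ]
    pos = lf_len + len(BAMHI_SITE)
    pair_intervals: list[tuple[int, int]] = []
    pair_alleles: list[tuple[str, str]] = []
    exon2_types: list[str] = []
    breakpoint = None
    for i, (block, feats, alleles, ex2_type, bp) in enumerate(blocks):
        p = pad(pad_sizes[i])
        chunks.append(p)
        pos += len(p)
        chunks.append(block)
        pair_intervals.append((pos, pos + len(block)))
        for f in feats:
            features.append(f.shifted(pos, seqid=name))
        pair_alleles.append(alleles)
        if ex2_type is not None:
            exon2_types.append(ex2_type)
        if bp is not None:
            breakpoint = pos + bp
        pos += len(block)
    chunks.append(pad(pad_sizes[-1]))
    pos += pad_sizes[-1]
    assert pos == lf_len + len(BAMHI_SITE) + interior_len
    features.append(Feature(name, "restriction_site", pos, pos + 6, strand="+",
                            attrs={"enzyme": "BamHI"}))
    chunks.append(BAMHI_SITE)
    pos += len(BAMHI_SITE)

    rf_len = spec["total"] - pos
    if rf_len < 3000:
        raise GenerationError(f"no room for BRD2 on {name}")
    brd2 = pad(2000)
    features.append(Feature(name, "gene", pos + 800, pos + 800 + len(brd2),
                            strand="+", attrs={"ID": "BRD2"}))
    chunks.append(pad(800) + brd2 + pad(rf_len - 2800))

    seq = "".join(chunks)
    assert len(seq) == spec["total"]

    protected = list(pair_intervals)
    protected.append((lf_len, lf_len + 6))
    right_site = lf_len + len(BAMHI_SITE) + interior_len
    protected.append((right_site, right_site + 6))
    seq = scrub(seq, banned, rng, protected=protected)
    seq = _remove_stray_probe_kmers(seq, comp.probes, pair_intervals, rng)

    enzymes = default_enzymes()
    c1 = lf_len + 1
    if find_sites(seq, enzymes["BamHI"]) != [c1, c1 + spec["bamhi"]]:
        raise GenerationError(f"unexpected BamHI map on {name}")
    if find_sites(seq, enzymes["EcoRI"]):
        raise GenerationError(f"stray EcoRI site on {name}")
    amps = amplify(seq, comp.family.fwd_primer, comp.family.rev_primer,
                   template_id=name)
    if len(amps) != len(blocks) or any(len(a) != DAB_EXON2 for a in amps):
        raise GenerationError(f"virtual PCR check failed on {name}")

    return Haplotype(
        name=name, seq=seq, features=tuple(features),
        bamhi_interval=(c1, c1 + spec["bamhi"]), bamhi_size=spec["bamhi"],
        pair_alleles=tuple(pair_alleles), exon2_types=tuple(exon2_types),
        breakpoint=breakpoint,
    )


def _remove_stray_probe_kmers(
    seq: str,
    probes: Mapping[str, str],
    allowed: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    kmer: int = HYBRIDIZATION_KMER,
    max_rounds: int = 50,
) -> str:
    """Destroy probe k-mers outside the gene-pair blocks.

    Astronomically unlikely in uniform padding, but the single-locus Southern
    property must hold with certainty, not probability.
    """
    kmers: set[str] = set()
    for p in probes.values():
        for s in (p, revcomp(p)):
            kmers.update(s[i:i + kmer] for i in range(len(s) - kmer + 1))
    chars = list(seq)
    for _ in range(max_rounds):
        s = "".join(chars)
        hit = None
        for i in range(len(s) - kmer + 1):
            if s[i:i + kmer] in kmers:
                if not any(a <= i and i + kmer <= e for a, e in allowed):
                    hit = i
                    break
        if hit is None:
            return s
        mutable = [p for p in range(hit, hit + kmer)
                   if not any(a <= p < e for a, e in allowed)]
        p = mutable[int(rng.integers(0, len(mutable)))]
        chars[p] = "ACGT"[int(rng.integers(0, 4))]
    raise GenerationError("probe k-mer scrub did not converge")


@dataclass(frozen=True)
class ReferenceSet:
    """Everything a run needs: haplotypes, genes, primers, probes, truth."""

    seed: int
    haplotypes: Mapping[str, Haplotype]
    genes: Mapping[str, GeneModel]
    components: ClassIIComponents

    @property
    def fwd_primer(self) -> Primer:
        return self.components.family.fwd_primer

    @property
    def rev_primer(self) -> Primer:
        return self.components.family.rev_primer

    @property
    def probes(self) -> Mapping[str, str]:
        return self.components.probes

    @property
    def exon2_family(self) -> Exon2Family:
        return self.components.family


def build_reference_set(seed: int, attempts: int = 40) -> ReferenceSet:
    """Build the three reference haplotypes, bit-reproducibly for a seed.

    Rejected draws (junction motifs, non-converging scrubs) advance to the
    next spawned stream, so the result is deterministic in *seed* alone.
    """
    ss = np.random.SeedSequence(seed)
    last: Exception | None = None
    for child in ss.spawn(attempts):
        rng = np.random.default_rng(child)
        try:
            comp = build_components(rng)
            haps = {name: build_haplotype(name, comp, rng)
                    for name in HAPLOTYPE_DEFS}
        except GenerationError as exc:
            last = exc
            continue
        genes: dict[str, GeneModel] = {}
        for hap in HAPLOTYPE_DEFS.values():
            for daa_id, dab_id, _ in hap["pairs"]:
                genes[daa_id] = build_daa_allele(daa_id, comp)
                genes[dab_id] = build_dab_allele(dab_id, comp)
        return ReferenceSet(seed=seed, haplotypes=haps, genes=genes,
                            components=comp)
    raise GenerationError(f"reference build failed after {attempts} attempts: {last}")
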