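# Methods

## The genotyping model

The package models presence/absence genotyping of a multigene family whose
haplotypes differ in gene copy number.  Three reference haplotypes (hp1,
hp2, hp3) carry 1, 2 and 3 head-to-head MHC-IIA/IIB gene pairs; the typed
marker is a 279-bp MHC-IIB exon-2 amplicon whose sequence falls into four
classes (types I–IV) separable by *Pst*I/*Rsa*I/*Sal*I digestion.  Two
independent evidence channels constrain a diploid genotype:

* **PCR-RFLP lanes.** All of an individual's amplicons are digested and run
  pooled, one lane per enzyme.  A lane is a *set* of band sizes — copy
  number and dosage are invisible.  Lane decoding is exact set-cover
  enumeration: a type set S is consistent with an observation iff, for every
  enzyme, the union of the reference band multisets over S collapses to the
  observed band set.  All consistent subsets are returned; committing to one
  is deliberately left to evidence integration.
* **Southern bands.** Both chromosomes are digested with *Bam*HI+*Eco*RI and
  probed with three class II probes (238 bp of IIA exon 3, the 279-bp IIB
  exon 2, 307 bp of IIB exon 3).  Each haplotype's class II cluster sits in
  a single BamHI fragment (8000/13000/18000 bp), so a genotype shows the set
  union of its two diagnostic bands.

Genotype calling intersects the candidate pairs from each channel over a
closed-world catalogue of haplotypes (unordered pairs with replacement —
presence/absence data cannot distinguish a homozygote from a hemizygote).
An empty intersection is reported as `inconsistent`, never repaired by
inventing a novel haplotype.  Over the six possible genotypes the RFLP
channel alone leaves exactly one ambiguous pair (hp1/hp2 vs hp2/hp2, because
the type II bands are a subset of the I+IV band union) and the Southern
channel is injective, so the combination identifies every genotype — the
test suite asserts both facts exhaustively.

## The synthetic-data generator

The generator *is* the study system, not a convenience fixture: its defaults
encode the published architecture, and every analysis module is exercised
against it blind.

**Exon-2 alleles.** Each type is random stop-free codons with recognition
hexamers planted so the cuts fall exactly where the printed fragment lists
put them, reading those lists in positional order from the 5' end: RsaI cuts
at 124 and 178 (types I/III), SalI at 201 (type III), PstI at 168 (type IV).
All other catalogued enzyme sites are scrubbed from the amplicon.  The four
types are built jointly off one backbone so that

* the first 36 bp and last 21 bp are identical across types (they carry the
  primer footprints, so one primer pair amplifies every allele);
* type I equals type III except at the SalI hexamer — nothing constrains
  further I/III differences, so none are introduced;
* the three DAB1-locus alleles (types II, IV, III) are polymorphic at
  exactly 12 amino-acid columns: the planted sites contribute what they
  contribute, and additional nonsynonymous substitutions are engineered at
  free codons until the count is exact.

**Genes and lineages.** IIB genes are exon1(75) – intron1 – exon2(279) –
intron2(400) – exon3(309) – intron3(350) – exon4(120); intron 1 is 661 bp in
the DAB1 lineage and 285 bp in the DAB3 lineage, the published
lineage-diagnostic length difference.  DAB2\*03 carries 1 engineered
amino-acid difference in exon 1 and 7 in exon 3 relative to the (identical)
DAB3 alleles.  The three DAA1-locus alleles differ at exactly 2 intron-1
SNPs, and the hp2/hp3 copies of the DAA3-DAB3 pair promoter at exactly 1
SNP; IIA proteins are invariant within each published group.

**The hybrid allele.** DAB1\*01 takes its 5' part from the DAB1-lineage
backbone and everything from the middle of intron 2 onward from the DAB3
lineage (the published account places the transition only somewhere between
the 5'- and 3'-terminal regions; the intron-2 midpoint is the package's
configurable default).  The two lineage intron-2 backbones differ by one
substitution every 25 bp, which is what makes the breakpoint detectable;
exon 3, intron 3 and exon 4 are shared between lineages so the DAB1 alleles
stay amino-acid-identical outside exon 2.  Because the lineages differ in
intron-1 length, aligned (equal-length) donor comparison is run on the
region from intron 2 to the gene end; exon 2 itself is excluded because the
query's type II sequence is roughly equidistant from both donors there and
window assignments would be arbitrary.

**Haplotypes.** Each haplotype is left flank (with a partial COL11A2
feature) + `GGATCC` + interior + `GGATCC` + right flank (with BRD2), the two
planted sites exactly 8000/13000/18000 bp apart cut-to-cut.  Padding is
uniform random DNA scrubbed of BamHI/EcoRI sites, primer footprints and any
18-mer shared with a probe, which guarantees the single-band Southern
property deterministically.  PstI/RsaI/SalI sites are banned only inside the
typed amplicons; elsewhere they are irrelevant to every assay the package
models.  Totals are 35/35/40 kb.

**Populations.** The five founders get the genotypes inferred for the real
founder population (hp1/2, hp1/3, hp1/3, hp1/1, hp2/3) verbatim; progeny
receive one haplotype drawn uniformly from each parent.  The real pedigree
is unpublished, so the default cross is D x E with 20 progeny, which
reproduces the published typing cohort size (2 founders + 20 progeny, four
exon-2 types in the union, 1–3 types per bird).

## Numerical and modelling choices

* **Coordinates** are 0-based half-open everywhere; a cut position counts
  bases 5' of the cut on the top strand.  GFF3 output converts to 1-based
  inclusive.  Cuts landing exactly on a sequence boundary are dropped
  (they would create empty fragments).
* **Gel model.** Bands below 40 bp (amplicon lanes) / 500 bp (Southern
  lanes) are undetectable; sizes within a relative tolerance of 0.05 are
  merged to their mean, iterated to a fixed point so the operation is
  idempotent.  Amplicon-scale digest comparison uses exact integer equality
  (the reference table is printed exact); the proportional tolerance only
  matters at Southern scale, where "approximately 8, 13, 18 kb" lives.
  Only presence/absence is modelled — no intensity, dosage or partial
  digestion.
* **Primer binding** (defaults): 0 mismatches, 3-bp exact 3' clamp, maximum
  product 5000 bp.  Real binding stringency is unknowable from band data;
  the defaults make binding deterministic.  Both strand-role assignments of
  the pair are searched, so amplification is invariant under
  reverse-complementing the template.
* **Hybridization** is a shared perfect 18-mer between fragment and probe,
  on either strand (configurable; blot stringency is otherwise
  unquantified).
* **Dot plots** default to window 20, step 1, identity 0.9.  Step 1 uses
  per-diagonal sliding sums (O(nm)); larger steps evaluate the step x step
  anchor grid.
* **Breakpoint scanning** assigns each window to the donor with fewer
  mismatches.  Ties inherit the neighbouring assignment; leading ties
  inherit the first *decided* window, so a donor-identical leading region
  never manufactures a switch.  One switch is a hybrid verdict with the
  breakpoint bracketed between the last window of one donor and the first
  of the other; more than one switch is reported as `complex`, not an
  error.  The bracket is only as tight as the informative-site spacing:
  the recovery-within-one-window property holds when every window contains
  a donor-discriminating site, which is how the simulated recombinants in
  the test suite are built (one substitution per 10-bp block).
* **Translation** uses the standard nuclear code; reading frames come from
  annotation, never from ORF scanning.  An internal stop codon is an error
  by construction — every synthetic allele is protein-coding.
* **Randomness.** One `numpy` SeedSequence per run; constraint-satisfaction
  retries advance to the next spawned stream, so builds are bit-reproducible
  in the seed alone.  Problem sizes in the shipped tests (one reference
  build per session, 1000 progeny for the Mendelian check, 100 random
  sequences for the digestion cross-check, 50 simulated recombinants) keep
  the full suite around ten seconds without weakening any exhaustive check
  — genotype-space properties are enumerated completely, not sampled.

## What passing tests do and do not show

The generator emulates the *structure* of the system — copy-number
architecture, digestion profiles, lineage-diagnostic intron lengths,
engineered polymorphism counts — not the real sequences: no codon-usage or
GC realism, no gapped alignment (all comparisons are between equal-length
constructs), no partial digestion, methylation, band-intensity or
heteroduplex effects, and no attempt to match the deposited sequences
base-for-base.  Passing tests therefore demonstrate that the inference
machinery is correct *given* the published architecture and decoding rules;
they say nothing about wet-lab failure modes (incomplete digestion, weak
hybridization, allele dropout) or about haplotypes outside the closed-world
catalogue, which the caller sees only as `inconsistent` calls.  The real
breakpoint of the hybrid allele is unpublished; only recovery of the
synthetic breakpoint is asserted.
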