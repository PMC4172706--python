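# Reference MHC class II haplotypes of the Japanese Crested Ibis founder
# population: exon-2 type content of the IIB loci carried by each haplotype
# and the diagnostic BamHI fragment size seen on a Southern blot.
haplotypes:
  hp1:
    exon2_types: [II]
    southern_bp: 8000
  hp2:
    exon2_types: [IV, I]
    southern_bp: 13000
  hp3:
    exon2_types: [III, I, I]
    southern_bp: 18000
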