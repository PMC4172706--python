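"""File formats: FASTA, GFF3, TSV tables and the YAML run manifest.

Internally all coordinates are 0-based half-open; the GFF3 writer converts
to the format's 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Feature", "write_fasta", "read_fasta", "write_gff3", "write_manifest"]


@dataclass(frozen=True)
class Feature:
    """A genomic feature in 0-based half-open coordinates."""

    seqid: str
    type: str  # gene | exon | intron | promoter | probe_target | restriction_site
    start: int
    end: int
    strand: str = "+"
    attrs: Mapping[str, str] = field(default_factory=dict)
    #: marker consumed by consumers that accept both conventions
    zero_based: bool = True

    def shifted(self, offset: int, seqid: str | None = None) -> "Feature":
        return Feature(seqid=seqid or self.seqid, type=self.type,
                       start=self.start + offset, end=self.end + offset,
                       strand=self.strand, attrs=dict(self.attrs))


def write_fasta(records: Mapping[str, str] | Sequence[tuple[str, str]], path) -> None:
    if isinstance(records, Mapping):
        records = list(records.items())
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _gff3_attrs(attrs: Mapping[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features: Iterable[Feature], path, source: str = "ibismhc") -> None:
    """Write features as GFF3 (1-based, inclusive)."""
    lines = ["##gff-version 3"]
    for f in sorted(features, key=lambda f: (f.seqid, f.start, f.end)):
        lines.append(
            "\t".join([
                f.seqid, source, f.type,
                str(f.start + 1), str(f.end),
                ".", f.strand, ".",
                _gff3_attrs(f.attrs),
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(config: Mapping, path) -> None:
    """Echo the effective configuration (including the seed) as YAML."""
    import yaml

    Path(path).write_text(yaml.safe_dump(dict(config), sort_keys=True))
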