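"""End-to-end orchestration: simulate -> amplify -> type -> blot -> genotype.

:func:`run_pipeline` drives the whole analysis for one configuration and
seed, writes every intermediate artifact (FASTA/GFF3/TSV/JSON plus a YAML
manifest echoing the configuration), and returns an in-memory report.  The
genotyping stage is *blind*: it sees only the individuals' sequences, the
primers, the probes and the reference tables, never the generator's truth,
which is used solely for the concordance column of the summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io
from .enzymes import default_enzymes, load_enzymes
from .inference import (GenotypeCall, HaplotypeCatalog, PopulationSummary,
                        default_catalog, genotypes_from_lanes,
                        genotypes_from_southern, integrate_evidence,
                        population_summary, simulate_southern)
from .pcr import Primer, amplify
from .rflp import TableError, TypeProfileTable, default_profile_table, simulate_lanes
from .sim import (ReferenceSet, TruthTable, build_reference_set,
                  default_population, simulate_population)

__all__ = ["RunConfig", "Report", "run_pipeline", "simulate_to_dir",
           "genotype_from_dir", "validate_tables"]


@dataclass
class RunConfig:
    """Reproducible configuration of one pipeline run."""

    seed: int = 0
    outdir: str | Path = "ibismhc-run"
    n_progeny: int = 20
    dam: str = "D"
    sire: str = "E"
    #: founder genotypes; None means the standard five founders A-E
    founders: dict | None = None
    channels: tuple[str, ...] = ("rflp", "southern")
    strict: bool = False
    southern_tolerance: float = 0.05
    southern_min_detectable: int = 500
    lane_min_detectable: int = 40

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "channels" in doc:
            doc["channels"] = tuple(doc["channels"])
        return cls(**doc)

    def manifest(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(d["outdir"])
        d["channels"] = list(d["channels"])
        return d


@dataclass(frozen=True)
class Report:
    """Per-individual calls with evidence, plus the population summary."""

    calls: Mapping[str, GenotypeCall]
    summary: PopulationSummary
    truth: TruthTable | None = None

    @property
    def all_consistent(self) -> bool:
        return all(c.status == "unique" for c in self.calls.values())


def _fmt_pair(pair) -> str:
    return "/".join(pair)


def simulate_to_dir(config: RunConfig) -> tuple[ReferenceSet, dict, TruthTable]:
    """Build the reference and population; write all generator artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = build_reference_set(config.seed)
    if config.founders is None:
        pop = default_population(n_progeny=config.n_progeny, dam=config.dam,
                                 sire=config.sire, seed=config.seed)
    else:
        from .sim import PopulationSpec

        pedigree = tuple((f"P{i + 1:02d}", config.dam, config.sire)
                         for i in range(config.n_progeny))
        pop = PopulationSpec(founders=dict(config.founders), pedigree=pedigree,
                             seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    individuals, truth = simulate_population(pop, rng=rng)

    io.write_fasta({n: h.seq for n, h in ref.haplotypes.items()},
                   out / "haplotypes.fasta")
    feats = [f for h in ref.haplotypes.values() for f in h.features]
    io.write_gff3(feats, out / "haplotypes.gff3")
    io.write_fasta(
        [(f"{ind.id}|hap{tag}", ref.haplotypes[h].seq)
         for ind in individuals.values()
         for tag, h in zip("AB", ind.haplotypes)],
        out / "individuals.fasta",
    )
    io.write_fasta(dict(ref.probes), out / "probes.fasta")
    io.write_fasta(dict(ref.exon2_family.sequences), out / "exon2_alleles.fasta")
    with open(out / "primers.tsv", "w") as fh:
        fh.write("name\tsequence\tdirection\n")
        fh.write(f"{ref.fwd_primer.name}\t{ref.fwd_primer.sequence}\tforward\n")
        fh.write(f"{ref.rev_primer.name}\t{ref.rev_primer.sequence}\treverse\n")
    truth.to_frame().to_csv(out / "truth_individuals.tsv", sep="\t", index=False)
    io.write_manifest({**config.manifest(), "stage": "simulate"},
                      out / "manifest.yaml")
    return ref, individuals, truth


def genotype_individuals(
    individuals: Mapping[str, Sequence[str]],
    fwd: Primer,
    rev: Primer,
    probes: Sequence[str],
    config: RunConfig,
    catalog: HaplotypeCatalog | None = None,
    table: TypeProfileTable | None = None,
) -> dict[str, GenotypeCall]:
    """Blind genotyping of {individual_id: [hapA_seq, hapB_seq]}."""
    if catalog is None:
        catalog = default_catalog()
    if table is None:
        table = default_profile_table()
    calls: dict[str, GenotypeCall] = {}
    for ind_id, seqs in individuals.items():
        channels: dict[str, list] = {}
        if "rflp" in config.channels:
            amps = [a.sequence for s in seqs for a in amplify(s, fwd, rev)]
            lanes = simulate_lanes(amps, table=table,
                                   min_detectable=config.lane_min_detectable)
            channels["rflp"] = genotypes_from_lanes(
                lanes, catalog, table, min_detectable=config.lane_min_detectable)
        if "southern" in config.channels:
            obs = simulate_southern(
                list(seqs), list(probes),
                relative_tolerance=config.southern_tolerance,
                min_detectable=config.southern_min_detectable)
            channels["southern"] = genotypes_from_southern(
                obs, catalog, relative_tolerance=config.southern_tolerance)
        calls[ind_id] = integrate_evidence(ind_id, channels)
    return calls


def run_pipeline(config: RunConfig) -> Report:
    """Execute the full pipeline and write the report artifacts."""
    out = Path(config.outdir)
    ref, individuals, truth = simulate_to_dir(config)
    seq_map = {
        ind.id: [ref.haplotypes[h].seq for h in ind.haplotypes]
        for ind in individuals.values()
    }
    calls = genotype_individuals(seq_map, ref.fwd_primer, ref.rev_primer,
                                 list(ref.probes.values()), config)
    summary = population_summary(calls, truth={i: g for i, g in
                                               truth.genotypes.items()})
    _write_report(out, calls, summary, truth)
    io.write_manifest({**config.manifest(), "stage": "report"},
                      out / "manifest.yaml")
    return Report(calls=calls, summary=summary, truth=truth)


def _write_report(out: Path, calls, summary, truth) -> None:
    import pandas as pd

    rows = []
    for ind, call in calls.items():
        rows.append({
            "individual": ind,
            "status": call.status,
            "genotype": _fmt_pair(call.genotype) if call.genotype else ".",
            "candidates": ";".join(_fmt_pair(p) for p in call.candidates),
            "truth": _fmt_pair(truth.genotypes[ind]) if truth else ".",
            **{f"{ch}_candidates": ";".join(_fmt_pair(p) for p in cands)
               for ch, cands in call.evidence.items()},
        })
    pd.DataFrame(rows).to_csv(out / "calls.tsv", sep="\t", index=False)
    doc = {
        "n_individuals": summary.n_individuals,
        "n_called": summary.n_called,
        "distinct_haplotypes": summary.distinct_haplotypes,
        "haplotype_frequencies": dict(summary.haplotype_frequencies),
        "types_per_individual": dict(summary.types_per_individual),
        "concordance": summary.concordance,
    }
    (out / "summary.json").write_text(json.dumps(doc, indent=2, sort_keys=True))


def genotype_from_dir(run_dir, config: RunConfig | None = None) -> Report:
    """Re-genotype a simulate output directory from its files alone."""
    run_dir = Path(run_dir)
    if config is None:
        config = RunConfig(outdir=run_dir)
    records = io.read_fasta(run_dir / "individuals.fasta")
    individuals: dict[str, list[str]] = {}
    for name, seq in records.items():
        ind_id = name.split("|")[0]
        individuals.setdefault(ind_id, []).append(seq)
    import pandas as pd

    primers = pd.read_csv(run_dir / "primers.tsv", sep="\t")
    by_dir = {str(r.direction): Primer(str(r.name), str(r.sequence))
              for r in primers.itertuples(index=False)}
    probes = list(io.read_fasta(run_dir / "probes.fasta").values())
    calls = genotype_individuals(individuals, by_dir["forward"],
                                 by_dir["reverse"], probes, config)
    summary = population_summary(calls)
    _write_report(Path(config.outdir), calls, summary, truth=None)
    return Report(calls=calls, summary=summary)


def validate_tables(enzymes_path=None, profiles_path=None,
                    catalog_path=None) -> list[str]:
    """Machine-readable diagnostics for the reference tables (empty = clean)."""
    diagnostics: list[str] = []
    try:
        enz = load_enzymes(enzymes_path) if enzymes_path else default_enzymes()
        if not enz:
            diagnostics.append("enzymes: table is empty")
    except Exception as exc:  # parse or invariant error
        diagnostics.append(f"enzymes: {exc}")
    try:
        if profiles_path:
            TypeProfileTable.from_tsv(profiles_path)
        else:
            default_profile_table()
    except TableError as exc:
        diagnostics.append(f"profiles: {exc}")
    except Exception as exc:
        diagnostics.append(f"profiles: {exc}")
    try:
        if catalog_path:
            HaplotypeCatalog.from_yaml(catalog_path)
        else:
            default_catalog()
    except Exception as exc:
        diagnostics.append(f"catalog: {exc}")
    return diagnostics
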