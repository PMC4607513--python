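"""End-to-end orchestration: simulate -> filter -> bias -> quartets -> coding
-> expectations, with a manifest of per-stage counts.

A run is described by a :class:`RunConfig` (usually loaded from YAML): either
a simulation block (the synthetic panel is generated, written to disk, then
read back through the ordinary readers so the whole I/O surface is
exercised) or explicit input paths.  All randomness flows from the single
configured seed; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .coding import CodingAnnotation, coding_summary
from .context import bias_profile_with_sd
from .inbreeding import InbreedingParams, equilibrium_heterozygosity, parallel_enrichment, sib_mating_trajectory
from .quartets import classify_quartets, genome_quartet_tally, snp_quartet_tally
from .seqio import (
    HOMOSITE,
    build_records,
    filter_sites,
    read_genome,
    read_panel,
    write_records,
)
from .simulate import (
    SimConfig,
    breed_panel,
    plant_mutations,
    simulate_genome,
    write_compartments_bed,
    write_genome_fasta,
    write_panel_vcf,
    write_truth,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    outdir: str = "run"
    simulate: dict | None = None  # SimConfig fields
    inputs: dict | None = None  # fasta, bed, vcf, strains
    analyses: list[dict] = field(
        default_factory=lambda: [{"canonical_class": "AG", "compartment": "intergenic"}]
    )
    min_depth: int = 30
    min_phred: float = 60.0
    alpha: float = 0.05
    bootstrap_reps: int = 2000
    zygosity: str = HOMOSITE
    expectations: dict = field(default_factory=dict)  # InbreedingParams overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)


def _exonic_gene_annotations(genome) -> list[CodingAnnotation]:
    """Treat each exonic block as a plus-strand single-exon gene (frame 0),
    trimmed to a multiple of 3 — enough structure for NS/S calls on
    synthetic panels."""
    out = []
    for i, (contig, start, end, label) in enumerate(genome.compartments):
        if label != "exonic":
            continue
        length = (end - start) // 3 * 3
        if length >= 3:
            out.append(
                CodingAnnotation(
                    gene=f"gene{i}", contig=contig, strand="+", intervals=[(start, start + length)]
                )
            )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}}

    # --- stage: simulate or load inputs -----------------------------------
    try:
        if config.simulate is not None:
            sim = SimConfig(**config.simulate)
            manifest["seed"] = sim.seed
            genome0 = simulate_genome(sim)
            truth = plant_mutations(genome0, sim)
            panel, truth = breed_panel(genome0, truth, sim)
            fasta = outdir / "genome.fa"
            bed = outdir / "compartments.bed"
            vcf = outdir / "panel.vcf"
            write_genome_fasta(genome0, fasta)
            write_compartments_bed(genome0, bed)
            write_panel_vcf(panel, genome0, vcf)
            write_truth(truth, outdir / "truth_ancestral.tsv", outdir / "truth_denovo.tsv")
            strains = panel.strain_names
            manifest["stages"]["simulate"] = {
                "ancestral_sites": int(len(truth.ancestral)),
                "denovo_events": int(len(truth.denovo)),
                "strains": len(strains),
            }
        else:
            if not config.inputs:
                raise PipelineError("config must provide either 'simulate' or 'inputs'")
            fasta = Path(config.inputs["fasta"])
            bed = Path(config.inputs["bed"])
            vcf = Path(config.inputs["vcf"])
            strains = list(config.inputs["strains"])
            for path in (fasta, bed, vcf):
                if not path.exists():
                    raise PipelineError(f"input path does not exist: {path}")
            truth = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'inputs' failed: {exc}") from exc

    # --- stage: read back + filter ----------------------------------------
    try:
        genome = read_genome(fasta, bed)
        calls = read_panel(vcf, strains)
        manifest["stages"]["parse"] = {"site_calls": len(calls)}
    except Exception as exc:
        raise PipelineError(f"stage 'parse' failed: {exc}") from exc

    het_by_strain = {s: set() for s in strains}
    hom_minor_by_strain = {s: set() for s in strains}
    for call in calls:
        minor, _ = call.minor_allele()
        target = "hom_alt" if minor == call.alt else "hom_ref"
        for s, g in call.genotypes.items():
            key = (call.contig, call.pos)
            if g == "het":
                het_by_strain[s].add(key)
            elif g == target:
                hom_minor_by_strain[s].add(key)

    # --- stage: per-analysis bias + quartets ------------------------------
    for analysis_entry in config.analyses:
        cls = analysis_entry["canonical_class"]
        compartment = analysis_entry["compartment"]
        tag = f"{cls}_{compartment}"
        try:
            homs, hets = filter_sites(
                calls, genome, compartment, min_depth=config.min_depth, min_phred=config.min_phred
            )
            chosen = homs if config.zygosity == HOMOSITE else hets
            records, dropped = build_records(genome, chosen, zygosity_kind=config.zygosity)
            records = [r for r in records if r.canonical_class == cls]
            manifest["stages"][f"filter_{tag}"] = {
                "homosites": len(homs),
                "heterosites": len(hets),
                "records": len(records),
                "context_unavailable": dict(dropped),
            }
            if not records:
                logger.warning("no %s records in %s; skipping analysis", cls, compartment)
                continue
            write_records(records, outdir / f"records_{tag}.tsv")
            profile = bias_profile_with_sd(
                records, genome, compartment, n_reps=config.bootstrap_reps,
                seed=manifest.get("seed", 0),
            )
            profile.to_tsv(outdir / f"bias_{tag}.tsv")
            observed = snp_quartet_tally(records)
            gtally = genome_quartet_tally(genome, compartment, cls)
            qtable = classify_quartets(
                observed, gtally, len(records), cls, compartment, alpha=config.alpha
            )
            qtable.to_tsv(outdir / f"quartets_{tag}.tsv")
            verdicts = qtable.table["verdict"].value_counts().to_dict()
            manifest["stages"][f"quartets_{tag}"] = {k: int(v) for k, v in verdicts.items()}
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'analysis:{tag}' failed: {exc}") from exc

    # --- stage: coding metrics on exonic homosites ------------------------
    try:
        annotations = _exonic_gene_annotations(genome)
        homs, hets = filter_sites(
            calls, genome, "exonic", min_depth=config.min_depth, min_phred=config.min_phred
        )
        sites = homs if config.zygosity == HOMOSITE else hets
        if annotations and sites:
            summary = coding_summary(sites, annotations, genome)
            manifest["stages"]["coding"] = summary.to_dict()
        else:
            manifest["stages"]["coding"] = {"skipped": "no exonic sites or annotations"}
    except Exception as exc:
        raise PipelineError(f"stage 'coding' failed: {exc}") from exc

    # --- stage: analytic expectations + parallel concordance --------------
    try:
        L = sum(len(seq) for seq in genome.contigs.values())
        params = InbreedingParams(
            **{"L": L, "n_strains": len(strains), **config.expectations}
        )
        trajectory = sib_mating_trajectory(params.generations)
        expectations = {
            "params": {
                "mu": params.mu,
                "Ne": params.Ne,
                "L": params.L,
                "n_strains": params.n_strains,
                "generations": params.generations,
            },
            "equilibrium": equilibrium_heterozygosity(params),
            "fixed_fraction": trajectory.fixed_fraction(),
            "remaining_per_1e5": float(trajectory.P[-1] * 1e5),
        }
        stats = parallel_enrichment(het_by_strain, hom_minor_by_strain, L)
        expectations["parallel"] = stats.to_dict()
        with open(outdir / "expectations.json", "w") as out:
            json.dump(expectations, out, indent=2, sort_keys=True)
        manifest["stages"]["expectations"] = expectations
    except Exception as exc:
        raise PipelineError(f"stage 'expectations' failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
    return manifest
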