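"""Synthetic genomes, context-weighted mutation planting, and inbred panels.

Every analysis stage in this package is exercised against data with known
planted structure.  The generator emulates, at reduced scale, a multi-strain
inbred resequencing panel:

* a compartmentalised genome (exonic / intronic / intergenic blocks) drawn
  from configurable base composition, optionally with first-order
  dinucleotide bias (e.g. CpG depletion);
* ancestral polymorphic sites planted with per-position rate proportional to
  a configurable multiplier of the dinucleotide quartet around the position
  (the planted analogue of "permissive" and "shielded" contexts), with the
  substitution class drawn from a transition-rich six-class spectrum;
* a panel of strains, each propagated as an explicit two-individual
  full-sib line (effective population size 2): per generation each offspring
  receives one gamete from each parent, gametes pick one parental chromosome
  per locus, and acquire de-novo mutations at rate ``mu`` per bp with the
  same quartet weighting.  Ancestral alleles are tracked as founder tokens,
  so fixation (autozygosity) arises mechanistically rather than from a
  bookkeeping shortcut;
* per-site depth (shifted Poisson) and Phred-scaled quality annotations,
  with a knob to inject low-quality sites for filter tests.

All randomness flows from one seed through named child streams, so output is
fully reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Genome
from .util import (
    BASES,
    REVCOMP_QID,
    SNP_CLASSES,
    parse_quartet,
    quartet_id,
    quartet_str,
)

_STREAM_GENOME, _STREAM_PLANT, _STREAM_BREED, _STREAM_EMIT = range(4)

_DEFAULT_COMPOSITION = {
    # GC fraction ~0.52 in coding DNA, ~0.42 elsewhere
    "exonic": {"A": 0.24, "C": 0.26, "G": 0.26, "T": 0.24},
    "intronic": {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29},
    "intergenic": {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29},
}

# transition-rich spectrum: 77.7% transitions split between the two
# transition classes, the remainder split over the four transversion classes
_DEFAULT_SPECTRUM = {
    "AG": 0.3885,
    "CT": 0.3885,
    "AC": 0.05575,
    "AT": 0.05575,
    "CG": 0.05575,
    "GT": 0.05575,
}

_DEFAULT_CONTIGS = {
    "chr1": [
        ("intergenic", 50_000),
        ("intronic", 25_000),
        ("exonic", 10_000),
        ("intronic", 25_000),
        ("intergenic", 50_000),
    ],
    "chr2": [
        ("intergenic", 60_000),
        ("intronic", 15_000),
        ("exonic", 5_000),
        ("intronic", 15_000),
        ("intergenic", 45_000),
    ],
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    ``ancestral_snp_rate`` (default 1/1500 per bp, a conservative ancestral
    heterozygosity) governs how many ancestral polymorphic sites are planted;
    ``ancestral_count`` pins the number exactly instead.  ``mu`` is the
    per-bp per-generation de-novo substitution rate (default 30e-9).
    ``quartet_multipliers`` maps 4-base quartets (purine-center folded
    orientation, 'ACTG' or 'AC|TG') to positive rate multipliers.
    """

    seed: int = 0
    contigs: dict[str, list[tuple[str, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_CONTIGS.items()}
    )
    base_composition: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COMPOSITION.items()}
    )
    dinucleotide_bias: dict[str, float] | None = None
    snp_class_spectrum: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SPECTRUM))
    quartet_multipliers: dict[str, float] = field(default_factory=dict)
    ancestral_snp_rate: float = 1.0 / 1500.0
    ancestral_count: int | None = None
    mu: float = 30e-9
    n_strains: int = 16
    filial_generations: int = 50
    depth_offset: int = 20
    depth_lambda: float = 15.0
    phred_quality: float = 99.0
    low_quality_fraction: float = 0.0
    low_quality_phred: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu < 1e-2):
            raise ValueError("mu must lie in [0, 1e-2)")
        if self.n_strains < 1 or self.filial_generations < 0:
            raise ValueError("need n_strains >= 1 and filial_generations >= 0")
        for label, comp in self.base_composition.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"base composition for {label!r} sums to {total}, not 1")
        total = sum(self.snp_class_spectrum.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"snp_class_spectrum sums to {total}, not 1")
        cleaned = {}
        for key, mult in self.quartet_multipliers.items():
            if mult <= 0:
                raise ValueError(f"multiplier for {key!r} must be positive")
            cleaned[parse_quartet(key)] = float(mult)
        self.quartet_multipliers = cleaned
        if self.dinucleotide_bias is not None:
            for key in self.dinucleotide_bias:
                if len(key) != 2 or any(c not in BASES for c in key):
                    raise ValueError(f"dinucleotide key must be 2 bases, got {key!r}")

    @property
    def strain_names(self) -> list[str]:
        return [f"strain{i + 1:02d}" for i in range(self.n_strains)]

    def total_length(self) -> int:
        return sum(length for blocks in self.contigs.values() for _, length in blocks)


@dataclass
class TruthSet:
    """Planted ground truth: ancestral sites, de-novo events, final states."""

    ancestral: pd.DataFrame  # contig,pos,ref,alt,snp_class,quartet,multiplier
    denovo: pd.DataFrame  # strain,generation,contig,pos,ref,alt,snp_class
    het_trajectory: np.ndarray | None = None  # non-autozygous count per generation
    het_trajectory_total: int = 0  # ancestral loci x strains behind the counts
    genotypes: pd.DataFrame | None = None  # final genotype codes per strain


@dataclass
class PanelResult:
    """Final panel: per-site annotations and genotype codes (0/1/2) per strain."""

    sites: pd.DataFrame  # contig,pos,ref,alt,depth,snp_quality,map_quality,consensus_quality
    genotypes: pd.DataFrame  # one int8 column per strain, aligned with sites
    strain_names: list[str]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[stream])


def _sample_block(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    dinuc_weights: np.ndarray | None,
) -> np.ndarray:
    if dinuc_weights is None:
        return rng.choice(4, size=length, p=probs).astype(np.uint8)
    # first-order chain: P(b2 | b1) proportional to pi(b2) * w(b1, b2)
    trans = probs[None, :] * dinuc_weights
    trans /= trans.sum(axis=1, keepdims=True)
    cum = np.cumsum(trans, axis=1)
    out = np.empty(length, dtype=np.uint8)
    out[0] = rng.choice(4, p=probs)
    u = rng.random(length)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i], side="right")
    return out


def markov_stationary(probs: np.ndarray, dinuc_weights: np.ndarray) -> np.ndarray:
    """Stationary base distribution of the first-order chain (for oracles)."""
    trans = probs[None, :] * dinuc_weights
    trans /= trans.sum(axis=1, keepdims=True)
    vals, vecs = np.linalg.eig(trans.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    return pi / pi.sum()


def _dinuc_weight_matrix(config: SimConfig) -> np.ndarray | None:
    if config.dinucleotide_bias is None:
        return None
    w = np.ones((4, 4))
    for key, weight in config.dinucleotide_bias.items():
        w[BASES.index(key[0]), BASES.index(key[1])] = weight
    return w


def simulate_genome(config: SimConfig) -> Genome:
    """Draw a compartmentalised genome from the configured composition."""
    rng = _rng(config, _STREAM_GENOME)
    weights = _dinuc_weight_matrix(config)
    contigs: dict[str, str] = {}
    compartments: list[tuple[str, int, int, str]] = []
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    for contig, blocks in config.contigs.items():
        parts: list[np.ndarray] = []
        offset = 0
        for label, length in blocks:
            probs = np.array([config.base_composition[label][b] for b in BASES], dtype=float)
            probs /= probs.sum()
            parts.append(_sample_block(rng, length, probs, weights))
            compartments.append((contig, offset, offset + length, label))
            offset += length
        contigs[contig] = lut[np.concatenate(parts)].tobytes().decode("ascii")
    return Genome(contigs=contigs, compartments=compartments)


# ---------------------------------------------------------------------------
# mutation planting


def position_weights(genome: Genome, config: SimConfig) -> pd.DataFrame:
    """Per-position mutability weights over all quartet-complete positions.

    Returns a frame with columns contig, pos, weight, quartet.  The quartet
    is taken in the purine-center folded orientation: positions whose center
    base is C or T are keyed by the reverse-complement quartet, matching how
    transition-class SNP records are folded downstream.
    """
    wq = np.ones(256)
    for q, mult in config.quartet_multipliers.items():
        wq[quartet_id(q)] = mult
    frames = []
    for contig, seq in genome.contigs.items():
        c = genome.codes(contig).astype(np.int64)
        n = c.size
        if n < 5:
            continue
        center = c[2 : n - 2]
        qid = c[0 : n - 4] * 64 + c[1 : n - 3] * 16 + c[3 : n - 1] * 4 + c[4:n]
        valid = (
            (center < 4)
            & (c[0 : n - 4] < 4)
            & (c[1 : n - 3] < 4)
            & (c[3 : n - 1] < 4)
            & (c[4:n] < 4)
        )
        qid = np.where(valid, qid, 0)
        folded = np.where((center == 1) | (center == 3), REVCOMP_QID[qid], qid)
        weight = np.where(valid, wq[folded], 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "pos": np.arange(2, n - 2),
                    "weight": weight,
                    "qid": folded,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _draw_classes(rng: np.random.Generator, refs: np.ndarray, spectrum: dict[str, float]) -> list[str]:
    """Draw one SNP class per event, conditioned on the reference base."""
    out = np.empty(refs.size, dtype=object)
    for code, base in enumerate(BASES):
        idx = np.nonzero(refs == code)[0]
        if idx.size == 0:
            continue
        candidates = [cls for cls in SNP_CLASSES if base in cls]
        probs = np.array([spectrum.get(cls, 0.0) for cls in candidates])
        if probs.sum() <= 0:
            probs = np.ones(len(candidates))
        probs = probs / probs.sum()
        out[idx] = rng.choice(candidates, size=idx.size, p=probs)
    return list(out)


def plant_mutations(genome: Genome, config: SimConfig) -> TruthSet:
    """Plant ancestral polymorphic sites with quartet-weighted rates.

    Per-position probability is ``ancestral_snp_rate * multiplier``; the
    event count is Poisson in the summed rate (or ``ancestral_count`` when
    pinned) and positions are sampled without replacement.
    """
    rng = _rng(config, _STREAM_PLANT)
    table = position_weights(genome, config)
    eligible = table[table["weight"] > 0]
    p = eligible["weight"].to_numpy() * config.ancestral_snp_rate
    if config.ancestral_count is not None:
        n_events = min(config.ancestral_count, len(eligible))
    else:
        n_events = min(int(rng.poisson(p.sum())), len(eligible))
    if n_events == 0:
        ancestral = pd.DataFrame(
            columns=["contig", "pos", "ref", "alt", "snp_class", "quartet", "multiplier"]
        )
        return TruthSet(ancestral=ancestral, denovo=_empty_denovo())
    take = rng.choice(len(eligible), size=n_events, replace=False, p=p / p.sum())
    chosen = eligible.iloc[np.sort(take)]
    refs = np.array(
        [genome.codes(c)[pos] for c, pos in zip(chosen["contig"], chosen["pos"])],
        dtype=np.int64,
    )
    classes = _draw_classes(rng, refs, config.snp_class_spectrum)
    ref_bases = [BASES[r] for r in refs]
    alts = [cls.replace(ref, "", 1) for cls, ref in zip(classes, ref_bases)]
    ancestral = pd.DataFrame(
        {
            "contig": chosen["contig"].to_numpy(),
            "pos": chosen["pos"].to_numpy(),
            "ref": ref_bases,
            "alt": alts,
            "snp_class": classes,
            "quartet": [quartet_str(q) for q in chosen["qid"]],
            "multiplier": [
                config.quartet_multipliers.get(quartet_str(q), 1.0) for q in chosen["qid"]
            ],
        }
    )
    return TruthSet(ancestral=ancestral, denovo=_empty_denovo())


def _empty_denovo() -> pd.DataFrame:
    return pd.DataFrame(columns=["strain", "generation", "contig", "pos", "ref", "alt", "snp_class"])


def ancestral_records(genome, truth: TruthSet, canonical_class: str | None = None, flank: int = 50):
    """Fold the planted ancestral sites into :class:`~snpcontext.SnpRecord`s.

    Shortcut for analyses that operate on the planted polymorphism itself
    (no breeding / genotype emission); sites with unavailable context are
    skipped.  Optionally restrict to one canonical class.
    """
    from .seqio import ContextUnavailable, SiteCall, extract_context

    records = []
    for row in truth.ancestral.itertuples():
        site = SiteCall(
            contig=row.contig,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            genotypes={},
            depth=30,
            snp_quality=99.0,
            map_quality=99.0,
            consensus_quality=99.0,
        )
        try:
            rec = extract_context(genome, site, flank=flank)
        except ContextUnavailable:
            continue
        if canonical_class is None or rec.canonical_class == canonical_class:
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# full-sib breeding


def _gamete_sparse(rng: np.random.Generator, parent: dict[tuple[str, int], tuple[bool, bool]]):
    """Transmit de-novo alleles: one chromosome picked per mutated locus."""
    out = {}
    for key, (on_a, on_b) in parent.items():
        if rng.random() < 0.5:
            if on_a:
                out[key] = True
        elif on_b:
            out[key] = True
    return out


def breed_panel(genome: Genome, truth: TruthSet, config: SimConfig) -> tuple[PanelResult, TruthSet]:
    """Propagate each strain as a full-sib line and emit the final panel.

    Each line is founded by two full sibs carrying four distinguishable
    founder tokens at every ancestral polymorphic locus (tokens 0/2 carry the
    reference allele, 1/3 the alternate).  ``truth.het_trajectory[t]`` counts
    loci (summed over strains) at which the measured individual still carries
    two non-identical-by-descent tokens at generation ``t`` — the quantity
    the full-sib heterozygosity recursion predicts.  Observed allele-state
    heterozygosity is lower, because distinct founder tokens can coincide in
    state at a biallelic site; both views are preserved in the outputs.
    """
    strain_seeds = np.random.SeedSequence(config.seed).spawn(4)[_STREAM_BREED].spawn(config.n_strains)
    anc = truth.ancestral.reset_index(drop=True)
    m = len(anc)
    T = config.filial_generations

    weights = position_weights(genome, config)
    weights = weights[weights["weight"] > 0].reset_index(drop=True)
    w = weights["weight"].to_numpy()
    w_prob = w / w.sum() if w.sum() > 0 else None
    total_len = config.total_length()

    trajectory = np.zeros(T + 1, dtype=np.int64)
    anc_genotypes = np.zeros((m, config.n_strains), dtype=np.int8)
    denovo_rows: list[dict] = []
    denovo_geno: list[dict[tuple[str, int], int]] = []
    anc_positions = set(zip(anc["contig"], anc["pos"])) if m else set()

    for s, seed in enumerate(strain_seeds):
        rng = np.random.default_rng(seed)
        i1 = np.stack([rng.integers(0, 2, m), 2 + rng.integers(0, 2, m)]).astype(np.int8)
        i2 = np.stack([rng.integers(0, 2, m), 2 + rng.integers(0, 2, m)]).astype(np.int8)
        m1: dict[tuple[str, int], tuple[bool, bool]] = {}
        m2: dict[tuple[str, int], tuple[bool, bool]] = {}
        trajectory[0] += int(np.count_nonzero(i1[0] != i1[1]))
        for gen in range(1, T + 1):
            children = []
            child_sparse = []
            for _ in range(2):
                g1 = np.where(rng.random(m) < 0.5, i1[0], i1[1])
                g2 = np.where(rng.random(m) < 0.5, i2[0], i2[1])
                children.append(np.stack([g1, g2]))
                sparse_a = _gamete_sparse(rng, m1)
                sparse_b = _gamete_sparse(rng, m2)
                # de-novo hits on each gamete
                for sparse in (sparse_a, sparse_b):
                    n_new = rng.poisson(config.mu * total_len) if config.mu > 0 else 0
                    for _ in range(n_new):
                        if w_prob is None:
                            break
                        k = rng.choice(len(weights), p=w_prob)
                        contig = weights.at[k, "contig"]
                        pos = int(weights.at[k, "pos"])
                        if (contig, pos) in anc_positions:
                            continue  # collision with an ancestral site
                        ref = genome.base_at(contig, pos)
                        # alt is keyed by position so that independent hits in
                        # different strains recreate the same variant
                        alt = _alt_for(contig, pos, config, genome)
                        cls = "".join(sorted((ref, alt)))
                        sparse[(contig, pos)] = True
                        denovo_rows.append(
                            {
                                "strain": config.strain_names[s],
                                "generation": gen,
                                "contig": contig,
                                "pos": pos,
                                "ref": ref,
                                "alt": alt,
                                "snp_class": cls,
                            }
                        )
                keys = set(sparse_a) | set(sparse_b)
                child_sparse.append(
                    {k: (sparse_a.get(k, False), sparse_b.get(k, False)) for k in keys}
                )
            i1, i2 = children
            m1, m2 = child_sparse
            trajectory[gen] += int(np.count_nonzero(i1[0] != i1[1]))
        # individual 1 of the final generation is "the sequenced strain"
        if m:
            anc_genotypes[:, s] = (i1[0] & 1) + (i1[1] & 1)
        denovo_geno.append({k: int(a) + int(b) for k, (a, b) in m1.items() if a or b})

    sites, genotypes = _assemble_panel(genome, config, anc, anc_genotypes, denovo_geno)
    truth_out = TruthSet(
        ancestral=anc,
        denovo=pd.DataFrame(denovo_rows, columns=_empty_denovo().columns),
        het_trajectory=trajectory,
        het_trajectory_total=m * config.n_strains,
        genotypes=genotypes,
    )
    panel = PanelResult(sites=sites, genotypes=genotypes, strain_names=config.strain_names)
    return panel, truth_out


def _assemble_panel(genome, config, anc, anc_genotypes, denovo_geno):
    rows = []
    geno_cols: dict[str, list[int]] = {name: [] for name in config.strain_names}
    for i, row in anc.iterrows():
        rows.append((row["contig"], int(row["pos"]), row["ref"], row["alt"]))
        for s, name in enumerate(config.strain_names):
            geno_cols[name].append(int(anc_genotypes[i, s]))
    denovo_sites = sorted({key for geno in denovo_geno for key in geno})
    for contig, pos in denovo_sites:
        ref = genome.base_at(contig, pos)
        rows.append((contig, pos, ref, _alt_for(contig, pos, config, genome)))
        for s, name in enumerate(config.strain_names):
            geno_cols[name].append(int(denovo_geno[s].get((contig, pos), 0)))
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    order = np.lexsort((sites["pos"].to_numpy(), sites["contig"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    genotypes = pd.DataFrame(geno_cols).iloc[order].reset_index(drop=True)

    rng = _rng(config, _STREAM_EMIT)
    n = len(sites)
    sites["depth"] = config.depth_offset + rng.poisson(config.depth_lambda, size=n)
    qual = np.full(n, config.phred_quality)
    if config.low_quality_fraction > 0 and n:
        k = int(round(config.low_quality_fraction * n))
        low = rng.choice(n, size=min(k, n), replace=False)
        qual[low] = config.low_quality_phred
    sites["snp_quality"] = qual
    sites["map_quality"] = qual
    sites["consensus_quality"] = qual
    return sites, genotypes


def _alt_for(contig: str, pos: int, config: SimConfig, genome: Genome) -> str:
    """Deterministic alt allele for a de-novo site (position-keyed draw)."""
    ref = genome.base_at(contig, pos)
    key = zlib.crc32(f"{contig}:{pos}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, key]))
    cls = _draw_classes(rng, np.array([BASES.index(ref)]), config.snp_class_spectrum)[0]
    return cls.replace(ref, "", 1)


# ---------------------------------------------------------------------------
# writers (FASTA + BED + VCF + truth TSV)

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in genome.contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_compartments_bed(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as out:
        for contig, start, end, label in genome.compartments:
            out.write(f"{contig}\t{start}\t{end}\t{label}\n")


def write_panel_vcf(panel: PanelResult, genome: Genome, path: str | Path) -> None:
    """Emit the panel as an uncompressed VCF with DP/SQ/MQ/CQ INFO fields."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=snpcontext-simulator\n")
        for name, seq in genome.contigs.items():
            out.write(f"##contig=<ID={name},length={len(seq)}>\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Sequencing depth">\n')
        out.write('##INFO=<ID=SQ,Number=1,Type=Float,Description="SNP quality (Phred)">\n')
        out.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality (Phred)">\n')
        out.write('##INFO=<ID=CQ,Number=1,Type=Float,Description="Consensus quality (Phred)">\n')
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.strain_names)
            + "\n"
        )
        for i, site in panel.sites.iterrows():
            info = (
                f"DP={int(site['depth'])};SQ={site['snp_quality']:g};"
                f"MQ={site['map_quality']:g};CQ={site['consensus_quality']:g}"
            )
            gts = "\t".join(
                _GT_STRING[int(panel.genotypes.at[i, name])] for name in panel.strain_names
            )
            out.write(
                f"{site['contig']}\t{int(site['pos']) + 1}\t.\t{site['ref']}\t{site['alt']}"
                f"\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_truth(truth: TruthSet, ancestral_path: str | Path, denovo_path: str | Path) -> None:
    truth.ancestral.to_csv(ancestral_path, sep="\t", index=False)
    truth.denovo.to_csv(denovo_path, sep="\t", index=False)
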