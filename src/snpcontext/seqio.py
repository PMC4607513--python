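"""Reference/compartment/genotype-panel I/O and SNP filtering.

The data model mirrors a multi-strain resequencing panel: a reference genome
partitioned into exonic / intronic / intergenic compartments (BED, 0-based
half-open), per-strain genotype calls with depth and three Phred-scaled
quality annotations (VCF), and strand-folded SNP records carrying +/-50 bp
of flanking sequence for context analyses.

Filtering follows the stringent thresholds used for inbred-strain panels:
sequencing depth >= 30, SNP/mapping/consensus quality >= Phred 60, and the
minor allele homozygous in at least 2 strains (exonic) or 4 strains
(noncoding) for "homosites"; "heterosites" additionally require at least one
heterozygous strain and are interpreted as recent mutations on an otherwise
congenic background.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .util import (
    CANONICAL_CLASS,
    COMPARTMENT_CODE,
    COMPARTMENTS,
    encode,
    revcomp,
    snp_class,
)

logger = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

HOMOSITE = "homosite"
HETEROSITE = "heterosite"

#: default mapping of SiteCall annotation names to VCF INFO keys
DEFAULT_FIELD_MAP = {
    "depth": "DP",
    "snp_quality": "SQ",
    "map_quality": "MQ",
    "consensus_quality": "CQ",
}

RECORD_TSV_COLUMNS = [
    "contig",
    "pos0",
    "class",
    "canonical_class",
    "compartment",
    "zygosity",
    "n_minor_strains",
    "flank5",
    "flank3",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally valid input that violates a model invariant."""


class ContextUnavailable(Exception):
    """Flanking context cannot be extracted (truncated window or N base)."""

    def __init__(self, reason: str, contig: str, pos: int):
        self.reason = reason
        self.contig = contig
        self.pos = pos
        super().__init__(f"{contig}:{pos}: context unavailable ({reason})")


@dataclass
class Genome:
    """Reference sequence plus a compartment partition.

    ``contigs`` maps contig id to an uppercase string over A/C/G/T/N.
    ``compartments`` is a list of ``(contig, start, end, label)`` intervals,
    0-based half-open.  Labels of distinct compartments may not overlap;
    overlapping intervals of the *same* label are merged silently.
    """

    contigs: dict[str, str]
    compartments: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}
        for name, seq in self.contigs.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(f"contig {name!r} contains invalid characters {sorted(bad)}")
        self._codes = {name: encode(seq) for name, seq in self.contigs.items()}
        self._labels = self._build_label_arrays()

    def _build_label_arrays(self) -> dict[str, np.ndarray]:
        labels = {name: np.zeros(len(seq), dtype=np.uint8) for name, seq in self.contigs.items()}
        for contig, start, end, label in self.compartments:
            if contig not in self.contigs:
                raise ValidationError(f"compartment interval on unknown contig {contig!r}")
            if label not in COMPARTMENT_CODE:
                raise ValidationError(f"unknown compartment label {label!r}")
            n = len(self.contigs[contig])
            if not (0 <= start < end <= n):
                raise ValidationError(
                    f"interval {contig}:{start}-{end} outside contig bounds (length {n})"
                )
            code = COMPARTMENT_CODE[label]
            segment = labels[contig][start:end]
            clash = (segment != 0) & (segment != code)
            if clash.any():
                pos = start + int(np.argmax(clash))
                raise ValidationError(
                    f"position {contig}:{pos} assigned conflicting compartment labels"
                )
            segment[:] = code
        return labels

    def codes(self, contig: str) -> np.ndarray:
        """Sequence of ``contig`` as uint8 codes (A=0..T=3, N=4)."""
        return self._codes[contig]

    def labels(self, contig: str) -> np.ndarray:
        """Per-position compartment codes for ``contig`` (0 = unannotated)."""
        return self._labels[contig]

    def label_at(self, contig: str, pos: int) -> str:
        code = int(self._labels[contig][pos])
        return COMPARTMENTS[code - 1] if code else "unannotated"

    def compartment_positions(self, label: str) -> Iterable[tuple[str, np.ndarray]]:
        """Yield ``(contig, positions)`` arrays for one compartment label."""
        if label not in COMPARTMENT_CODE:
            raise ValidationError(f"unknown compartment label {label!r}")
        code = COMPARTMENT_CODE[label]
        for contig, arr in self._labels.items():
            positions = np.nonzero(arr == code)[0]
            if positions.size:
                yield contig, positions

    def base_at(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos]


@dataclass
class SiteCall:
    """One biallelic genotype call across the strain panel."""

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotypes: dict[str, str]  # strain -> hom_ref | het | hom_alt | missing
    depth: int
    snp_quality: float
    map_quality: float
    consensus_quality: float

    def __post_init__(self) -> None:
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError(f"{self.contig}:{self.pos}: ref/alt must be distinct single bases")
        if self.depth < 0:
            raise ValidationError(f"{self.contig}:{self.pos}: negative depth")
        for q in (self.snp_quality, self.map_quality, self.consensus_quality):
            if q < 0:
                raise ValidationError(f"{self.contig}:{self.pos}: negative quality")

    @property
    def snp_class(self) -> str:
        return snp_class(self.ref, self.alt)

    def minor_allele(self) -> tuple[str, int]:
        """The rarer allele among homozygous strains and its carrier count.

        Ties go to the alternate allele.  Heterozygous and missing genotypes
        do not contribute to the homozygous carrier counts.
        """
        n_alt = sum(1 for g in self.genotypes.values() if g == HOM_ALT)
        n_ref = sum(1 for g in self.genotypes.values() if g == HOM_REF)
        return (self.alt, n_alt) if n_alt <= n_ref else (self.ref, n_ref)

    def n_het_strains(self) -> int:
        return sum(1 for g in self.genotypes.values() if g == HET)


@dataclass(frozen=True)
class SnpRecord:
    """A strand-folded SNP with 50-bp flanks, ready for context analyses.

    ``snp_class`` is the unordered allele pair before folding; classes whose
    reverse complement sorts first (C<->T, G<->T) are folded so that
    ``canonical_class`` is one of A<->G, A<->C, A<->T, C<->G and the flanks
    are reported in the folded (plus) orientation.
    """

    contig: str
    pos: int
    snp_class: str
    canonical_class: str
    compartment: str
    flank5: str
    flank3: str
    zygosity_kind: str  # homosite | heterosite
    n_minor_strains: int

    def __post_init__(self) -> None:
        if CANONICAL_CLASS[self.snp_class] != self.canonical_class:
            raise ValidationError(
                f"canonical_class {self.canonical_class} is not the fold of {self.snp_class}"
            )
        if len(self.flank5) != len(self.flank3):
            raise ValidationError("flanks must have equal length")

    def quartet(self) -> str:
        """The folded dinucleotide quartet X1X2|X3X4 around the site."""
        return self.flank5[-2:] + self.flank3[:2]


# ---------------------------------------------------------------------------
# readers


def _read_bed(bed_path: str | Path) -> list[tuple[str, int, int, str]]:
    intervals: list[tuple[str, int, int, str]] = []
    try:
        table = pd.read_csv(
            bed_path,
            sep="\t",
            header=None,
            comment="#",
            names=["contig", "start", "end", "label"],
            dtype={"contig": str, "label": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse BED file {bed_path}: {exc}") from exc
    for idx, row in table.iterrows():
        line_no = idx + 1
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise FormatError(f"{bed_path} line {line_no}: non-integer coordinates")
        if pd.isna(row["label"]) or row["label"] not in COMPARTMENT_CODE:
            raise FormatError(
                f"{bed_path} line {line_no}: compartment label must be one of {COMPARTMENTS}"
            )
        if start < 0 or end <= start:
            raise FormatError(f"{bed_path} line {line_no}: invalid interval {start}-{end}")
        intervals.append((str(row["contig"]), start, end, str(row["label"])))
    return intervals


def read_genome(fasta_path: str | Path, bed_path: str | Path | None = None) -> Genome:
    """Load a reference FASTA plus (optionally) a compartment BED.

    Raises :class:`FormatError` for malformed input (naming the line where
    detectable) and :class:`ValidationError` for out-of-bounds intervals or
    conflicting compartment labels.
    """
    with open(fasta_path) as handle:
        first = handle.readline()
        if not first.startswith(">"):
            raise FormatError(f"{fasta_path} line 1: expected FASTA header starting with '>'")
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise FormatError(f"{fasta_path}: no FASTA records found")
    compartments = _read_bed(bed_path) if bed_path is not None else []
    return Genome(contigs=contigs, compartments=compartments)


def _classify_gt(sample) -> str:
    alleles = sample.get("GT", (None, None))
    if alleles is None or any(a is None for a in alleles):
        return MISSING
    s = set(alleles)
    if s == {0}:
        return HOM_REF
    if s == {1}:
        return HOM_ALT
    return HET


def read_panel(
    vcf_path: str | Path,
    strain_ids: Sequence[str],
    field_map: dict[str, str] | None = None,
    skip_counter: Counter | None = None,
) -> list[SiteCall]:
    """Read a genotype panel VCF into :class:`SiteCall` records.

    Only biallelic single-base substitutions are kept; indel and multiallelic
    lines are skipped with a logged count (also accumulated into
    ``skip_counter`` when given).  VCF positions are converted 1-based ->
    0-based.  ``field_map`` maps the annotation names ``depth``,
    ``snp_quality``, ``map_quality``, ``consensus_quality`` to INFO keys
    (defaults: DP, SQ, MQ, CQ) since quality-field dialects vary.
    """
    fmap = dict(DEFAULT_FIELD_MAP, **(field_map or {}))
    counter = skip_counter if skip_counter is not None else Counter()
    calls: list[SiteCall] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        present = set(vcf.header.samples)
        absent = [s for s in strain_ids if s not in present]
        if absent:
            raise ValidationError(f"strain columns absent from {vcf_path}: {absent}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                counter["multiallelic"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                counter["indel"] += 1
                continue
            genotypes = {s: _classify_gt(rec.samples[s]) for s in strain_ids}
            info = rec.info
            calls.append(
                SiteCall(
                    contig=rec.contig,
                    pos=rec.pos - 1,
                    ref=ref,
                    alt=alt,
                    genotypes=genotypes,
                    depth=int(info.get(fmap["depth"], 0)),
                    snp_quality=float(info.get(fmap["snp_quality"], 0.0)),
                    map_quality=float(info.get(fmap["map_quality"], 0.0)),
                    consensus_quality=float(info.get(fmap["consensus_quality"], 0.0)),
                )
            )
    if counter:
        logger.info("read_panel skipped lines: %s", dict(counter))
    return calls


# ---------------------------------------------------------------------------
# filtering and context extraction


def filter_sites(
    calls: Iterable[SiteCall],
    genome: Genome,
    compartment: str,
    min_depth: int = 30,
    min_phred: float = 60.0,
    min_minor_hom: int | None = None,
) -> tuple[list[SiteCall], list[SiteCall]]:
    """Split calls from one compartment into retained homosites/heterosites.

    A homosite passes when depth and all three qualities meet the thresholds
    and the minor allele is homozygous in at least ``min_minor_hom`` strains
    (default 2 for exonic, 4 for intronic/intergenic).  A heterosite passes
    the same depth/quality thresholds with at least one heterozygous strain.
    The same site may qualify for both lists.
    """
    if compartment not in COMPARTMENT_CODE:
        raise ValidationError(f"unknown compartment label {compartment!r}")
    if min_minor_hom is None:
        min_minor_hom = 2 if compartment == "exonic" else 4
    homosites: list[SiteCall] = []
    heterosites: list[SiteCall] = []
    for call in calls:
        if genome.label_at(call.contig, call.pos) != compartment:
            continue
        if call.depth < min_depth:
            continue
        if min(call.snp_quality, call.map_quality, call.consensus_quality) < min_phred:
            continue
        _, n_minor = call.minor_allele()
        if n_minor >= min_minor_hom:
            homosites.append(call)
        if call.n_het_strains() >= 1:
            heterosites.append(call)
    return homosites, heterosites


def extract_context(
    genome: Genome,
    site: SiteCall,
    flank: int = 50,
    zygosity_kind: str = HOMOSITE,
) -> SnpRecord:
    """Build the strand-folded :class:`SnpRecord` for one retained site.

    Folding: classes C<->T and G<->T are reported on the opposite strand, so
    the flanks are reverse complemented and swapped.  Sites within ``flank``
    bases of a contig end, or with any N in either flank, raise
    :class:`ContextUnavailable` rather than being silently dropped.
    """
    seq = genome.contigs[site.contig]
    pos = site.pos
    if pos - flank < 0 or pos + flank + 1 > len(seq):
        raise ContextUnavailable("truncated", site.contig, pos)
    flank5 = seq[pos - flank : pos]
    flank3 = seq[pos + 1 : pos + 1 + flank]
    if "N" in flank5 or "N" in flank3:
        raise ContextUnavailable("contains_N", site.contig, pos)
    cls = site.snp_class
    canonical = CANONICAL_CLASS[cls]
    if canonical != cls:  # fold to the reverse-complement orientation
        flank5, flank3 = revcomp(flank3), revcomp(flank5)
    if zygosity_kind == HOMOSITE:
        _, n_minor = site.minor_allele()
    elif zygosity_kind == HETEROSITE:
        n_minor = site.n_het_strains()
    else:
        raise ValidationError(f"unknown zygosity kind {zygosity_kind!r}")
    return SnpRecord(
        contig=site.contig,
        pos=pos,
        snp_class=cls,
        canonical_class=canonical,
        compartment=genome.label_at(site.contig, pos),
        flank5=flank5,
        flank3=flank3,
        zygosity_kind=zygosity_kind,
        n_minor_strains=n_minor,
    )


def build_records(
    genome: Genome,
    sites: Iterable[SiteCall],
    zygosity_kind: str = HOMOSITE,
    flank: int = 50,
) -> tuple[list[SnpRecord], Counter]:
    """Extract contexts for many sites; returns (records, drop-reason counts)."""
    records: list[SnpRecord] = []
    dropped: Counter = Counter()
    for site in sites:
        try:
            records.append(extract_context(genome, site, flank=flank, zygosity_kind=zygosity_kind))
        except ContextUnavailable as exc:
            dropped[exc.reason] += 1
    if dropped:
        logger.info("context unavailable for %s sites: %s", sum(dropped.values()), dict(dropped))
    return records, dropped


# ---------------------------------------------------------------------------
# retained-SNP report round trip


def write_records(records: Iterable[SnpRecord], path: str | Path) -> None:
    rows = [
        {
            "contig": r.contig,
            "pos0": r.pos,
            "class": r.snp_class,
            "canonical_class": r.canonical_class,
            "compartment": r.compartment,
            "zygosity": r.zygosity_kind,
            "n_minor_strains": r.n_minor_strains,
            "flank5": r.flank5,
            "flank3": r.flank3,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> list[SnpRecord]:
    table = pd.read_csv(path, sep="\t", dtype={"contig": str, "flank5": str, "flank3": str})
    missing = set(RECORD_TSV_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        SnpRecord(
            contig=row["contig"],
            pos=int(row["pos0"]),
            snp_class=row["class"],
            canonical_class=row["canonical_class"],
            compartment=row["compartment"],
            flank5=row["flank5"],
            flank3=row["flank3"],
            zygosity_kind=row["zygosity"],
            n_minor_strains=int(row["n_minor_strains"]),
        )
        for _, row in table.iterrows()
    ]
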