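"""Coding impact of SNPs: Ts:Tv split, NS:S classification, CG-codon usage.

Transitions are the purine<->purine / pyrimidine<->pyrimidine classes
(A<->G, C<->T); the other four classes are transversions.  Synonymous /
nonsynonymous calls substitute the alternate allele into the strand-aware
codon under the standard genetic code (stop gain/loss counts as
nonsynonymous).  The CG-codon analysis measures, per amino acid, how often
usage falls on codons containing the CG dinucleotide, against the
expectation from the mononucleotide composition of the coding sequence —
quantifying the CpG depletion that shields exons from context-biased
mutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

from .seqio import Genome, SiteCall, ValidationError
from .util import BASES, complement_base, is_transition, revcomp

TRANSITION = "transition"
TRANSVERSION = "transversion"
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"


def classify_tstv(cls: str) -> str:
    """'AG'/'CT' -> transition; the four other classes -> transversion."""
    if cls not in {"AC", "AG", "AT", "CG", "CT", "GT"}:
        raise ValidationError(f"not a SNP class: {cls!r}")
    return TRANSITION if is_transition(cls) else TRANSVERSION


@dataclass
class CodingAnnotation:
    """One gene's CDS: ordered genomic intervals plus strand.

    Intervals are 0-based half-open, stored in genomic order and
    non-overlapping; total length must be divisible by 3.  For minus-strand
    genes the coding sequence is the reverse complement of the concatenated
    intervals read right-to-left.
    """

    gene: str
    contig: str
    strand: str  # '+' or '-'
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene}: strand must be '+' or '-'")
        ivs = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ValidationError(f"{self.gene}: overlapping CDS intervals")
        if any(e <= s for s, e in ivs):
            raise ValidationError(f"{self.gene}: empty CDS interval")
        self.intervals = ivs
        if self.cds_length % 3 != 0:
            raise ValidationError(f"{self.gene}: CDS length {self.cds_length} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def cds_sequence(self, genome: Genome) -> str:
        seq = genome.contigs[self.contig]
        plus = "".join(seq[s:e] for s, e in self.intervals)
        return plus if self.strand == "+" else revcomp(plus)

    def cds_offset(self, pos: int) -> int | None:
        """CDS coordinate (in transcription direction) of a genomic position."""
        off = 0
        plus_offset = None
        for s, e in self.intervals:
            if s <= pos < e:
                plus_offset = off + (pos - s)
                break
            off += e - s
        if plus_offset is None:
            return None
        return plus_offset if self.strand == "+" else self.cds_length - 1 - plus_offset


def classify_ns_s(
    annotation: CodingAnnotation, genome: Genome, pos: int, ref: str, alt: str
) -> str:
    """Synonymous / nonsynonymous / noncoding call for one substitution.

    ``ref``/``alt`` are plus-strand alleles at genomic ``pos``; for
    minus-strand genes they are complemented before substitution into the
    codon.  Stop<->sense changes count as nonsynonymous.
    """
    offset = annotation.cds_offset(pos)
    if offset is None:
        return NONCODING
    cds = annotation.cds_sequence(genome)
    ref_t = ref if annotation.strand == "+" else complement_base(ref)
    alt_t = alt if annotation.strand == "+" else complement_base(alt)
    if cds[offset] != ref_t:
        raise ValidationError(
            f"{annotation.gene}: reference mismatch at CDS offset {offset} "
            f"({cds[offset]} != {ref_t})"
        )
    codon_start = offset - offset % 3
    codon = cds[codon_start : codon_start + 3]
    mutant = codon[: offset % 3] + alt_t + codon[offset % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    return SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS


def ns_s_ratio(n_nonsynonymous: int, n_synonymous: int) -> float:
    """S per NS, as in '1:x' ratio reporting, rounded to 2 decimals."""
    if n_nonsynonymous <= 0:
        raise ValidationError("need at least one nonsynonymous SNP for a 1:x ratio")
    return round(n_synonymous / n_nonsynonymous, 2)


@dataclass
class CodingSummary:
    n_transitions: int
    n_transversions: int
    n_nonsynonymous: int
    n_synonymous: int
    chi2_ns_s: float | None = None
    p_ns_s: float | None = None

    @property
    def pct_transition(self) -> float:
        total = self.n_transitions + self.n_transversions
        return 100.0 * self.n_transitions / total if total else float("nan")

    @property
    def pct_transversion(self) -> float:
        # exact complement so the two percentages sum to 100
        return 100.0 - self.pct_transition

    @property
    def ratio_s_per_ns(self) -> float:
        return ns_s_ratio(self.n_nonsynonymous, self.n_synonymous)

    def ratio_string(self) -> str:
        return f"1:{self.ratio_s_per_ns:.2f}"

    def to_dict(self) -> dict:
        return {
            "n_transitions": self.n_transitions,
            "n_transversions": self.n_transversions,
            "pct_transition": self.pct_transition,
            "pct_transversion": self.pct_transversion,
            "n_nonsynonymous": self.n_nonsynonymous,
            "n_synonymous": self.n_synonymous,
            "ns_s": self.ratio_string(),
            "chi2_ns_s": self.chi2_ns_s,
            "p_ns_s": self.p_ns_s,
        }


def coding_summary(
    sites: list[SiteCall],
    annotations: list[CodingAnnotation],
    genome: Genome,
    expected_s_fraction: float | None = None,
) -> CodingSummary:
    """Aggregate Ts/Tv and NS/S over exonic sites.

    Sites falling outside every annotated CDS contribute to the Ts/Tv split
    only.  ``expected_s_fraction`` (synonymous fraction under a stochastic
    formation model) enables a Yates-corrected goodness-of-fit chi-square of
    the observed NS/S split; the expectation model is deliberately
    config-supplied.
    """
    if not sites:
        raise ValidationError("no sites")
    by_contig: dict[str, list[CodingAnnotation]] = {}
    for ann in annotations:
        by_contig.setdefault(ann.contig, []).append(ann)
    n_ts = n_tv = n_ns = n_s = 0
    for site in sites:
        if classify_tstv(site.snp_class) == TRANSITION:
            n_ts += 1
        else:
            n_tv += 1
        for ann in by_contig.get(site.contig, []):
            call = classify_ns_s(ann, genome, site.pos, site.ref, site.alt)
            if call == SYNONYMOUS:
                n_s += 1
                break
            if call == NONSYNONYMOUS:
                n_ns += 1
                break
    chi2 = p = None
    total = n_ns + n_s
    if expected_s_fraction is not None and total > 0:
        e = np.array([(1 - expected_s_fraction) * total, expected_s_fraction * total])
        o = np.array([n_ns, n_s], dtype=float)
        diff = np.clip(np.abs(o - e) - 0.5, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = float((diff**2 / e).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    return CodingSummary(
        n_transitions=n_ts,
        n_transversions=n_tv,
        n_nonsynonymous=n_ns,
        n_synonymous=n_s,
        chi2_ns_s=chi2,
        p_ns_s=p,
    )


# ---------------------------------------------------------------------------
# CG-codon usage


def _codon_table() -> dict[str, list[str]]:
    """amino acid (or '*') -> list of codons, standard code."""
    table: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        table.setdefault(aa, []).append(codon)
    table["*"] = list(standard_dna_table.stop_codons)
    return table


def cg_codon_usage(cds_sequences: list[str]) -> pd.DataFrame:
    """Per-amino-acid usage of CG-containing codons versus expectation.

    A CG codon is one whose three bases contain 'CG' as a substring (TCG,
    CCG, ACG, GCG and the CGx family); CG dinucleotides spanning codon
    junctions are a separate genomic-depletion question and are not counted
    here.  The expected CG fraction for each amino acid weights its codons
    by the product of mononucleotide frequencies of the pooled coding
    sequence.  One Yates-corrected 1-df chi-square per amino acid with at
    least two codons and at least one observed codon.
    """
    for seq in cds_sequences:
        if len(seq) % 3 != 0:
            raise ValidationError("every CDS length must be divisible by 3")
    codons: list[str] = []
    for seq in cds_sequences:
        s = seq.upper()
        codons.extend(s[i : i + 3] for i in range(0, len(s), 3))
    codons = [c for c in codons if all(b in BASES for b in c)]
    if not codons:
        raise ValidationError("no complete codons")
    pooled = "".join(codons)
    counts = pd.Series(list(pooled)).value_counts()
    freqs = {b: counts.get(b, 0) / len(pooled) for b in BASES}
    usage = pd.Series(codons).value_counts()

    rows = []
    for aa, aa_codons in sorted(_codon_table().items()):
        if aa == "*" or len(aa_codons) < 2:
            continue
        n_total = int(sum(usage.get(c, 0) for c in aa_codons))
        cg_codons = [c for c in aa_codons if "CG" in c]
        n_cg = int(sum(usage.get(c, 0) for c in cg_codons))
        weight = {c: np.prod([freqs[b] for b in c]) for c in aa_codons}
        denom = sum(weight.values())
        exp_frac = sum(weight[c] for c in cg_codons) / denom if denom > 0 else np.nan
        chi2 = p = np.nan
        if n_total > 0 and 0 < exp_frac < 1:
            e = np.array([exp_frac * n_total, (1 - exp_frac) * n_total])
            o = np.array([n_cg, n_total - n_cg], dtype=float)
            diff = np.clip(np.abs(o - e) - 0.5, 0.0, None)
            chi2 = float((diff**2 / e).sum())
            p = float(stats.chi2.sf(chi2, df=1))
        rows.append(
            {
                "amino_acid": aa,
                "n_codons_total": n_total,
                "n_cg_codons": n_cg,
                "cg_fraction": n_cg / n_total if n_total else np.nan,
                "expected_cg_fraction": exp_frac,
                "chi2": chi2,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-table I/O


def read_gene_table(path) -> list[CodingAnnotation]:
    """Gene table TSV: columns gene, contig, strand, cds_intervals.

    ``cds_intervals`` is a ';'-separated list of 0-based half-open
    'start-end' spans, e.g. '100-190;250-340'.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "contig", "strand", "cds_intervals"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in table.iterrows():
        intervals = []
        for span in str(row["cds_intervals"]).split(";"):
            start, end = span.split("-")
            intervals.append((int(start), int(end)))
        out.append(
            CodingAnnotation(
                gene=row["gene"], contig=row["contig"], strand=row["strand"], intervals=intervals
            )
        )
    return out


def write_gene_table(annotations: list[CodingAnnotation], path) -> None:
    rows = [
        {
            "gene": a.gene,
            "contig": a.contig,
            "strand": a.strand,
            "cds_intervals": ";".join(f"{s}-{e}" for s, e in a.intervals),
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
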