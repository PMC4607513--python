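"""Dinucleotide-quartet enrichment around SNPs.

A quartet is the four bases X1X2|X3X4 immediately flanking a focal position
(two upstream, two downstream; the focal base itself is excluded).  For one
canonical SNP class and one genome compartment, each of the 256 quartets is
tested for over-/underrepresentation around SNPs relative to its genomic
incidence, with one 2x2 chi-square (Yates-corrected) per center base of the
class and a Bonferroni family of 256 comparisons.  A quartet is called
"permissive" only when both center-base tests are significantly above
expectation, "shielded" only when both are significantly below; rows where
any expected cell of a 2x2 table falls under 5 are untestable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import Genome, SnpRecord, ValidationError
from .util import (
    BASES,
    CANONICAL_CLASSES,
    COMPARTMENT_CODE,
    REVCOMP_QID,
    complement_base,
    encode,
    format_quartet,
    quartet_id,
    quartet_str,
)

__all__ = [
    "TestResult",
    "QuartetTable",
    "genome_quartet_tally",
    "snp_quartet_tally",
    "yates_chi2_2x2",
    "classify_quartets",
    "orf_quartet_scan",
]

PERMISSIVE = "permissive"
SHIELDED = "shielded"
NEUTRAL = "neutral"
UNTESTABLE = "untestable"


@dataclass
class TestResult:
    """One 2x2 (or 1-df goodness-of-fit) chi-square with Yates correction."""

    chi2: float
    p_value: float
    expected_cells_ok: bool
    testable: bool = True
    alpha: float | None = None
    alpha_adjusted: float | None = None
    n_tests: int | None = None
    observed: float | None = None
    expected: float | None = None
    direction: str | None = None  # 'over' / 'under' for goodness-of-fit scans


def yates_chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Yates-corrected chi-square for the 2x2 table [[a, b], [c, d]].

    The continuity correction is clamped at zero (cells with |O-E| < 0.5
    contribute nothing).  A zero marginal yields an untestable result rather
    than an exception.  ``expected_cells_ok`` records whether all four
    expected counts reach 5, the validity condition used downstream.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValidationError("cell counts must be nonnegative")
    total = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if total == 0 or (rows == 0).any() or (cols == 0).any():
        return TestResult(chi2=float("nan"), p_value=float("nan"), expected_cells_ok=False, testable=False)
    expected = np.outer(rows, cols) / total
    diff = np.clip(np.abs(obs - expected) - 0.5, 0.0, None)
    chi2 = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(chi2=chi2, p_value=p, expected_cells_ok=bool((expected >= 5).all()))


def _class_center_bases(canonical_class: str) -> tuple[str, str]:
    if canonical_class not in CANONICAL_CLASSES:
        raise ValidationError(f"{canonical_class!r} is not a canonical class")
    return canonical_class[0], canonical_class[1]


def genome_quartet_tally(
    genome: Genome, compartment: str, canonical_class: str
) -> dict[str, np.ndarray]:
    """Genomic quartet counts per center base of a canonical class.

    For each compartment position whose center base is one of the class's
    two bases (with two valid flanking bases each side, N-windows skipped)
    the surrounding quartet is tallied.  For folded classes (A<->G, A<->C)
    complementary-strand centers are tallied too, under the
    reverse-complement quartet, so the counts live in the same canonical
    orientation as folded SNP records.  Returns ``{base: counts[256]}``.
    """
    b1, b2 = _class_center_bases(canonical_class)
    out = {b1: np.zeros(256, dtype=np.int64), b2: np.zeros(256, dtype=np.int64)}
    if compartment not in COMPARTMENT_CODE:
        raise ValidationError(f"unknown compartment label {compartment!r}")
    comp_code = COMPARTMENT_CODE[compartment]
    for contig in genome.contigs:
        c = genome.codes(contig).astype(np.int64)
        n = c.size
        if n < 5:
            continue
        labels = genome.labels(contig)[2 : n - 2]
        center = c[2 : n - 2]
        valid = (
            (labels == comp_code)
            & (center < 4)
            & (c[0 : n - 4] < 4)
            & (c[1 : n - 3] < 4)
            & (c[3 : n - 1] < 4)
            & (c[4:n] < 4)
        )
        qid = c[0 : n - 4] * 64 + c[1 : n - 3] * 16 + c[3 : n - 1] * 4 + c[4:n]
        qid = np.where(valid, qid, 0)
        for base in (b1, b2):
            code = BASES.index(base)
            direct = valid & (center == code)
            out[base] += np.bincount(qid[direct], minlength=256)
            comp_b = complement_base(base)
            if comp_b not in (b1, b2):  # folded class: count the minus strand
                comp_code_base = BASES.index(comp_b)
                folded = valid & (center == comp_code_base)
                out[base] += np.bincount(REVCOMP_QID[qid[folded]], minlength=256)
    return out


def snp_quartet_tally(records: list[SnpRecord]) -> np.ndarray:
    """Observed quartet counts O(q) over a homogeneous record set."""
    if not records:
        raise ValidationError("no records")
    classes = {r.canonical_class for r in records}
    compartments = {r.compartment for r in records}
    if len(classes) != 1 or len(compartments) != 1:
        raise ValidationError("records must share canonical class and compartment")
    counts = np.zeros(256, dtype=np.int64)
    for rec in records:
        q = rec.quartet()
        assert len(q) == 4, "records with short flanks must be excluded upstream"
        counts[quartet_id(q)] += 1
    return counts


@dataclass
class QuartetTable:
    """256-row observed/expected table with per-center-base test results."""

    canonical_class: str
    compartment: str
    table: pd.DataFrame
    alpha: float
    alpha_adjusted: float
    n_snps: int

    def verdicts(self, verdict: str) -> list[str]:
        sub = self.table[self.table["verdict"] == verdict]
        return list(sub["quartet"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _vector_yates(o: np.ndarray, n: int, g: np.ndarray, t: int):
    """Vectorised Yates 2x2 over 256 quartets: [[O, n-O], [G, T-G]]."""
    obs = np.stack([o, n - o, g, t - g], axis=1).astype(float)
    rows1 = float(n)
    rows2 = float(t)
    cols1 = o + g
    cols2 = (n - o) + (t - g)
    total = float(n + t)
    e = np.stack(
        [rows1 * cols1, rows1 * cols2, rows2 * cols1, rows2 * cols2], axis=1
    ) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.clip(np.abs(obs - e) - 0.5, 0.0, None)
        chi2 = np.where((e > 0).all(axis=1), np.nansum(diff**2 / e, axis=1), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    ok = (e >= 5).all(axis=1)
    testable = np.isfinite(chi2)
    return chi2, p, ok, testable


def classify_quartets(
    observed: np.ndarray,
    genome_counts: dict[str, np.ndarray],
    n_snps: int,
    canonical_class: str,
    compartment: str,
    alpha: float = 0.05,
) -> QuartetTable:
    """Classify all 256 quartets as permissive / shielded / neutral / untestable.

    ``observed`` is the SNP quartet tally; ``genome_counts`` the per-center
    base genomic tallies.  For each quartet and each center base, the 2x2
    table {SNPs with q, SNPs without q} x {genome base positions with q,
    without q} is tested at the Bonferroni-adjusted level ``alpha/256``.
    Permissive requires both tests significant with observed fraction above
    the genomic fraction for both bases; shielded is the symmetric
    depletion call.  Rows with any expected cell below 5 are untestable.
    Testable rows are ranked by descending O/E (ties broken by quartet
    string).
    """
    if n_snps <= 0:
        raise ValidationError("n_snps must be positive")
    b1, b2 = _class_center_bases(canonical_class)
    g1, g2 = genome_counts[b1], genome_counts[b2]
    t1, t2 = int(g1.sum()), int(g2.sum())
    if t1 == 0 or t2 == 0:
        raise ValidationError("empty genome tally for one center base")
    alpha_adj = alpha / 256.0
    chi2_1, p1, ok1, test1 = _vector_yates(observed, n_snps, g1, t1)
    chi2_2, p2, ok2, test2 = _vector_yates(observed, n_snps, g2, t2)
    obs_frac = observed / n_snps
    frac1 = g1 / t1
    frac2 = g2 / t2
    expected = n_snps * (g1 + g2) / (t1 + t2)

    sig1 = test1 & (p1 < alpha_adj)
    sig2 = test2 & (p2 < alpha_adj)
    above = (obs_frac > frac1) & (obs_frac > frac2)
    below = (obs_frac < frac1) & (obs_frac < frac2)
    untestable = ~(ok1 & ok2 & test1 & test2)
    verdict = np.full(256, NEUTRAL, dtype=object)
    verdict[sig1 & sig2 & above] = PERMISSIVE
    verdict[sig1 & sig2 & below] = SHIELDED
    verdict[untestable] = UNTESTABLE

    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, observed / expected, np.nan)
    quartet_names = [quartet_str(i) for i in range(256)]
    table = pd.DataFrame(
        {
            "class": canonical_class,
            "compartment": compartment,
            "quartet": [format_quartet(q) for q in quartet_names],
            "O": observed,
            "E": expected,
            f"G_{b1}": g1,
            f"G_{b2}": g2,
            f"chi2_{b1}": chi2_1,
            f"p_{b1}": p1,
            f"chi2_{b2}": chi2_2,
            f"p_{b2}": p2,
            "o_over_e": oe,
            "verdict": verdict,
        }
    )
    testable_mask = verdict != UNTESTABLE
    ranked = table[testable_mask].sort_values(
        by=["o_over_e", "quartet"], ascending=[False, True], kind="mergesort"
    )
    table["rank"] = pd.Series(
        np.arange(1, len(ranked) + 1), index=ranked.index, dtype="Int64"
    )
    return QuartetTable(
        canonical_class=canonical_class,
        compartment=compartment,
        table=table,
        alpha=alpha,
        alpha_adjusted=alpha_adj,
        n_snps=n_snps,
    )


def orf_quartet_scan(
    cds_sequence: str,
    permissive_set: set[str],
    shielding_set: set[str],
) -> dict[str, TestResult]:
    """Over-/underrepresentation of quartet sets among the 4-mers of an ORF.

    Counts occurrences of each set's quartets among all overlapping 4-mers
    (len - 3 windows) and compares the total against the expectation from
    the ORF's own mononucleotide composition with a Yates-corrected 1-df
    goodness-of-fit chi-square.  Results carry a ``direction`` attribute
    ('over' / 'under').
    """
    cds = cds_sequence.upper()
    if len(cds) < 4:
        raise ValidationError("cds must be at least 4 bases")
    permissive = {q.replace("|", "") for q in permissive_set}
    shielding = {q.replace("|", "") for q in shielding_set}
    if permissive & shielding:
        raise ValidationError("permissive and shielding sets must be disjoint")
    codes = encode(cds)
    freqs = np.bincount(codes[codes < 4], minlength=4) / max((codes < 4).sum(), 1)
    n_windows = len(cds) - 3
    valid = (
        (codes[:-3] < 4) & (codes[1:-2] < 4) & (codes[2:-1] < 4) & (codes[3:] < 4)
    )
    qids = codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
    window_counts = np.bincount(qids[valid].astype(np.int64), minlength=256)

    def _one(qset: set[str]) -> TestResult:
        observed = int(sum(window_counts[quartet_id(q)] for q in qset))
        p_set = float(
            sum(np.prod([freqs[BASES.index(c)] for c in q]) for q in qset)
        )
        expected = n_windows * p_set
        o = np.array([observed, n_windows - observed], dtype=float)
        e = np.array([expected, n_windows - expected], dtype=float)
        if expected <= 0 or expected >= n_windows:
            return TestResult(
                float("nan"), float("nan"), expected_cells_ok=False, testable=False,
                observed=observed, expected=expected,
            )
        diff = np.clip(np.abs(o - e) - 0.5, 0.0, None)
        chi2 = float((diff**2 / e).sum())
        return TestResult(
            chi2=chi2,
            p_value=float(stats.chi2.sf(chi2, df=1)),
            expected_cells_ok=bool((e >= 5).all()),
            observed=observed,
            expected=expected,
            direction="over" if observed > expected else "under",
        )

    return {"permissive": _one(permissive), "shielding": _one(shielding)}
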