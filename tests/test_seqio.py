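import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpcontext.seqio import (
    ContextUnavailable,
    FormatError,
    Genome,
    SiteCall,
    ValidationError,
    extract_context,
    filter_sites,
    read_genome,
    read_panel,
    read_records,
    write_records,
)
from snpcontext.util import revcomp


def _call(contig="c1", pos=55, ref="C", alt="T", depth=35, q=99.0, genotypes=None):
    return SiteCall(
        contig=contig,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=genotypes or {},
        depth=depth,
        snp_quality=q,
        map_quality=q,
        consensus_quality=q,
    )


# ---------------------------------------------------------------------------
# genome reading


def test_read_genome_uppercases_and_labels(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">c1\nacgt\n")
    bed = tmp_path / "g.bed"
    bed.write_text("c1\t0\t4\texonic\n")
    genome = read_genome(fasta, bed)
    assert genome.contigs["c1"] == "ACGT"
    assert all(genome.label_at("c1", i) == "exonic" for i in range(4))


def test_bed_interval_beyond_contig_rejected(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">c1\nacgt\n")
    bed = tmp_path / "g.bed"
    bed.write_text("c1\t0\t10\texonic\n")
    with pytest.raises(ValidationError, match="bounds"):
        read_genome(fasta, bed)


def test_conflicting_compartment_labels_rejected():
    with pytest.raises(ValidationError, match="conflicting"):
        Genome(
            contigs={"c1": "ACGTACGT"},
            compartments=[("c1", 0, 4, "exonic"), ("c1", 2, 6, "intronic")],
        )


def test_same_label_overlap_is_merged():
    genome = Genome(
        contigs={"c1": "ACGTACGT"},
        compartments=[("c1", 0, 4, "exonic"), ("c1", 2, 6, "exonic")],
    )
    assert [genome.label_at("c1", i) for i in range(8)] == ["exonic"] * 6 + ["unannotated"] * 2


def test_malformed_fasta_names_line(tmp_path):
    bad = tmp_path / "bad.fa"
    bad.write_text("ACGT\n>c1\nACGT\n")
    with pytest.raises(FormatError, match="line 1"):
        read_genome(bad)


def test_bad_bed_label_names_line(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">c1\nacgtacgt\n")
    bed = tmp_path / "g.bed"
    bed.write_text("c1\t0\t4\texonic\nc1\t4\t8\tpromoter\n")
    with pytest.raises(FormatError, match="line 2"):
        read_genome(fasta, bed)


# ---------------------------------------------------------------------------
# panel reading

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=c1,length=1000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="d">
##INFO=<ID=SQ,Number=1,Type=Float,Description="s">
##INFO=<ID=MQ,Number=1,Type=Float,Description="m">
##INFO=<ID=CQ,Number=1,Type=Float,Description="c">
##FORMAT=<ID=GT,Number=1,Type=String,Description="g">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
"""


def _write_vcf(tmp_path, body):
    path = tmp_path / "p.vcf"
    path.write_text(VCF_HEADER + body)
    return path


def test_read_panel_genotypes_positions_and_skips(tmp_path):
    body = (
        "c1\t100\t.\tC\tT\t.\tPASS\tDP=35;SQ=60;MQ=60;CQ=60\tGT\t1/1\t1/1\t0/0\t./.\n"
        "c1\t200\t.\tAT\tA\t.\tPASS\tDP=35;SQ=60;MQ=60;CQ=60\tGT\t0/0\t0/0\t0/0\t0/0\n"
        "c1\t300\t.\tA\tG,C\t.\tPASS\tDP=35;SQ=60;MQ=60;CQ=60\tGT\t0/0\t0/0\t0/0\t0/1\n"
        "c1\t400\t.\tA\tG\t.\tPASS\tDP=31;SQ=61;MQ=62;CQ=63\tGT\t0/1\t0/0\t0/0\t0/0\n"
    )
    from collections import Counter

    skips = Counter()
    calls = read_panel(_write_vcf(tmp_path, body), ["s1", "s2", "s3", "s4"], skip_counter=skips)
    assert len(calls) == 2
    assert skips == {"indel": 1, "multiallelic": 1}
    first = calls[0]
    assert first.pos == 99  # 1-based VCF -> 0-based internal
    assert first.genotypes == {"s1": "hom_alt", "s2": "hom_alt", "s3": "hom_ref", "s4": "missing"}
    assert calls[1].genotypes["s1"] == "het"
    assert (calls[1].depth, calls[1].snp_quality) == (31, 61.0)


def test_read_panel_missing_strain_errors(tmp_path):
    body = "c1\t100\t.\tC\tT\t.\tPASS\tDP=35;SQ=60;MQ=60;CQ=60\tGT\t1/1\t1/1\t0/0\t0/0\n"
    with pytest.raises(ValidationError, match="s9"):
        read_panel(_write_vcf(tmp_path, body), ["s1", "s9"])


# ---------------------------------------------------------------------------
# filtering


def _panel_genome(length=200):
    seq = ("ACGT" * 64)[:length]
    return Genome(contigs={"c1": seq}, compartments=[("c1", 0, length // 2, "intronic"),
                                                     ("c1", length // 2, length, "exonic")])


def _genotypes(n_minor_hom, n_total=17, het=0):
    g = {}
    for i in range(n_total):
        if i < n_minor_hom:
            g[f"s{i}"] = "hom_alt"
        elif i < n_minor_hom + het:
            g[f"s{i}"] = "het"
        else:
            g[f"s{i}"] = "hom_ref"
    return g


def test_depth_threshold_is_thirty():
    genome = _panel_genome()
    passing = _call(pos=10, depth=30, genotypes=_genotypes(4))
    failing = _call(pos=14, depth=29, genotypes=_genotypes(4))
    homs, _ = filter_sites([passing, failing], genome, "intronic")
    assert [h.pos for h in homs] == [10]


def test_minor_hom_strain_rule_noncoding_vs_exonic():
    genome = _panel_genome()
    three = _call(pos=10, genotypes=_genotypes(3))
    four = _call(pos=14, genotypes=_genotypes(4))
    homs, _ = filter_sites([three, four], genome, "intronic")
    assert [h.pos for h in homs] == [14]
    # exonic compartment only needs 2 homozygous minor strains
    two_exonic = _call(pos=110, depth=30, genotypes=_genotypes(2))
    homs, _ = filter_sites([two_exonic], genome, "exonic")
    assert [h.pos for h in homs] == [110]


def test_phred_threshold_and_heterosites():
    genome = _panel_genome()
    low_q = _call(pos=10, q=59.9, genotypes=_genotypes(4, het=1))
    good = _call(pos=14, q=60.0, genotypes=_genotypes(1, het=2))
    homs, hets = filter_sites([low_q, good], genome, "intronic")
    assert homs == []  # low quality excluded; `good` has only 1 minor hom
    assert [h.pos for h in hets] == [14]


def test_unknown_compartment_rejected():
    with pytest.raises(ValidationError):
        filter_sites([], _panel_genome(), "telomeric")


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    depth=st.integers(25, 35),
    q=st.floats(55, 65),
    n_minor=st.integers(0, 6),
    d_up=st.integers(0, 5),
    q_up=st.floats(0, 5),
    m_up=st.integers(0, 3),
)
def test_filter_monotone_in_thresholds(depth, q, n_minor, d_up, q_up, m_up):
    """Raising any threshold never adds a retained site."""
    genome = _panel_genome()
    calls = [_call(pos=10, depth=depth, q=q, genotypes=_genotypes(n_minor, het=1))]
    base_h, base_t = filter_sites(calls, genome, "intronic")
    strict_h, strict_t = filter_sites(
        calls, genome, "intronic",
        min_depth=30 + d_up, min_phred=60 + q_up, min_minor_hom=4 + m_up,
    )
    assert set(c.pos for c in strict_h) <= set(c.pos for c in base_h)
    assert set(c.pos for c in strict_t) <= set(c.pos for c in base_t)


# ---------------------------------------------------------------------------
# context extraction and folding


def _context_genome(center_five, flank=50):
    """Genome whose positions flank..flank+4 spell ``center_five``."""
    left = ("TGCA" * 25)[:flank - 2]
    right = ("GACT" * 25)[: flank - 2]
    seq = left + center_five + right
    return Genome(contigs={"c1": seq}, compartments=[("c1", 0, len(seq), "intergenic")]), flank


def test_ct_class_is_folded_to_ag_with_revcomp_flanks():
    # 5'-AG[C/T]CA-3' must fold to A<->G with flank5 ...TG and flank3 CT...
    genome, flank = _context_genome("AGCCA")
    site = _call(pos=flank, ref="C", alt="T", genotypes={})
    rec = extract_context(genome, site, flank=4)
    assert (rec.snp_class, rec.canonical_class) == ("CT", "AG")
    assert rec.flank5.endswith("TG")
    assert rec.flank3.startswith("CT")
    # folded flanks are the reverse complement of the plus-strand ones
    seq = genome.contigs["c1"]
    assert rec.flank5 == revcomp(seq[flank + 1 : flank + 5])
    assert rec.flank3 == revcomp(seq[flank - 4 : flank])


def test_ag_class_left_unfolded():
    genome, flank = _context_genome("AGACA")
    site = _call(pos=flank, ref="A", alt="G", genotypes={})
    rec = extract_context(genome, site, flank=4)
    seq = genome.contigs["c1"]
    assert rec.canonical_class == "AG"
    assert rec.flank5 == seq[flank - 4 : flank]
    assert rec.flank3 == seq[flank + 1 : flank + 5]


def test_context_unavailable_near_contig_end():
    genome = Genome(contigs={"c1": "ACGT" * 18}, compartments=[])  # 72 bp
    site = _call(pos=10, ref="G", alt="A", genotypes={})
    with pytest.raises(ContextUnavailable, match="truncated"):
        extract_context(genome, site)


def test_context_unavailable_on_N():
    genome, flank = _context_genome("AGNCA")
    site = _call(pos=flank + 3, ref="A", alt="G", genotypes={})
    with pytest.raises(ContextUnavailable, match="N"):
        extract_context(genome, site, flank=5)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_folding_is_strand_involution(seed):
    """The same molecule viewed from the other strand yields the identical
    folded record for foldable classes."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=30))
    pos = 15
    ref = seq[pos]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    genome = Genome(contigs={"c1": seq}, compartments=[])
    rec = extract_context(genome, _call(pos=pos, ref=ref, alt=alt, genotypes={}), flank=6)

    flipped = Genome(contigs={"c1": revcomp(seq)}, compartments=[])
    site2 = _call(
        pos=len(seq) - 1 - pos, ref=revcomp(ref), alt=revcomp(alt), genotypes={}
    )
    rec2 = extract_context(flipped, site2, flank=6)
    assert rec2.canonical_class == rec.canonical_class
    if rec.canonical_class not in ("AT", "CG"):  # self-complementary never folds
        assert (rec2.flank5, rec2.flank3) == (rec.flank5, rec.flank3)


def test_records_tsv_round_trip(tmp_path, null_ag_panel):
    _, _, records = null_ag_panel
    subset = records[:25]
    path = tmp_path / "records.tsv"
    write_records(subset, path)
    assert read_records(path) == subset
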