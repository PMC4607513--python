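import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from snpcontext.quartets import (
    classify_quartets,
    genome_quartet_tally,
    orf_quartet_scan,
    snp_quartet_tally,
    yates_chi2_2x2,
)
from snpcontext.seqio import Genome, SnpRecord, ValidationError
from snpcontext.util import format_quartet, quartet_id, quartet_str

from conftest import null_simulation
from oracles import brute_genome_quartet_tally


def _labels(genome, contig):
    return [genome.label_at(contig, i) for i in range(len(genome.contigs[contig]))]


# ---------------------------------------------------------------------------
# Yates chi-square


def test_yates_chi2_frozen_example():
    res = yates_chi2_2x2(20, 80, 10, 90)
    assert res.chi2 == pytest.approx(3.1765, abs=1e-3)
    assert res.p_value == pytest.approx(0.0747, abs=1e-3)
    assert res.expected_cells_ok


def test_yates_chi2_zero_when_observed_equals_expected():
    res = yates_chi2_2x2(10, 10, 10, 10)
    assert res.chi2 == 0.0
    assert res.p_value == 1.0


def test_yates_chi2_small_expected_flagged():
    res = yates_chi2_2x2(2, 3, 1, 4)  # expected cells < 5
    assert not res.expected_cells_ok


def test_yates_chi2_zero_marginal_untestable():
    res = yates_chi2_2x2(0, 0, 5, 5)
    assert not res.testable


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    a=st.integers(0, 200), b=st.integers(0, 200), c=st.integers(0, 200), d=st.integers(0, 200)
)
def test_yates_chi2_matches_scipy(a, b, c, d):
    table = np.array([[a, b], [c, d]])
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        assert not yates_chi2_2x2(a, b, c, d).testable
        return
    expected = chi2_contingency(table, correction=True)
    res = yates_chi2_2x2(a, b, c, d)
    assert res.chi2 == pytest.approx(expected.statistic, rel=1e-9, abs=1e-12)
    assert res.p_value == pytest.approx(expected.pvalue, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# genome tallies


def test_tally_skips_truncated_windows():
    genome = Genome(contigs={"c1": "AACGT"}, compartments=[("c1", 0, 5, "intergenic")])
    tally = genome_quartet_tally(genome, "intergenic", "AG")
    # only position 2 (C, folded) has two flanking bases on each side
    assert tally["A"].sum() == 0
    assert tally["G"].sum() == 1


def test_tally_folds_pyrimidine_centers():
    genome = Genome(contigs={"c1": "CCACGTT"}, compartments=[("c1", 0, 7, "intergenic")])
    tally = genome_quartet_tally(genome, "intergenic", "AG")
    # center 2 = A: quartet CC|CG counted directly under A
    assert tally["A"][quartet_id("CCCG")] == 1
    # center 3 = C folds to G on the minus strand: revcomp(CA|GT) = AC|TG
    assert tally["G"][quartet_id("ACTG")] == 1
    # center 4 = G: quartet AC|TT counted directly under G
    assert tally["G"][quartet_id("ACTT")] == 1
    assert tally["A"].sum() + tally["G"].sum() == 3


@pytest.mark.parametrize("canonical", ["AG", "AC", "AT", "CG"])
def test_tally_matches_brute_force(canonical):
    rng = np.random.default_rng(17)
    seq = "".join(rng.choice(list("ACGTN"), size=1000, p=[0.27, 0.23, 0.23, 0.25, 0.02]))
    genome = Genome(
        contigs={"c1": seq},
        compartments=[("c1", 0, 600, "intronic"), ("c1", 600, 1000, "intergenic")],
    )
    b1, b2 = canonical[0], canonical[1]
    expected = brute_genome_quartet_tally(seq, _labels(genome, "c1"), "intronic", b1, b2)
    tally = genome_quartet_tally(genome, "intronic", canonical)
    for base in (b1, b2):
        got = {quartet_str(i): int(n) for i, n in enumerate(tally[base]) if n}
        assert got == expected[base]


# ---------------------------------------------------------------------------
# SNP tallies and classification


def _rec(flank5, flank3):
    return SnpRecord(
        contig="c1", pos=100, snp_class="AG", canonical_class="AG",
        compartment="intergenic", flank5=flank5, flank3=flank3,
        zygosity_kind="homosite", n_minor_strains=4,
    )


def test_snp_tally_reads_inner_flank_bases():
    records = [_rec("GGAC", "TGCC")] * 3 + [_rec("TTTT", "AAAA")]
    tally = snp_quartet_tally(records)
    assert tally[quartet_id("ACTG")] == 3
    assert tally[quartet_id("TTAA")] == 1
    assert tally.sum() == len(records)


def test_classify_alpha_bonferroni():
    genome, truth, records = null_simulation(seed=41, n_events=3000)
    observed = snp_quartet_tally(records)
    gtally = genome_quartet_tally(genome, "intergenic", "AG")
    table = classify_quartets(observed, gtally, len(records), "AG", "intergenic", alpha=0.05)
    assert table.alpha_adjusted == pytest.approx(0.05 / 256)
    # expected counts over testable rows sum to n
    t = table.table
    testable = t[t["verdict"] != "untestable"]
    assert t["O"].sum() == len(records)
    assert t["E"].sum() == pytest.approx(len(records), rel=1e-6)
    # ranks cover the testable rows and follow descending O/E
    ranked = testable.sort_values("rank")
    assert list(ranked["rank"]) == list(range(1, len(testable) + 1))
    assert (ranked["o_over_e"].diff().dropna() <= 1e-12).all()


def test_classify_small_sample_untestable():
    genome, truth, records = null_simulation(seed=43, n_events=260)
    observed = snp_quartet_tally(records)
    gtally = genome_quartet_tally(genome, "intergenic", "AG")
    table = classify_quartets(observed, gtally, len(records), "AG", "intergenic")
    # with ~200 SNPs over 256 quartets every SNP-side expected cell is < 5
    assert set(table.table["verdict"]) == {"untestable"}


def test_classify_matches_direct_2x2_assembly():
    """Verdicts agree with scipy tests on 2x2 tables assembled by direct
    counting, for every quartet."""
    genome, truth, records = null_simulation(
        seed=47, n_events=5000, multipliers={"CCTG": 6.0, "GGAA": 0.1}
    )
    observed = snp_quartet_tally(records)
    gtally = genome_quartet_tally(genome, "intergenic", "AG")
    n = len(records)
    table = classify_quartets(observed, gtally, n, "AG", "intergenic")
    alpha_adj = 0.05 / 256
    for qid in range(256):
        row = table.table.iloc[qid]
        assert row["quartet"] == format_quartet(quartet_str(qid))
        sides = {}
        for base in "AG":
            g = int(gtally[base][qid])
            t_total = int(gtally[base].sum())
            cont = np.array([[observed[qid], n - observed[qid]], [g, t_total - g]])
            if (cont.sum(axis=1) == 0).any() or (cont.sum(axis=0) == 0).any():
                sides[base] = None
                continue
            res = chi2_contingency(cont, correction=True)
            ok = (res.expected_freq >= 5).all()
            direction = observed[qid] / n - g / t_total
            sides[base] = (res.pvalue, ok, direction)
        if any(s is None or not s[1] for s in sides.values()):
            assert row["verdict"] == "untestable"
        else:
            both_sig = all(s[0] < alpha_adj for s in sides.values())
            if both_sig and all(s[2] > 0 for s in sides.values()):
                assert row["verdict"] == "permissive"
            elif both_sig and all(s[2] < 0 for s in sides.values()):
                assert row["verdict"] == "shielded"
            else:
                assert row["verdict"] == "neutral"


def test_planted_multiplier_ranks_first():
    genome, truth, records = null_simulation(seed=53, n_events=5000, multipliers={"CCTG": 10.0})
    observed = snp_quartet_tally(records)
    gtally = genome_quartet_tally(genome, "intergenic", "AG")
    table = classify_quartets(observed, gtally, len(records), "AG", "intergenic")
    assert table.verdicts("permissive") == ["CC|TG"]
    top = table.table.loc[table.table["rank"] == 1, "quartet"].item()
    assert top == "CC|TG"


def test_classify_requires_snps():
    gtally = {"A": np.ones(256, dtype=int), "G": np.ones(256, dtype=int)}
    with pytest.raises(ValidationError):
        classify_quartets(np.zeros(256, dtype=int), gtally, 0, "AG", "intergenic")


# ---------------------------------------------------------------------------
# ORF quartet scans


def test_orf_scan_extreme_shielding_construction():
    cds = "GGCC" * 60  # 240 bp of a single shielding quartet
    res = orf_quartet_scan(cds, permissive_set={"ACTG"}, shielding_set={"GGCC"})
    shielding = res["shielding"]
    assert shielding.direction == "over"
    assert shielding.p_value < 1e-5
    assert res["permissive"].observed == 0


def test_orf_scan_window_count():
    cds = "ACGTACGTACGT"
    res = orf_quartet_scan(cds, permissive_set={"AAAA"}, shielding_set={"CCCC"})
    # expectation computed over len - 3 overlapping windows
    assert res["permissive"].expected == pytest.approx((len(cds) - 3) * (0.25**4))


def test_orf_scan_rejects_overlapping_sets():
    with pytest.raises(ValidationError):
        orf_quartet_scan("ACGTACGT", {"ACTG"}, {"ACTG", "GGCC"})


def test_orf_scan_null_rarely_significant():
    rng = np.random.default_rng(59)
    hits = 0
    n_orfs = 40
    for _ in range(n_orfs):
        cds = "".join(rng.choice(list("ACGT"), size=999))
        quartets = ["".join(q) for q in rng.choice(list("ACGT"), size=(8, 4))]
        permissive, shielding = set(quartets[:4]), set(quartets[4:]) - set(quartets[:4])
        res = orf_quartet_scan(cds, permissive, shielding)
        hits += sum(1 for r in res.values() if r.testable and r.p_value < 0.001)
    assert hits <= int(0.05 * 2 * n_orfs)
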