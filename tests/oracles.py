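"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package internals: plain string
scans and whole-protein translation, used to cross-check the vectorised
quartet tallies, the Yates chi-square, and codon-level NS/S calls.
"""

from Bio.Seq import Seq

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def brute_genome_quartet_tally(seq: str, labels: list[str], compartment: str, b1: str, b2: str):
    """Window-by-window quartet tally with minus-strand folding.

    ``labels`` gives the compartment label of every position.  For a folded
    class (complement of a center base not itself in the class), positions
    carrying the complementary base are counted under the reverse-complement
    quartet.
    """
    out = {b1: {}, b2: {}}
    for i in range(2, len(seq) - 2):
        if labels[i] != compartment:
            continue
        window = seq[i - 2 : i + 3]
        if "N" in window:
            continue
        quartet = window[:2] + window[3:]
        center = window[2]
        for base in (b1, b2):
            if center == base:
                out[base][quartet] = out[base].get(quartet, 0) + 1
            elif COMPLEMENT[base] not in (b1, b2) and center == COMPLEMENT[base]:
                folded = rc(quartet)
                out[base][folded] = out[base].get(folded, 0) + 1
    return out


def brute_ns_s(cds: str, offset: int, alt_in_cds: str) -> str:
    """Translate the whole CDS before and after the substitution."""
    mutant = cds[:offset] + alt_in_cds + cds[offset + 1 :]
    ref_protein = str(Seq(cds).translate())
    alt_protein = str(Seq(mutant).translate())
    return "synonymous" if ref_protein == alt_protein else "nonsynonymous"


def brute_position_weight(seq: str, pos: int, multipliers: dict[str, float]) -> float:
    """Mutability weight at one position (purine-center folded quartet)."""
    if pos < 2 or pos + 3 > len(seq):
        return 0.0
    window = seq[pos - 2 : pos + 3]
    if "N" in window:
        return 0.0
    quartet = window[:2] + window[3:]
    if window[2] in "CT":
        quartet = rc(quartet)
    return multipliers.get(quartet, 1.0)
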