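"""Shared sequence-encoding helpers (base codes, strand folding, quartet ids)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_CODE_TABLE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: the six unordered SNP classes, written as the sorted pair of alleles
SNP_CLASSES = ("AC", "AG", "AT", "CG", "CT", "GT")

#: strand folding of reverse-complement class pairs: A<->G absorbs C<->T,
#: A<->C absorbs G<->T; A<->T and C<->G are self-complementary.
CANONICAL_CLASS = {"AC": "AC", "AG": "AG", "AT": "AT", "CG": "CG", "CT": "AG", "GT": "AC"}
CANONICAL_CLASSES = ("AC", "AG", "AT", "CG")
TRANSITION_CLASSES = frozenset({"AG", "CT"})

COMPARTMENTS = ("exonic", "intronic", "intergenic")
#: integer codes used in per-contig label arrays; 0 means unannotated
COMPARTMENT_CODE = {label: i + 1 for i, label in enumerate(COMPARTMENTS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes A=0, C=1, G=2, T=3, N/other=4."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def snp_class(ref: str, alt: str) -> str:
    """Unordered class of a substitution, e.g. ('G','A') -> 'AG'."""
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    return "".join(sorted((ref, alt)))


def is_transition(cls: str) -> bool:
    return cls in TRANSITION_CLASSES


# ---------------------------------------------------------------------------
# dinucleotide quartets: the 4 bases X1 X2 | X3 X4 flanking a focal position.
# Internally a quartet is a plain 4-letter string or an integer id in [0, 256).

def quartet_id(q: str) -> int:
    if len(q) != 4 or any(c not in BASES for c in q):
        raise ValueError(f"quartet must be 4 characters over ACGT, got {q!r}")
    i = 0
    for c in q:
        i = i * 4 + BASES.index(c)
    return i


def quartet_str(qid: int) -> str:
    out = []
    for shift in (6, 4, 2, 0):
        out.append(BASES[(qid >> shift) & 3])
    return "".join(out)


def format_quartet(q: str) -> str:
    """Display form 'X1X2|X3X4' with the focal position marked."""
    return f"{q[:2]}|{q[2:]}"


def parse_quartet(q: str) -> str:
    """Accept either 'ACTG' or 'AC|TG'; return the plain 4-letter form."""
    plain = q.replace("|", "").upper()
    if len(plain) != 4 or any(c not in BASES for c in plain):
        raise ValueError(f"quartet must be 4 bases over ACGT, got {q!r}")
    return plain


def revcomp_quartet(q: str) -> str:
    """Quartet seen from the opposite strand (flanks swap and complement)."""
    return revcomp(q)


def _build_revcomp_qid_table() -> np.ndarray:
    table = np.empty(256, dtype=np.int64)
    for qid in range(256):
        table[qid] = quartet_id(revcomp_quartet(quartet_str(qid)))
    return table


#: lookup table: id of the reverse-complement quartet for each quartet id
REVCOMP_QID = _build_revcomp_qid_table()
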