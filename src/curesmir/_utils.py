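"""Small shared helpers: alphabets, rounding, dot-bracket parsing, IUPAC codes."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")
_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

NUCLEOTIDES = set("ACGTU")


def to_rna(seq: str) -> str:
    """Uppercase and unify T -> U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and unify U -> T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement; alphabet (DNA vs RNA) inferred from the input."""
    s = seq.upper()
    table = _RNA_COMP if "U" in s and "T" not in s else _DNA_COMP
    return s.translate(table)[::-1]


def is_nucleotide(seq: str) -> bool:
    return bool(seq) and all(c in NUCLEOTIDES for c in seq.upper())


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed tables conventionally do.

    Python's builtin round() is banker's rounding; report columns here follow
    the half-up convention (1.496 -> 1.50, 27.414 -> 27.41).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# Watson-Crick partners in RNA space.
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_state(a: str, b: str) -> str:
    """Classify an antiparallel base opposition: 'match', 'wobble' or 'mismatch'.

    Both bases are read 5'->3' on their own strand (RNA space).
    """
    p = (a, b)
    if p in _WC:
        return "match"
    if p in _WOBBLE:
        return "wobble"
    return "mismatch"


def can_pair(a: str, b: str) -> bool:
    p = (a, b)
    return p in _WC or p in _WOBBLE


def pair_table(structure: str) -> list[int]:
    """1-based partner table for a dot-bracket string; 0 means unpaired.

    Returns a list of length len(structure)+1; index 0 is unused.
    """
    pt = [0] * (len(structure) + 1)
    stack: list[int] = []
    for i, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} in dot-bracket string")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(motif: str) -> str:
    return motif.upper().translate(_IUPAC_COMP)[::-1]


def iupac_matches(base: str, code: str) -> bool:
    try:
        return base.upper().replace("U", "T") in IUPAC_DNA[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None
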