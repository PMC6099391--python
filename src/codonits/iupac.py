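"""IUPAC nucleotide codes: base-set expansion, complements, reverse complement.

Only the codes that actually occur in direct-sequenced ITS reads of this
system (plain bases plus one- and two-base ambiguities, with N as the
catch-all) are given dedicated handling; three-base codes are still
expandable for robustness.
"""

from __future__ import annotations

CODE_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_SET.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

BASES = "ACGT"


def expand(code: str) -> frozenset[str]:
    """Base set denoted by a single IUPAC code."""
    try:
        return CODE_TO_SET[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(bases: frozenset[str] | set[str]) -> str:
    """IUPAC code for a non-empty set of plain bases."""
    key = frozenset(bases)
    try:
        return SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from None


def complement(code: str) -> str:
    try:
        return COMPLEMENT[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(complement(c) for c in reversed(seq))


def is_ambiguous(code: str) -> bool:
    return len(expand(code)) > 1
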