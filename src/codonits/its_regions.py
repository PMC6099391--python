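"""Contig assembly and motif-based ITS1 / 5.8S / ITS2 extraction.

The full ITS is delimited by its first five bases ("TCGAA") and its last
seven ("TCCGACC"); the internal 5.8S gene begins with "AAACGACTCT" and
ends with "CGTCACGC". ITS1 and ITS2 are the flanks of 5.8S within the
ITS. G+C content follows the convention that reproduces the published
per-type values: ambiguity codes count as neither G nor C.

Assembly of the two sequencing directions is exact-overlap based (the
simulator never emits indels): the reverse read is reverse-complemented,
slid against the forward read, and merged position-wise. A plain base
meeting its own IUPAC superset resolves to the superset; two disagreeing
plain bases are recorded as a conflict and resolved to their IUPAC union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .iupac import code_for, expand, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """A subsequence with 1-based inclusive coordinates on the ITS."""

    name: str
    sequence: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ITSRegions:
    """The three contiguous, non-overlapping ITS regions."""

    its1: Region
    s58: Region
    its2: Region

    def __post_init__(self):
        if self.its1.end + 1 != self.s58.start or self.s58.end + 1 != self.its2.start:
            raise ValueError("regions must be contiguous and non-overlapping")

    @property
    def its(self) -> str:
        return self.its1.sequence + self.s58.sequence + self.its2.sequence

    def lengths(self) -> tuple[int, int, int]:
        return len(self.its1), len(self.s58), len(self.its2)


@dataclass(frozen=True)
class ContigResult:
    """Consensus of a forward/reverse read pair plus recorded conflicts."""

    sequence: str
    conflicts: tuple[int, ...] = field(default_factory=tuple)
    offset: int = 0  # forward-read position at which the reverse read starts


def _compatible(a: str, b: str) -> bool:
    return bool(expand(a) & expand(b))


def assemble_contig(fwd_seq: str, rev_seq: str,
                    min_overlap: int = 50) -> ContigResult:
    """Merge a forward read with a reverse-strand read.

    ``rev_seq`` is given as read (it is reverse-complemented here). The
    relative placement maximizing the number of IUPAC-compatible
    overlapping positions is used; an assembly error is raised when no
    placement achieves an overlap of at least ``min_overlap``.
    """
    fwd = fwd_seq.upper()
    rc = reverse_complement(rev_seq.upper())
    nf, nr = len(fwd), len(rc)
    best: tuple[int, int, int] | None = None  # (score, -mismatches, offset)
    for offset in range(-(nr - min_overlap), nf - min_overlap + 1):
        lo = max(0, offset)
        hi = min(nf, offset + nr)
        if hi - lo < min_overlap:
            continue
        compat = sum(1 for i in range(lo, hi) if _compatible(fwd[i], rc[i - offset]))
        mismatch = (hi - lo) - compat
        # net score: a correct placement keeps almost every position
        # compatible, while a spurious one pays for each chance mismatch
        cand = (compat - mismatch, hi - lo, offset)
        if best is None or cand > best:
            best = cand
    if best is None:
        raise ValueError(f"assembly error: no placement with >= {min_overlap} nt "
                         "overlap")
    offset = best[2]
    lo, hi = max(0, offset), min(nf, offset + nr)
    out: list[str] = []
    conflicts: list[int] = []
    left = fwd[:lo] if lo > 0 else rc[:-offset] if offset < 0 else ""
    out.append(left)
    for i in range(lo, hi):
        a, b = fwd[i], rc[i - offset]
        sa, sb = expand(a), expand(b)
        if sa == sb:
            out.append(a)
        elif sa < sb:
            out.append(b)
        elif sb < sa:
            out.append(a)
        else:
            union = sa | sb
            code = code_for(union) if len(union) <= 2 else "N"
            conflicts.append(len("".join(out)) + 1)
            logger.warning("strand conflict at contig position %d: %s vs %s -> %s",
                           len("".join(out)) + 1, a, b, code)
            out.append(code)
    right = fwd[hi:] if hi == offset + nr else rc[hi - offset:]
    out.append(right)
    return ContigResult("".join(out), tuple(conflicts), offset)


def _find_once(seq: str, motif: str, label: str) -> int:
    """0-based index of a motif required to occur exactly once."""
    first = seq.find(motif)
    if first < 0:
        raise ValueError(f"{label} motif {motif!r} not found")
    if seq.find(motif, first + 1) >= 0:
        raise ValueError(f"{label} motif {motif!r} occurs more than once")
    return first


def extract_regions(seq: str,
                    start_motif: str = "TCGAA",
                    end_motif: str = "TCCGACC",
                    s58_start_motif: str = "AAACGACTCT",
                    s58_end_motif: str = "CGTCACGC") -> ITSRegions:
    """Delimit ITS1 / 5.8S / ITS2 by the four boundary motifs.

    Coordinates in the result are 1-based relative to the first base of the
    ITS start motif, making the published site numbers directly
    addressable.
    """
    seq = seq.upper()
    i_start = _find_once(seq, start_motif, "ITS start")
    i_end = _find_once(seq, end_motif, "ITS end") + len(end_motif)  # exclusive
    i_s58 = _find_once(seq, s58_start_motif, "5.8S start")
    i_s58_end = _find_once(seq, s58_end_motif, "5.8S end") + len(s58_end_motif)
    if not i_start < i_s58 < i_s58_end <= i_end:
        raise ValueError("boundary motifs out of order: expected ITS start < "
                         "5.8S start < 5.8S end <= ITS end")
    its = seq[i_start:i_end]
    a = i_s58 - i_start          # 0-based 5.8S start within ITS
    b = i_s58_end - i_start      # exclusive 5.8S end within ITS
    return ITSRegions(
        its1=Region("ITS1", its[:a], 1, a),
        s58=Region("5.8S", its[a:b], a + 1, b),
        its2=Region("ITS2", its[b:], b + 1, len(its)),
    )


def gc_content(seq: str) -> float:
    """Percent G+C, ambiguity codes excluded from the numerator; 2 decimals."""
    if not seq:
        raise ValueError("empty sequence")
    for c in seq.upper():
        expand(c)  # validates the alphabet
    gc = sum(1 for c in seq.upper() if c in "GC")
    return round(100.0 * gc / len(seq), 2)
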