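"""ITS-type registry, variable-site genotyping, and parental-lineage inference.

The cultivated *Codonopsis* ITS haplotypes differ at four aligned positions
(122, 135, 226, 500 on the 655-nt ITS). Four homozygous pure lines anchor
the system — P0 (*C. pilosula*), PM0 (*C. pilosula* var. *modesta*),
T0 (*C. tangshen*) and S0 (an unidentified *Codonopsis*) — and each
cultivated specimen carries a named ITS type: a genotype over the four
sites, where a heterozygous site is an additive nucleotide written with an
IUPAC code (Y = C+T, R = A+G) plus the major/minor peak orientation
(e.g. Y (T > C) means both bases present, T the taller peak).

A hybrid type is explained by a cross if, at every site, one allele can be
drawn from each parent so that the drawn pair equals the target's base
composition. Peak orientation is deliberately ignored for feasibility —
which repeat type dominates an rDNA array is not predicted by a cross —
and is used only for type labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement

import pandas as pd

from .iupac import code_for, expand, is_ambiguous

logger = logging.getLogger(__name__)

#: the four aligned variable positions, 1-based on the ITS
VARIABLE_SITES: tuple[int, ...] = (122, 135, 226, 500)

SPECIES_PILOSULA = "C. pilosula"
SPECIES_MODESTA = "C. pilosula var. modesta"
SPECIES_TANGSHEN = "C. tangshen"
SPECIES_UNIDENTIFIED = "unidentified"


@dataclass(frozen=True)
class SiteGenotype:
    """Base composition at one position, optionally with peak orientation.

    ``major`` is the base under the taller peak when the site is
    heterozygous and the orientation is known (from trace data or a type
    definition); None otherwise.
    """

    position: int
    composition: frozenset[str]
    major: str | None = None

    def __post_init__(self):
        if not 1 <= len(self.composition) <= 2:
            raise ValueError("composition must contain 1 or 2 plain bases")
        if any(b not in "ACGT" for b in self.composition):
            raise ValueError(f"composition must be plain bases, "
                             f"got {sorted(self.composition)}")
        if self.major is not None:
            if len(self.composition) == 1:
                object.__setattr__(self, "major", None)
            elif self.major not in self.composition:
                raise ValueError("major base must belong to the composition")

    @property
    def iupac(self) -> str:
        return code_for(self.composition)

    @property
    def heterozygous(self) -> bool:
        return len(self.composition) == 2

    @property
    def minor(self) -> str | None:
        if not self.heterozygous or self.major is None:
            return None
        (other,) = self.composition - {self.major}
        return other

    def __str__(self) -> str:
        if self.heterozygous and self.major is not None:
            return f"{self.iupac}({self.major}>{self.minor})"
        return self.iupac


def parse_genotype(position: int, text: str) -> SiteGenotype:
    """Parse 'C', 'Y', or 'Y:T>C' into a SiteGenotype."""
    text = text.strip()
    if ":" in text:
        code, orient = text.split(":")
        major, minor = orient.split(">")
        comp = frozenset({major, minor})
        if comp != expand(code):
            raise ValueError(f"orientation {orient!r} inconsistent with {code!r}")
        return SiteGenotype(position, comp, major=major)
    return SiteGenotype(position, expand(text))


@dataclass(frozen=True)
class ITSTypeDef:
    """One named ITS type: species context, four-site genotype, metadata."""

    label: str
    species_context: str
    genotypes: dict[int, SiteGenotype]
    gc_percent: float
    specimen_count: int | None = None
    accession: str | None = None
    parents_text: str | None = None

    @property
    def is_pure_line(self) -> bool:
        return all(not g.heterozygous for g in self.genotypes.values())

    @property
    def heterozygous(self) -> bool:
        return any(g.heterozygous for g in self.genotypes.values())

    def allele_sets(self) -> dict[int, frozenset[str]]:
        return {p: g.composition for p, g in self.genotypes.items()}


def _load_type_defs() -> dict[str, ITSTypeDef]:
    path = resources.files("codonits.data") / "its_types.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    defs: dict[str, ITSTypeDef] = {}
    for row in df.itertuples(index=False):
        genotypes = {pos: parse_genotype(pos, getattr(row, f"g{pos}"))
                     for pos in VARIABLE_SITES}
        count = row.n_specimens
        defs[row.label] = ITSTypeDef(
            label=row.label,
            species_context=row.species_context,
            genotypes=genotypes,
            gc_percent=float(row.gc_percent),
            specimen_count=int(count) if isinstance(count, str) and count else None,
            accession=row.accession if isinstance(row.accession, str) else None,
            parents_text=row.parents if isinstance(row.parents, str) else None,
        )
    return defs


#: all thirteen named types (nine cultivar types + four pure lines)
TYPE_DEFS: dict[str, ITSTypeDef] = _load_type_defs()

#: the four homozygous reference haplotypes
PURE_LINES: dict[str, ITSTypeDef] = {
    k: v for k, v in TYPE_DEFS.items() if k in ("P0", "PM0", "T0", "S0")
}

#: the nine heterozygous cultivar types
CULTIVAR_TYPES: dict[str, ITSTypeDef] = {
    k: v for k, v in TYPE_DEFS.items() if k not in PURE_LINES
}


# ---------------------------------------------------------------------------
# Genotyping and type assignment
# ---------------------------------------------------------------------------

def genotype_variable_sites(seq: str,
                            positions: tuple[int, ...] = VARIABLE_SITES,
                            majors: dict[int, str] | None = None,
                            ) -> list[SiteGenotype]:
    """Read the genotype at each canonical variable site of ``seq``.

    Ambiguity codes anywhere else in the sequence are reported too. Peak
    orientation cannot be recovered from a plain sequence; pass ``majors``
    (position -> taller-peak base, e.g. taken from trace channel heights)
    to set it.
    """
    majors = majors or {}
    sites = sorted(set(positions) |
                   {i + 1 for i, c in enumerate(seq) if is_ambiguous(c)})
    out = []
    for pos in sites:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
        comp = expand(seq[pos - 1])  # raises on non-IUPAC characters
        if len(comp) > 2:
            raise ValueError(f"more than two bases at position {pos}: "
                             f"{seq[pos - 1]!r}")
        out.append(SiteGenotype(pos, comp, major=majors.get(pos)))
    return out


def assign_type(species_context: str,
                genotypes: list[SiteGenotype] | dict[int, SiteGenotype]) -> str:
    """Match a four-site genotype (plus species context) to a named ITS type.

    Orientation is compared only where both the query and the definition
    know it. Returns ``"novel"`` when nothing matches; raises when the
    query is ambiguous between several types (e.g. Y/Y without orientation
    in *C. pilosula*, which could be P1, P3 or P4).
    """
    if not isinstance(genotypes, dict):
        genotypes = {g.position: g for g in genotypes}
    missing = [p for p in VARIABLE_SITES if p not in genotypes]
    if missing:
        raise ValueError(f"genotypes must cover positions {missing}")
    candidates = []
    for tdef in TYPE_DEFS.values():
        if tdef.species_context != species_context:
            continue
        ok = True
        for pos in VARIABLE_SITES:
            q, d = genotypes[pos], tdef.genotypes[pos]
            if q.composition != d.composition:
                ok = False
                break
            if (q.major is not None and d.major is not None
                    and q.major != d.major):
                ok = False
                break
        if ok:
            candidates.append(tdef.label)
    if not candidates:
        logger.warning("no ITS type matches genotype %s in context %r",
                       {p: str(g) for p, g in genotypes.items()}, species_context)
        return "novel"
    if len(candidates) > 1:
        raise ValueError(
            f"genotype matches several types {candidates}; peak orientation "
            "(major base) is needed to disambiguate")
    return candidates[0]


def census_heterozygosity(panel: pd.DataFrame,
                          type_column: str = "its_type") -> dict:
    """Count heterozygous vs pure-line specimens, per species and total.

    A specimen is heterozygous when its assigned ITS type carries at least
    one additive (two-base) genotype.
    """
    het_by_species: dict[str, int] = {}
    total_by_species: dict[str, int] = {}
    for row in panel.itertuples(index=False):
        label = getattr(row, type_column)
        tdef = TYPE_DEFS.get(label)
        if tdef is None:
            raise KeyError(f"unknown ITS type {label!r} in panel")
        total_by_species[row.species] = total_by_species.get(row.species, 0) + 1
        if tdef.heterozygous:
            het_by_species[row.species] = het_by_species.get(row.species, 0) + 1
    total = int(len(panel))
    het = sum(het_by_species.values())
    return {
        "total": total,
        "heterozygous": het,
        "pure": total - het,
        "heterozygous_by_species": het_by_species,
        "total_by_species": total_by_species,
    }


def genotypes_from_trace_replicates(pairs,
                                    positions: tuple[int, ...] = VARIABLE_SITES,
                                    alpha: float | None = None,
                                    direct_threshold: float | None = None,
                                    min_secondary: float | None = None,
                                    ) -> tuple[dict[int, SiteGenotype], dict]:
    """Call genotypes from replicate forward/reverse trace pairs.

    The full decision path of the method: a position is a candidate when
    its secondary peak clears the screen on both strands in any replicate;
    candidates are then confirmed (or not) by the replicate S-vs-N
    analysis on the forward strand. Confirmed sites become heterozygous
    genotypes whose major base is the called (taller-peak) base; every
    other requested position is called homozygous.

    Returns (position -> SiteGenotype, position -> AdditivityDecision).
    """
    from . import additivity
    from .chromatogram import extract_peaks, n_value, s_value

    alpha = additivity.DEFAULT_ALPHA if alpha is None else alpha
    direct_threshold = (additivity.DEFAULT_DIRECT_THRESHOLD
                        if direct_threshold is None else direct_threshold)
    min_secondary = (additivity.DEFAULT_MIN_SECONDARY
                     if min_secondary is None else min_secondary)
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one trace pair")
    candidates: set[int] = set()
    for fwd, rev in pairs:
        candidates.update(
            additivity.detect_candidate_sites(fwd, rev, min_secondary))
    decisions: dict[int, "additivity.AdditivityDecision"] = {}
    genotypes: dict[int, SiteGenotype] = {}
    calls = pairs[0][0].calls
    for pos in sorted(set(positions) | candidates):
        called = calls[pos - 1]
        if pos in candidates:
            triplets = [extract_peaks(fwd, pos) for fwd, _ in pairs]
            decision = additivity.decide_additivity(
                [s_value(t) for t in triplets],
                [n_value(t) for t in triplets],
                alpha=alpha, direct_threshold=direct_threshold, site=pos)
            decisions[pos] = decision
            if decision.confirmed:
                # modal secondary-channel base across replicates
                seconds = []
                for fwd, _ in pairs:
                    ch = fwd.channels[pos - 1]
                    order = sorted(range(4), key=lambda k: ch[k], reverse=True)
                    seconds.append("ACGT"[order[1]])
                minor = max(set(seconds), key=seconds.count)
                genotypes[pos] = SiteGenotype(
                    pos, frozenset({called, minor}), major=called)
                continue
        if pos in set(positions):
            genotypes[pos] = SiteGenotype(pos, frozenset({called}))
    return genotypes, decisions


# ---------------------------------------------------------------------------
# Cross feasibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossHypothesis:
    """An unordered candidate parent pair for a target ITS type."""

    parent_a: str
    parent_b: str
    feasible: bool
    explanation: dict[int, tuple[str, str]] = field(default_factory=dict)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.parent_a, self.parent_b})

    def __str__(self) -> str:
        verdict = "feasible" if self.feasible else "infeasible"
        return f"{self.parent_a} x {self.parent_b} ({verdict})"


def cross_feasible(parent_a: ITSTypeDef, parent_b: ITSTypeDef,
                   target: ITSTypeDef) -> CrossHypothesis:
    """Can one allele from each parent reproduce the target at every site?

    Parents may themselves be heterozygous (each contributes one base per
    site from its composition). Orientation never enters.
    """
    witness: dict[int, tuple[str, str]] = {}
    feasible = True
    for pos in VARIABLE_SITES:
        want = target.genotypes[pos].composition
        ca = parent_a.genotypes[pos].composition
        cb = parent_b.genotypes[pos].composition
        found = None
        for ga in sorted(ca):
            for gb in sorted(cb):
                if frozenset({ga, gb}) == want:
                    found = (ga, gb)
                    break
            if found:
                break
        if found is None:
            feasible = False
            break
        witness[pos] = found
    return CrossHypothesis(parent_a.label, parent_b.label, feasible,
                           witness if feasible else {})


def infer_single_cross(target: ITSTypeDef,
                       lines: dict[str, ITSTypeDef] | None = None,
                       ) -> set[frozenset[str]]:
    """All unordered pure-line pairs (self-pairs included) explaining ``target``."""
    lines = lines if lines is not None else PURE_LINES
    for line in lines.values():
        if not line.is_pure_line:
            raise ValueError(f"{line.label} is not homozygous at all sites")
    out: set[frozenset[str]] = set()
    for a, b in combinations_with_replacement(sorted(lines), 2):
        hyp = cross_feasible(lines[a], lines[b], target)
        if hyp.feasible:
            out.add(frozenset({a, b}))
    return out


def enumerate_two_step(target: ITSTypeDef,
                       lines: dict[str, ITSTypeDef] | None = None,
                       intermediates: dict[str, ITSTypeDef] | None = None,
                       ) -> list[tuple[frozenset[str], str, str]]:
    """Two-generation chains line x line -> intermediate, intermediate x line -> target.

    Returns deduplicated ``(first_cross_pair, intermediate_label,
    second_parent_label)`` triples. A target with no heterozygous site
    needs no hybridization and yields an empty list.
    """
    lines = lines if lines is not None else PURE_LINES
    if intermediates is None:
        intermediates = {k: v for k, v in CULTIVAR_TYPES.items()
                         if k != target.label}
    if not target.heterozygous:
        return []
    chains: list[tuple[frozenset[str], str, str]] = []
    seen = set()
    for ilabel, inter in intermediates.items():
        first_crosses = infer_single_cross(inter, lines)
        if not first_crosses:
            continue
        for second in sorted(lines):
            if not cross_feasible(inter, lines[second], target).feasible:
                continue
            for pair in sorted(first_crosses, key=sorted):
                key = (pair, ilabel, second)
                if key not in seen:
                    seen.add(key)
                    chains.append(key)
    return chains


def hypothetical_missing_parent(target: ITSTypeDef,
                                lines: dict[str, ITSTypeDef] | None = None,
                                ) -> list[tuple[dict[int, str], str]]:
    """Minimal unsampled homozygous parent that would explain ``target``.

    For each known pure line, solve for the homozygous partner genotype
    whose cross with it yields the target composition at every site;
    returns (partner genotype, known-line label) pairs, clearly marked
    hypothetical by the caller. Used for types (like P2) with no feasible
    cross among the sampled lines.
    """
    lines = lines if lines is not None else PURE_LINES
    out = []
    for label in sorted(lines):
        line = lines[label]
        partner: dict[int, str] = {}
        ok = True
        for pos in VARIABLE_SITES:
            want = target.genotypes[pos].composition
            (allele,) = line.genotypes[pos].composition
            if allele not in want:
                ok = False
                break
            rest = want - {allele}
            partner[pos] = next(iter(rest)) if rest else allele
        if ok:
            out.append((partner, label))
    return out
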