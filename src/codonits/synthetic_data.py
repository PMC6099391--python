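"""Simulated inputs: reference ITS, type sequences, (S,N) replicates, traces.

The raw AB1 chromatograms behind the *Codonopsis* study are not deposited,
so every input the pipeline consumes is generated here:

* a 655-nt reference ITS carrying the documented boundary motifs, the
  pure-line alleles at the four variable sites, and the pure-line G+C
  count (397), with GC-constrained random filler elsewhere;
* the thirteen named type sequences (Table-2-style edits of the reference);
* a moment-level sampler of replicate (S, N) statistics matching the
  published mixed-template calibration series — this sampler is canonical
  for all calibration statistics;
* a full four-channel trace renderer for pipeline I/O tests;
* the packaged 46-specimen panel (vouchers, species, localities,
  altitudes, ITS types, per-site hybrid ratios).

The S-mean model is linear in the minor-template fraction f:
E[S] = slope_a * f + intercept_b, with slope_a = 0.905 and
intercept_b = 0.025 fitted to the published calibration means; replicate
S and N values are truncated normals on [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import genotyping
from .chromatogram import CHANNELS, Trace
from .iupac import complement, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams", "ReferenceLayout", "DEFAULT_LAYOUT",
    "make_reference", "default_reference", "render_type_sequence",
    "simulate_sn_replicates", "render_trace", "render_type_traces",
    "build_specimen_panel", "load_calibration_series",
    "TYPE_DISCREPANT_VOUCHERS", "write_fasta", "read_fasta",
]


@dataclass(frozen=True)
class SimParams:
    """Generator parameters for the mixed-template trace model.

    amplitude        main-peak intensity, arbitrary fluorescence units
    slope_a,
    intercept_b      linear S-mean model E[S] = a*f + b (dimensionless)
    s_rep_sd         replicate SD of S (fraction)
    noise_mean_frac  mean noise-channel intensity as a fraction of amplitude
    noise_rep_sd     replicate SD of the N-value (fraction)
    seed             root seed; all randomness derives from it
    """

    amplitude: float = 1000.0
    slope_a: float = 0.905
    intercept_b: float = 0.025
    s_rep_sd: float = 0.015
    noise_mean_frac: float = 0.11
    noise_rep_sd: float = 0.011
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.slope_a <= 1:
            raise ValueError("slope_a must lie in (0, 1]")
        if not 0 <= self.intercept_b < 0.1:
            raise ValueError("intercept_b must lie in [0, 0.1)")
        if min(self.s_rep_sd, self.noise_rep_sd) < 0:
            raise ValueError("replicate SDs must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        for f in (0.0, 0.5):
            if not 0 < self.expected_s(f) < 1:
                raise ValueError("expected S must lie in (0,1) on [0, 0.5]")

    def expected_s(self, fraction: float) -> float:
        """Mean S-value at minor-template fraction ``fraction``."""
        return self.slope_a * fraction + self.intercept_b

    @property
    def expected_n(self) -> float:
        """Mean N-value implied by the noise level."""
        return self.noise_mean_frac / (1.0 + self.noise_mean_frac)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ReferenceLayout:
    """Structural constraints of the reference ITS.

    Coordinates are 1-based relative to the first base of the ITS start
    motif; ITS1 / 5.8S / ITS2 are contiguous.
    """

    its1_len: int = 257
    s58_len: int = 163
    its2_len: int = 235
    start_motif: str = "TCGAA"
    end_motif: str = "TCCGACC"
    s58_start_motif: str = "AAACGACTCT"
    s58_end_motif: str = "CGTCACGC"
    gc_count: int = 397
    p0_alleles: dict[int, str] = field(
        default_factory=lambda: {122: "C", 135: "G", 226: "C", 500: "G"})

    @property
    def total_len(self) -> int:
        return self.its1_len + self.s58_len + self.its2_len

    def fixed_positions(self) -> dict[int, str]:
        """All hard-constrained positions (motifs + variable-site alleles)."""
        fixed: dict[int, str] = {}

        def place(motif: str, start: int):
            for off, base in enumerate(motif):
                pos = start + off
                if fixed.get(pos, base) != base:
                    raise ValueError(
                        f"layout infeasible: position {pos} claimed by two "
                        f"motifs with different bases")
                fixed[pos] = base

        place(self.start_motif, 1)
        place(self.end_motif, self.total_len - len(self.end_motif) + 1)
        s58_start = self.its1_len + 1
        place(self.s58_start_motif, s58_start)
        place(self.s58_end_motif,
              self.its1_len + self.s58_len - len(self.s58_end_motif) + 1)
        for pos, base in self.p0_alleles.items():
            if fixed.get(pos, base) != base:
                raise ValueError(f"layout infeasible: variable position {pos} "
                                 "conflicts with a boundary motif")
            fixed[pos] = base
        return fixed


DEFAULT_LAYOUT = ReferenceLayout()


def make_reference(layout: ReferenceLayout = DEFAULT_LAYOUT,
                   seed: int = 1, max_attempts: int = 1000) -> str:
    """Generate a reference ITS satisfying every layout invariant.

    Filler outside the fixed positions is random but GC-constrained so the
    total G+C count equals ``layout.gc_count`` exactly; candidate draws in
    which any boundary motif occurs more than once are rejected.
    Deterministic for a fixed seed.
    """
    total = layout.total_len
    fixed = layout.fixed_positions()
    fixed_gc = sum(1 for b in fixed.values() if b in "GC")
    free = [p for p in range(1, total + 1) if p not in fixed]
    need_gc = layout.gc_count - fixed_gc
    if not 0 <= need_gc <= len(free):
        raise ValueError(
            f"layout infeasible: need {need_gc} G/C among {len(free)} free "
            f"positions to reach a total G+C count of {layout.gc_count}")
    motifs = (layout.start_motif, layout.end_motif,
              layout.s58_start_motif, layout.s58_end_motif)
    rng = np.random.default_rng(seed)
    free_arr = np.array(free)
    for _ in range(max_attempts):
        seq = [""] * total
        for pos, base in fixed.items():
            seq[pos - 1] = base
        gc_positions = rng.choice(free_arr, size=need_gc, replace=False)
        gc_set = set(int(p) for p in gc_positions)
        for pos in free:
            pool = "GC" if pos in gc_set else "AT"
            seq[pos - 1] = pool[rng.integers(2)]
        rendered = "".join(seq)
        if all(rendered.count(m) == 1 for m in motifs):
            return rendered
    raise ValueError("could not place filler without duplicating a boundary "
                     f"motif after {max_attempts} attempts")


_DEFAULT_REFERENCE: dict[int, str] = {}


def default_reference(seed: int = 1) -> str:
    """Cached reference for the default layout."""
    if seed not in _DEFAULT_REFERENCE:
        _DEFAULT_REFERENCE[seed] = make_reference(DEFAULT_LAYOUT, seed=seed)
    return _DEFAULT_REFERENCE[seed]


def render_type_sequence(type_label: str, reference: str) -> str:
    """Apply a named type's four-site genotype to the reference sequence.

    Heterozygous sites render as their IUPAC code (Y or R); peak
    orientation is carried by the type definition, not the sequence.
    """
    try:
        tdef = genotyping.TYPE_DEFS[type_label]
    except KeyError:
        raise ValueError(
            f"unknown ITS type {type_label!r}; valid labels: "
            f"{sorted(genotyping.TYPE_DEFS)}") from None
    seq = list(reference)
    for pos, g in tdef.genotypes.items():
        seq[pos - 1] = g.iupac
    return "".join(seq)


# ---------------------------------------------------------------------------
# (S, N) replicate sampler — canonical for calibration statistics
# ---------------------------------------------------------------------------

def _trunc01(rng: np.random.Generator, mean: float, sd: float,
             size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, 0.0, 1.0))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_sn_replicates(fraction: float, n: int,
                           params: SimParams = SimParams(),
                           rng: np.random.Generator | None = None,
                           ) -> list[tuple[float, float]]:
    """Draw ``n`` replicate (S, N) pairs at minor-template ``fraction``.

    S replicates are truncated normal around the linear S-mean model; N
    replicates around the noise-implied mean. The calibration design never
    exceeds an equimolar mix, so fractions above 0.5 are rejected.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError(f"fraction must lie in [0, 0.5], got {fraction}")
    if n < 2:
        raise ValueError("need at least 2 replicates")
    rng = rng if rng is not None else params.rng()
    s = _trunc01(rng, params.expected_s(fraction), params.s_rep_sd, n)
    nv = _trunc01(rng, params.expected_n, params.noise_rep_sd, n)
    return list(zip(s.tolist(), nv.tolist()))


# ---------------------------------------------------------------------------
# Full trace rendering
# ---------------------------------------------------------------------------

def render_trace(sequence: str,
                 het_sites: dict[int, tuple[str, float]] | None = None,
                 params: SimParams = SimParams(),
                 strand: str = "forward",
                 rng: np.random.Generator | None = None) -> Trace:
    """Render a four-channel trace for ``sequence``.

    ``sequence`` must be plain bases (the called, i.e. major, base at any
    heterozygous site); ``het_sites`` maps position -> (minor_base,
    minor-template fraction). The called channel sits at ``amplitude``;
    the minor channel at a het site encodes a replicate S draw
    (minor = amplitude * S / (1 - S)); remaining channels are background
    noise. The reverse strand is the reverse complement with het sites
    mirrored (position p -> L - p + 1, bases complemented).
    """
    het_sites = dict(het_sites or {})
    rng = rng if rng is not None else params.rng()
    L = len(sequence)
    for pos, (minor, frac) in het_sites.items():
        if not 1 <= pos <= L:
            raise ValueError(f"het site {pos} outside sequence of length {L}")
        if not 0.0 <= frac <= 0.5:
            raise ValueError(f"het fraction must lie in [0, 0.5], got {frac}")
        if minor == sequence[pos - 1]:
            raise ValueError(f"minor base at {pos} equals the called base")
    if strand == "reverse":
        sequence = reverse_complement(sequence)
        het_sites = {L - pos + 1: (complement(minor), frac)
                     for pos, (minor, frac) in het_sites.items()}
    elif strand != "forward":
        raise ValueError(f"strand must be forward/reverse, got {strand!r}")
    if any(b not in CHANNELS for b in sequence):
        raise ValueError("sequence for rendering must be plain A/C/G/T "
                         "(use the major base at heterozygous sites)")

    A = params.amplitude
    noise = A * _trunc01(rng, params.noise_mean_frac, params.noise_rep_sd,
                         4 * L).reshape(L, 4)
    channels = noise
    base_idx = {b: i for i, b in enumerate(CHANNELS)}
    call_cols = np.fromiter((base_idx[b] for b in sequence), dtype=int, count=L)
    channels[np.arange(L), call_cols] = A
    for pos, (minor, frac) in het_sites.items():
        s = float(_trunc01(rng, params.expected_s(frac), params.s_rep_sd, 1)[0])
        s = min(s, 0.499)  # keep the called base the taller peak
        channels[pos - 1, base_idx[minor]] = A * s / (1.0 - s)
    return Trace(channels, sequence, strand=strand)


def render_type_traces(type_label: str, reference: str,
                       site_fractions: dict[int, float] | None = None,
                       params: SimParams = SimParams(),
                       rng: np.random.Generator | None = None,
                       default_fraction: float = 0.3,
                       ) -> tuple[Trace, Trace]:
    """Forward/reverse trace pair for a named type.

    The called base at each heterozygous site is the type's major base
    (falling back to the reference allele when the orientation is
    undefined, as for the R sites of T1); ``site_fractions`` gives the
    minor-template fraction per site, defaulting to ``default_fraction``.
    """
    tdef = genotyping.TYPE_DEFS[type_label]
    rng = rng if rng is not None else params.rng()
    site_fractions = site_fractions or {}
    seq = list(reference)
    het: dict[int, tuple[str, float]] = {}
    for pos, g in tdef.genotypes.items():
        if not g.heterozygous:
            seq[pos - 1] = g.iupac
            continue
        ref_allele = reference[pos - 1]
        major = g.major if g.major is not None else (
            ref_allele if ref_allele in g.composition else sorted(g.composition)[0])
        (minor,) = g.composition - {major}
        seq[pos - 1] = major
        het[pos] = (minor, site_fractions.get(pos, default_fraction))
    plain = "".join(seq)
    fwd = render_trace(plain, het, params=params, strand="forward", rng=rng)
    rev = render_trace(plain, het, params=params, strand="reverse", rng=rng)
    return fwd, rev


# ---------------------------------------------------------------------------
# Packaged study tables
# ---------------------------------------------------------------------------

#: vouchers whose ITS-type assignment differs between the study's
#: hybrid-ratio table (canonical, column ``its_type``) and its specimen
#: metadata table (provenance column ``its_type_table4``)
TYPE_DISCREPANT_VOUCHERS = ("CP34", "CP37", "CP38",
                            "CPM42", "CPM43", "CPM44", "CPM45")


def _read_packaged(name: str) -> pd.DataFrame:
    path = resources.files("codonits.data") / name
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def build_specimen_panel(warn_discrepancies: bool = True) -> pd.DataFrame:
    """The 46 packaged specimen records.

    Columns: voucher, species, locality, locality_no, altitude_m, date,
    its_type (canonical), its_type_table4 (provenance), and the per-site
    hybrid-ratio summaries ratio{122,226}_{mean,sd} (percent; NaN where
    the specimen has no additive peak at that site).
    """
    panel = _read_packaged("specimens.tsv")
    if warn_discrepancies:
        disc = panel[panel.its_type != panel.its_type_table4]
        for row in disc.itertuples(index=False):
            logger.warning(
                "type assignment discrepancy for %s: hybrid-ratio table says "
                "%s, specimen-metadata table says %s (using %s)",
                row.voucher, row.its_type, row.its_type_table4, row.its_type)
    return panel


def load_calibration_series() -> pd.DataFrame:
    """The published mixed-template calibration summaries (percent scale)."""
    return _read_packaged("calibration_series.tsv")


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write
    from Bio.SeqRecord import SeqRecord
    write([SeqRecord(Seq(s), id=k, description="") for k, s in records.items()],
          str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse
    return {rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")}
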