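"""Four-channel trace model, peak extraction, and the S/N peak statistics.

A direct Sanger read of a mixed or heterozygous template shows, at the
variable position, a secondary peak underneath the main peak. Two ratios
summarize a query site:

* S-value = I2 / (I1 + I2), the secondary-peak share of the site signal,
* N-value = I0 / (I0 + I1), the background-noise share,

where I1 and I2 are the largest and second-largest channel intensities at
the site and I0 is the average noise intensity over a window of flanking
positions. Comparing replicate S-values against replicate N-values decides
whether the secondary peak is real (see :mod:`codonits.additivity`).

Traces are stored as a positions x 4 intensity matrix (channel order
A, C, G, T), one called base per position, 1-based coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .iupac import BASES

logger = logging.getLogger(__name__)

#: channel order of the intensity matrix
CHANNELS = BASES

#: half-width of the default noise window (117..127 around site 122)
DEFAULT_WINDOW_HALF = 5

_BASE_INDEX = {b: i for i, b in enumerate(CHANNELS)}


class TraceFormatError(ValueError):
    """Malformed trace file (carries the offending 1-based line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def calls_from_channels(channels: np.ndarray) -> str:
    """Called base per position = argmax channel; ties broken A<C<G<T."""
    channels = np.asarray(channels, dtype=float)
    idx = np.argmax(channels, axis=1)  # first (lowest-letter) argmax on ties
    n_ties = int((channels == channels.max(axis=1, keepdims=True)).sum(axis=1).max())
    if n_ties > 1:
        logger.info("argmax tie at %d position(s); broke by base order A<C<G<T",
                    int(((channels == channels.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum()))
    return "".join(CHANNELS[i] for i in idx)


@dataclass
class Trace:
    """An electropherogram: per-position channel intensities plus base calls.

    Positions are 1-based and contiguous. ``strand`` records whether the
    read is the forward or the reverse sequencing reaction; intensities are
    in arbitrary fluorescence units.
    """

    channels: np.ndarray  # shape (L, 4), order A C G T
    calls: str
    strand: str = "forward"

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 4:
            raise ValueError("channels must have shape (L, 4)")
        if np.any(self.channels < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.calls) != self.channels.shape[0]:
            raise ValueError("calls length does not match channel matrix")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"strand must be forward/reverse, got {self.strand!r}")
        maxima = self.channels.max(axis=1)
        for pos0, base in enumerate(self.calls):
            if base not in _BASE_INDEX:
                raise ValueError(f"called base {base!r} at position {pos0 + 1} "
                                 "is not a plain nucleotide")
            if self.channels[pos0, _BASE_INDEX[base]] != maxima[pos0]:
                raise ValueError(f"called base at position {pos0 + 1} is not the "
                                 "argmax channel")

    def __len__(self) -> int:
        return self.channels.shape[0]

    def __eq__(self, other) -> bool:
        return (isinstance(other, Trace)
                and self.strand == other.strand
                and self.calls == other.calls
                and np.array_equal(self.channels, other.channels))

    @property
    def sequence(self) -> str:
        return self.calls

    def intensity(self, pos: int, base: str) -> float:
        return float(self.channels[pos - 1, _BASE_INDEX[base]])


@dataclass(frozen=True)
class PeakTriplet:
    """The three intensities entering the S/N statistics at one site."""

    i0: float  # average noise intensity over the window (site excluded)
    i1: float  # main-peak intensity at the site
    i2: float  # secondary-peak intensity at the site
    site: int
    window: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self):
        if self.i1 < self.i2:
            raise ValueError("main peak i1 must be >= secondary peak i2")
        if min(self.i0, self.i1, self.i2) < 0:
            raise ValueError("peak intensities must be non-negative")


@dataclass(frozen=True)
class SNPair:
    """One replicate's (S, N) measurement at a site."""

    s: float
    n: float

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.n <= 1.0):
            raise ValueError("S and N must lie in [0, 1]")


def default_window(site: int, length: int,
                   half: int = DEFAULT_WINDOW_HALF) -> tuple[int, int]:
    """Symmetric noise window around ``site``, clipped to the trace."""
    return max(1, site - half), min(length, site + half)


def extract_peaks(trace: Trace, site: int,
                  window: tuple[int, int] | None = None) -> PeakTriplet:
    """Measure I0/I1/I2 at ``site``.

    I1 and I2 are the largest and second-largest channel intensities at the
    site. I0 is the mean, over every *other* window position, of that
    position's second-largest channel intensity — the main peak there is
    true base signal, and the runner-up channel is the natural noise
    analogue of I2. The window endpoints are inclusive, 1-based.
    """
    length = len(trace)
    if not (1 <= site <= length):
        raise ValueError(f"site {site} outside trace of length {length}")
    if window is None:
        window = default_window(site, length)
    lo, hi = window
    if not (1 <= lo <= site <= hi <= length):
        raise ValueError(f"window {window} must contain site {site} and lie "
                         f"within the trace (length {length})")
    noise_positions = [p for p in range(lo, hi + 1) if p != site]
    if len(noise_positions) < 3:
        raise ValueError("noise window too short: need >= 3 positions after "
                         "excluding the query site")
    sub = np.sort(trace.channels[np.array(noise_positions) - 1], axis=1)
    i0 = float(sub[:, 2].mean())  # second-largest of 4 channels
    at_site = np.sort(trace.channels[site - 1])
    return PeakTriplet(i0=i0, i1=float(at_site[3]), i2=float(at_site[2]),
                       site=site, window=(lo, hi))


def s_value(p: PeakTriplet) -> float:
    """Secondary-peak ratio I2/(I1+I2)."""
    if p.i1 + p.i2 <= 0:
        raise ValueError("empty signal: i1 + i2 = 0")
    return p.i2 / (p.i1 + p.i2)


def n_value(p: PeakTriplet) -> float:
    """Background-noise ratio I0/(I0+I1)."""
    if p.i0 + p.i1 <= 0:
        raise ValueError("empty signal: i0 + i1 = 0")
    return p.i0 / (p.i0 + p.i1)


def per_position_s(trace: Trace) -> np.ndarray:
    """Site-wise secondary-peak ratio for every position (vectorized)."""
    srt = np.sort(trace.channels, axis=1)
    denom = srt[:, 3] + srt[:, 2]
    with np.errstate(invalid="ignore"):
        s = np.where(denom > 0, srt[:, 2] / denom, 0.0)
    return s


# ---------------------------------------------------------------------------
# Tabular trace dialect: TSV with header "pos A C G T call strand"
# ---------------------------------------------------------------------------

_HEADER = ["pos", "A", "C", "G", "T", "call", "strand"]


def write_trace(trace: Trace, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for i in range(len(trace)):
            row = [str(i + 1)]
            row += [repr(float(v)) for v in trace.channels[i]]
            row += [trace.calls[i], trace.strand]
            fh.write("\t".join(row) + "\n")


def read_trace(path) -> Trace:
    channels: list[list[float]] = []
    calls: list[str] = []
    strand: str | None = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise TraceFormatError(f"bad header {header!r}", line=1)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise TraceFormatError(f"expected 7 fields, got {len(fields)}",
                                       line=lineno)
            try:
                pos = int(fields[0])
                vals = [float(v) for v in fields[1:5]]
            except ValueError as exc:
                raise TraceFormatError(str(exc), line=lineno) from None
            if pos != len(channels) + 1:
                raise TraceFormatError(
                    f"non-contiguous position index {pos} "
                    f"(expected {len(channels) + 1})", line=lineno)
            if any(v < 0 for v in vals):
                raise TraceFormatError("negative intensity", line=lineno)
            if strand is None:
                strand = fields[6]
            elif fields[6] != strand:
                raise TraceFormatError("inconsistent strand flag", line=lineno)
            channels.append(vals)
            calls.append(fields[5])
    if not channels:
        raise TraceFormatError("empty trace file")
    return Trace(np.array(channels), "".join(calls), strand=strand or "forward")
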