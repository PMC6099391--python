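"""Additive-nucleotide decision machinery and hybrid-ratio estimation.

A secondary peak is accepted as a real additive nucleotide when either

* its replicate mean S-value reaches the direct-confirmation threshold
  (0.15, the mixing fraction from which double peaks are unmistakable), or
* a two-group variance analysis finds the replicate S-values significantly
  above the replicate N-values (one-way ANOVA with two groups, identical
  to the pooled-variance t-test via F = t^2), at alpha = 0.01.

Candidate sites must first show the secondary peak on BOTH sequencing
strands; S and N are then computed on the forward strand. The S-value of a
confirmed peak, expressed in percent, is the specimen's hybrid ratio at
that site: the share of the minor parental repeat type in its rDNA array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chromatogram import Trace, per_position_s

logger = logging.getLogger(__name__)

#: replicate mean S at or above this confirms an additive site outright
DEFAULT_DIRECT_THRESHOLD = 0.15

#: significance level of the S-vs-N variance analysis
DEFAULT_ALPHA = 0.01

#: per-position secondary-peak ratio needed (on both strands) for a
#: position to become a candidate site; sits > 3 noise SDs above the
#: noise ceiling yet below the smallest hybrid ratio of interest
DEFAULT_MIN_SECONDARY = 0.13


@dataclass(frozen=True)
class AdditivityDecision:
    """Outcome of the S-vs-N analysis at one site."""

    site: int | None
    s_mean: float
    s_sd: float
    n_mean: float
    n_sd: float
    n_reps: int
    p_value: float
    verdict: str  # confirmed_direct | confirmed_by_test | not_confirmed

    @property
    def confirmed(self) -> bool:
        return self.verdict.startswith("confirmed")


@dataclass(frozen=True)
class CalibrationRow:
    """One mixing fraction's replicate summary (percent scale)."""

    fraction: float
    main_signal: str
    s_mean: float
    s_sd: float
    n_mean: float
    n_sd: float
    p_value: float
    significant: bool


def anova_s_vs_n(s_reps, n_reps_list, method: str = "anova",
                 ) -> tuple[float, float]:
    """Two-group variance analysis of replicate S against replicate N.

    ``method='anova'`` is the one-way two-group ANOVA (pooled-variance
    F-test, F = t^2); ``method='welch'`` substitutes Welch's unequal-
    variance t-test. Two identical zero-variance groups give p = 1 by
    convention.
    """
    s = np.asarray(list(s_reps), dtype=float)
    n = np.asarray(list(n_reps_list), dtype=float)
    if len(s) < 2 or len(n) < 2:
        raise ValueError("need at least 2 replicates in each group")
    if np.ptp(s) == 0 and np.ptp(n) == 0:
        if s.mean() == n.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    if method == "anova":
        stat, p = stats.f_oneway(s, n)
    elif method == "welch":
        stat, p = stats.ttest_ind(s, n, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


def decide_additivity(s_reps, n_reps_list,
                      alpha: float = DEFAULT_ALPHA,
                      direct_threshold: float = DEFAULT_DIRECT_THRESHOLD,
                      site: int | None = None,
                      method: str = "anova") -> AdditivityDecision:
    """Apply the direct-threshold / significance rule to replicate S and N."""
    s = np.asarray(list(s_reps), dtype=float)
    n = np.asarray(list(n_reps_list), dtype=float)
    stat, p = anova_s_vs_n(s, n, method=method)
    s_mean = float(s.mean())
    if s_mean >= direct_threshold:
        verdict = "confirmed_direct"
    elif p < alpha and s_mean > float(n.mean()):
        verdict = "confirmed_by_test"
    else:
        verdict = "not_confirmed"
    return AdditivityDecision(
        site=site, s_mean=s_mean, s_sd=float(s.std(ddof=1)),
        n_mean=float(n.mean()), n_sd=float(n.std(ddof=1)),
        n_reps=int(len(s)), p_value=p, verdict=verdict)


def detect_candidate_sites(fwd: Trace, rev: Trace,
                           min_secondary: float = DEFAULT_MIN_SECONDARY,
                           ) -> list[int]:
    """Positions whose secondary-peak ratio exceeds the screen on BOTH strands.

    Reverse-strand positions are mapped back to forward (ITS) coordinates
    through the reverse complement (position p -> L - p + 1). Returned
    sorted ascending.
    """
    if len(fwd) != len(rev):
        raise ValueError("forward and reverse traces must cover the same "
                         f"coordinates (lengths {len(fwd)} vs {len(rev)})")
    s_f = per_position_s(fwd)
    s_r = per_position_s(rev)[::-1]  # index i now refers to forward pos i+1
    hits = np.nonzero((s_f > min_secondary) & (s_r > min_secondary))[0] + 1
    return [int(p) for p in hits]


def calibration_table(fractions,
                      n: int = 5,
                      params=None,
                      alpha: float = DEFAULT_ALPHA,
                      main_signal: str = "C",
                      rng=None) -> list[CalibrationRow]:
    """Simulate the mixed-template calibration series.

    For each mixing fraction, ``n`` replicate (S, N) pairs are drawn from
    the moment-level sampler and summarized as mean +/- SD in percent
    (2 decimals), with the S-vs-N variance analysis applied at ``alpha``.
    """
    from .synthetic_data import SimParams, simulate_sn_replicates

    fractions = list(fractions)
    if not fractions:
        raise ValueError("fractions must be non-empty")
    params = params if params is not None else SimParams()
    rng = rng if rng is not None else params.rng()
    rows = []
    for frac in fractions:
        pairs = simulate_sn_replicates(frac, n, params=params, rng=rng)
        s = np.array([p[0] for p in pairs])
        nv = np.array([p[1] for p in pairs])
        _, p_val = anova_s_vs_n(s, nv)
        rows.append(CalibrationRow(
            fraction=frac, main_signal=main_signal,
            s_mean=round(float(s.mean()) * 100, 2),
            s_sd=round(float(s.std(ddof=1)) * 100, 2),
            n_mean=round(float(nv.mean()) * 100, 2),
            n_sd=round(float(nv.std(ddof=1)) * 100, 2),
            p_value=p_val,
            significant=bool(p_val < alpha and s.mean() > nv.mean())))
    return rows


def calibration_frame(rows: list[CalibrationRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "fraction_pct": round(r.fraction * 100, 2),
        "main_signal": r.main_signal,
        "s_mean_pct": r.s_mean, "s_sd_pct": r.s_sd,
        "n_mean_pct": r.n_mean, "n_sd_pct": r.n_sd,
        "p_value": r.p_value, "significant": r.significant,
    } for r in rows])


def smallest_significant_fraction(rows: list[CalibrationRow]) -> float | None:
    """Detection limit of one calibration run (None if nothing significant)."""
    sig = [r.fraction for r in rows if r.significant]
    return min(sig) if sig else None


def detection_limit_over_seeds(fractions, n: int = 5, params=None,
                               n_seeds: int = 20, base_seed: int = 0,
                               alpha: float = DEFAULT_ALPHA) -> float | None:
    """Majority detection limit over ``n_seeds`` independent calibration runs."""
    from .synthetic_data import SimParams

    params = params if params is not None else SimParams()
    limits = []
    for k in range(n_seeds):
        p = params.with_seed((base_seed + 1_000_003 * k) % (2**31 - 1))
        rows = calibration_table(fractions, n=n, params=p, alpha=alpha)
        limits.append(smallest_significant_fraction(rows))
    vals, counts = np.unique(
        np.array([np.nan if v is None else v for v in limits]),
        return_counts=True)
    best = vals[np.argmax(counts)]
    return None if np.isnan(best) else float(best)


def hybrid_ratio(s_reps) -> tuple[float, float]:
    """Replicate mean +/- sample SD of S, in percent (2 decimals)."""
    s = np.asarray(list(s_reps), dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 replicates")
    return (round(float(s.mean()) * 100, 2),
            round(float(s.std(ddof=1)) * 100, 2))


def aggregate_ratios_by_type(panel: pd.DataFrame,
                             sites=(122, 226),
                             type_column: str = "its_type") -> pd.DataFrame:
    """Mean hybrid ratio per (ITS type, site) over the specimen panel.

    Types with no measured specimen at a site are omitted (NaN), logged.
    Values are unrounded; presentation layers round to the 1-2 decimals
    used in print.
    """
    cols = {site: f"ratio{site}_mean" for site in sites}
    agg = panel.groupby(type_column)[list(cols.values())].mean()
    agg.columns = [f"mean_ratio_{site}" for site in sites]
    for site in sites:
        empty = agg.index[agg[f"mean_ratio_{site}"].isna()]
        if len(empty):
            logger.info("no hybrid-ratio values at site %d for type(s) %s",
                        site, ", ".join(empty))
    return agg
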