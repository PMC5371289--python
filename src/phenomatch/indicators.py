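"""Phenological indicators and temporal overlap, computed per posterior draw.

Five indicators summarise a yearly pattern (12-vector of monthly
proportions):

- central tendency T: month coordinate of the pattern's centre of gravity,
  T = sum_m m * a_m / sum_m a_m (optionally over a half-year window for
  species with two seasonal peaks);
- quantiles Q10 / Q50 / Q90: month coordinate at which 10/50/90% of annual
  abundance has accrued, with linear interpolation between month boundaries
  (operational "beginning", "middle" and "end" of the occurrence period);
- residence time Tr: the minimum number of months jointly carrying 90% of
  annual abundance.

The temporal overlap between two species in the same period is
O = sum_m min(a1_m, a2_m), a Schoener-type index in [0, 1] used as a proxy
of potential trophic-interaction magnitude.

Applying each indicator to every MCMC draw of the period-average patterns
turns parameter uncertainty into indicator-level credibility intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorSample
from .simulate import N_MONTHS

TIMING_INDICATORS = ("T", "T1", "T2", "Q10", "Q50", "Q90")
MAGNITUDE_INDICATORS = ("Tr", "overlap")


def _atleast_2d(pattern) -> tuple[np.ndarray, bool]:
    p = np.asarray(pattern, dtype=float)
    if p.ndim == 1:
        return p[None, :], True
    return p, False


def central_tendency(pattern, window: tuple[int, int] = (1, N_MONTHS)):
    """Centre of gravity of the pattern, in month coordinates.

    ``window`` restricts the computation to months [lo, hi] (1-based,
    inclusive); species with two seasonal peaks use (1, 6) and (7, 12).
    Raises ValueError if the pattern carries no mass inside the window.
    """
    p, single = _atleast_2d(pattern)
    lo, hi = window
    if not (1 <= lo <= hi <= N_MONTHS):
        raise ValueError(f"invalid window {window}")
    sub = p[:, lo - 1:hi]
    mass = sub.sum(axis=1)
    if (mass <= 0).any():
        raise ValueError("zero mass inside the window")
    months = np.arange(lo, hi + 1, dtype=float)
    t = (sub * months).sum(axis=1) / mass
    return float(t[0]) if single else t


def quantile(pattern, q: float):
    """Month coordinate at which fraction ``q`` of annual abundance accrues.

    Month m's mass accrues linearly over the interval (m-1, m], with the
    cumulative anchored at C(0) = 0: the result is
    m + (q - C(m)) / (C(m+1) - C(m)) for the unique m with C(m) < q <= C(m+1).
    A uniform pattern therefore has Q50 = 6.0 and results lie in (0, 12].
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p, single = _atleast_2d(pattern)
    c = np.cumsum(p, axis=1)
    c = c / c[:, -1:]
    m = (c < q).sum(axis=1)                       # months fully below q
    c_prev = np.where(m > 0, np.take_along_axis(
        c, np.maximum(m - 1, 0)[:, None], axis=1)[:, 0], 0.0)
    c_next = np.take_along_axis(c, m[:, None], axis=1)[:, 0]
    out = m + (q - c_prev) / (c_next - c_prev)
    return float(out[0]) if single else out


def residence_time(pattern, coverage: float = 0.9, contiguous: bool = False):
    """Minimum number of months jointly holding ``coverage`` of the year.

    By default months need not be consecutive, so the answer is the length
    of the shortest prefix of the proportions sorted in decreasing order
    whose sum reaches the coverage (greedy selection is optimal for this
    objective).  With ``contiguous=True`` the months must form a consecutive
    block within the ecological year (a windowed sensitivity variant).
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    p, single = _atleast_2d(pattern)
    p = p / p.sum(axis=1, keepdims=True)
    if contiguous:
        out = np.full(p.shape[0], N_MONTHS, dtype=int)
        for k in range(1, N_MONTHS + 1):
            windows = np.lib.stride_tricks.sliding_window_view(p, k, axis=1)
            best = windows.sum(axis=2).max(axis=1)
            hit = (best >= coverage - 1e-12) & (out == N_MONTHS)
            out[hit] = k
            if (out < N_MONTHS).all():
                break
    else:
        srt = np.sort(p, axis=1)[:, ::-1]
        csum = np.cumsum(srt, axis=1)
        out = (csum < coverage - 1e-12).sum(axis=1) + 1
        out = np.minimum(out, N_MONTHS)
    return int(out[0]) if single else out


def overlap(p1, p2):
    """Temporal overlap O = sum_m min(p1_m, p2_m) of two patterns in [0, 1].

    Symmetric; 1 iff the patterns are identical, 0 iff their supports are
    disjoint.  Reported as a percentage in output tables.
    """
    a, single1 = _atleast_2d(p1)
    b, single2 = _atleast_2d(p2)
    o = np.minimum(a, b).sum(axis=1)
    return float(o[0]) if (single1 and single2) else o


# ---------------------------------------------------------------------------
# posterior propagation
# ---------------------------------------------------------------------------

@dataclass
class IndicatorPosterior:
    """Posterior summaries (mean, equal-tailed 95% CI) of all indicators.

    ``species_summary`` has one row per species x period x indicator;
    ``overlap_summary`` one row per predator x prey x period (NaN rows mark
    interactions undefined in a period because one member is absent).
    ``draws`` retains the per-draw indicator values keyed by
    (species, period, indicator) and (predator, prey, period).
    """

    species_summary: pd.DataFrame
    overlap_summary: pd.DataFrame
    draws: dict

    def ci(self, species: str, period: str, indicator: str):
        row = self.species_summary[
            (self.species_summary["species"] == species)
            & (self.species_summary["period"] == period)
            & (self.species_summary["indicator"] == indicator)]
        if len(row) == 0:
            raise KeyError((species, period, indicator))
        r = row.iloc[0]
        return float(r["mean"]), float(r["ci_low"]), float(r["ci_high"])


def _summ(values: np.ndarray, level: float = 0.95):
    q = (1 - level) / 2
    return (float(values.mean()), float(np.quantile(values, q)),
            float(np.quantile(values, 1 - q)))


def indicator_posterior(
    sample: PosteriorSample,
    modality: Mapping[str, str] | None = None,
    interactions: Sequence[tuple[str, str]] = (),
    coverage: float = 0.9,
    contiguous: bool = False,
    level: float = 0.95,
) -> IndicatorPosterior:
    """Compute every indicator on every posterior draw and summarise.

    ``modality`` maps species to "unimodal"/"bimodal"; bimodal species get
    the peak-timing indicator per half-year (T1 on months 1-6, T2 on 7-12)
    while quantiles and residence time remain whole-year.  Interactions use
    the two species' draws matched by chain and iteration; since species are
    fitted independently the pairing is exchangeable, but matching keeps the
    computation a deterministic function of the stored draws.
    """
    modality = dict(modality or {})
    srows, orows = [], []
    draws: dict = {}
    for sp in sample:
        pooled = sp.pooled_a()
        for ji, pid in enumerate(sp.period_ids):
            pats = pooled[:, ji, :]
            vals: dict[str, np.ndarray] = {}
            if modality.get(sp.species, "unimodal") == "bimodal":
                vals["T1"] = central_tendency(pats, (1, 6))
                vals["T2"] = central_tendency(pats, (7, 12))
            else:
                vals["T"] = central_tendency(pats)
            vals["Q10"] = quantile(pats, 0.10)
            vals["Q50"] = quantile(pats, 0.50)
            vals["Q90"] = quantile(pats, 0.90)
            vals["Tr"] = residence_time(pats, coverage, contiguous)
            for ind, v in vals.items():
                mean, lo, hi = _summ(v, level)
                srows.append((sp.species, pid, ind, mean, lo, hi))
                draws[(sp.species, pid, ind)] = v
    for pred, prey in interactions:
        if pred not in sample.species or prey not in sample.species:
            raise KeyError(f"interaction ({pred}, {prey}) references a "
                           "species without a fitted posterior")
        sp1, sp2 = sample[pred], sample[prey]
        for pid in sample.period_ids:
            if pid not in sp1.period_ids or pid not in sp2.period_ids:
                orows.append((pred, prey, pid, np.nan, np.nan, np.nan))
                continue
            a1 = sp1.pooled_a()[:, sp1.period_index(pid), :]
            a2 = sp2.pooled_a()[:, sp2.period_index(pid), :]
            n = min(len(a1), len(a2))
            o = overlap(a1[:n], a2[:n])
            mean, lo, hi = _summ(o, level)
            orows.append((pred, prey, pid, mean, lo, hi))
            draws[(pred, prey, pid)] = o
    species_summary = pd.DataFrame(
        srows, columns=["species", "period", "indicator", "mean",
                        "ci_low", "ci_high"])
    overlap_summary = pd.DataFrame(
        orows, columns=["predator", "prey", "period", "mean",
                        "ci_low", "ci_high"])
    overlap_summary["mean_pct"] = 100.0 * overlap_summary["mean"]
    return IndicatorPosterior(species_summary=species_summary,
                              overlap_summary=overlap_summary, draws=draws)
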