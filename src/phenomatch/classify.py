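"""Trajectory classification of inter-period indicator changes.

Two periods differ "significantly" for an indicator when their equal-tailed
95% credibility intervals are strictly disjoint.  The pattern of significant
pairwise differences among the three periods is condensed into one trajectory
symbol per species x indicator (and per predator-prey interaction):

========  ======================================  =========================
symbol    timing indicators (T, Q10, Q50, Q90)    magnitude (Tr, overlap)
========  ======================================  =========================
``/``     precocity across periods (dates         increase across periods
          decrease)
``\\``     delay across periods (dates increase)   decrease across periods
``C``     period 2 earlier than periods 1 and 3   dip in period 2
``Ɔ``     period 2 later than periods 1 and 3     bump in period 2
``NS``    no significant pairwise difference
========  ======================================  =========================

Symbols are serialised as ASCII tokens named after the *glyph*:
``inc`` = "/", ``dec`` = "\\", ``C``, ``revC`` = "Ɔ", plus ``NS`` and
``undef`` (a needed species-period is absent).  Because the printed glyph
maps to opposite value directions for timing vs magnitude indicators, the
mapping is centralised here.  A ``legacy_overlap_symbols`` switch swaps
"/" and "\\" for the overlap indicator only, reproducing table conventions
in which "/" denoted an overlap decrease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .indicators import IndicatorPosterior, TIMING_INDICATORS

log = logging.getLogger(__name__)

SYMBOL_GLYPHS = {"C": "C", "revC": "Ɔ", "inc": "/", "dec": "\\",
                 "NS": "NS", "undef": ""}

FIRST_FOUR = ("T", "Q10", "Q50", "Q90")


def _round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TrajectoryCall:
    """Outcome of the decision tree for one species x indicator (or pair)."""

    unit: tuple
    indicator: str
    symbol: str                       # token: C/revC/inc/dec/NS/undef
    n_significant_pairs: int
    significant_pairs: tuple[tuple[str, str], ...] = ()
    directions: Mapping[tuple[str, str], int] = field(default_factory=dict)
    warning: str | None = None

    @property
    def glyph(self) -> str:
        return SYMBOL_GLYPHS[self.symbol]


def pairwise_significance(ci1, ci2, mean1: float, mean2: float):
    """CI-disjointness test between two periods.

    Returns ``(significant, sign)`` with sign = +1 if the value increased
    from the first to the second period (by posterior means), -1 if it
    decreased; intervals sharing an endpoint are *not* disjoint.
    """
    lo1, hi1 = ci1
    lo2, hi2 = ci2
    significant = bool(hi1 < lo2 or hi2 < lo1)
    sign = 0 if not significant else (1 if mean2 > mean1 else -1)
    return significant, sign


def _shape_from_signs(signs: Mapping[tuple[int, int], int | None]):
    """Condense pairwise change signs into a monotone/extremum shape.

    ``signs`` maps period-index pairs (0,1), (0,2), (1,2) to +1/-1 for a
    significant increase/decrease, 0 for no significant change, or None when
    the comparison is undefined.  Returns (shape, warning) with shape in
    {"inc", "dec", "dip", "bump", "NS"} on the raw value scale.

    Precedence: no significant pair -> NS; a period-2 extremum (dip/bump)
    requires all three periods and no significant end-to-end trend; otherwise
    a consistent monotone direction; contradictory directions fall back to
    the majority of significant pairs, ties -> NS with a warning.
    """
    defined = {p: s for p, s in signs.items() if s is not None}
    sig = {p: s for p, s in defined.items() if s != 0}
    if not sig:
        return "NS", None
    s01, s02, s12 = (signs.get(p) for p in ((0, 1), (0, 2), (1, 2)))
    if None not in (s01, s02, s12) and s02 == 0:
        dip = (s01 != 1 and s12 != -1) and (s01 == -1 or s12 == 1)
        bump = (s01 != -1 and s12 != 1) and (s01 == 1 or s12 == -1)
        if dip:
            return "dip", None
        if bump:
            return "bump", None
    vals = list(sig.values())
    if all(v == 1 for v in vals):
        return "inc", None
    if all(v == -1 for v in vals):
        return "dec", None
    pos, neg = vals.count(1), vals.count(-1)
    warning = "contradictory significant directions %s" % (dict(sig),)
    if pos > neg:
        return "inc", warning
    if neg > pos:
        return "dec", warning
    return "NS", warning


_SHAPE_TO_SYMBOL = {
    # timing: earlier dates = smaller values = "precocity" glyph "/"
    "timing": {"dec": "inc", "inc": "dec", "dip": "C", "bump": "revC",
               "NS": "NS"},
    "magnitude": {"inc": "inc", "dec": "dec", "dip": "C", "bump": "revC",
                  "NS": "NS"},
}


def assign_symbol(
    pair_results: Mapping[tuple[str, str], tuple[bool, int] | None],
    indicator_class: str,
    unit: tuple = (),
    indicator: str = "",
    legacy_overlap_symbols: bool = False,
) -> TrajectoryCall:
    """Map pairwise comparison outcomes to one trajectory symbol.

    ``pair_results`` maps (period_id_a, period_id_b) — ordered pairs over the
    period partition — to (significant, sign) or None for an undefined
    comparison.  ``indicator_class`` is "timing" or "magnitude".
    """
    if indicator_class not in _SHAPE_TO_SYMBOL:
        raise ValueError(f"unknown indicator class {indicator_class!r}")
    pairs = sorted(pair_results)
    if all(v is None for v in pair_results.values()):
        return TrajectoryCall(unit, indicator, "undef", 0)
    pid_order = sorted({p for pair in pairs for p in pair})
    idx = {pid: i for i, pid in enumerate(pid_order)}
    signs = {}
    for (pa, pb), res in pair_results.items():
        key = (idx[pa], idx[pb])
        signs[key] = None if res is None else (res[1] if res[0] else 0)
    shape, warning = _shape_from_signs(signs)
    symbol = _SHAPE_TO_SYMBOL[indicator_class][shape]
    if legacy_overlap_symbols and indicator == "overlap":
        symbol = {"inc": "dec", "dec": "inc"}.get(symbol, symbol)
    sig_pairs = tuple(p for p in pairs
                      if pair_results[p] is not None and pair_results[p][0])
    if warning:
        warning = f"{unit} {indicator}: {warning}"
        log.warning(warning)
    return TrajectoryCall(
        unit=unit, indicator=indicator, symbol=symbol,
        n_significant_pairs=len(sig_pairs), significant_pairs=sig_pairs,
        directions={p: pair_results[p][1] for p in sig_pairs},
        warning=warning,
    )


def count_possible_comparisons(presence: Mapping[str, Sequence[bool]]) -> int:
    """Number of theoretically possible pairwise period comparisons.

    Each species contributes C(k, 2) where k is the number of periods in
    which it is present; the total is summed over species (identical for
    every indicator).
    """
    total = 0
    for flags in presence.values():
        k = int(np.sum(np.asarray(flags, dtype=bool)))
        total += k * (k - 1) // 2
    return total


# ---------------------------------------------------------------------------
# pipeline-level classification
# ---------------------------------------------------------------------------

def _pairs_from_summary(sub: pd.DataFrame, period_ids: Sequence[str]):
    present = [p for p in period_ids if p in set(sub["period"])]
    out = {}
    for pa, pb in combinations(period_ids, 2):
        if pa not in present or pb not in present:
            out[(pa, pb)] = None
            continue
        ra = sub[sub["period"] == pa].iloc[0]
        rb = sub[sub["period"] == pb].iloc[0]
        if np.isnan(ra["mean"]) or np.isnan(rb["mean"]):
            out[(pa, pb)] = None
            continue
        out[(pa, pb)] = pairwise_significance(
            (ra["ci_low"], ra["ci_high"]), (rb["ci_low"], rb["ci_high"]),
            ra["mean"], rb["mean"])
    return out


def classify_species_indicators(
    ind: IndicatorPosterior, period_ids: Sequence[str],
) -> list[TrajectoryCall]:
    """One TrajectoryCall per species x indicator from posterior summaries."""
    calls = []
    summary = ind.species_summary
    for (species, indicator), sub in summary.groupby(
            ["species", "indicator"], sort=True):
        klass = "timing" if indicator in TIMING_INDICATORS else "magnitude"
        pair_results = _pairs_from_summary(sub, period_ids)
        calls.append(assign_symbol(pair_results, klass, (species,), indicator))
    return calls


def classify_interactions(
    ind: IndicatorPosterior, period_ids: Sequence[str],
    legacy_overlap_symbols: bool = False,
) -> list[TrajectoryCall]:
    """One TrajectoryCall per predator-prey pair for the overlap index."""
    calls = []
    for (pred, prey), sub in ind.overlap_summary.groupby(
            ["predator", "prey"], sort=True):
        pair_results = _pairs_from_summary(sub, period_ids)
        calls.append(assign_symbol(
            pair_results, "magnitude", (pred, prey), "overlap",
            legacy_overlap_symbols=legacy_overlap_symbols))
    return calls


@dataclass
class SummaryTables:
    """Summary tabulations of a classified analysis.

    ``species_table``: species x indicator matrix of "glyph (n)" strings;
    ``interaction_table``: predator x prey glyph matrix; ``overlap_changes``:
    "X% -> Y%" strings for changed interactions; ``stats``: the headline
    counts and percentages (per-indicator significant-pair totals and
    percentage of possible comparisons, changed-cell fractions overall and
    by group, interaction counts and symbol breakdown, 5% chance-threshold
    flags).
    """

    species_table: pd.DataFrame
    interaction_table: pd.DataFrame
    overlap_changes: pd.DataFrame
    stats: dict


def summarize(
    species_calls: Sequence[TrajectoryCall],
    interaction_calls: Sequence[TrajectoryCall] = (),
    presence: Mapping[str, Sequence[bool]] | None = None,
    groups: Mapping[str, str] | None = None,
    overlap_period_means: Mapping[tuple, Sequence[float]] | None = None,
    indicator_order: Sequence[str] = ("T", "Q10", "Q50", "Q90", "Tr"),
    chance_threshold_pct: float = 5.0,
) -> SummaryTables:
    """Tabulate trajectory calls into the analysis' headline summaries.

    ``presence`` maps species to per-period presence booleans (used for the
    possible-comparison count); ``groups`` maps species to a community group
    (e.g. fish / zooplankton) for the per-group breakdowns;
    ``overlap_period_means`` maps (predator, prey) to per-period posterior
    mean overlaps (fractions) used for the "X% -> Y%" change strings.
    """
    groups = dict(groups or {})
    presence = dict(presence or {})
    species_calls = list(species_calls)
    interaction_calls = list(interaction_calls)

    def cell(c: TrajectoryCall) -> str:
        if c.symbol == "undef":
            return ""
        if c.symbol == "NS":
            return "NS"
        return f"{c.glyph} ({c.n_significant_pairs})"

    sp_rows = {}
    for c in species_calls:
        sp_rows.setdefault(c.unit[0], {})[c.indicator] = cell(c)
    indicators_present = [i for i in indicator_order
                          if any(i in r for r in sp_rows.values())]
    extra = sorted({c.indicator for c in species_calls}
                   - set(indicators_present))
    species_table = pd.DataFrame.from_dict(sp_rows, orient="index")
    species_table = species_table.reindex(
        columns=indicators_present + extra).fillna("")
    species_table.index.name = "species"

    possible = count_possible_comparisons(presence) if presence else None

    per_indicator: dict[str, dict] = {}
    for ind in indicators_present + extra:
        calls = [c for c in species_calls if c.indicator == ind
                 and c.symbol != "undef"]
        n_pairs = sum(c.n_significant_pairs for c in calls)
        entry = {"significant_pairs": n_pairs,
                 "changed_cells": sum(c.symbol != "NS" for c in calls),
                 "defined_cells": len(calls)}
        if possible:
            pct = 100.0 * n_pairs / possible
            entry["pct_of_possible"] = _round_half_up(pct, 1)
            entry["exceeds_chance_threshold"] = pct > chance_threshold_pct
        per_indicator[ind] = entry

    defined = [c for c in species_calls if c.symbol != "undef"]
    changed = [c for c in defined if c.symbol != "NS"]
    stats = {
        "per_indicator": per_indicator,
        "possible_pairwise_comparisons": possible,
        "cells_defined": len(defined),
        "cells_changed": len(changed),
        "pct_cells_changed": _round_half_up(
            100.0 * len(changed) / len(defined), 1) if defined else 0.0,
        "species_symbol_counts": _symbol_counts(changed),
    }

    if groups:
        by_group = {}
        for grp in sorted(set(groups.values())):
            gcalls = [c for c in defined if groups.get(c.unit[0]) == grp]
            ff = [c for c in gcalls if c.indicator in FIRST_FOUR]
            by_group[grp] = {
                "first_four_changed": sum(c.symbol != "NS" for c in ff),
                "first_four_defined": len(ff),
            }
        stats["by_group"] = by_group
    tr_calls = [c for c in defined if c.indicator == "Tr"]
    if tr_calls:
        n_changed = sum(c.symbol != "NS" for c in tr_calls)
        stats["residence_time"] = {
            "changed": n_changed,
            "defined": len(tr_calls),
            "pct_changed": _round_half_up(100.0 * n_changed / len(tr_calls)),
        }

    int_rows = {}
    for c in interaction_calls:
        if c.symbol == "undef":
            continue
        pred, prey = c.unit
        int_rows.setdefault(pred, {})[prey] = (
            "NS" if c.symbol == "NS" else c.glyph)
    interaction_table = pd.DataFrame.from_dict(int_rows, orient="index")
    interaction_table = interaction_table.fillna("").sort_index()
    interaction_table.index.name = "predator"

    ichanged = [c for c in interaction_calls
                if c.symbol not in ("undef", "NS")]
    idefined = [c for c in interaction_calls if c.symbol != "undef"]
    stats["interactions"] = {
        "documented": len(idefined),
        "changed": len(ichanged),
        "pct_changed": _round_half_up(
            100.0 * len(ichanged) / len(idefined)) if idefined else 0.0,
        "symbol_counts": _symbol_counts(ichanged),
    }

    ov_rows = []
    if overlap_period_means:
        for c in ichanged:
            means = overlap_period_means.get(tuple(c.unit))
            if means is None:
                continue
            vals = [v for v in means if v is not None and not np.isnan(v)]
            first, last = vals[0], vals[-1]
            ov_rows.append((*c.unit,
                            f"{_round_half_up(100 * first):.0f}% -> "
                            f"{_round_half_up(100 * last):.0f}%"))
    overlap_changes = pd.DataFrame(
        ov_rows, columns=["predator", "prey", "change"])

    return SummaryTables(species_table=species_table,
                         interaction_table=interaction_table,
                         overlap_changes=overlap_changes, stats=stats)


def _symbol_counts(calls: Sequence[TrajectoryCall]) -> dict[str, int]:
    out = {s: 0 for s in ("inc", "dec", "C", "revC")}
    for c in calls:
        if c.symbol in out:
            out[c.symbol] += 1
    return out
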