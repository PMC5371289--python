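"""Reference classification results for the 19-taxon Gironde estuary study.

The long-term Gironde survey (14 fish taxa sampled year-round around the
Blayais site, 5 zooplankton taxa sampled March-November) was analysed over
three regimes of ecological years — 1985-1988, 1989-2002 and 2003-2010 —
separated by two abrupt ecosystem shifts.  The per-cell outcomes of that
analysis (trajectory symbol and number of significant pairwise differences
for every species x indicator, the documented predator-prey pairs with their
overlap trajectory and overlap change) are public summary results; they are
encoded here so that the tabulation stage can be exercised and its headline
statistics recomputed from the per-cell calls.

The raw survey abundances themselves are not public; simulation provides
statistically comparable inputs for everything upstream of this table.

Note on glyph convention: the encoded interaction symbols follow the
published tables, in which "/" marks an overlap *decrease* (the
``legacy_overlap_symbols`` convention of :mod:`phenomatch.classify`).
"""

from __future__ import annotations

from .classify import TrajectoryCall

PERIODS = (("P1", 1985, 1988), ("P2", 1989, 2002), ("P3", 2003, 2010))

FISH = (
    "L. ramada", "A. anguilla", "A. alosa", "A. fallax", "E. encrasicolus",
    "O. eperlanus", "G. aculeatus", "P. flesus", "Pomatoschistus sp.",
    "A. regius", "Dicentrarchus sp.", "Solea sp.", "S. sprattus",
    "Syngnathus sp.",
)
ZOOPLANKTON = (
    "E. affinis", "A. bifilosa", "A. tonsa", "N. integer", "M. slabberi",
)
SPECIES = FISH + ZOOPLANKTON
GROUPS = {s: ("fish" if s in FISH else "zooplankton") for s in SPECIES}

#: winter-maximal species use July-anchored ecological years
ECO_YEAR_START = {s: 3 for s in SPECIES}
ECO_YEAR_START["L. ramada"] = 7
ECO_YEAR_START["A. anguilla"] = 7

#: per-period presence; the meagre colonised the study area after period 1
PRESENCE = {s: (True, True, True) for s in SPECIES}
PRESENCE["A. regius"] = (False, True, True)

INDICATORS = ("T", "Q10", "Q50", "Q90", "Tr")

# (symbol token, significant-pair count) per species x indicator; NS
# elsewhere.  Tokens name glyphs: inc="/", dec="\", revC="Ɔ".
_CALLS: dict[str, dict[str, tuple[str, int]]] = {
    "A. alosa": {"T": ("inc", 3), "Q10": ("inc", 2), "Q50": ("inc", 3),
                 "Q90": ("inc", 2), "Tr": ("revC", 1)},
    "A. fallax": {"T": ("inc", 2), "Q50": ("inc", 2), "Q90": ("inc", 2),
                  "Tr": ("inc", 2)},
    "E. encrasicolus": {"T": ("inc", 2), "Q10": ("inc", 2),
                        "Q50": ("inc", 2), "Tr": ("dec", 2)},
    "G. aculeatus": {"T": ("inc", 2), "Q50": ("inc", 1), "Q90": ("inc", 2),
                     "Tr": ("inc", 2)},
    "Pomatoschistus sp.": {"Q90": ("revC", 1), "Tr": ("revC", 1)},
    "A. regius": {"T": ("dec", 1), "Q10": ("dec", 1), "Q50": ("dec", 1),
                  "Q90": ("inc", 1), "Tr": ("inc", 1)},
    "Dicentrarchus sp.": {"T": ("C", 1), "Q50": ("C", 1)},
    "S. sprattus": {"T": ("revC", 1), "Q10": ("revC", 1),
                    "Q50": ("revC", 1)},
    "Syngnathus sp.": {"T": ("C", 1), "Q10": ("C", 1), "Q50": ("C", 1),
                       "Q90": ("C", 1), "Tr": ("C", 1)},
    "E. affinis": {"T": ("C", 1), "Q10": ("C", 1)},
    "A. bifilosa": {"T": ("inc", 2), "Q50": ("inc", 1)},
    "A. tonsa": {"Q50": ("C", 1), "Q90": ("C", 1)},
    "N. integer": {"T": ("inc", 1), "Q50": ("inc", 1)},
    "M. slabberi": {"Q10": ("inc", 1)},
}

# documented predator-prey pairs: symbol token or "NS" (legacy overlap
# glyph convention); undocumented pairs are simply absent.
_INTERACTIONS: dict[tuple[str, str], str] = {
    ("L. ramada", "E. affinis"): "NS",
    ("L. ramada", "A. bifilosa"): "NS",
    ("A. anguilla", "N. integer"): "NS",
    ("A. anguilla", "M. slabberi"): "NS",
    ("A. alosa", "E. affinis"): "NS",
    ("A. alosa", "A. bifilosa"): "NS",
    ("A. alosa", "A. tonsa"): "NS",
    ("A. alosa", "N. integer"): "revC",
    ("A. alosa", "M. slabberi"): "NS",
    ("A. fallax", "E. affinis"): "NS",
    ("A. fallax", "A. bifilosa"): "NS",
    ("A. fallax", "A. tonsa"): "revC",
    ("A. fallax", "N. integer"): "NS",
    ("A. fallax", "M. slabberi"): "NS",
    ("E. encrasicolus", "E. affinis"): "NS",
    ("E. encrasicolus", "A. bifilosa"): "revC",
    ("E. encrasicolus", "A. tonsa"): "NS",
    ("E. encrasicolus", "N. integer"): "revC",
    ("E. encrasicolus", "M. slabberi"): "NS",
    ("O. eperlanus", "E. affinis"): "NS",
    ("O. eperlanus", "A. bifilosa"): "revC",
    ("O. eperlanus", "A. tonsa"): "NS",
    ("G. aculeatus", "N. integer"): "NS",
    ("G. aculeatus", "M. slabberi"): "NS",
    ("P. flesus", "N. integer"): "NS",
    ("P. flesus", "M. slabberi"): "NS",
    ("Pomatoschistus sp.", "E. affinis"): "NS",
    ("Pomatoschistus sp.", "A. bifilosa"): "NS",
    ("Pomatoschistus sp.", "A. tonsa"): "NS",
    ("Pomatoschistus sp.", "N. integer"): "inc",
    ("Pomatoschistus sp.", "M. slabberi"): "NS",
    ("A. regius", "E. affinis"): "inc",
    ("A. regius", "A. bifilosa"): "inc",
    ("A. regius", "A. tonsa"): "dec",
    ("A. regius", "N. integer"): "inc",
    ("A. regius", "M. slabberi"): "inc",
    ("Dicentrarchus sp.", "E. affinis"): "NS",
    ("Dicentrarchus sp.", "A. bifilosa"): "NS",
    ("Dicentrarchus sp.", "A. tonsa"): "NS",
    ("Dicentrarchus sp.", "N. integer"): "revC",
    ("Dicentrarchus sp.", "M. slabberi"): "NS",
    ("S. sprattus", "E. affinis"): "C",
    ("S. sprattus", "A. bifilosa"): "NS",
    ("S. sprattus", "A. tonsa"): "revC",
    ("Syngnathus sp.", "N. integer"): "inc",
    ("Syngnathus sp.", "M. slabberi"): "revC",
}

#: overlap magnitude changes (percent, first -> last) for changed pairs
OVERLAP_CHANGES_PCT: dict[tuple[str, str], tuple[int, int]] = {
    ("A. alosa", "N. integer"): (27, 50),
    ("A. fallax", "A. tonsa"): (60, 27),
    ("E. encrasicolus", "A. bifilosa"): (68, 46),
    ("E. encrasicolus", "N. integer"): (25, 45),
    ("O. eperlanus", "A. bifilosa"): (60, 45),
    ("Pomatoschistus sp.", "N. integer"): (50, 30),
    ("A. regius", "E. affinis"): (50, 25),
    ("A. regius", "A. bifilosa"): (64, 25),
    ("A. regius", "A. tonsa"): (30, 80),
    ("A. regius", "N. integer"): (70, 25),
    ("A. regius", "M. slabberi"): (60, 27),
    ("Dicentrarchus sp.", "N. integer"): (60, 75),
    ("S. sprattus", "E. affinis"): (65, 40),
    ("S. sprattus", "A. tonsa"): (23, 45),
    ("Syngnathus sp.", "N. integer"): (50, 25),
    ("Syngnathus sp.", "M. slabberi"): (60, 50),
}


def reference_species_calls() -> list[TrajectoryCall]:
    """Per-cell trajectory calls of the species x indicator grid."""
    calls = []
    for species in SPECIES:
        for indicator in INDICATORS:
            sym, n = _CALLS.get(species, {}).get(indicator, ("NS", 0))
            calls.append(TrajectoryCall(
                unit=(species,), indicator=indicator, symbol=sym,
                n_significant_pairs=n))
    return calls


def reference_interaction_calls() -> list[TrajectoryCall]:
    """Per-pair trajectory calls of the documented interactions."""
    calls = []
    for (pred, prey), sym in _INTERACTIONS.items():
        n = 0 if sym == "NS" else 1
        calls.append(TrajectoryCall(
            unit=(pred, prey), indicator="overlap", symbol=sym,
            n_significant_pairs=n))
    return calls


def reference_overlap_means() -> dict[tuple[str, str], tuple[float, float]]:
    """Per-pair (first, last) posterior-mean overlaps as fractions."""
    return {pair: (x / 100.0, y / 100.0)
            for pair, (x, y) in OVERLAP_CHANGES_PCT.items()}
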