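"""From raw survey samples to yearly proportion patterns.

Raw rows (one per sample: species, calendar date, optional station/depth,
abundance) are averaged to one value per species x month x year, filtered by
frequency of occurrence, remapped onto species-specific ecological years, and
normalised into yearly 12-vectors of monthly proportions — the data the
hierarchical Dirichlet model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import N_MONTHS

log = logging.getLogger(__name__)

PATTERN_COLS = [f"m{m}" for m in range(1, N_MONTHS + 1)]

_MONTH_NAMES = {name.lower(): i + 1 for i, name in enumerate(
    ["january", "february", "march", "april", "may", "june", "july",
     "august", "september", "october", "november", "december"])}


def month_number(month: int | str) -> int:
    """Accept a month as 1..12 or an English name ('March' -> 3)."""
    if isinstance(month, str):
        try:
            return _MONTH_NAMES[month.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown month name {month!r}") from None
    m = int(month)
    if not 1 <= m <= 12:
        raise ValueError(f"month must be in 1..12, got {m}")
    return m


def average_monthly(raw: pd.DataFrame) -> pd.DataFrame:
    """One arithmetic-mean abundance per species x year x month.

    All samples of a month (stations, depths, replicate hauls) enter the mean
    with equal weight.  Months with no samples produce no row.
    """
    _check_columns(raw, ("species", "year", "month", "abundance"))
    if (raw["abundance"] < 0).any():
        bad = raw.loc[raw["abundance"] < 0].iloc[0]
        raise ValueError(
            f"negative abundance for {bad['species']} "
            f"{int(bad['year'])}-{int(bad['month'])}"
        )
    if ((raw["month"] < 1) | (raw["month"] > 12)).any():
        raise ValueError("month outside 1..12 in raw table")
    out = (
        raw.groupby(["species", "year", "month"], as_index=False)["abundance"]
        .mean()
        .sort_values(["species", "year", "month"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def filter_by_occurrence(raw: pd.DataFrame, threshold: float = 0.02) -> pd.DataFrame:
    """Species whose frequency of occurrence strictly exceeds ``threshold``.

    The frequency is the proportion of raw samples (rows) of that species in
    which it was actually caught (abundance > 0), reported as a percentage.
    Rare species are dropped because a seasonal pattern cannot be estimated
    from a handful of positive catches.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    _check_columns(raw, ("species", "abundance"))
    if len(raw) == 0:
        raise ValueError("empty raw table")
    grp = raw.groupby("species")["abundance"]
    freq = grp.apply(lambda a: (a > 0).mean())
    out = pd.DataFrame({
        "species": freq.index,
        "n_samples": grp.size().values,
        "frequency_pct": 100.0 * freq.values,
    })
    out = out[out["frequency_pct"] > 100.0 * threshold]
    return out.sort_values("species", kind="mergesort").reset_index(drop=True)


def calendar_to_eco(year, month, start: int):
    """Vectorised (calendar year, month) -> (eco year, eco month 1..12)."""
    month = np.asarray(month)
    year = np.asarray(year)
    before = month < start
    eco_year = np.where(before, year - 1, year)
    eco_month = np.where(before, month - start + 13, month - start + 1)
    return eco_year, eco_month


def to_ecological_year(
    monthly: pd.DataFrame,
    eco_year_start: int | str | Mapping[str, int | str] = 1,
) -> pd.DataFrame:
    """Remap calendar dates onto species-specific ecological years.

    ``eco_year_start`` is the calendar month that opens the ecological year
    (3 = March for spring/summer species, 7 = July for winter species), given
    either globally or as a per-species mapping.  The remap is a bijection on
    dates: eco month 1 is the start month and eco year x covers start(x) ..
    start(x)+11 months.
    """
    _check_columns(monthly, ("species", "year", "month", "abundance"))
    if isinstance(eco_year_start, Mapping):
        starts = {s: month_number(m) for s, m in eco_year_start.items()}
        start_series = monthly["species"].map(
            lambda s: starts.get(s, 1)).to_numpy()
    else:
        start_series = np.full(len(monthly), month_number(eco_year_start))
    eco_year, eco_month = calendar_to_eco(
        monthly["year"].to_numpy(), monthly["month"].to_numpy(), start_series
    )
    out = pd.DataFrame({
        "species": monthly["species"].to_numpy(),
        "eco_year": eco_year.astype(int),
        "eco_month": eco_month.astype(int),
        "abundance": monthly["abundance"].to_numpy(),
    })
    return out.sort_values(["species", "eco_year", "eco_month"],
                           kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class ZeroFillPolicy:
    """How exact zeros and unsampled months enter the Dirichlet likelihood.

    A Dirichlet density is undefined on the boundary of the simplex, so a
    yearly pattern with a zero month cannot be scored as observed.

    - ``"epsilon"`` (default): every zero or missing monthly proportion is
      replaced by ``epsilon`` and the vector renormalised — the standard
      multiplicative replacement of compositional data analysis; all 12
      months stay comparable across species.
    - ``"aggregate-observed"``: months never sampled for a species (across
      the whole table) are treated as structural zeros outside the pattern's
      support; zeros among *sampled* months are still epsilon-replaced.  The
      model then operates on the reduced simplex of sampled months.
    """

    policy: str = "epsilon"
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.policy not in ("epsilon", "aggregate-observed"):
            raise ValueError(f"unknown zero-fill policy {self.policy!r}")
        if not 0 < self.epsilon < 1 / N_MONTHS:
            raise ValueError("epsilon must be in (0, 1/12)")


def to_yearly_patterns(
    monthly_eco: pd.DataFrame,
    zero_fill: ZeroFillPolicy = ZeroFillPolicy(),
) -> pd.DataFrame:
    """Normalise monthly abundances into yearly proportion patterns.

    Returns one row per species x ecological year with columns ``m1..m12``
    summing to 1.  Years with zero total abundance are excluded (logged);
    a species with no surviving year in some period is simply absent from
    that period downstream.
    """
    _check_columns(monthly_eco, ("species", "eco_year", "eco_month",
                                 "abundance"))
    wide = monthly_eco.pivot_table(
        index=["species", "eco_year"], columns="eco_month",
        values="abundance", aggfunc="mean",
    ).reindex(columns=range(1, N_MONTHS + 1))
    sampled_by_species = wide.notna().groupby(level="species").any()

    rows = []
    for (species, eco_year), row in wide.iterrows():
        v = row.to_numpy(dtype=float)
        observed = ~np.isnan(v)
        v = np.nan_to_num(v)
        total = v.sum()
        if total <= 0:
            log.info("dropping %s eco_year %s: zero total abundance",
                     species, eco_year)
            continue
        p = v / total
        if zero_fill.policy == "epsilon":
            support = np.ones(N_MONTHS, dtype=bool)
        else:
            support = sampled_by_species.loc[species].to_numpy()
        eps = zero_fill.epsilon
        fill = support & ((p <= 0) | ~observed)
        p = np.where(fill, eps, p)
        p = np.where(support, p, 0.0)
        p = p / p.sum()
        rows.append((species, int(eco_year), *p))
    return pd.DataFrame(rows, columns=["species", "eco_year"] + PATTERN_COLS)


def empirical_mean_pattern(patterns: pd.DataFrame, species: str) -> np.ndarray:
    """Average yearly pattern of one species over all its years."""
    sub = patterns.loc[patterns["species"] == species, PATTERN_COLS]
    if len(sub) == 0:
        raise KeyError(f"no patterns for species {species!r}")
    m = sub.mean().to_numpy()
    return m / m.sum()


def detect_modality(
    mean_pattern: np.ndarray,
    rel_height: float = 0.2,
    trough_frac: float = 0.5,
) -> str:
    """Classify a species' average yearly pattern as unimodal or bimodal.

    Bimodal iff the pattern has at least two local maxima each reaching
    ``rel_height`` of the global maximum, separated by a trough at most
    ``trough_frac`` of the smaller of the two peaks.  Coastal temperate
    systems commonly show a spring and an autumn production peak; bimodal
    species get their peak-timing indicator computed per half-year.
    """
    p = np.asarray(mean_pattern, dtype=float)
    peaks = []
    for i in range(N_MONTHS):
        left = p[i - 1] if i > 0 else -np.inf
        right = p[i + 1] if i < N_MONTHS - 1 else -np.inf
        if p[i] >= left and p[i] >= right and p[i] > 0:
            if not peaks or peaks[-1] != i - 1 or p[i] != p[i - 1]:
                peaks.append(i)
    peaks = [i for i in peaks if p[i] >= rel_height * p.max()]
    for a, b in zip(peaks, peaks[1:]):
        trough = p[a + 1:b].min() if b > a + 1 else p[a]
        if trough <= trough_frac * min(p[a], p[b]):
            return "bimodal"
    return "unimodal"


def _check_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table lacks required columns {missing}")
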