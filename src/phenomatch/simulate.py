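"""Synthetic monthly survey data with known phenological ground truth.

The generator inverts the analysis model: for every species and every year of
each multi-year period, a yearly pattern of monthly proportions is drawn from a
Dirichlet distribution centred on the period's true mean pattern with a
species-specific concentration, scaled by a lognormal yearly total.  Because
the truth (mean patterns, concentration, presence, modality) is recorded,
every downstream stage — pretreatment, MCMC inference, indicator computation
and trajectory classification — can be tested for recovery without any
external data.

Months are expressed on the *ecological* month axis (1..12 from the species'
ecological-year start month); output rows carry calendar year/month so that
the pretreatment stage has to perform the ecological-year remapping itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

N_MONTHS = 12

#: default period partition (ecological years between the two abrupt shifts)
DEFAULT_PERIODS = (("P1", 1985, 1988), ("P2", 1989, 2002), ("P3", 2003, 2010))

LAMBDA_MIN, LAMBDA_MAX = 0.3, 2000.0


@dataclass(frozen=True)
class Period:
    """A block of consecutive ecological years treated as one regime."""

    id: str
    first_year: int
    last_year: int

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1


def _as_periods(periods: Sequence) -> tuple[Period, ...]:
    out = []
    for p in periods:
        out.append(p if isinstance(p, Period) else Period(*p))
    prev_last = None
    for p in out:
        if p.first_year > p.last_year:
            raise ValueError(f"period {p.id}: first_year > last_year")
        if prev_last is not None and p.first_year <= prev_last:
            raise ValueError("period year ranges must be disjoint and ordered")
        prev_last = p.last_year
    return tuple(out)


@dataclass
class SpeciesScenario:
    """True generative state of one species.

    ``period_mean_patterns`` holds one 12-vector of monthly proportions per
    period (``None`` for a period in which the species is absent).  The
    ``concentration`` is the Dirichlet precision of yearly patterns around the
    period mean: large values make every year resemble the mean pattern,
    values below 1 make years sparse/erratic.
    """

    species_id: str
    period_mean_patterns: Sequence[np.ndarray | None]
    concentration: float
    modality: str = "unimodal"
    eco_year_start: int = 3  # calendar month number; 3=March, 7=July
    total_abundance_scale: float = 1000.0
    total_cv: float = 0.5
    observation_noise: float = 0.0  # >0: Poisson-resample monthly values
    missing_months: frozenset[int] = field(default_factory=frozenset)
    group: str = "fish"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(
                f"{self.species_id}: concentration must be positive"
            )
        if not (LAMBDA_MIN <= self.concentration <= LAMBDA_MAX):
            raise ValueError(
                f"{self.species_id}: concentration outside "
                f"[{LAMBDA_MIN}, {LAMBDA_MAX}]"
            )
        pats = []
        for pat in self.period_mean_patterns:
            if pat is None:
                pats.append(None)
                continue
            pat = np.asarray(pat, dtype=float)
            if pat.shape != (N_MONTHS,) or (pat < 0).any():
                raise ValueError(
                    f"{self.species_id}: pattern must be a nonnegative "
                    "12-vector"
                )
            if abs(pat.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.species_id}: pattern must sum to 1 (got "
                    f"{pat.sum():.12f})"
                )
            pats.append(pat)
        self.period_mean_patterns = pats
        if all(p is None for p in pats):
            raise ValueError(f"{self.species_id}: absent in every period")
        self.missing_months = frozenset(int(m) for m in self.missing_months)
        if len(self.missing_months) >= N_MONTHS:
            raise ValueError(f"{self.species_id}: all months missing")
        if self.modality not in ("unimodal", "bimodal"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def present_in_period(self) -> tuple[bool, ...]:
        return tuple(p is not None for p in self.period_mean_patterns)


@dataclass
class SimulationConfig:
    periods: Sequence = DEFAULT_PERIODS
    species: Sequence[SpeciesScenario] = ()
    interactions: Sequence[tuple[str, str]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.periods = _as_periods(self.periods)
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species_id in config")
        for s in self.species:
            if len(s.period_mean_patterns) != len(self.periods):
                raise ValueError(
                    f"{s.species_id}: {len(s.period_mean_patterns)} patterns "
                    f"for {len(self.periods)} periods"
                )
        known = set(ids)
        for pred, prey in self.interactions:
            if pred not in known or prey not in known:
                raise ValueError(f"interaction ({pred}, {prey}) references "
                                 "unknown species")


@dataclass
class GroundTruth:
    """Echo of the generative state plus the actually drawn yearly vectors."""

    config: SimulationConfig
    yearly_patterns: pd.DataFrame  # species, eco_year, m1..m12 (the drawn p)
    yearly_totals: pd.DataFrame    # species, eco_year, total


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    # gamma-based so that alpha entries equal to 0 give exact zeros
    # (the degenerate Dirichlet limit); numpy's dirichlet rejects zeros.
    g = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-300)), 0.0)
    return g / g.sum()


def eco_to_calendar(eco_year: int, eco_month: int, start: int) -> tuple[int, int]:
    """Map (ecological year, eco month 1..12) to (calendar year, month)."""
    m = start + eco_month - 1
    if m > 12:
        return eco_year + 1, m - 12
    return eco_year, m


def generate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format survey table.

    Returns ``(table, truth)`` where ``table`` has columns
    ``species, year, month, abundance`` (calendar dates; months the species'
    protocol never samples are *absent rows*, not zeros) and ``truth`` echoes
    the configuration together with every drawn yearly proportion vector.

    Randomness is split into one independent substream per species (keyed by
    its position in the species list), so appending a species leaves the
    simulated data of the existing ones unchanged under the same seed.
    """
    rows: list[tuple] = []
    truth_pat: list[tuple] = []
    truth_tot: list[tuple] = []
    sigma_cache: dict[float, float] = {}
    for i, sc in enumerate(config.species):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        )
        cv = sc.total_cv
        if cv not in sigma_cache:
            sigma_cache[cv] = float(np.sqrt(np.log1p(cv * cv)))
        sigma = sigma_cache[cv]
        mu = np.log(sc.total_abundance_scale) - 0.5 * sigma * sigma
        for j, period in enumerate(config.periods):
            pattern = sc.period_mean_patterns[j]
            if pattern is None:
                continue
            alpha = sc.concentration * pattern
            for year in period.years:
                p = _dirichlet(rng, alpha)
                total = float(rng.lognormal(mu, sigma))
                monthly = total * p
                if sc.observation_noise > 0:
                    k = sc.observation_noise
                    monthly = rng.poisson(monthly / k) * k
                truth_pat.append((sc.species_id, year, *p))
                truth_tot.append((sc.species_id, year, total))
                for em in range(1, N_MONTHS + 1):
                    if em in sc.missing_months:
                        continue
                    cy, cm = eco_to_calendar(year, em, sc.eco_year_start)
                    rows.append((sc.species_id, cy, cm, float(monthly[em - 1])))
    table = pd.DataFrame(rows, columns=["species", "year", "month", "abundance"])
    table = table.sort_values(["species", "year", "month"], kind="mergesort")
    table = table.reset_index(drop=True)
    truth = GroundTruth(
        config=config,
        yearly_patterns=pd.DataFrame(
            truth_pat,
            columns=["species", "eco_year"] + [f"m{m}" for m in range(1, 13)],
        ),
        yearly_totals=pd.DataFrame(
            truth_tot, columns=["species", "eco_year", "total"]
        ),
    )
    return table, truth


# ---------------------------------------------------------------------------
# scenario construction for trajectory-recovery experiments
# ---------------------------------------------------------------------------

_GLYPH_TO_TOKEN = {"/": "inc", "\\": "dec", "Ɔ": "revC", "C": "C",
                   "inc": "inc", "dec": "dec", "revC": "revC"}

TIMING_INDICATORS = ("T", "Q10", "Q50", "Q90")
MAGNITUDE_INDICATORS = ("Tr",)


def _bump_pattern(center: float, half_width: int = 2) -> np.ndarray:
    """Compact triangular bump on months [center-hw, center+hw], zero outside.

    Exact zeros outside the support make integer translations shift every
    timing indicator by exactly the translation (no wrap-around mass).
    """
    m = np.arange(1, N_MONTHS + 1, dtype=float)
    w = np.maximum(0.0, 1.0 - np.abs(m - center) / (half_width + 1))
    return w / w.sum()


def shift_pattern(p: np.ndarray, delta: float) -> np.ndarray:
    """Translate a pattern by ``delta`` months (linear blend for fractions).

    The centre of gravity shifts by exactly ``delta`` provided the support
    stays inside months 1..12.
    """
    k = int(np.floor(delta))
    f = delta - k
    shifted = np.roll(p, k)
    if f > 0:
        shifted = (1 - f) * shifted + f * np.roll(p, k + 1)
    return shifted


def _plateau_pattern(k: int, center: int = 6, mass: float = 0.94) -> np.ndarray:
    """k consecutive months share ``mass`` equally; the rest share 1-mass.

    By construction the residence time at 90% coverage is exactly ``k``.
    """
    p = np.full(N_MONTHS, (1.0 - mass) / (N_MONTHS - k))
    start = max(0, min(N_MONTHS - k, center - 1 - k // 2))
    p[start:start + k] = mass / k
    return p / p.sum()


def make_trajectory_scenario(
    symbol: str,
    indicator: str,
    shift_months: float = 2.0,
    *,
    concentration: float = 200.0,
    species_id: str | None = None,
    n_periods: int = 3,
    **kwargs,
) -> SpeciesScenario:
    """Build a species whose true patterns realise a trajectory symbol.

    For timing indicators (T, Q10, Q50, Q90) the symbol is encoded by integer
    translations of a compact seasonal bump: "/" (precocity) puts the
    period-1 peak ``shift_months`` later than periods 2 and 3; "\\" the
    reverse; "C" dips period 2 earlier; "Ɔ" bumps it later.  For the
    magnitude indicator Tr the symbol is encoded by the width of a plateau
    pattern (increasing, decreasing, dip or bump in the true residence time).
    """
    token = _GLYPH_TO_TOKEN.get(symbol)
    if token is None:
        raise ValueError(f"unknown trajectory symbol {symbol!r}")
    if n_periods != 3:
        raise ValueError("trajectory scenarios are defined for 3 periods")
    if indicator in TIMING_INDICATORS:
        if shift_months < 1:
            raise ValueError("shift_months must be >= 1")
        base = _bump_pattern(center=5.0)
        late = shift_pattern(base, shift_months)
        if token == "inc":          # "/": period 1 later than 2 and 3
            pats = [late, base, base]
        elif token == "dec":        # "\": period 1 earlier than 2 and 3
            pats = [base, late, late]
        elif token == "C":          # period 2 earlier than 1 and 3
            pats = [late, base, late]
        else:                       # "Ɔ": period 2 later than 1 and 3
            pats = [base, late, base]
    elif indicator in MAGNITUDE_INDICATORS:
        widths = {"inc": (3, 5, 7), "dec": (7, 5, 3),
                  "C": (6, 3, 6), "revC": (3, 6, 3)}[token]
        pats = [_plateau_pattern(k) for k in widths]
    else:
        raise ValueError(f"unknown indicator {indicator!r}")
    return SpeciesScenario(
        species_id=species_id or f"{token}_{indicator}",
        period_mean_patterns=pats,
        concentration=concentration,
        **kwargs,
    )


def make_interaction_scenario(
    symbol: str,
    shift_months: float = 3.0,
    *,
    concentration: float = 200.0,
    prefix: str = "pair",
    **kwargs,
) -> tuple[SpeciesScenario, SpeciesScenario]:
    """Predator/prey pair whose true temporal overlap follows a symbol.

    The predator keeps a fixed seasonal bump; the prey pattern is translated
    away from (or back towards) the predator across the three periods, which
    lowers (raises) the true overlap index.  Symbols use the magnitude
    nomenclature: "/" overlap increase, "\\" decrease, "C" dip, "Ɔ" bump.
    """
    token = _GLYPH_TO_TOKEN.get(symbol)
    if token is None:
        raise ValueError(f"unknown trajectory symbol {symbol!r}")
    base = _bump_pattern(center=5.0)
    near, far = base, shift_pattern(base, shift_months)
    prey_pats = {"inc": [far, near, near], "dec": [near, near, far],
                 "C": [near, far, near], "revC": [far, near, far]}[token]
    predator = SpeciesScenario(
        species_id=f"{prefix}_pred", period_mean_patterns=[base] * 3,
        concentration=concentration, **kwargs)
    prey = SpeciesScenario(
        species_id=f"{prefix}_prey", period_mean_patterns=list(prey_pats),
        concentration=concentration, group="zooplankton", **kwargs)
    return predator, prey


def demo_config(seed: int = 0, n_species: int = 19) -> SimulationConfig:
    """A small community emulating the study design: fish sampled year-round
    (March-anchored ecological years, two winter species July-anchored) and
    zooplankton sampled March-November only, with one species absent from the
    first period and a spread of trajectory types."""
    species: list[SpeciesScenario] = []
    base_specs = [
        ("inc", "T"), ("dec", "T"), ("C", "T"), ("revC", "T"),
        ("inc", "Q50"), ("C", "Q50"), ("dec", "Tr"), ("inc", "Tr"),
    ]
    rng = np.random.default_rng(seed)
    for i in range(n_species):
        group = "zooplankton" if i >= n_species - 5 else "fish"
        if i < len(base_specs):
            sym, ind = base_specs[i]
            sc = make_trajectory_scenario(
                sym, ind, 2.0, species_id=f"sp{i:02d}",
                concentration=float(rng.uniform(50, 300)))
            sc = replace(sc, group=group)
        else:
            center = float(rng.uniform(4, 8))
            pat = _bump_pattern(center, half_width=3)
            sc = SpeciesScenario(
                species_id=f"sp{i:02d}", period_mean_patterns=[pat] * 3,
                concentration=float(rng.uniform(20, 200)), group=group)
        if group == "zooplankton":
            # winter months never sampled (eco months 10..12 of a March year)
            sc = replace(sc, missing_months=frozenset({10, 11, 12}),
                         group=group)
        species.append(sc)
    if n_species >= 10:
        # one species absent from the first period
        sc = species[9]
        pats = list(sc.period_mean_patterns)
        pats[0] = None
        species[9] = replace(sc, period_mean_patterns=pats)
    interactions = []
    fish = [s.species_id for s in species if s.group == "fish"]
    zoo = [s.species_id for s in species if s.group == "zooplankton"]
    for i, f in enumerate(fish):
        for z in zoo[: 1 + i % 3]:
            interactions.append((f, z))
    return SimulationConfig(species=species, interactions=interactions,
                            seed=seed)
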