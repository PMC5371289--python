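"""Hierarchical Dirichlet model of yearly abundance patterns, fitted by MCMC.

Model, for one species s with yearly patterns P_s(y) (12-vectors of monthly
proportions) and a partition of years into periods j:

    P_s(y) ~ Dirichlet(lambda_s * a_{s,j(y)})        (likelihood)
    a_{s,j} ~ Dirichlet(1/12, ..., 1/12)             (flat prior on patterns)
    lambda_s ~ Uniform(0.3, 2000)                    (flat prior on precision)

a_{s,j} is the average yearly pattern of period j and lambda_s the Dirichlet
concentration: the larger it is, the closer every year's pattern sits to the
period mean.  Species are independent, so each is fitted separately.

Sampling uses componentwise adaptive random-walk Metropolis on transformed
coordinates, with proposal scales tuned during burn-in only.  Each period
pattern is parameterised through the gamma representation of the Dirichlet:
with z_m = log g_m and g_m ~ Gamma(1/12) independent, a = softmax(z) has
exactly the flat Dirichlet prior, every month owns one well-pinned coordinate
(log-gamma density alpha0*z - exp(z)), and lambda moves on the log scale.
The Dirichlet log-likelihood depends on the data solely through the
per-period sums of log-proportions, so a posterior evaluation is O(12)
regardless of the number of years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .pretreatment import PATTERN_COLS
from .simulate import N_MONTHS, Period, _as_periods

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Priors of the hierarchy (flat by default)."""

    lambda_bounds: tuple[float, float] = (0.3, 2000.0)
    pattern_prior_concentration: float = 1.0 / N_MONTHS

    def __post_init__(self) -> None:
        lo, hi = self.lambda_bounds
        if not (0 < lo < hi):
            raise ValueError("lambda prior bounds must satisfy 0 < lo < hi")


@dataclass(frozen=True)
class McmcSettings:
    n_chains: int = 3
    n_burnin: int = 10_000
    n_keep_per_chain: int = 50_000
    thinning: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_burnin", "n_keep_per_chain", "thinning"):
            if getattr(self, name) < 1 and name != "n_burnin":
                raise ValueError(f"{name} must be positive")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be nonnegative")


#: reduced-iteration profile for tests and quick exploratory runs
FAST_MCMC = McmcSettings(n_chains=3, n_burnin=1_000, n_keep_per_chain=2_000)


@dataclass
class SpeciesPosterior:
    """Posterior draws for one species.

    ``a`` has shape (n_chains, n_keep, n_periods_present, 12); each draw of
    each present period is a point on the simplex (structural-zero months,
    if any, are exactly zero in every draw).  ``lam`` has shape
    (n_chains, n_keep).
    """

    species: str
    period_ids: tuple[str, ...]
    a: np.ndarray
    lam: np.ndarray
    support: np.ndarray            # bool (12,) months inside the simplex
    n_years: tuple[int, ...]
    rhat: dict[str, float]
    warnings: tuple[str, ...] = ()

    def pooled_a(self) -> np.ndarray:
        """(n_chains*n_keep, n_periods, 12) with chains concatenated."""
        c, n, j, m = self.a.shape
        return self.a.reshape(c * n, j, m)

    def pooled_lam(self) -> np.ndarray:
        return self.lam.reshape(-1)

    def period_index(self, period_id: str) -> int:
        try:
            return self.period_ids.index(period_id)
        except ValueError:
            raise KeyError(
                f"{self.species}: absent in period {period_id!r}"
            ) from None

    def pattern_mean(self, period_id: str) -> np.ndarray:
        return self.pooled_a()[:, self.period_index(period_id), :].mean(0)

    def pattern_ci(self, period_id: str, level: float = 0.95):
        """Equal-tailed credibility bounds per month: (low, high) 12-vectors."""
        q = (1 - level) / 2
        draws = self.pooled_a()[:, self.period_index(period_id), :]
        return (np.quantile(draws, q, axis=0),
                np.quantile(draws, 1 - q, axis=0))


@dataclass
class PosteriorSample:
    """Per-species posteriors plus the settings that produced them."""

    species: dict[str, SpeciesPosterior]
    periods: tuple[Period, ...]
    settings: McmcSettings
    spec: ModelSpec

    def __getitem__(self, species: str) -> SpeciesPosterior:
        return self.species[species]

    def __iter__(self):
        return iter(self.species.values())

    @property
    def period_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.periods)

    def rhat_summary(self) -> pd.DataFrame:
        rows = [
            (sp.species, param, val)
            for sp in self
            for param, val in sp.rhat.items()
        ]
        return pd.DataFrame(rows, columns=["species", "parameter", "rhat"])

    def to_frame(self, thinning: int = 1) -> pd.DataFrame:
        """Long-format draws: species,period,parameter,month,chain,iteration,value."""
        frames = []
        for sp in self:
            c, n, j, m = sp.a.shape
            keep = np.arange(0, n, thinning)
            for ci in range(c):
                for ji, pid in enumerate(sp.period_ids):
                    sub = sp.a[ci, keep, ji, :]
                    frames.append(pd.DataFrame({
                        "species": sp.species, "period": pid, "parameter": "a",
                        "month": np.tile(np.arange(1, m + 1), len(keep)),
                        "chain": ci, "iteration": np.repeat(keep, m),
                        "value": sub.reshape(-1),
                    }))
                frames.append(pd.DataFrame({
                    "species": sp.species, "period": "", "parameter": "lambda",
                    "month": 0, "chain": ci, "iteration": keep,
                    "value": sp.lam[ci, keep],
                }))
        return pd.concat(frames, ignore_index=True)


def sample_from_frame(frame: pd.DataFrame, periods, settings: McmcSettings,
                      spec: ModelSpec = ModelSpec()) -> PosteriorSample:
    """Rebuild a PosteriorSample from its long-format CSV export."""
    periods = _as_periods(periods)
    species = {}
    for name, sub in frame.groupby("species"):
        a_sub = sub[sub["parameter"] == "a"]
        pids = [p.id for p in periods if p.id in set(a_sub["period"])]
        chains = sorted(a_sub["chain"].unique())
        iters = np.sort(a_sub["iteration"].unique())
        a = np.empty((len(chains), len(iters), len(pids), N_MONTHS))
        for ji, pid in enumerate(pids):
            pj = a_sub[a_sub["period"] == pid]
            for ci in chains:
                pc = pj[pj["chain"] == ci].sort_values(["iteration", "month"])
                a[ci, :, ji, :] = pc["value"].to_numpy().reshape(
                    len(iters), N_MONTHS)
        lam_sub = frame[(frame["species"] == name)
                        & (frame["parameter"] == "lambda")]
        lam = np.empty((len(chains), len(iters)))
        for ci in chains:
            lam[ci] = (lam_sub[lam_sub["chain"] == ci]
                       .sort_values("iteration")["value"].to_numpy())
        support = a.reshape(-1, N_MONTHS).sum(0) > 0
        species[name] = SpeciesPosterior(
            species=name, period_ids=tuple(pids), a=a, lam=lam,
            support=support, n_years=tuple(0 for _ in pids), rhat={})
    return PosteriorSample(species=species, periods=periods,
                           settings=settings, spec=spec)


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R-hat of one scalar parameter.

    ``chains`` is an (m, n) array of m independent chains with n draws each.
    Uses the classic between/within-chain variance formula
    R = sqrt(((n-1)/n * W + B/n) / W); values near 1 indicate that the
    chains have mixed into the same distribution.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _softmax_rows(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise softmax; returns (a, log_a)."""
    zs = z - z.max(axis=-1, keepdims=True)
    e = np.exp(zs)
    tot = e.sum(axis=-1, keepdims=True)
    a = e / tot
    log_a = zs - np.log(tot)
    return a, log_a


def _loglik(a: np.ndarray, lam: np.ndarray, n_years: int,
            s_logp: np.ndarray) -> np.ndarray:
    """Dirichlet log-likelihood of one period via sufficient statistics.

    ``a``: (C, D) patterns, ``lam``: (C,), ``s_logp``: (D,) sum over years of
    log observed proportions.  Additive constants in the data are dropped.
    """
    al = lam[:, None] * a
    return (n_years * (gammaln(lam) - gammaln(al).sum(axis=1))
            + ((al - 1.0) * s_logp).sum(axis=1))


def _fit_one_species(
    name: str,
    period_ids: list[str],
    pmats: list[np.ndarray],
    spec: ModelSpec,
    mcmc: McmcSettings,
    rng: np.random.Generator,
) -> SpeciesPosterior:
    support = np.zeros(N_MONTHS, dtype=bool)
    for pm in pmats:
        support |= pm.sum(axis=0) > 0
    for pid, pm in zip(period_ids, pmats):
        bad = (pm[:, support] <= 0)
        if bad.any():
            yi, mi = np.argwhere(bad)[0]
            month = np.flatnonzero(support)[mi] + 1
            raise ValueError(
                f"non-positive proportion for species {name}, period {pid}, "
                f"year index {yi}, month {month}; apply a zero-fill policy "
                "before fitting"
            )
    d = int(support.sum())
    j = len(period_ids)
    c = mcmc.n_chains
    lo, hi = spec.lambda_bounds
    alpha0 = spec.pattern_prior_concentration
    n_years = [pm.shape[0] for pm in pmats]
    s_logp = [np.log(pm[:, support]).sum(axis=0) for pm in pmats]

    # initialisation: empirical mean pattern per period, lambda spread across
    # chains for an honest convergence diagnostic
    z0 = np.empty((j, d))
    for ji, pm in enumerate(pmats):
        a_emp = np.maximum(pm[:, support].mean(axis=0), 1e-5)
        a_emp = a_emp / a_emp.sum()
        z0[ji] = np.log(a_emp)
    z = z0[None, :, :] + rng.normal(0, 0.2, size=(c, j, d))
    lam_init = np.clip(10.0 * 2.0 ** (np.arange(c) - (c - 1) / 2),
                       lo * 1.01, hi * 0.99)
    theta = np.log(lam_init) + rng.normal(0, 0.1, size=c)
    theta = np.clip(theta, np.log(lo) + 1e-6, np.log(hi) - 1e-6)
    lam = np.exp(theta)

    a = np.empty((c, j, d))
    ll = np.empty((c, j))
    for ji in range(j):
        a[:, ji], _ = _softmax_rows(z[:, ji])
        ll[:, ji] = _loglik(a[:, ji], lam, n_years[ji], s_logp[ji])
    # log-gamma prior terms alpha0 * z - exp(z), summed per period
    zprior = (alpha0 * z - np.exp(z)).sum(axis=2)

    scale_z = np.full((c, j, d), 0.4)
    scale_t = np.full(c, 0.3)
    acc_z = np.zeros_like(scale_z)
    acc_t = np.zeros(c)

    total_iter = mcmc.n_burnin + mcmc.n_keep_per_chain * mcmc.thinning
    out_a = np.empty((c, mcmc.n_keep_per_chain, j, d))
    out_lam = np.empty((c, mcmc.n_keep_per_chain))
    kept = 0
    adapt_every = 50
    target = 0.35

    for it in range(total_iter):
        for ji in range(j):
            for dd in range(d):
                step = scale_z[:, ji, dd] * rng.standard_normal(c)
                znew = z[:, ji, :].copy()
                znew[:, dd] += step
                a_new, _ = _softmax_rows(znew)
                ll_new = _loglik(a_new, lam, n_years[ji], s_logp[ji])
                zprior_new = zprior[:, ji] + alpha0 * step \
                    + np.exp(z[:, ji, dd]) - np.exp(znew[:, dd])
                delta = (ll_new + zprior_new) - (ll[:, ji] + zprior[:, ji])
                accept = np.log(rng.random(c)) < delta
                if accept.any():
                    z[accept, ji, dd] = znew[accept, dd]
                    a[accept, ji] = a_new[accept]
                    ll[accept, ji] = ll_new[accept]
                    zprior[accept, ji] = zprior_new[accept]
                acc_z[:, ji, dd] += accept

        # log-lambda update (affects every period's likelihood)
        tnew = theta + scale_t * rng.standard_normal(c)
        inb = (tnew > np.log(lo)) & (tnew < np.log(hi))
        lam_new = np.exp(np.clip(tnew, np.log(lo), np.log(hi)))
        ll_new_all = np.stack(
            [_loglik(a[:, ji], lam_new, n_years[ji], s_logp[ji])
             for ji in range(j)], axis=1)
        delta = ll_new_all.sum(axis=1) + tnew - (ll.sum(axis=1) + theta)
        accept = inb & (np.log(rng.random(c)) < delta)
        if accept.any():
            theta[accept] = tnew[accept]
            lam[accept] = lam_new[accept]
            ll[accept] = ll_new_all[accept]
        acc_t += accept

        if it < mcmc.n_burnin and (it + 1) % adapt_every == 0:
            step = min(0.25, 2.0 / np.sqrt((it + 1) / adapt_every))
            scale_z *= np.exp(step * (acc_z / adapt_every - target))
            scale_t *= np.exp(step * (acc_t / adapt_every - target))
            acc_z[:] = 0.0
            acc_t[:] = 0.0

        if it >= mcmc.n_burnin:
            k = it - mcmc.n_burnin
            if k % mcmc.thinning == 0:
                out_a[:, kept] = a
                out_lam[:, kept] = lam
                kept += 1

    a_full = np.zeros((c, mcmc.n_keep_per_chain, j, N_MONTHS))
    a_full[:, :, :, support] = out_a

    rhat: dict[str, float] = {}
    months = np.flatnonzero(support) + 1
    for ji, pid in enumerate(period_ids):
        for mi, month in enumerate(months):
            rhat[f"a[{pid},m{month}]"] = gelman_rubin(out_a[:, :, ji, mi])
    rhat["lambda"] = gelman_rubin(out_lam)
    warnings = tuple(
        f"{name}: R-hat {v:.3f} > {mcmc.rhat_threshold} for {param}"
        for param, v in rhat.items() if v > mcmc.rhat_threshold
    )
    for w in warnings:
        log.warning(w)
    return SpeciesPosterior(
        species=name, period_ids=tuple(period_ids), a=a_full, lam=out_lam,
        support=support, n_years=tuple(n_years), rhat=rhat,
        warnings=warnings,
    )


def fit_model(
    patterns: pd.DataFrame,
    periods: Sequence = None,
    spec: ModelSpec = ModelSpec(),
    mcmc: McmcSettings = McmcSettings(),
) -> PosteriorSample:
    """Fit the hierarchy independently for every species in ``patterns``.

    ``patterns`` is the yearly-pattern table (``species, eco_year, m1..m12``)
    produced by :func:`phenomatch.pretreatment.to_yearly_patterns`;
    ``periods`` the partition of ecological years into regimes.  Periods in
    which a species has no pattern are treated as absent for that species.
    Fits are sequential and seeded per species, so results do not depend on
    which other species are present or on fit order.
    """
    from .simulate import DEFAULT_PERIODS

    periods = _as_periods(DEFAULT_PERIODS if periods is None else periods)
    species_names = sorted(patterns["species"].unique())
    out: dict[str, SpeciesPosterior] = {}
    for name in species_names:
        sub = patterns[patterns["species"] == name]
        pids, pmats = [], []
        for p in periods:
            block = sub[(sub["eco_year"] >= p.first_year)
                        & (sub["eco_year"] <= p.last_year)]
            if len(block):
                pids.append(p.id)
                pmats.append(block[PATTERN_COLS].to_numpy(dtype=float))
        if not pids:
            log.warning("species %s has no years inside the period "
                        "partition; skipped", name)
            continue
        # seed derived from the species name so the fit is invariant to the
        # composition of the rest of the table
        import zlib
        sub_seed = zlib.crc32(name.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=mcmc.seed, spawn_key=(sub_seed,)))
        log.info("fitting %s (%d periods, %s years)", name, len(pids),
                 [m.shape[0] for m in pmats])
        out[name] = _fit_one_species(name, pids, pmats, spec, mcmc, rng)
    return PosteriorSample(species=out, periods=periods, settings=mcmc,
                           spec=spec)


def significant_pattern_change(
    sample: PosteriorSample, species: str, j1: str, j2: str,
    level: float = 0.95,
) -> tuple[bool, list[int]]:
    """Is the average pattern of ``species`` different between two periods?

    Significant iff at least one month whose equal-tailed credibility
    intervals in the two periods are strictly disjoint; returns that list of
    months.  Raises KeyError if the species is absent in either period
    (comparison undefined).
    """
    sp = sample[species]
    lo1, hi1 = sp.pattern_ci(j1, level)
    lo2, hi2 = sp.pattern_ci(j2, level)
    disjoint = (hi1 < lo2) | (hi2 < lo1)
    months = [int(m) for m in np.flatnonzero(disjoint) + 1]
    return bool(months), months
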