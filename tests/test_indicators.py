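"""Indicator kernels and their posterior propagation."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenomatch import (central_tendency, overlap, quantile, residence_time,
                        indicator_posterior)
from phenomatch.inference import PosteriorSample, SpeciesPosterior
from phenomatch.simulate import Period, _bump_pattern

from conftest import TINY_MCMC


def vec(**kw):
    p = np.zeros(12)
    for k, v in kw.items():
        p[int(k[1:]) - 1] = v
    return p


UNIFORM = np.full(12, 1 / 12)

simplex_vectors = st.lists(
    st.floats(0.001, 1.0), min_size=12, max_size=12
).map(lambda xs: np.array(xs) / np.sum(xs))


class TestCentralTendency:
    @pytest.mark.parametrize("pattern, expected", [
        (vec(m5=1.0), 5.0),
        (UNIFORM, 6.5),
        (vec(m3=0.2, m4=0.5, m5=0.3), 4.1),
    ])
    def test_known_values(self, pattern, expected):
        assert central_tendency(pattern) == pytest.approx(expected)

    def test_window_restriction(self):
        p = vec(m2=0.5, m10=0.5)
        assert central_tendency(p, (1, 6)) == pytest.approx(2.0)
        assert central_tendency(p, (7, 12)) == pytest.approx(10.0)

    def test_zero_mass_window_flagged(self):
        with pytest.raises(ValueError, match="zero mass"):
            central_tendency(vec(m2=1.0), (7, 12))


class TestQuantile:
    @pytest.mark.parametrize("pattern, q, expected", [
        (vec(m1=1.0), 0.1, 0.1),
        (UNIFORM, 0.5, 6.0),
        (vec(m1=0.1, m2=0.4, m3=0.5), 0.9, 2.8),
    ])
    def test_known_values(self, pattern, q, expected):
        assert quantile(pattern, q) == pytest.approx(expected)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.3])
    def test_invalid_q_rejected(self, q):
        with pytest.raises(ValueError):
            quantile(UNIFORM, q)

    @given(simplex_vectors)
    @settings(max_examples=50, deadline=None)
    def test_quantiles_ordered_and_in_range(self, p):
        q10, q50, q90 = (quantile(p, q) for q in (0.1, 0.5, 0.9))
        assert 0 < q10 <= q50 <= q90 <= 12


class TestResidenceTime:
    @pytest.mark.parametrize("pattern, expected", [
        (vec(m4=1.0), 1),
        (UNIFORM, 11),
    ])
    def test_known_values(self, pattern, expected):
        assert residence_time(pattern) == expected

    def test_greedy_equals_exhaustive_subset_minimum(self, rng):
        def brute(p, coverage=0.9):
            for k in range(1, 13):
                for subset in combinations(range(12), k):
                    if p[list(subset)].sum() >= coverage - 1e-12:
                        return k
            return 12

        for _ in range(200):
            p = rng.dirichlet(np.full(12, rng.uniform(0.2, 5.0)))
            assert residence_time(p) == brute(p)

    def test_monotone_in_coverage(self, rng):
        p = rng.dirichlet(np.full(12, 0.7))
        values = [residence_time(p, c) for c in (0.5, 0.7, 0.9, 0.99)]
        assert values == sorted(values)

    def test_contiguous_variant_never_shorter(self, rng):
        p = _bump_pattern(3, 1) + _bump_pattern(9, 1)
        p = p / p.sum()
        assert residence_time(p, contiguous=True) >= residence_time(p)


class TestOverlap:
    def test_identical_patterns_full_overlap(self):
        p = _bump_pattern(6, 3)
        assert overlap(p, p) == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        assert overlap(vec(m1=0.5, m2=0.5), vec(m7=1.0)) == 0.0

    def test_hand_computed_example(self):
        p1 = vec(m1=0.5, m2=0.5)
        p2 = vec(m1=0.25, m2=0.25, m3=0.5)
        assert overlap(p1, p2) == pytest.approx(0.5)

    @given(simplex_vectors, simplex_vectors)
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, p1, p2):
        o = overlap(p1, p2)
        assert o == pytest.approx(overlap(p2, p1))
        assert 0 <= o <= 1 + 1e-12

    def test_moving_mass_off_shared_month_cannot_increase_overlap(self):
        p1 = vec(m5=0.6, m6=0.4)
        p2 = vec(m5=0.5, m9=0.5)
        moved = vec(m5=0.4, m6=0.4, m11=0.2)   # shared month 5 -> disjoint 11
        assert overlap(moved, p2) <= overlap(p1, p2)


class TestTranslationProperty:
    def test_shift_moves_timing_not_magnitude(self):
        p = _bump_pattern(5, 2)          # support months 3..7, interior
        shifted = np.roll(p, 1)
        assert central_tendency(shifted) == pytest.approx(
            central_tendency(p) + 1)
        for q in (0.1, 0.5, 0.9):
            assert quantile(shifted, q) == pytest.approx(quantile(p, q) + 1)
        assert residence_time(shifted) == residence_time(p)
        assert overlap(shifted, shifted) == pytest.approx(1.0)


def degenerate_sample(v, period_ids=("P1",), n=50, species="s"):
    j = len(period_ids)
    a = np.tile(v, (2, n, j, 1))
    sp = SpeciesPosterior(species=species, period_ids=tuple(period_ids),
                          a=a, lam=np.full((2, n), 10.0),
                          support=v > 0, n_years=(5,) * j, rhat={})
    periods = tuple(Period(pid, 2000 + 10 * i, 2009 + 10 * i)
                    for i, pid in enumerate(period_ids))
    return PosteriorSample(species={species: sp}, periods=periods,
                           settings=TINY_MCMC, spec=None)


class TestIndicatorPosterior:
    def test_degenerate_posterior_collapses_to_plain_values(self):
        v = _bump_pattern(6, 3)
        sample = degenerate_sample(v)
        ind = indicator_posterior(sample)
        for name, want in [("T", central_tendency(v)),
                           ("Q10", quantile(v, 0.1)),
                           ("Q50", quantile(v, 0.5)),
                           ("Q90", quantile(v, 0.9)),
                           ("Tr", residence_time(v))]:
            mean, lo, hi = ind.ci("s", "P1", name)
            assert mean == pytest.approx(want)
            assert lo == pytest.approx(want) and hi == pytest.approx(want)

    def test_quantile_ordering_holds_per_draw(self, shifted_fit):
        sample, _ = shifted_fit
        ind = indicator_posterior(sample)
        for pid in ("P1", "P2", "P3"):
            q10 = ind.draws[("shifted", pid, "Q10")]
            q50 = ind.draws[("shifted", pid, "Q50")]
            q90 = ind.draws[("shifted", pid, "Q90")]
            assert (q10 <= q50 + 1e-12).all()
            assert (q50 <= q90 + 1e-12).all()

    def test_bimodal_species_gets_half_year_peaks(self):
        v = _bump_pattern(3, 1) + _bump_pattern(9, 1)
        v = v / v.sum()
        sample = degenerate_sample(v)
        ind = indicator_posterior(sample, modality={"s": "bimodal"})
        names = set(ind.species_summary["indicator"])
        assert {"T1", "T2", "Q10", "Q50", "Q90", "Tr"} == names
        t1, _, _ = ind.ci("s", "P1", "T1")
        t2, _, _ = ind.ci("s", "P1", "T2")
        assert 1 <= t1 <= 6 < t2 <= 12

    def test_overlap_summary_matches_recomputation_on_draws(self, rng):
        n = 400
        a1 = rng.dirichlet(np.full(12, 3.0), size=n)
        a2 = rng.dirichlet(np.full(12, 3.0), size=n)
        sp = {}
        for name, draws in [("pred", a1), ("prey", a2)]:
            a = draws.reshape(2, n // 2, 1, 12)
            sp[name] = SpeciesPosterior(
                species=name, period_ids=("P1",), a=a,
                lam=np.full((2, n // 2), 10.0), support=np.ones(12, bool),
                n_years=(5,), rhat={})
        sample = PosteriorSample(species=sp,
                                 periods=(Period("P1", 2000, 2009),),
                                 settings=TINY_MCMC, spec=None)
        ind = indicator_posterior(sample, interactions=[("pred", "prey")])
        o = np.minimum(a1, a2).sum(axis=1)
        row = ind.overlap_summary.iloc[0]
        assert row["mean"] == pytest.approx(o.mean())
        assert row["ci_low"] == pytest.approx(np.quantile(o, 0.025))
        assert row["ci_high"] == pytest.approx(np.quantile(o, 0.975))

    def test_absent_period_interaction_is_undefined_not_error(self):
        v = _bump_pattern(6, 3)
        full = degenerate_sample(v, ("P1", "P2"))
        partial = degenerate_sample(v, ("P2",), species="late")
        sample = PosteriorSample(
            species={"s": full["s"], "late": partial["late"]},
            periods=full.periods, settings=TINY_MCMC, spec=None)
        ind = indicator_posterior(sample, interactions=[("s", "late")])
        sub = ind.overlap_summary.set_index("period")
        assert np.isnan(sub.loc["P1", "mean"])
        assert sub.loc["P2", "mean"] == pytest.approx(1.0)
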