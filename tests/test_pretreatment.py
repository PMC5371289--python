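"""Pretreatment: averaging, occurrence filter, eco years, patterns."""

import numpy as np
import pandas as pd
import pytest

from phenomatch import (SimulationConfig, SpeciesScenario, ZeroFillPolicy,
                        average_monthly, detect_modality, filter_by_occurrence,
                        generate_dataset, to_ecological_year,
                        to_yearly_patterns)
from phenomatch.pretreatment import PATTERN_COLS, calendar_to_eco
from phenomatch.simulate import _bump_pattern


def raw(rows):
    return pd.DataFrame(rows, columns=["species", "year", "month",
                                       "abundance"])


class TestAverageMonthly:
    def test_mean_over_samples(self):
        table = raw([("X", 2000, 5, v) for v in (0, 0, 3, 3, 6, 6)])
        out = average_monthly(table)
        assert len(out) == 1
        assert out.loc[0, "abundance"] == pytest.approx(3.0)

    def test_single_sample_identity(self):
        out = average_monthly(raw([("X", 2000, 5, 7.5)]))
        assert out.loc[0, "abundance"] == 7.5

    def test_row_order_invariance(self, rng):
        rows = [("X", 2000 + i % 3, 1 + i % 12, float(v))
                for i, v in enumerate(rng.uniform(0, 5, 60))]
        t = raw(rows)
        shuffled = t.sample(frac=1, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(average_monthly(t),
                                      average_monthly(shuffled))

    def test_zero_sum_perturbed_replicates_recover_cell_means(self, rng):
        # k replicates per cell whose perturbations sum to zero: the mean
        # must reproduce the original cell value exactly
        base = raw([("X", 2001, m, float(v))
                    for m, v in enumerate(rng.uniform(1, 9, 12), start=1)])
        k = 4
        reps = []
        for _, row in base.iterrows():
            eps = rng.normal(0, 0.1, k - 1)
            eps = np.append(eps, -eps.sum())
            for e in eps:
                reps.append((row["species"], row["year"], row["month"],
                             row["abundance"] + e))
        out = average_monthly(raw(reps))
        np.testing.assert_allclose(out["abundance"].to_numpy(),
                                   base["abundance"].to_numpy(), atol=1e-12)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            average_monthly(raw([("X", 2000, 5, -1.0)]))


class TestOccurrenceFilter:
    def _table(self, n_present, n_total, species="Pomatoschistus sp"):
        rows = [(species, 2000, 1, 1.0)] * n_present
        rows += [(species, 2000, 1, 0.0)] * (n_total - n_present)
        return raw(rows)

    def test_frequent_species_retained_with_percentage(self):
        out = filter_by_occurrence(self._table(735, 1000))
        assert list(out["species"]) == ["Pomatoschistus sp"]
        assert out.loc[0, "frequency_pct"] == pytest.approx(73.5)

    def test_rare_species_dropped(self):
        out_all = pd.concat([self._table(19, 1000, "rare"),
                             self._table(1000, 1000, "common")])
        out = filter_by_occurrence(out_all)
        assert list(out["species"]) == ["common"]
        assert out.loc[0, "frequency_pct"] == pytest.approx(100.0)

    def test_exact_threshold_excluded(self):
        out_all = pd.concat([self._table(20, 1000, "edge"),
                             self._table(30, 1000, "keep")])
        out = filter_by_occurrence(out_all, threshold=0.02)
        assert list(out["species"]) == ["keep"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_by_occurrence(raw([]))


class TestEcologicalYear:
    @pytest.mark.parametrize("cal, start, eco", [
        ((1986, 2), 3, (1985, 12)),   # Feb belongs to the previous March year
        ((1990, 7), 7, (1990, 1)),
        ((1985, 3), 3, (1985, 1)),
        ((2000, 12), 1, (2000, 12)),
    ])
    def test_date_mapping(self, cal, start, eco):
        ey, em = calendar_to_eco(cal[0], cal[1], start)
        assert (int(ey), int(em)) == eco

    def test_january_start_is_identity(self):
        t = raw([("X", 2000, m, float(m)) for m in range(1, 13)])
        out = to_ecological_year(t, 1)
        assert (out["eco_year"] == 2000).all()
        assert list(out["eco_month"]) == list(range(1, 13))

    def test_remap_is_bijection_preserving_values(self, rng):
        t = raw([("X", y, m, float(rng.uniform()))
                 for y in (1999, 2000) for m in range(1, 13)])
        out = to_ecological_year(t, "March")
        assert sorted(out["abundance"]) == sorted(t["abundance"])
        assert out.groupby(["eco_year", "eco_month"]).size().max() == 1

    def test_per_species_start_months(self):
        t = raw([("spring", 1990, 2, 1.0), ("winter", 1990, 2, 1.0)])
        out = to_ecological_year(t, {"spring": 3, "winter": "July"})
        spring = out[out["species"] == "spring"].iloc[0]
        winter = out[out["species"] == "winter"].iloc[0]
        assert (spring["eco_year"], spring["eco_month"]) == (1989, 12)
        assert (winter["eco_year"], winter["eco_month"]) == (1989, 8)


class TestYearlyPatterns:
    def eco(self, rows):
        return pd.DataFrame(rows, columns=["species", "eco_year",
                                           "eco_month", "abundance"])

    def test_normalisation(self):
        t = self.eco([("X", 2000, m, a) for m, a in
                      [(5, 10.0), (6, 30.0), (7, 60.0)]])
        out = to_yearly_patterns(t, ZeroFillPolicy(epsilon=1e-9))
        p = out[PATTERN_COLS].to_numpy()[0]
        assert p[4:7] == pytest.approx([0.1, 0.3, 0.6], abs=1e-6)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_month_year_is_near_indicator_vector(self):
        t = self.eco([("X", 2000, 4, 5.0)])
        out = to_yearly_patterns(t, ZeroFillPolicy(epsilon=1e-3))
        p = out[PATTERN_COLS].to_numpy()[0]
        assert p.argmax() == 3
        assert p[3] > 0.98
        assert (p > 0).all()

    def test_zero_total_year_dropped(self):
        t = self.eco([("X", 2000, 5, 0.0), ("X", 2001, 5, 3.0)])
        out = to_yearly_patterns(t)
        assert list(out["eco_year"]) == [2001]

    def test_noiseless_patterns_equal_generator_draws(self):
        base = 0.9 * _bump_pattern(6.0, 4) + 0.1 / 12
        base /= base.sum()
        sc = SpeciesScenario("a", [base], concentration=30.0,
                             eco_year_start=1)
        table, truth = generate_dataset(SimulationConfig(
            periods=(("P1", 1, 10),), species=[sc], seed=2))
        monthly = to_ecological_year(average_monthly(table), 1)
        pats = to_yearly_patterns(monthly)
        got = pats.sort_values("eco_year")[PATTERN_COLS].to_numpy()
        want = truth.yearly_patterns.sort_values("eco_year")[
            PATTERN_COLS].to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_aggregate_observed_keeps_structural_zeros(self):
        rows = [("z", y, m, 1.0) for y in (2000, 2001) for m in range(1, 10)]
        out = to_yearly_patterns(self.eco(rows),
                                 ZeroFillPolicy("aggregate-observed"))
        p = out[PATTERN_COLS].to_numpy()
        assert (p[:, 9:] == 0).all()
        assert p.sum(1) == pytest.approx([1.0, 1.0], abs=1e-9)


class TestModality:
    def test_single_bump_is_unimodal(self):
        assert detect_modality(_bump_pattern(6.0, 3)) == "unimodal"

    def test_two_separated_peaks_are_bimodal(self):
        p = _bump_pattern(3.0, 1) + _bump_pattern(9.0, 1)
        assert detect_modality(p / p.sum()) == "bimodal"

    def test_minor_secondary_peak_stays_unimodal(self):
        p = _bump_pattern(4.0, 2) + 0.1 * _bump_pattern(10.0, 1)
        assert detect_modality(p / p.sum()) == "unimodal"
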