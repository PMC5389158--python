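from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirest import (
    Individual,
    PYTable,
    RateTable,
    adjust_person_years,
    expected_py_individual,
    lexis_expand,
    raw_person_years,
    simulate_individual,
    yearly_expected_py,
)

DAYS = 365.25


def flat_gamma(rate):
    return RateTable.from_records(
        [{"age_low": 0, "age_high": None, "year_low": 1900, "year_high": 2100,
          "sex": "any", "rate": rate}],
        name="gamma",
    )


class TestIndividual:
    def test_ordering_constraints(self):
        with pytest.raises(ValueError, match="entry"):
            Individual("x", "any", date(1990, 1, 1), date(1980, 1, 1))
        with pytest.raises(ValueError, match="diagnosis"):
            Individual("x", "any", date(1950, 1, 1), date(1990, 1, 1), date(1989, 1, 1))


class TestLexisExpand:
    def test_single_year_single_cell(self):
        ind = Individual("x", "any", date(1950, 1, 1), date(1990, 1, 1))
        segs = lexis_expand(ind, date(1991, 1, 1), 5.0)
        assert len(segs) == 1
        group, year, dur = segs[0]
        assert (group, year) == (40.0, 1990)
        assert dur == pytest.approx(1.0, abs=0.01)

    def test_zero_interval_is_empty(self):
        ind = Individual("x", "any", date(1950, 1, 1), date(1990, 1, 1))
        assert lexis_expand(ind, date(1990, 1, 1), 5.0) == []

    def test_end_before_entry_rejected(self):
        ind = Individual("x", "any", date(1950, 1, 1), date(1990, 1, 1))
        with pytest.raises(ValueError):
            lexis_expand(ind, date(1989, 12, 31), 5.0)

    def test_splits_at_age_and_year_boundaries(self):
        # born mid-1950: crosses age 40 on 1990-07-01-ish, plus two Jan 1 splits
        ind = Individual("x", "any", date(1950, 7, 1), date(1990, 1, 1))
        segs = lexis_expand(ind, date(1992, 1, 1), 5.0)
        assert [(g, y) for g, y, _ in segs] == [
            (35.0, 1990), (40.0, 1990), (40.0, 1991)
        ]
        total = sum(d for _, _, d in segs)
        assert total == pytest.approx((date(1992, 1, 1) - date(1990, 1, 1)).days / DAYS)

    @given(
        birth_off=st.integers(0, 15000),
        entry_off=st.integers(0, 20000),
        length=st.integers(0, 8000),
        width=st.sampled_from([1.0, 5.0, 10.0]),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_over_random_dates(self, birth_off, entry_off, length, width):
        birth = date(1930, 1, 1) + timedelta(days=birth_off)
        entry = birth + timedelta(days=entry_off)
        end = entry + timedelta(days=length)
        ind = Individual("x", "any", birth, entry)
        segs = lexis_expand(ind, end, width)
        assert sum(d for _, _, d in segs) == pytest.approx(length / DAYS, abs=1e-9)
        assert all(d > 0 for _, _, d in segs)


class TestRawPersonYears:
    def test_noncase_accrues_to_study_end(self, worked_cohort, study_end):
        raw, cases = raw_person_years(worked_cohort[:1], study_end)
        assert raw.total() == pytest.approx(15.0, abs=0.01)
        assert cases.total() == 0.0

    def test_linearity_over_identical_individuals(self, worked_cohort, study_end):
        raw, _ = raw_person_years(worked_cohort, study_end)
        assert raw.total() == pytest.approx(15000.0, abs=10.0)

    def test_case_time_goes_to_cases_table(self, study_end):
        ind = Individual("c", "any", date(1950, 1, 1), date(1990, 1, 1),
                         diagnosis_date=date(1991, 1, 1))
        raw, cases = raw_person_years([ind], study_end)
        assert raw.total() == 0.0
        assert cases.total() == pytest.approx(1.0, abs=0.01)

    def test_diagnosis_after_study_end_is_noncase(self, study_end):
        ind = Individual("c", "any", date(1950, 1, 1), date(1990, 1, 1),
                         diagnosis_date=date(2010, 6, 1))
        raw, cases = raw_person_years([ind], study_end)
        assert cases.total() == 0.0
        assert raw.total() == pytest.approx(15.0, abs=0.01)


class TestYearlyExpectedPy:
    def test_first_year_half_credit(self):
        assert yearly_expected_py([0.015])[0] == pytest.approx(0.9925)

    def test_second_year_thousand_cohort(self):
        vals = yearly_expected_py([0.015, 0.015])
        assert 1000 * vals[0] == pytest.approx(992.5)
        assert 1000 * vals[1] == pytest.approx(977.612, abs=1e-3)

    def test_zero_rates_identity(self):
        assert np.allclose(yearly_expected_py([0.0] * 10), 1.0)


class TestExpectedPyIndividual:
    def test_zero_gamma_equals_raw(self, reference_individual, study_end):
        tab = expected_py_individual(reference_individual, flat_gamma(0.0), study_end)
        raw, _ = raw_person_years([reference_individual], study_end)
        assert tab.total() == pytest.approx(raw.total(), abs=1e-9)
        assert dict(tab.cells()) == pytest.approx(dict(raw.cells()))

    def test_worked_individual_fifteen_year_total(
        self, reference_individual, gamma, study_end
    ):
        tab = expected_py_individual(reference_individual, gamma, study_end)
        # per-year display rounding in the reference total allows <= 0.3%
        assert tab.total() == pytest.approx(13.487, rel=3e-3)
        yearly = [sum(v for (a, y, s), v in tab.data.items() if y == yr)
                  for yr in range(1990, 2005)]
        assert yearly[0] == pytest.approx(0.992, abs=2e-3)
        assert yearly[1] == pytest.approx(0.978, abs=2e-3)
        # later display years drift up to ~1% from the exact recursion
        assert yearly[14] == pytest.approx(0.816, abs=1e-2)

    def test_case_is_rejected(self, gamma, study_end):
        case = Individual("c", "any", date(1950, 1, 1), date(1990, 1, 1),
                          diagnosis_date=date(1995, 5, 5))
        with pytest.raises(ValueError, match="incident case"):
            expected_py_individual(case, gamma, study_end)

    def test_monte_carlo_mean_matches_closed_form(self, gamma):
        # discrete-annual loss model: the half-year credit is the exact
        # conditional expectation, so 10k replicates must bracket the
        # closed form within 3 standard errors
        g = [gamma.lookup(40 + t, 1990 + t) for t in range(15)]
        expected = yearly_expected_py(g).sum()
        rng = np.random.default_rng(20260927)
        zeros = np.zeros(15)
        draws = np.array([
            simulate_individual(zeros, np.asarray(g), zeros, 15, rng)[2]
            for _ in range(10_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se


class TestAdjustPersonYears:
    def test_zero_gamma_identity(self, worked_cohort, study_end):
        raw, _ = raw_person_years(worked_cohort, study_end)
        adj = adjust_person_years(raw, flat_gamma(0.0))
        assert adj.total() == pytest.approx(raw.total(), abs=1e-9)

    def test_first_year_literal_and_credited_accounting(self):
        raw = PYTable("raw", 5.0)
        raw.add(40, 1990, "any", 1000.0)
        raw.add(40, 1991, "any", 1000.0)
        g = flat_gamma(0.015)
        literal = adjust_person_years(raw, g, 5.0)
        assert literal.get(40, 1990, "any") == pytest.approx(985.0)
        # synchronized cohort in one group: the no-aging accounting applies
        credited = adjust_person_years(raw, g, 5.0, year_of_loss_credit=0.5,
                                       aging=False)
        assert credited.get(40, 1990, "any") == pytest.approx(992.5)
        assert credited.get(40, 1991, "any") == pytest.approx(977.612, abs=1e-3)

    def test_requires_raw_role(self):
        with pytest.raises(ValueError, match="raw"):
            adjust_person_years(PYTable("cases"), flat_gamma(0.01))

    def test_dominance_and_monotonicity_in_gamma(self, worked_cohort, study_end):
        raw, _ = raw_person_years(worked_cohort, study_end, 20.0)
        lo = adjust_person_years(raw, flat_gamma(0.01), 20.0)
        hi = adjust_person_years(raw, flat_gamma(0.02), 20.0)
        assert hi.total() < lo.total() < raw.total()

    def test_aggregate_matches_individual_on_common_entry_cohort(
        self, worked_cohort, gamma, study_end
    ):
        # one broad age group, half-year credit: the aggregate iteration
        # and the per-individual recursion are the same accounting
        raw, _ = raw_person_years(worked_cohort, study_end, 20.0)
        agg = adjust_person_years(raw, gamma, 20.0, year_of_loss_credit=0.5,
                                  aging=False)
        per = 1000 * expected_py_individual(
            worked_cohort[0], gamma, study_end, 20.0
        ).total()
        assert agg.total() == pytest.approx(per, rel=5e-3)

    def test_aggregate_matches_individual_on_staggered_toy(
        self, staggered_toy, gamma
    ):
        end = date(1999, 12, 31)
        raw, _ = raw_person_years(staggered_toy, end, 5.0)
        agg = adjust_person_years(raw, gamma, 5.0, year_of_loss_credit=0.5)
        per = sum(
            expected_py_individual(i, gamma, end, 5.0).total()
            for i in staggered_toy
        )
        assert agg.total() == pytest.approx(per, rel=2e-2)

    def test_sparse_cell_floored_not_negative(self, caplog):
        raw = PYTable("raw", 5.0)
        raw.add(40, 1990, "any", 10.0)
        raw.add(40, 1991, "any", 0.01)  # carried loss exceeds this cell
        with caplog.at_level("WARNING", logger="sirest.person_time"):
            adj = adjust_person_years(raw, flat_gamma(0.9), 5.0)
        assert all(v >= 0 for _, v in adj.cells())
        assert any("floored" in rec.message for rec in caplog.records)
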