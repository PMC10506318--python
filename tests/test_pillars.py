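"""Per-pillar consumption formulas: sessions, group work, stay workload, home care."""

import pytest
from hypothesis import given, strategies as st

import midwdemand as md
from midwdemand import pillars as pl
from midwdemand.caseload import stratify
from midwdemand.params import ValidationError, apply_overlay


@pytest.fixture(scope="module")
def weights(common):
    return pl.DayWeightTable.from_params(common)


class TestPrenatalMinutes:
    def test_scenario_a_2041_low_risk_primiparous(self, common, scenarios):
        # n = 5.0 sessions: (52 + 4*30) * 1.20
        params = apply_overlay(common, scenarios["A"])
        minutes = pl.prenatal_minutes_per_pregnancy(
            params, 2041, "low", "primiparous", vulnerable=False
        )
        assert minutes == pytest.approx(206.4)

    def test_single_session_is_first_session_only(self, common, constant_setter):
        params = constant_setter(common, "coordination_uplift", 0.0, unit="proportion")
        params = constant_setter(params, "n_prenatal_low[primiparous]", 1.0)
        minutes = pl.prenatal_minutes_per_pregnancy(
            params, 2016, "low", "primiparous", vulnerable=False
        )
        assert minutes == pytest.approx(52.0)

    def test_fractional_sessions_high_risk_vulnerable(self, common, constant_setter):
        # 52 + 0.4*35 + 1.4*15
        params = constant_setter(common, "coordination_uplift", 0.0, unit="proportion")
        params = constant_setter(params, "n_prenatal_modhigh", 1.4)
        minutes = pl.prenatal_minutes_per_pregnancy(
            params, 2016, "modhigh", "primiparous", vulnerable=True
        )
        assert minutes == pytest.approx(87.0)

    def test_negative_session_count_rejected(self, common, constant_setter):
        params = constant_setter(common, "n_prenatal_modhigh", -0.5)
        with pytest.raises(ValidationError):
            pl.prenatal_minutes_per_pregnancy(params, 2016, "modhigh", "primiparous", False)


class TestBirthPrepMinutes:
    def test_base_year_not_vulnerable(self, common):
        # 0.6*60 + 0.4*(120/7)
        minutes = pl.birthprep_minutes_per_pregnancy(common, 2016, "primiparous", False)
        assert minutes == pytest.approx(0.6 * 60 + 0.4 * 120 / 7)

    def test_vulnerability_adds_two_individual_sessions_from_2026(self, common):
        base = pl.birthprep_minutes_per_pregnancy(common, 2026, "multiparous", False)
        vuln = pl.birthprep_minutes_per_pregnancy(common, 2026, "multiparous", True)
        assert vuln - base == pytest.approx(2.0 * 60)

    def test_zero_session_counts_give_zero(self, common, constant_setter):
        params = common
        for parity in ("primiparous", "multiparous"):
            params = constant_setter(params, f"n_birthprep_ind[{parity}]", 0.0)
            params = constant_setter(params, f"n_birthprep_group[{parity}]", 0.0)
        assert pl.birthprep_minutes_per_pregnancy(params, 2016, "primiparous", False) == 0.0

    def test_nonpositive_group_size_rejected(self, common, constant_setter):
        params = constant_setter(common, "group_session_size", 0.0)
        with pytest.raises(ValidationError):
            pl.birthprep_minutes_per_pregnancy(params, 2016, "primiparous", False)


class TestStayWorkload:
    @pytest.mark.parametrize(
        "alos, expected",
        [
            (3.0, 376.0),          # 155 + 129 + 92
            (3.7, 434.8),          # 376 + 0.7 * 84
            (0.0, 0.0),
            (6.0, 614.0),          # day 6 reuses the day-5 weight 77
        ],
    )
    def test_severity_one_examples(self, weights, alos, expected):
        assert pl.stay_workload(weights, "1", alos) == pytest.approx(expected)

    def test_unknown_severity_rejected(self, weights):
        with pytest.raises(ValidationError):
            pl.stay_workload(weights, "9", 3.0)

    def test_negative_stay_rejected(self, weights):
        with pytest.raises(ValidationError):
            pl.stay_workload(weights, "1", -1.0)

    @given(
        alos=st.floats(0.0, 12.0),
        step=st.floats(0.01, 1.0),
        soi=st.sampled_from(["1", "2", "3_4"]),
    )
    def test_nondecreasing_with_bounded_increments(self, weights, alos, step, soi):
        # increments per day are bounded by the largest day weight (for
        # severity 2 the day-2 weight exceeds the day-1 weight)
        lo = pl.stay_workload(weights, soi, alos)
        hi = pl.stay_workload(weights, soi, alos + step)
        w_max = max(weights.weight(soi, d) for d in range(1, 6))
        assert 0.0 <= hi - lo <= step * w_max + 1e-9


class TestInpatient:
    def test_scenario_c_uses_reduced_alos(self, common, scenarios):
        params = apply_overlay(common, scenarios["C"])
        assert params.value("alos[560][1][25_34]", 2026) == pytest.approx(2.0)

    def test_single_cell_casemix_degenerates_to_one_workload(self, common, weights):
        cell = ("560", "1", "25_34")
        table = stratify(common, 2026, casemix={cell: 1.0})
        expected = table.total_stays * pl.stay_workload(
            weights, "1", common.value("alos[560][1][25_34]", 2026)
        )
        assert pl.inpatient_consumption(table, common, 2026) == pytest.approx(expected)

    def test_per_stay_workload_drop_2016_to_2026(self, common, weights):
        w16 = pl.stay_workload(weights, "1", common.value("alos[560][1][25_34]", 2016))
        w26 = pl.stay_workload(weights, "1", common.value("alos[560][1][25_34]", 2026))
        assert (w16, w26) == (pytest.approx(434.8), pytest.approx(376.0))
        assert w26 / w16 - 1 == pytest.approx(-0.135, abs=5e-4)


class TestOutpatientPostnatal:
    def test_scenario_c_primiparous_2026_without_early_component(self, common, scenarios):
        # (7.0 + 0.1 + 0.4) * 1.22
        params = apply_overlay(common, scenarios["C"])
        services = pl.outpatient_services_per_pregnancy(params, 2026, "primiparous", early=0.0)
        assert services == pytest.approx(9.15)

    def test_early_component_observed_in_2016(self, common, casemix):
        assert pl.early_postnatal_services(common, casemix, 2016) == pytest.approx(0.8)

    def test_early_component_zero_once_stays_reach_five_days(self, common):
        long_stay = {("540", "3_4", "25_34"): 1.0}  # ALOS 7.0 days in 2026
        assert pl.early_postnatal_services(common, long_stay, 2026) == 0.0

    def test_early_component_home_day_rule(self, common, casemix):
        alos = pl.mean_alos(common, casemix, 2026)
        early = pl.early_postnatal_services(common, casemix, 2026)
        assert early == pytest.approx(max(0.0, 5.0 - alos))

    def test_per_stay_convention_flag(self, common, casemix):
        assert pl.early_postnatal_services(common, casemix, 2026, "per_stay") == 1.0


class TestPillarSeries:
    def test_every_pillar_scales_linearly_in_total_stays(self, common, casemix):
        from midwdemand.caseload import CaseloadTable

        table = stratify(common, 2026, casemix=casemix)
        doubled = CaseloadTable(
            year=table.year,
            total_stays=2 * table.total_stays,
            strata={k: 2 * v for k, v in table.strata.items()},
            casemix=table.casemix,
        )
        for fn in (
            pl.prenatal_consumption,
            pl.birth_prep_consumption,
            pl.inpatient_consumption,
            pl.outpatient_postnatal_consumption,
            pl.other_consumption,
        ):
            assert fn(doubled, common, 2026) == pytest.approx(2 * fn(table, common, 2026))

    def test_scenario_with_baseline_values_reproduces_baseline(self, common, scenarios, casemix, key):
        """An overlay that re-states the common trajectories changes nothing."""
        echo = md.ScenarioSpec(
            "A", {tid: common.trajectories[tid] for tid in scenarios["A"].overrides}
        )
        years = [2021, 2031]
        base = md.run_scenario(common, scenarios["baseline"], casemix, key, years)
        same = md.run_scenario(common, echo, casemix, key, years)
        assert base.totals == same.totals

    def test_frozen_other_pillar_is_constant(self, common, casemix):
        table16 = stratify(common, 2016, casemix=casemix)
        table41 = stratify(common, 2041, casemix=casemix)
        assert pl.other_consumption(table41, common, 2041, "frozen") == pytest.approx(
            pl.other_consumption(table16, common, 2016, "frozen")
        )
        assert pl.other_consumption(table41, common, 2041) > pl.other_consumption(
            table16, common, 2016
        )
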