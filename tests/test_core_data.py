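"""Unit canonicalization, domain-type invariants and CSV round-trips."""
import math

import pytest

from nutlim.core_data import (
    Concentration,
    Experiment,
    Level,
    LimitationResult,
    Nutrient,
    Treatment,
    format_added,
    format_limitation,
    parse_added,
    parse_limitation,
    read_experiments,
    read_growth_responses,
    read_station_table,
    write_experiments,
    write_results,
)
from nutlim.growth_rates import compute_responses


class TestConcentration:
    @pytest.mark.parametrize(
        "value,unit,molar",
        [(1.0, "umol/L", 1e-6), (1000.0, "nmol/L", 1e-6),
         (1e6, "pmol/L", 1e-6)],
    )
    def test_unit_canonicalization_exact(self, value, unit, molar):
        assert Concentration(value, unit).molar == molar

    def test_general_conversion(self):
        assert Concentration(2.5, "nmol/L").molar == pytest.approx(2.5e-9, rel=1e-15)

    def test_micro_sign_alias(self):
        assert Concentration(1.0, "µmol/L").unit == "umol/L"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            Concentration(-0.1, "umol/L")

    def test_below_detection_flag_keeps_limit_value(self):
        c = Concentration(0.02, "nmol/L", below_detection=True)
        assert c.below_detection
        assert c.molar == pytest.approx(2e-11, rel=1e-15)


class TestAddedSetParsing:
    def test_combined_addition(self):
        assert parse_added("N+Fe") == frozenset({Nutrient.N, Nutrient.Fe})

    def test_empty_is_control(self):
        assert parse_added("") == frozenset()

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="unknown nutrient"):
            parse_added("N+Xx")

    def test_format_sorted(self):
        assert format_added({Nutrient.Fe, Nutrient.N}) == "Fe+N"


class TestLimitationCodec:
    @pytest.mark.parametrize(
        "text", ["N", "Fe+N", "Fe&N", "N>Fe", "N>Fe>Co", "Fe+N>Co",
                 "replete", "indeterminate"],
    )
    def test_round_trip(self, text):
        assert format_limitation(parse_limitation(text)) == text

    def test_tertiary_structure(self):
        res = parse_limitation("N>Fe>Co")
        assert [lv.sorted_symbols() for lv in res.levels] == [["N"], ["Fe"], ["Co"]]

    def test_nutrient_repeat_across_levels_rejected(self):
        with pytest.raises(ValueError, match="repeat"):
            LimitationResult(
                category="limited",
                levels=[Level({Nutrient.N}), Level({Nutrient.N})],
            )


class TestExperimentInvariants:
    def test_duplicate_added_set_rejected(self):
        t1 = Treatment(added={Nutrient.N}, chl_final=(1, 1, 1))
        t2 = Treatment(added={Nutrient.N}, chl_final=(2, 2, 2), label="again")
        with pytest.raises(ValueError, match="duplicate"):
            Experiment(id="x", latitude=0, longitude=0, duration=2,
                       chl_initial=0.2, treatments=[t1, t2])

    def test_longitude_normalized(self):
        e = Experiment(id="x", latitude=0, longitude=270.0, duration=2,
                       chl_initial=0.2)
        assert e.longitude == -90.0

    def test_classifiable_requires_triplicates_and_control(self):
        ctrl = Treatment(added=set(), chl_final=(1, 1, 1))
        n2 = Treatment(added={Nutrient.N}, chl_final=(2, 2))
        e = Experiment(id="x", latitude=0, longitude=0, duration=2,
                       chl_initial=0.2, treatments=[ctrl, n2])
        assert not e.classifiable()


class TestExperimentCSV:
    def _toy_csv(self, tmp_path, extra_rows=""):
        header = ("experiment_id,lat,lon,duration_d,chl_initial_ugL,"
                  "added_nutrients,chl_final_ugL,nutrient_N_umolL")
        rows = ["e1,10,-30,2,0.2,,0.21,0.5", "e1,10,-30,2,0.2,,0.19,0.5",
                "e1,10,-30,2,0.2,,0.20,0.5", "e1,10,-30,2,0.2,N,0.60,0.5",
                "e1,10,-30,2,0.2,N,0.62,0.5", "e1,10,-30,2,0.2,N,0.58,0.5"]
        p = tmp_path / "exp.csv"
        p.write_text("\n".join([header] + rows + ([extra_rows] if extra_rows else [])) + "\n")
        return p

    def test_minimal_long_form(self, tmp_path):
        result = read_experiments(self._toy_csv(tmp_path))
        assert len(result) == 1 and not result.rejections
        (exp,) = result
        assert len(exp.treatments) == 2
        assert exp.control is not None
        assert exp.nutrients[Nutrient.N].molar == 0.5e-6

    def test_combined_addition_parsed_as_set(self, tmp_path):
        p = self._toy_csv(tmp_path, extra_rows="e1,10,-30,2,0.2,N+Fe,1.0,0.5")
        (exp,) = read_experiments(p)
        assert frozenset({Nutrient.N, Nutrient.Fe}) in {t.added for t in exp.treatments}

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("experiment_id,lat,lon\ne1,0,0\n")
        with pytest.raises(ValueError, match="duration_d"):
            read_experiments(p)

    def test_wide_dialect(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text(
            "experiment_id,lat,lon,duration_d,chl_initial_ugL,added_nutrients,"
            "chl_final_1,chl_final_2,chl_final_3\n"
            "e1,10,-30,2,0.2,,0.2,0.21,0.19\n"
            "e1,10,-30,2,0.2,N,0.6,0.58,0.62\n"
        )
        result = read_experiments(p, {"dialect": "wide"})
        assert len(result) == 1 and len(result.experiments[0].treatments) == 2

    def test_round_trip_identity_on_synthetic_survey(self, tmp_path, small_survey):
        path = tmp_path / "survey.csv"
        write_experiments(small_survey.experiments, path)
        back = read_experiments(path)
        assert not back.rejections
        assert len(back) == len(small_survey.experiments)
        for a, b in zip(small_survey.experiments, back.experiments):
            assert a.id == b.id
            assert a.latitude == pytest.approx(b.latitude)
            assert a.temperature == pytest.approx(b.temperature)
            assert format_limitation(a.recorded_limitation) == \
                format_limitation(b.recorded_limitation)
            ta = {t.added: t.chl_final for t in a.treatments}
            tb = {t.added: t.chl_final for t in b.treatments}
            assert ta.keys() == tb.keys()
            for k in ta:
                assert ta[k] == pytest.approx(tb[k])
            for nut, conc in a.nutrients.items():
                assert conc.molar == pytest.approx(b.nutrients[nut].molar)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        assert len(read_experiments(p)) == 0


class TestStationCSV:
    def test_three_stations(self, tmp_path):
        p = tmp_path / "st.csv"
        p.write_text(
            "station_id,lat,lon,depth_m,nutrient_N_umolL,nutrient_P_umolL,"
            "nutrient_Fe_nmolL\n"
            "s1,0,0,5,1.0,0.1,0.5\ns2,10,10,2,2.0,0.2,1.0\ns3,20,20,8,0.1,0.3,2.0\n"
        )
        assert len(read_station_table(p)) == 3

    def test_deep_station_excluded(self, tmp_path):
        p = tmp_path / "st.csv"
        p.write_text("station_id,lat,lon,depth_m,nutrient_N_umolL\n"
                     "s1,0,0,25,1.0\ns2,0,0,5,1.0\n")
        stations = read_station_table(p)
        assert [s.id for s in stations] == ["s2"]

    def test_no_nutrient_column_is_schema_error(self, tmp_path):
        p = tmp_path / "st.csv"
        p.write_text("station_id,lat,lon\ns1,0,0\n")
        with pytest.raises(ValueError, match="nutrient"):
            read_station_table(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "st.csv"
        p.write_text("")
        assert read_station_table(p) == []


class TestResultsRoundTrip:
    def test_growth_responses_round_trip(self, tmp_path, small_survey):
        responses = compute_responses(small_survey.experiments[:3])
        path = tmp_path / "resp.csv"
        write_results(responses, path)
        back = read_growth_responses(path)
        assert len(back) == len(responses)
        for a, b in zip(responses, back):
            assert a.added == b.added
            assert a.mu_net == pytest.approx(b.mu_net)
            assert (a.mu_rel is None) == (b.mu_rel is None)
            if a.mu_rel is not None:
                assert a.mu_rel == pytest.approx(b.mu_rel)

    def test_empty_collection_writes_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_results([], path)
        assert path.exists()

    def test_tertiary_limitation_serialized_as_level_list(self, tmp_path):
        res = parse_limitation("N>Fe>Co")
        path = tmp_path / "lim.csv"
        write_results([("e1", res)], path)
        text = path.read_text()
        assert "N>Fe>Co" in text


def test_rejection_report_for_duplicate_added_set(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text(
        "experiment_id,lat,lon,duration_d,chl_initial_ugL,treatment_label,"
        "added_nutrients,chl_final_ugL\n"
        "e1,0,0,2,0.2,ctl,,0.2\ne1,0,0,2,0.2,ctl,,0.2\ne1,0,0,2,0.2,ctl,,0.2\n"
        "e1,0,0,2,0.2,a,N,0.5\ne1,0,0,2,0.2,a,N,0.5\ne1,0,0,2,0.2,a,N,0.5\n"
        # same added-set under a different label -> duplicate
        "e1,0,0,2,0.2,b,N ,0.6\ne1,0,0,2,0.2,b,N ,0.6\ne1,0,0,2,0.2,b,N ,0.6\n"
    )
    result = read_experiments(p)
    assert len(result) == 0
    assert len(result.rejections) == 1
    assert "duplicate" in result.rejections[0]["reason"]
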