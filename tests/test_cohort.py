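import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertemetry.cohort import (
    PatientRecord,
    REGIONS,
    aggregate_levels,
    classify_region,
    classify_severity,
    findings_report,
    main_curve,
    regional_means,
)
from vertemetry.morphometry import VERTEBRAL_LEVELS

from conftest import make_measurement, random_cohort

SEV_RANK = {"mild": 0, "medium": 1, "strong": 2}


class TestClassifySeverity:
    @pytest.mark.parametrize("angle, expected", [
        (15.0, "mild"), (19.99, "mild"),
        (20.0, "medium"), (30.0, "medium"), (40.0, "medium"),
        (40.01, "strong"), (41.0, "strong"),
    ])
    def test_boundaries(self, angle, expected):
        assert classify_severity(angle) == expected

    def test_negative_angle_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(-1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 90), st.floats(0, 90))
    def test_monotone(self, a, b):
        if a < b:
            assert SEV_RANK[classify_severity(a)] <= SEV_RANK[classify_severity(b)]


class TestClassifyRegion:
    @pytest.mark.parametrize("curves, expected", [
        ([(50.0, "T8")], "thoracic"),
        ([(35.0, "T12")], "thoraco-lumbar"),
        ([(35.0, "L1")], "thoraco-lumbar"),
        ([(30.0, "L3")], "lumbar"),
        ([(30.0, "T7"), (28.0, "L3")], "combined"),
        ([(30.0, "T12"), (28.0, "L1")], "thoraco-lumbar"),  # TL apexes alone not combined
    ])
    def test_rules(self, curves, expected):
        assert classify_region(curves) == expected

    def test_unclassifiable_apex(self):
        with pytest.raises(ValueError):
            classify_region([(30.0, "C7")])

    def test_main_curve_tie_breaks_cranial(self):
        assert main_curve([(30.0, "L3"), (30.0, "T8")]) == (30.0, "T8")


def one_level_record(pid, level, L12, L13, curves=((30.0, "T8"),), gender="female"):
    return PatientRecord(pid, gender, curves, (make_measurement(level, L12, L13),))


class TestAggregateLevels:
    def test_mean_and_sample_sd(self):
        records = [one_level_record(f"P{i}", "T7", None, v) for i, v in enumerate([62, 58, 60])]
        table = aggregate_levels(records, "none").table
        row = table[table["level"] == "T7"].iloc[0]
        assert row["L13_mean"] == pytest.approx(60.0)
        assert row["L13_sd"] == pytest.approx(2.0)
        assert row["L13_n"] == 3

    def test_missing_L12_excluded(self):
        records = [
            one_level_record("P0", "T7", 62.0, 70.0),
            one_level_record("P1", "T7", None, 71.0),
            one_level_record("P2", "T7", 60.0, 72.0),
        ]
        row = aggregate_levels(records, "none").table.iloc[0]
        assert row["L12_mean"] == pytest.approx(61.0)
        assert row["L12_n"] == 2
        assert row["L13_n"] == 3

    def test_single_value_sd_undefined(self):
        row = aggregate_levels([one_level_record("P0", "L2", 70.0, 85.0)], "none").table.iloc[0]
        assert row["L13_mean"] == pytest.approx(85.0)
        assert math.isnan(row["L13_sd"])

    def test_duplicated_patient_leaves_means_unchanged(self):
        rng = np.random.default_rng(1)
        records = random_cohort(rng, n_patients=5)
        t1 = aggregate_levels(records, "severity").table
        t2 = aggregate_levels(records + [records[0]], "severity").table
        merged = t1.merge(t2, on=["group", "level"], suffixes=("_a", "_b"))
        dup_group = None
        from vertemetry.cohort import classify_severity as cs
        dup_group = cs(main_curve(records[0].curves)[0])
        for _, row in merged.iterrows():
            if row["group"] != dup_group:
                assert row["L13_mean_b"] == pytest.approx(row["L13_mean_a"], rel=1e-12)
                assert row["L13_n_b"] == row["L13_n_a"]
        # counts increase in the duplicated patient's group at its levels
        dup_levels = {m.level for m in records[0].measurements}
        extra = merged[(merged["group"] == dup_group) & merged["level"].isin(dup_levels)]
        assert (extra["L13_n_b"] == extra["L13_n_a"] + 1).all()


class TestRegionalMeans:
    def test_constant_patient_region(self):
        ms = tuple(make_measurement(lv, 60.0, 70.0) for lv in REGIONS["T2...T11"])
        rec = PatientRecord("P0", "female", ((25.0, "T8"),), ms)
        table = regional_means(aggregate_levels([rec], "none")).table
        row = table[table["level"] == "T2...T11"].iloc[0]
        assert row["L13_mean"] == pytest.approx(70.0)
        assert row["L13_sd"] == pytest.approx(0.0)

    def test_pooled_values_not_level_means(self):
        # two patients constant 60 / 80 over T12+L1: pooled {60,60,80,80},
        # sample SD = 11.547
        recs = []
        for pid, val in (("P0", 60.0), ("P1", 80.0)):
            ms = tuple(make_measurement(lv, None, val) for lv in ("T12", "L1"))
            recs.append(PatientRecord(pid, "male", ((35.0, "L1"),), ms))
        table = regional_means(aggregate_levels(recs, "none")).table
        row = table[table["level"] == "T12/L1"].iloc[0]
        assert row["L13_mean"] == pytest.approx(70.0)
        assert row["L13_sd"] == pytest.approx(statistics.stdev([60, 60, 80, 80]), rel=1e-12)
        assert row["L13_n"] == 4

    def test_all_row_pools_every_level(self):
        rng = np.random.default_rng(7)
        records = random_cohort(rng, n_patients=4)
        ct = regional_means(aggregate_levels(records, "none"))
        row = ct.table[ct.table["level"] == "all"].iloc[0]
        vals = ct.values["L13"].dropna()
        assert row["L13_mean"] == pytest.approx(vals.mean(), rel=1e-12)
        assert row["L13_n"] == len(vals)


def brute_force_table(records, grouping):
    """Independent oracle: plain-python aggregation."""
    from vertemetry.cohort import _group_of  # same grouping rule, trivial

    cells = {}
    for rec in records:
        g = _group_of(rec, grouping)
        for m in rec.measurements:
            cell = cells.setdefault((g, m.level), {"L12": [], "L13": []})
            if m.L12_mm is not None:
                cell["L12"].append(m.L12_mm)
            if m.L13_mm is not None:
                cell["L13"].append(m.L13_mm)
    out = {}
    for key, vals in cells.items():
        entry = {}
        for q in ("L12", "L13"):
            xs = vals[q]
            entry[f"{q}_mean"] = statistics.fmean(xs) if xs else None
            entry[f"{q}_sd"] = statistics.stdev(xs) if len(xs) >= 2 else None
            entry[f"{q}_n"] = len(xs)
        out[key] = entry
    return out


class TestAggregationOracle:
    @pytest.mark.parametrize("grouping", ["none", "severity", "region", "gender"])
    def test_matches_brute_force(self, grouping):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            records = random_cohort(rng)
            table = aggregate_levels(records, grouping).table
            oracle = brute_force_table(records, grouping)
            assert len(table) == len(oracle)
            for _, row in table.iterrows():
                exp = oracle[(row["group"], row["level"])]
                for col in ("L12_mean", "L12_sd", "L13_mean", "L13_sd"):
                    if exp[col] is None:
                        assert math.isnan(row[col])
                    else:
                        assert row[col] == pytest.approx(exp[col], rel=1e-12)
                assert row["L12_n"] == exp["L12_n"]
                assert row["L13_n"] == exp["L13_n"]


class TestFindingsReport:
    def test_constant_offset_gives_equal_sds(self):
        # L13 = L12 + constant per patient at a single level => SDs equal,
        # inequality (i) reported false
        records = []
        for i, base in enumerate([55.0, 60.0, 65.0]):
            ms = tuple(make_measurement(lv, base, base + 20.0) for lv in ("T5", "T6"))
            records.append(PatientRecord(f"P{i}", "female", ((25.0, "T8"),), ms))
        tables = {"none": aggregate_levels(records, "none")}
        rep = findings_report(tables)
        entry = rep["none"]["sd_L13_gt_sd_L12"]["all"]
        assert entry["sd_L13"] == pytest.approx(entry["sd_L12"], rel=1e-12)
        assert entry["holds"] is False

    def test_max_sd_region_detects_noisy_region(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(6):
            ms = []
            for lv in VERTEBRAL_LEVELS[2:]:
                noisy = lv in REGIONS["T2...T11"]
                L13 = 75.0 + (rng.normal(0, 12.0) if noisy else rng.normal(0, 1.0))
                ms.append(make_measurement(lv, 55.0, L13))
            records.append(PatientRecord(f"P{i}", "male", ((45.0, "T8"),), tuple(ms)))
        rep = findings_report({"region": aggregate_levels(records, "region")})
        entry = rep["region"]["max_sd_region_matches_curve_region"]["thoracic"]
        assert entry["max_sd_region"] == "thoracic"
        assert entry["holds"] is True

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        records = random_cohort(rng, n_patients=6)
        t = {"severity": aggregate_levels(records, "severity")}
        assert findings_report(t) == findings_report(t)

    def test_missing_group_not_evaluable(self):
        records = [one_level_record("P0", "T7", 55.0, 70.0, curves=((10.0, "T8"),))]
        rep = findings_report({"severity": aggregate_levels(records, "severity")})
        assert rep["severity"]["severity_sd_ordering_L13"]["holds"] is None
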