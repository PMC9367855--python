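"""Battery aggregation, discrepancy analysis, and correlations."""

import math

import numpy as np
import pytest

from promread.battery import (
    BatteryResult,
    SectionRow,
    analyze_battery,
    discrepancy_analysis,
    formula_correlations,
    length_readability_correlation,
    read_report_json,
    rows_from_reference,
    write_report_csv,
    write_report_json,
)
from promread.formulas import FORMULA_IDS, round_half_up
from promread.model import Questionnaire, Section, TextUnit


def make_row(name, section="items", ages=None, mean=None, target_min=None,
             n_words=None):
    ages = ages or {fid: 10.0 for fid in FORMULA_IDS}
    return SectionRow(
        questionnaire=name, section=section, reading_ages=ages,
        mean_reading_age=mean if mean is not None else sum(ages.values()) / 5,
        target_age_min=target_min, target_age_max=18, n_words=n_words,
    )


class TestReferenceFixture:
    def test_shape(self, reference_battery):
        assert len(reference_battery.section_rows("items")) == 21
        assert len(reference_battery.section_rows("instructions")) == 20

    def test_instrument_without_instructions(self, reference_battery):
        names = {r.questionnaire for r in reference_battery.section_rows("instructions")}
        assert "PQ-LES-Q" not in names

    def test_target_ages(self, reference_battery):
        row = next(
            r for r in reference_battery.section_rows("items")
            if r.questionnaire == "EQ-5D-Y"
        )
        assert (row.target_age_min, row.target_age_max) == (8, 15)

    def test_age_group_counts(self, reference_battery):
        groups = [r.age_group for r in reference_battery.section_rows("items")]
        assert groups.count("child") == 4
        assert groups.count("adolescent") == 8
        assert groups.count("child_and_adolescent") == 9


class TestSummary:
    def test_single_row_summary_is_the_row(self):
        row = make_row("only", ages={f: a for f, a in zip(FORMULA_IDS, [8, 9, 10, 11, 12])})
        result = BatteryResult(rows=[row])
        summary = result.summary("items")
        assert summary["CLI"]["mean"] == 8.0
        assert summary["mean"]["mean"] == pytest.approx(row.mean_reading_age)
        assert summary["mean"]["sd"] == 0.0

    def test_summary_recomputable_from_rows(self, reference_battery):
        summary = reference_battery.summary("items")
        means = [r.mean_reading_age for r in reference_battery.section_rows("items")]
        assert summary["mean"]["mean"] == pytest.approx(np.mean(means))
        assert summary["mean"]["sd"] == pytest.approx(np.std(means, ddof=1))
        assert summary["mean"]["min"] == min(means)
        assert summary["mean"]["max"] == max(means)

    def test_summary_invariant_to_row_order(self, reference_battery):
        reversed_result = BatteryResult(rows=list(reversed(reference_battery.rows)))
        forward = reference_battery.summary("items")
        backward = reversed_result.summary("items")
        for column, stats in forward.items():
            for key, value in stats.items():
                assert backward[column][key] == pytest.approx(value)

    def test_child_subgroup_mean(self, reference_battery):
        child = [
            r.mean_reading_age
            for r in reference_battery.section_rows("items")
            if r.age_group == "child"
        ]
        assert round_half_up(float(np.mean(child))) == 9.6


class TestDiscrepancy:
    def test_threshold_is_one_year(self):
        rows = [
            make_row("exact", mean=12.1, target_min=12),   # 0.1 over: not flagged
            make_row("over", mean=12.4, target_min=8),     # 4.4 over: flagged
            make_row("under", mean=9.2, target_min=14),    # below target: not flagged
            make_row("boundary", mean=9.0, target_min=8),  # exactly 1: flagged
        ]
        disc = discrepancy_analysis(BatteryResult(rows=rows), "items")
        flagged = {r.questionnaire: r.flagged for r in disc.records}
        assert flagged == {"exact": False, "over": True, "under": False, "boundary": True}

    def test_delta_sign_convention(self):
        rows = [make_row("q", mean=12.4, target_min=8)]
        disc = discrepancy_analysis(BatteryResult(rows=rows), "items")
        assert disc.records[0].delta == pytest.approx(-4.4)

    def test_rows_without_target_age_skipped(self):
        rows = [make_row("q", mean=12.0, target_min=None),
                make_row("r", mean=12.0, target_min=8)]
        disc = discrepancy_analysis(BatteryResult(rows=rows), "items")
        assert disc.n_total == 1

    def test_aggregate_recomputes_from_records(self, reference_battery):
        disc = discrepancy_analysis(reference_battery, "items")
        deltas = [abs(r.delta) for r in disc.records if r.flagged]
        assert disc.mean_flagged_discrepancy == pytest.approx(np.mean(deltas))
        assert disc.pct_flagged == pytest.approx(100 * disc.n_flagged / disc.n_total)

    def test_no_flags_yields_zero_percentage(self):
        rows = [make_row("ok", mean=10.0, target_min=11)]
        disc = discrepancy_analysis(BatteryResult(rows=rows), "items")
        assert disc.n_flagged == 0 and disc.pct_flagged == 0.0
        assert disc.mean_flagged_discrepancy is None


def brute_force_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


class TestCorrelations:
    def _battery(self, columns):
        rows = []
        for i in range(len(next(iter(columns.values())))):
            ages = {fid: columns[fid][i] for fid in FORMULA_IDS}
            rows.append(make_row(f"q{i}", ages=ages))
        return BatteryResult(rows=rows)

    def test_identical_vectors_r_one(self):
        v = [8.0, 9.0, 10.0, 11.0, 12.0]
        battery = self._battery({fid: v for fid in FORMULA_IDS})
        for corr in formula_correlations(battery, "items"):
            assert corr.r == pytest.approx(1.0)

    def test_anti_ordered_vectors_r_minus_one(self):
        battery = self._battery({
            "CLI": [1, 2, 3, 4, 5], "DC": [5, 4, 3, 2, 1],
            "FK": [1, 2, 3, 4, 5], "FOG": [1, 2, 3, 4, 5],
            "FCST": [1, 2, 3, 4, 5],
        })
        pair = next(c for c in formula_correlations(battery, "items")
                    if c.pair == ("CLI", "DC"))
        assert pair.r == pytest.approx(-1.0)

    def test_hand_computable_pair_matches_brute_force(self):
        x = [8.0, 9.5, 10.0, 12.0, 11.0]
        y = [9.0, 9.0, 11.0, 13.0, 10.5]
        battery = self._battery({
            "CLI": x, "DC": y, "FK": x, "FOG": y, "FCST": x,
        })
        pair = next(c for c in formula_correlations(battery, "items")
                    if c.pair == ("CLI", "DC"))
        assert pair.r == pytest.approx(brute_force_pearson(x, y), abs=1e-12)
        assert 0.0 <= pair.p <= 1.0

    def test_all_ten_pairs_reported(self, reference_battery):
        corrs = formula_correlations(reference_battery, "items")
        assert len(corrs) == 10
        assert all(-1.0 <= c.r <= 1.0 for c in corrs if c.defined)

    def test_zero_variance_column_undefined(self):
        battery = self._battery({
            "CLI": [10, 10, 10], "DC": [8, 9, 10],
            "FK": [8, 9, 10], "FOG": [8, 9, 10], "FCST": [8, 9, 10],
        })
        pair = next(c for c in formula_correlations(battery, "items")
                    if c.pair == ("CLI", "DC"))
        assert not pair.defined


class TestLengthCorrelation:
    def test_perfectly_linear_battery(self):
        rows = [make_row(f"q{i}", mean=8.0 + i, n_words=50 + 10 * i) for i in range(6)]
        corr = length_readability_correlation(BatteryResult(rows=rows), "items")
        assert corr.r == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        lengths = [65, 120, 300, 420, 510, 1024]
        means = [9.1, 10.3, 10.1, 11.8, 12.4, 12.1]
        rows = [make_row(f"q{i}", mean=m, n_words=w)
                for i, (w, m) in enumerate(zip(lengths, means))]
        corr = length_readability_correlation(BatteryResult(rows=rows), "items")
        assert corr.r == pytest.approx(brute_force_pearson(lengths, means), abs=1e-12)

    def test_exclusions_honored_and_recorded(self):
        rows = [make_row(f"q{i}", mean=8.0 + i, n_words=50 + 10 * i) for i in range(5)]
        rows.append(make_row("outlier", mean=8.0, n_words=10000))
        corr = length_readability_correlation(
            BatteryResult(rows=rows), "items", exclusions=("outlier",)
        )
        assert corr.excluded == ("outlier",)
        assert corr.n == 5
        assert corr.r == pytest.approx(1.0)

    def test_constant_word_counts_undefined(self):
        rows = [make_row(f"q{i}", mean=8.0 + i, n_words=100) for i in range(4)]
        corr = length_readability_correlation(BatteryResult(rows=rows), "items")
        assert not corr.defined


class TestFullTextBattery:
    def _questionnaire(self, name="Q"):
        return Questionnaire(
            name=name, target_age_min=8, target_age_max=12,
            sections=[
                Section(kind="instructions",
                        units=[TextUnit(text="Please answer every question")]),
                Section(kind="items",
                        units=[TextUnit(text="1. I feel happy"),
                               TextUnit(text="2. I sleep well at night")]),
            ],
        )

    def test_rows_per_section(self, easy_list):
        result = analyze_battery([self._questionnaire()], easy_list)
        assert {r.section for r in result.rows} == {"instructions", "items"}
        items = result.section_rows("items")[0]
        assert items.n_sentences == 2
        assert set(items.reading_ages) == set(FORMULA_IDS)

    def test_report_csv_json_parity(self, easy_list, tmp_path):
        result = analyze_battery(
            [self._questionnaire("A"), self._questionnaire("B")], easy_list
        )
        csv_path = tmp_path / "report.csv"
        json_path = tmp_path / "report.json"
        write_report_csv(result, csv_path)
        write_report_json(result, json_path)
        back = read_report_json(json_path)
        import csv as csv_mod
        with open(csv_path, newline="") as fh:
            csv_rows = list(csv_mod.DictReader(fh))
        assert len(csv_rows) == len(back.rows)
        for csv_row, row in zip(csv_rows, back.rows):
            for fid in FORMULA_IDS:
                assert float(csv_row[fid]) == row.reading_ages[fid]
            assert float(csv_row["mean"]) == row.mean_reading_age

    def test_empty_battery_rejected(self, easy_list):
        with pytest.raises(ValueError):
            analyze_battery([], easy_list)
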