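"""Aggregate the packaged reference battery of published reading ages.

Runs the aggregation stages in age-passthrough mode on the packaged
per-questionnaire reading ages for 21 youth quality-of-life questionnaires:
per-stream summary statistics, the reading-age vs minimum-target-age
discrepancy analysis, and the Pearson correlations among the five formulas.
Writes results/reference_report.{csv,json} and
results/reference_summary.json.
"""

import json
from pathlib import Path

from promread.battery import (
    discrepancy_analysis,
    formula_correlations,
    rows_from_reference,
    write_report_csv,
    write_report_json,
)
from promread.formulas import round_half_up
from promread.synthetic import generate_battery_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    battery = rows_from_reference(generate_battery_fixture())
    write_report_csv(battery, RESULTS / "reference_report.csv")
    write_report_json(battery, RESULTS / "reference_report.json")

    payload = {}
    for stream in ("items", "instructions"):
        summary = battery.summary(stream)
        disc = discrepancy_analysis(battery, stream)
        mean_col = summary["mean"]
        print(
            f"{stream}: n={mean_col['n']}, mean reading age "
            f"{round_half_up(mean_col['mean'])} years "
            f"(SD {round_half_up(mean_col['sd'])}, range "
            f"{mean_col['min']}-{mean_col['max']})"
        )
        print(
            f"  flagged {disc.n_flagged}/{disc.n_total} "
            f"({round_half_up(disc.pct_flagged)}%), mean discrepancy "
            f"{round_half_up(disc.mean_flagged_discrepancy)} years, "
            f"delta range {disc.delta_range}"
        )
        payload[stream] = {
            "summary": summary,
            "discrepancy": {
                "n_total": disc.n_total,
                "n_flagged": disc.n_flagged,
                "pct_flagged": disc.pct_flagged,
                "mean_flagged_discrepancy": disc.mean_flagged_discrepancy,
                "sd_flagged_discrepancy": disc.sd_flagged_discrepancy,
                "delta_range": disc.delta_range,
                "flagged": [r.questionnaire for r in disc.records if r.flagged],
            },
            "formula_correlations": [
                {"pair": list(c.pair), "r": c.r, "p": c.p, "n": c.n}
                for c in formula_correlations(battery, stream)
            ],
        }

    with open(RESULTS / "reference_summary.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    print(f"wrote {RESULTS / 'reference_summary.json'}")


if __name__ == "__main__":
    main()
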