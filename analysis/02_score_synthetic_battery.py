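"""Score the synthetic battery from its text and check it against the
construction-time expectations.

Runs the full pipeline (standardize -> lexical stats -> five formulas ->
reading ages) on the questionnaires written by 01_generate_synthetic_battery
and confirms that every analysed reading age equals the generator's
analytic expectation; writes the battery report to results/.
"""

import json
from pathlib import Path

from promread.battery import analyze_battery, write_report_csv, write_report_json
from promread.model import load_questionnaire
from promread.wordlist import load_default_easy_list

RESULTS = Path(__file__).resolve().parent.parent / "results"
SYNTH = RESULTS / "synthetic"


def main() -> None:
    q_paths = sorted(SYNTH.glob("*.questionnaire.json"))
    if not q_paths:
        raise SystemExit("run analysis/01_generate_synthetic_battery.py first")
    easy = load_default_easy_list()
    questionnaires = [load_questionnaire(p) for p in q_paths]
    result = analyze_battery(questionnaires, easy, round_ages=False)

    mismatches = 0
    for row in result.rows:
        expected = json.loads(
            (SYNTH / f"{row.questionnaire}.expected.json").read_text()
        )
        for fid, grade in expected["grades"].items():
            if abs(row.reading_ages[fid] - (grade + 5.0)) > 1e-9:
                mismatches += 1
                print(f"MISMATCH {row.questionnaire} {fid}: "
                      f"{row.reading_ages[fid]} vs {grade + 5.0}")
        print(
            f"{row.questionnaire}: mean reading age "
            f"{row.mean_reading_age:.2f} years ({row.n_words} words)"
        )
    if mismatches:
        raise SystemExit(f"{mismatches} reading ages diverged from construction")
    print("all analysed reading ages equal construction-time expectations")

    means = [r.mean_reading_age for r in result.rows]
    if means == sorted(means):
        print("mean reading age rises monotonically with the difficulty ladder")
    write_report_csv(result, RESULTS / "synthetic_report.csv")
    write_report_json(result, RESULTS / "synthetic_report.json")
    print(f"wrote {RESULTS / 'synthetic_report.csv'} and .json")


if __name__ == "__main__":
    main()
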