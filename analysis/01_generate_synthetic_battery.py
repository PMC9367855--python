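"""Generate a small synthetic questionnaire battery with graded difficulty.

Builds six questionnaires whose difficult-word percentage and syllable load
rise in steps, so downstream scripts can verify that every readability
formula responds in the expected direction. Writes questionnaire JSON files
and their construction-time expected statistics under results/synthetic/.
"""

import dataclasses
import json
from pathlib import Path

from promread.model import save_questionnaire
from promread.synthetic import SyntheticSpec, generate_questionnaire
from promread.wordlist import load_default_easy_list

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"

# pct difficult and ASW climb together: later questionnaires read harder
LEVELS = [
    ("synth-easy-1", 0.0, 1.0),
    ("synth-easy-2", 5.0, 1.1),
    ("synth-mid-1", 10.0, 1.2),
    ("synth-mid-2", 15.0, 1.3),
    ("synth-hard-1", 20.0, 1.4),
    ("synth-hard-2", 25.0, 1.5),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    easy = load_default_easy_list()
    for i, (name, pct, asw) in enumerate(LEVELS):
        spec = SyntheticSpec(
            n_items=10, words_per_item=10, target_pct_difficult=pct,
            target_asw=asw, seed=100 + i, name=name,
        )
        questionnaire, expected = generate_questionnaire(spec, easy)
        save_questionnaire(questionnaire, OUT / f"{name}.questionnaire.json")
        with open(OUT / f"{name}.expected.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"stats": dataclasses.asdict(expected.stats),
                 "grades": expected.grades},
                fh, indent=2,
            )
            fh.write("\n")
        print(
            f"{name}: {expected.stats.n_words} words, "
            f"{expected.stats.pct_difficult:.0f}% difficult, "
            f"ASW {expected.stats.syllables_per_word:.2f}, "
            f"DC grade {expected.grades['DC']:.4f}"
        )
    print(f"wrote {2 * len(LEVELS)} files under {OUT}")


if __name__ == "__main__":
    main()
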