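"""Battery-level aggregation: summaries, discrepancies, correlations.

A "battery" is a collection of questionnaires analysed together. Two entry
points produce the same row structure:

* :func:`analyze_battery` scores questionnaire text end to end
  (standardize -> lexical stats -> five formulas -> mean reading age);
* :func:`rows_from_reference` consumes already-computed per-formula reading
  ages (age-passthrough mode), so published per-instrument figures can feed
  the aggregation and discrepancy stages directly.

Downstream analyses: per-formula and cross-formula mean/SD/range summaries
per section stream; a discrepancy analysis comparing each questionnaire's
mean reading age against the youngest age of its target group (flagged when
the reading age exceeds that minimum by at least one year); and Pearson
correlations among formulas and between section length and reading age.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from promread.formulas import FORMULA_IDS, round_half_up, score_section
from promread.model import Questionnaire, standardize_questionnaire
from promread.wordlist import EasyWordList

logger = logging.getLogger(__name__)


@dataclass
class SectionRow:
    """One questionnaire x section: five reading ages plus metadata."""

    questionnaire: str
    section: str
    reading_ages: dict[str, float]
    mean_reading_age: float
    target_age_min: Optional[int] = None
    target_age_max: Optional[int] = None
    age_group: Optional[str] = None
    n_words: Optional[int] = None
    n_sentences: Optional[int] = None
    n_items: Optional[int] = None


@dataclass
class BatteryResult:
    rows: list[SectionRow] = field(default_factory=list)

    def section_rows(self, section_kind: str) -> list[SectionRow]:
        return [r for r in self.rows if r.section == section_kind]

    def summary(self, section_kind: str) -> dict[str, dict[str, float]]:
        """Mean, sample SD, min and max per formula and for the mean column,
        across questionnaires that have the section."""
        rows = self.section_rows(section_kind)
        if not rows:
            raise ValueError(f"no rows for section {section_kind!r}")
        out: dict[str, dict[str, float]] = {}
        columns = {fid: [r.reading_ages[fid] for r in rows] for fid in FORMULA_IDS}
        columns["mean"] = [r.mean_reading_age for r in rows]
        for name, values in columns.items():
            arr = np.asarray(values, dtype=float)
            out[name] = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "min": float(arr.min()),
                "max": float(arr.max()),
                "n": len(arr),
            }
        return out


def analyze_battery(
    questionnaires: Iterable[Questionnaire],
    easy: EasyWordList,
    round_ages: bool = True,
) -> BatteryResult:
    """Score every section of every questionnaire from its text.

    Reported reading ages are half-up rounded to 1 decimal (the package's
    reporting precision) unless ``round_ages`` is false; the cross-formula
    mean is always computed on unrounded ages first.
    """
    questionnaires = list(questionnaires)
    if not questionnaires:
        raise ValueError("battery requires at least one questionnaire")
    result = BatteryResult()
    for q in questionnaires:
        standardized = standardize_questionnaire(q)
        for kind, text in standardized.items():
            sec = score_section(text, easy)
            ages = sec.rounded_reading_ages() if round_ages else sec.reading_ages
            mean_age = (
                round_half_up(sec.mean_reading_age) if round_ages else sec.mean_reading_age
            )
            result.rows.append(
                SectionRow(
                    questionnaire=q.name,
                    section=kind,
                    reading_ages=dict(ages),
                    mean_reading_age=mean_age,
                    target_age_min=q.target_age_min,
                    target_age_max=q.target_age_max,
                    n_words=sec.stats.n_words,
                    n_sentences=sec.stats.n_sentences,
                )
            )
    return result


def rows_from_reference(records: Sequence[dict]) -> BatteryResult:
    """Age-passthrough mode: build a battery from per-formula reading ages.

    Each record carries name, target ages, optional group/item metadata and,
    per section, the five reading ages with an optional pre-computed mean
    (recomputed from the five, half-up to 1 decimal, when absent).
    """
    result = BatteryResult()
    for rec in records:
        for section in ("instructions", "items", "demographics"):
            ages = rec.get(section)
            if not ages:
                continue
            five = {fid: float(ages[fid]) for fid in FORMULA_IDS}
            mean_age = ages.get("mean")
            if mean_age is None:
                mean_age = round_half_up(sum(five.values()) / len(five))
            result.rows.append(
                SectionRow(
                    questionnaire=rec["name"],
                    section=section,
                    reading_ages=five,
                    mean_reading_age=float(mean_age),
                    target_age_min=rec.get("target_age_min"),
                    target_age_max=rec.get("target_age_max"),
                    age_group=rec.get("age_group"),
                    n_words=ages.get("n_words"),
                    n_sentences=ages.get("n_sentences"),
                    n_items=rec.get("n_items"),
                )
            )
    return result


# --------------------------------------------------------------------------
# Discrepancy analysis


@dataclass(frozen=True)
class DiscrepancyRecord:
    """Reading-age vs minimum-target-age comparison for one questionnaire.

    ``delta`` = target_age_min - mean_reading_age: negative values mean the
    text demands more reading skill than the youngest intended respondent is
    assumed to have; a deficit of a year or more sets ``flagged``.
    """

    questionnaire: str
    section: str
    mean_reading_age: float
    target_age_min: int
    delta: float
    flagged: bool


@dataclass
class DiscrepancySummary:
    records: list[DiscrepancyRecord]
    n_total: int
    n_flagged: int
    pct_flagged: float
    mean_flagged_discrepancy: Optional[float]
    sd_flagged_discrepancy: Optional[float]
    delta_range: Optional[tuple[float, float]]


FLAG_THRESHOLD_YEARS = 1.0


def discrepancy_analysis(
    result: BatteryResult, section_kind: str
) -> DiscrepancySummary:
    """Flag questionnaires whose required reading age exceeds the minimum
    target age by at least one year; aggregate over flagged records.

    The percentage denominator is the number of questionnaires that have the
    section at all. ``mean_flagged_discrepancy`` is the mean magnitude of
    flagged deltas, in years.
    """
    records: list[DiscrepancyRecord] = []
    for row in result.section_rows(section_kind):
        if row.target_age_min is None:
            logger.warning(
                "skipping %s (%s): no target age metadata", row.questionnaire, section_kind
            )
            continue
        delta = row.target_age_min - row.mean_reading_age
        records.append(
            DiscrepancyRecord(
                questionnaire=row.questionnaire,
                section=section_kind,
                mean_reading_age=row.mean_reading_age,
                target_age_min=row.target_age_min,
                delta=round_half_up(delta, 4),
                flagged=delta <= -FLAG_THRESHOLD_YEARS,
            )
        )
    flagged = [r for r in records if r.flagged]
    n_total = len(records)
    deltas = np.asarray([r.delta for r in flagged], dtype=float)
    return DiscrepancySummary(
        records=records,
        n_total=n_total,
        n_flagged=len(flagged),
        pct_flagged=100.0 * len(flagged) / n_total if n_total else float("nan"),
        mean_flagged_discrepancy=float(np.abs(deltas).mean()) if flagged else None,
        sd_flagged_discrepancy=(
            float(np.abs(deltas).std(ddof=1)) if len(flagged) > 1 else None
        ),
        delta_range=(float(deltas.min()), float(deltas.max())) if flagged else None,
    )


# --------------------------------------------------------------------------
# Correlations


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    excluded: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def _pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def formula_correlations(
    result: BatteryResult, section_kind: str
) -> list[CorrelationResult]:
    """Pearson r (two-sided p, t distribution with n-2 df) for all 10
    unordered formula pairs within one section stream."""
    rows = result.section_rows(section_kind)
    out: list[CorrelationResult] = []
    for i, a in enumerate(FORMULA_IDS):
        for b in FORMULA_IDS[i + 1 :]:
            r, p = _pearson(
                [row.reading_ages[a] for row in rows],
                [row.reading_ages[b] for row in rows],
            )
            out.append(CorrelationResult(pair=(a, b), r=r, p=p, n=len(rows)))
    return out


def length_readability_correlation(
    result: BatteryResult,
    section_kind: str,
    exclusions: Sequence[str] = (),
) -> CorrelationResult:
    """Pearson correlation between section word count and mean reading age.

    ``exclusions`` removes named questionnaires (e.g. outlying lengths)
    before computing; excluded names are recorded in the result.
    """
    rows = [
        r
        for r in result.section_rows(section_kind)
        if r.questionnaire not in exclusions and r.n_words is not None
    ]
    if len(rows) < 3:
        raise ValueError("length correlation requires >=3 rows with word counts")
    r, p = _pearson(
        [row.n_words for row in rows], [row.mean_reading_age for row in rows]
    )
    return CorrelationResult(
        pair=("length", "mean_reading_age"),
        r=r,
        p=p,
        n=len(rows),
        excluded=tuple(exclusions),
    )


# --------------------------------------------------------------------------
# Report writers


def _row_record(row: SectionRow) -> dict:
    rec = {
        "questionnaire": row.questionnaire,
        "section": row.section,
        "target_age_min": row.target_age_min,
        "target_age_max": row.target_age_max,
        "age_group": row.age_group,
        "n_items": row.n_items,
        "n_words": row.n_words,
        "n_sentences": row.n_sentences,
    }
    for fid in FORMULA_IDS:
        rec[fid] = round_half_up(row.reading_ages[fid])
    rec["mean"] = round_half_up(row.mean_reading_age)
    return rec


def write_report_csv(result: BatteryResult, path: str | Path) -> None:
    """Per-row CSV mirroring the standard battery table layout; floats are
    printed with 1 decimal, '.' decimal separator."""
    records = [_row_record(r) for r in result.rows]
    fieldnames = list(records[0].keys())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for rec in records:
            writer.writerow(
                {
                    k: (f"{v:.1f}" if isinstance(v, float) else v)
                    for k, v in rec.items()
                }
            )


def write_report_json(result: BatteryResult, path: str | Path) -> None:
    records = [_row_record(r) for r in result.rows]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"rows": records}, fh, indent=2)
        fh.write("\n")


def read_report_json(path: str | Path) -> BatteryResult:
    """Rebuild a :class:`BatteryResult` from a JSON report written by
    :func:`write_report_json` (the round-trip used by the summarize and
    correlate stages)."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    result = BatteryResult()
    for rec in payload["rows"]:
        result.rows.append(
            SectionRow(
                questionnaire=rec["questionnaire"],
                section=rec["section"],
                reading_ages={fid: float(rec[fid]) for fid in FORMULA_IDS},
                mean_reading_age=float(rec["mean"]),
                target_age_min=rec.get("target_age_min"),
                target_age_max=rec.get("target_age_max"),
                age_group=rec.get("age_group"),
                n_words=rec.get("n_words"),
                n_sentences=rec.get("n_sentences"),
                n_items=rec.get("n_items"),
            )
        )
    return result
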