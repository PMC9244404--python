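"""Questionnaire and anthropometric scoring rules.

The Mediterranean-Diet (MeDi) adequacy questionnaire has nine food items
(fruit, vegetables, legumes, cereals, fish, meat and cold cuts, milk and
derivatives, olive oil, alcohol), each scored 0 (no intake) to 2 (more than
once a week).  The total (0-18) maps onto four adequacy bands, and items
split into "positive" foods (fruit, vegetables, legumes, cereals, fish,
olive oil; 0-12) versus "negative" foods (meat, dairy, alcohol; 0-6).

Also implemented: IPAQ physical-activity bands (MET-min/week), WHO BMI
categories, sex-specific waist-circumference and waist-hip-ratio risk flags,
and smoking pack-years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical item order used throughout the package (and in the cohort CSV).
ITEMS = (
    "fruit",
    "vegetables",
    "legumes",
    "cereals",
    "fish",
    "meat",
    "dairy",
    "olive_oil",
    "alcohol",
)

POSITIVE_ITEMS = ("fruit", "vegetables", "legumes", "cereals", "fish", "olive_oil")
NEGATIVE_ITEMS = ("meat", "dairy", "alcohol")

MEDI_CATEGORIES = (
    "not_adequate",          # 0-4
    "poorly_adequate",       # 5-9
    "sufficiently_adequate", # 10-15
    "completely_adequate",   # 16-18
)

IPAQ_CATEGORIES = ("inactive", "sufficiently_active", "active")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")


@dataclass(frozen=True)
class MeDiProfile:
    total_score: int
    adequacy_category: str
    positive_score: int
    negative_score: int


@dataclass(frozen=True)
class AnthroProfile:
    bmi: float
    bmi_category: str
    waist_flag: bool
    whr: float
    whr_flag: bool


@dataclass(frozen=True)
class LifestyleProfile:
    pack_years: float
    ipaq_met: float
    ipaq_category: str


def _coerce_items(item_scores) -> dict:
    if isinstance(item_scores, Mapping):
        missing = [k for k in ITEMS if k not in item_scores]
        if missing:
            raise ValueError(f"missing item scores: {missing}")
        return {k: item_scores[k] for k in ITEMS}
    scores = list(item_scores)
    if len(scores) != len(ITEMS):
        raise ValueError(f"expected {len(ITEMS)} item scores, got {len(scores)}")
    return dict(zip(ITEMS, scores))


def medi_profile(item_scores: Sequence[int] | Mapping[str, int]) -> MeDiProfile:
    """Score one subject's nine MeDi items.

    Accepts either a mapping keyed by item name or a sequence in canonical
    :data:`ITEMS` order.  Raises with the offending item name if any score is
    outside {0, 1, 2}.
    """
    scores = _coerce_items(item_scores)
    for name, value in scores.items():
        if value not in (0, 1, 2):
            raise ValueError(f"item {name!r} has score {value!r}; must be 0, 1 or 2")
    total = sum(scores.values())
    positive = sum(scores[k] for k in POSITIVE_ITEMS)
    negative = sum(scores[k] for k in NEGATIVE_ITEMS)
    return MeDiProfile(
        total_score=total,
        adequacy_category=medi_category(total),
        positive_score=positive,
        negative_score=negative,
    )


def medi_category(total: int) -> str:
    """Adequacy band for a 0-18 MeDi total: 0-4 / 5-9 / 10-15 / 16-18."""
    if not 0 <= total <= 18:
        raise ValueError(f"MeDi total {total} outside 0-18")
    if total <= 4:
        return "not_adequate"
    if total <= 9:
        return "poorly_adequate"
    if total <= 15:
        return "sufficiently_adequate"
    return "completely_adequate"


def ipaq_category(met: float) -> str:
    """IPAQ activity band: <700 inactive, [700, 2520) sufficiently active,
    >=2520 active.  The source bands leave (2519, 2520) unstated; half-open
    intervals make the rule a partition."""
    if met < 0:
        raise ValueError(f"IPAQ MET-min/week must be >= 0, got {met}")
    if met < 700:
        return "inactive"
    if met < 2520:
        return "sufficiently_active"
    return "active"


def bmi_category(bmi: float) -> str:
    """WHO band: <18.5 / [18.5, 25) / [25, 30) / >=30 kg/m^2."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def anthro_profile(sex: str, weight: float, height: float, waist: float, hip: float) -> AnthroProfile:
    """BMI (kg/m^2, weight kg / height m), WHO BMI band, and sex-specific
    cardiovascular-risk flags: waist >= 94 cm (M) / 80 cm (F); waist-hip
    ratio strictly above 0.90 (M) / 0.85 (F)."""
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    for name, value in (("weight", weight), ("height", height), ("waist", waist), ("hip", hip)):
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")
    bmi = weight / height**2
    whr = waist / hip
    waist_cut = 94.0 if sex == "M" else 80.0
    whr_cut = 0.90 if sex == "M" else 0.85
    return AnthroProfile(
        bmi=bmi,
        bmi_category=bmi_category(bmi),
        waist_flag=waist >= waist_cut,
        whr=whr,
        whr_flag=whr > whr_cut,
    )


def pack_years(cigs_per_day: float, years: float) -> float:
    """Smoking pack-years: (cigarettes/day / 20) x years of habit."""
    if cigs_per_day < 0 or years < 0:
        raise ValueError("cigarettes/day and years smoked must be >= 0")
    return (cigs_per_day / 20.0) * years


def lifestyle_profile(cigs_per_day: float, years: float, ipaq_met: float) -> LifestyleProfile:
    return LifestyleProfile(
        pack_years=pack_years(cigs_per_day, years),
        ipaq_met=ipaq_met,
        ipaq_category=ipaq_category(ipaq_met),
    )


def score_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Append row-wise scores to a participant table.

    Adds: medi_total, medi_category, positive_score, negative_score,
    ipaq_category, bmi, bmi_category, waist_flag, whr, whr_flag, pack_years.
    """
    required = set(ITEMS) | {
        "sex", "weight_kg", "height_m", "waist_cm", "hip_cm",
        "cigs_per_day", "years_smoked", "ipaq_met",
    }
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"participant table missing columns: {missing}")

    out = table.copy()
    item_arr = out[list(ITEMS)].to_numpy()
    if not np.isin(item_arr, (0, 1, 2)).all():
        bad = np.argwhere(~np.isin(item_arr, (0, 1, 2)))[0]
        raise ValueError(
            f"row {out.index[bad[0]]}: item {ITEMS[bad[1]]!r} has score "
            f"{item_arr[tuple(bad)]!r}; must be 0, 1 or 2"
        )
    out["medi_total"] = item_arr.sum(axis=1)
    out["medi_category"] = [medi_category(t) for t in out["medi_total"]]
    out["positive_score"] = out[list(POSITIVE_ITEMS)].sum(axis=1)
    out["negative_score"] = out[list(NEGATIVE_ITEMS)].sum(axis=1)
    out["ipaq_category"] = [ipaq_category(m) for m in out["ipaq_met"]]
    anthro = [
        anthro_profile(s, w, h, wc, hc)
        for s, w, h, wc, hc in zip(
            out["sex"], out["weight_kg"], out["height_m"], out["waist_cm"], out["hip_cm"]
        )
    ]
    out["bmi"] = [a.bmi for a in anthro]
    out["bmi_category"] = [a.bmi_category for a in anthro]
    out["waist_flag"] = [a.waist_flag for a in anthro]
    out["whr"] = [a.whr for a in anthro]
    out["whr_flag"] = [a.whr_flag for a in anthro]
    out["pack_years"] = [
        pack_years(c, y) for c, y in zip(out["cigs_per_day"], out["years_smoked"])
    ]
    return out
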