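"""Deterministic phenotype classification and derived change scores.

Maternal serum 25(OH)D (ng/mL) is classified with the Institute of
Medicine cut-offs: deficient < 12, insufficient 12 to < 20, sufficient
>= 20.  The intervals are half-open on the real line, so there is no
gap between 19.99 and 20.

Newborn anthropometry uses the WHO child-growth cut-offs: low birth
weight < 2500 g, short birth length < 50 cm, small head circumference
< 35 cm; each label is independent of the others.

Pre-pregnancy BMI uses the WHO Asian-population bands; each printed
upper bound is treated as inclusive of its two-decimal value and the
band is half-open at the next band's lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .cohort_io import NeonatalRecord, Participant

VITD_DEFICIENT = 12.0   # ng/mL
VITD_SUFFICIENT = 20.0  # ng/mL

LBW_CUTOFF = 2500.0     # g
SHORT_CUTOFF = 50.0     # cm
SMALL_HC_CUTOFF = 35.0  # cm


@dataclass(frozen=True)
class VitDStatus:
    value: float
    category: str  # "deficient" | "insufficient" | "sufficient"


@dataclass(frozen=True)
class AnthroStatus:
    birth_weight_cat: Optional[str]      # "low" | "normal"
    birth_length_cat: Optional[str]      # "short" | "normal"
    head_circ_cat: Optional[str]         # "small" | "normal"


@dataclass(frozen=True)
class ChangeScore:
    delta_25ohd: float  # ng/mL, third minus first trimester


def classify_vitd(value: Optional[float]) -> Optional[VitDStatus]:
    """IOM vitamin D status from a serum 25(OH)D concentration in ng/mL."""
    if value is None:
        return None
    if value < 0:
        raise ValueError(f"25(OH)D cannot be negative: {value}")
    if value < VITD_DEFICIENT:
        category = "deficient"
    elif value < VITD_SUFFICIENT:
        category = "insufficient"
    else:
        category = "sufficient"
    return VitDStatus(value=value, category=category)


def classify_anthro(record: NeonatalRecord) -> AnthroStatus:
    """WHO binary labels for birth weight, length and head circumference."""

    def label(value: Optional[float], cutoff: float, adverse: str) -> Optional[str]:
        if value is None:
            return None
        return adverse if value < cutoff else "normal"

    return AnthroStatus(
        birth_weight_cat=label(record.birth_weight, LBW_CUTOFF, "low"),
        birth_length_cat=label(record.birth_length, SHORT_CUTOFF, "short"),
        head_circ_cat=label(record.head_circumference, SMALL_HC_CUTOFF, "small"),
    )


# WHO Asian-population BMI bands: (lower bound, label); half-open intervals
_BMI_BANDS = (
    (30.0, "obese"),
    (25.0, "pre-obese"),
    (23.5, "overweight"),
    (18.5, "normal"),
    (0.0, "underweight"),
)


def compute_bmi(weight_kg: float, height_cm: float) -> tuple[float, str]:
    """BMI (kg/m^2) and its WHO Asian-population category."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    # bands are defined at two-decimal precision, so classify the rounded value
    banded = round(bmi, 2)
    for lower, label in _BMI_BANDS:
        if banded >= lower:
            return bmi, label
    raise AssertionError("unreachable")  # bmi > 0 always matches a band


def change_25ohd(
    t1: Optional[float], t3: Optional[float]
) -> Optional[ChangeScore]:
    """Signed within-mother change in 25(OH)D, third minus first trimester."""
    if t1 is None or t3 is None:
        return None
    return ChangeScore(delta_25ohd=t3 - t1)


def derived_phenotypes(
    participants: Sequence[Participant], neonates: Sequence[NeonatalRecord]
) -> pd.DataFrame:
    """Category labels and change scores for a cohort, one row per mother."""
    neo = {record.sample_id: record for record in neonates}
    rows = []
    for mother in participants:
        status_t1 = classify_vitd(mother.vitd_t1)
        status_t3 = classify_vitd(mother.vitd_t3)
        change = change_25ohd(mother.vitd_t1, mother.vitd_t3)
        row = {
            "sample_id": mother.sample_id,
            "vitd_t1_cat": status_t1.category if status_t1 else None,
            "vitd_t3_cat": status_t3.category if status_t3 else None,
            "delta_25ohd": change.delta_25ohd if change else None,
        }
        if mother.prepreg_weight and mother.height:
            bmi, cat = compute_bmi(mother.prepreg_weight, mother.height)
            row["prepreg_bmi"] = mother.prepreg_bmi if mother.prepreg_bmi else bmi
            row["bmi_cat"] = cat
        else:
            row["prepreg_bmi"] = mother.prepreg_bmi
            row["bmi_cat"] = None
        baby = neo.get(mother.sample_id)
        if baby is not None:
            anthro = classify_anthro(baby)
            row.update(
                birth_weight_cat=anthro.birth_weight_cat,
                birth_length_cat=anthro.birth_length_cat,
                head_circ_cat=anthro.head_circ_cat,
            )
        rows.append(row)
    return pd.DataFrame(rows)
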