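"""Clinical-table summary statistics."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import ClinicalRecord

logger = logging.getLogger(__name__)


@dataclass
class ClinicalSummary:
    n: int
    mean_age: float  # reported to 1 decimal
    age_min: float
    age_max: float
    by_gender: dict[str, int]
    by_subtype: dict[str, int]
    by_extent: dict[str, int]
    by_status: dict[str, int]
    by_radiation: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_age": self.mean_age,
            "age_range": [self.age_min, self.age_max],
            "gender": self.by_gender,
            "subtype": self.by_subtype,
            "extent": self.by_extent,
            "status": self.by_status,
            "radiation": self.by_radiation,
        }


def summarize_clinical(records: Sequence[ClinicalRecord]) -> ClinicalSummary:
    """Cohort summary: mean age to one decimal, age range, and counts of
    each categorical level.  Records without a usable age are excluded
    from the age statistics with a warning."""
    if not records:
        raise ValueError("need at least one clinical record")
    ages = []
    for r in records:
        if r.age is None or not np.isfinite(r.age):
            logger.warning(
                "patient %d has no usable age; excluded from age summary",
                r.patient_no,
            )
            continue
        ages.append(r.age)
    if not ages:
        raise ValueError("no records with a usable age")
    return ClinicalSummary(
        n=len(records),
        mean_age=round(float(np.mean(ages)), 1),
        age_min=float(min(ages)),
        age_max=float(max(ages)),
        by_gender=dict(Counter(r.gender for r in records)),
        by_subtype=dict(Counter(r.subtype for r in records)),
        by_extent=dict(Counter(r.extent for r in records)),
        by_status=dict(Counter(r.status for r in records)),
        by_radiation=dict(Counter(r.radiation for r in records)),
    )
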