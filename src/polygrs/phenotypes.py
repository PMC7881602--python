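"""Phenotype records for a screening-colonoscopy cohort.

The outcome is binary: positive means one or more adenomatous polyps were
found at the first screening colonoscopy; negative means no polyps or
hyperplastic polyps only. Polyp subtype fields (size, count, location,
advanced-adenoma flag) are only meaningful for positives. Family history is
kept as a binary flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

from .errors import SchemaError

logger = logging.getLogger(__name__)

Sex = Literal["male", "female"]
SizeClass = Literal["none", "lt_0.5cm", "ge_0.5cm"]
CountClass = Literal["none", "one", "multiple"]
#: Colon segments: CA cecum/ascending, TD transverse/descending,
#: RS rectum/sigmoid.
LOCATIONS = ("CA", "TD", "RS")

#: Inclusion rule: age at first screening colonoscopy must exceed this.
MIN_AGE: float = 45.0


@dataclass
class PhenotypeRecord:
    subject_id: str
    age_at_colonoscopy: float
    sex: Sex
    family_history: bool
    outcome: bool  # True = adenomatous polyp(s) found
    bmi: Optional[float] = None
    polyp_size_class: SizeClass = "none"
    polyp_count_class: CountClass = "none"
    polyp_location: frozenset = field(default_factory=frozenset)
    advanced_adenoma: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_at_colonoscopy <= 0:
            raise SchemaError(
                f"{self.subject_id}: non-positive age {self.age_at_colonoscopy}"
            )
        if self.bmi is not None and self.bmi <= 0:
            raise SchemaError(f"{self.subject_id}: non-positive BMI {self.bmi}")
        if self.sex not in ("male", "female"):
            raise SchemaError(f"{self.subject_id}: sex must be male/female, got {self.sex!r}")
        unknown = set(self.polyp_location) - set(LOCATIONS)
        if unknown:
            raise SchemaError(f"{self.subject_id}: unknown polyp locations {sorted(unknown)}")
        if not self.outcome:
            if (
                self.polyp_size_class != "none"
                or self.polyp_count_class != "none"
                or self.polyp_location
                or self.advanced_adenoma
            ):
                raise SchemaError(
                    f"{self.subject_id}: negative outcome but polyp subtype "
                    "fields are populated"
                )
        elif self.polyp_size_class == "none" and self.polyp_count_class == "none":
            logger.warning(
                "subject %r: positive outcome but no polyp subtype recorded",
                self.subject_id,
            )

    @property
    def meets_inclusion(self) -> bool:
        return self.age_at_colonoscopy > MIN_AGE
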