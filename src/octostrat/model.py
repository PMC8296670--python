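"""Domain types shared by all pipeline stages.

The population is persons with clinically diagnosed knee osteoarthritis
(OA), drawn from five cohorts.  Each record carries the two stratification
variables (BMI in kg/m2 and upper-leg muscle strength), the radiographic
and clinical covariates used by the construct-validity comparisons, and
the three patient-reported / performance outcomes (knee pain, WOMAC
physical function, muscle strength) at baseline and — for exercise-arm
participants — at 3-month follow-up.

Muscle strength is measured by one of two instruments, fixed per cohort:

* ``isokinetic`` — isokinetic knee-extension dynamometry, Nm/kg; values
  of 1.2 Nm/kg or more count as high strength.
* ``cst30`` — 30-second chair-stand test, repetitions; 12 repetitions or
  more count as high strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Optional

__all__ = [
    "SubgroupLabel",
    "Sex",
    "PainScale",
    "KneeMeasurement",
    "InstrumentSpec",
    "INSTRUMENTS",
    "CohortProfile",
    "PatientRecord",
    "RecordValidationError",
    "CANONICAL_COHORTS",
]

#: The five cohorts emulated by the synthetic generator.  The pipeline
#: itself accepts any cohort identifier.
CANONICAL_COHORTS = ("AMS_OA", "STABILO", "NEXA", "CBT", "VIDEX")


class SubgroupLabel(str, Enum):
    """Three-way stratum assignment produced by the allocation rule."""

    LOW_STRENGTH = "low"
    HIGH_STRENGTH = "high"
    OBESITY = "obesity"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class PainScale(str, Enum):
    """Pain instruments; VAS scores are harmonized to 0-10 by /10."""

    NRS_0_10 = "nrs_0_10"
    VAS_0_100 = "vas_0_100"

    @property
    def upper(self) -> float:
        return 10.0 if self is PainScale.NRS_0_10 else 100.0


class RecordValidationError(ValueError):
    """A patient record (or table row) violates a domain invariant."""


@dataclass(frozen=True)
class InstrumentSpec:
    """One strength instrument and the rule constants attached to it.

    ``high_strength_cutoff`` is the threshold at or above which a
    non-obese person is allocated to the high-strength subgroup.
    ``mic_percent`` / ``mic_absolute`` define the minimal important
    change used in responder analysis (exactly one of them is set).
    """

    name: str
    units: str
    high_strength_cutoff: float
    improvement_direction: str = "increase_good"
    mic_percent: Optional[float] = None
    mic_absolute: Optional[float] = None

    def __post_init__(self) -> None:
        if self.high_strength_cutoff <= 0:
            raise ValueError("cutoff must be strictly positive")
        if (self.mic_percent is None) == (self.mic_absolute is None):
            raise ValueError("exactly one MIC rule per instrument")


#: Registry of the two strength instruments with the rule constants:
#: 1.2 Nm/kg and a 30% improvement MIC for isokinetic dynamometry,
#: 12 repetitions and a 2-repetition MIC for the 30s chair-stand test.
INSTRUMENTS: dict[str, InstrumentSpec] = {
    "isokinetic": InstrumentSpec(
        name="isokinetic",
        units="Nm/kg",
        high_strength_cutoff=1.2,
        mic_percent=0.30,
    ),
    "cst30": InstrumentSpec(
        name="cst30",
        units="repetitions",
        high_strength_cutoff=12.0,
        mic_absolute=2.0,
    ),
}


@dataclass(frozen=True)
class KneeMeasurement:
    """One knee, used only for index-knee selection.

    ``kl_grade`` and ``strength`` may be missing (``None``); at least
    one knee of an included patient has ``diagnosed_oa=True``.
    """

    side: str  # "left" | "right"
    diagnosed_oa: bool
    kl_grade: Optional[int] = None
    strength: Optional[float] = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.kl_grade is not None and not 0 <= self.kl_grade <= 4:
            raise ValueError("K/L grade must be in 0..4")


@dataclass(frozen=True)
class CohortProfile:
    """Cohort-level metadata: instrument and structural missingness."""

    cohort_id: str
    strength_instrument: str
    has_surgery_data: bool
    has_comorbidity_data: bool
    has_followup: bool
    n: int = 0

    def __post_init__(self) -> None:
        if self.strength_instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.strength_instrument!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")


@dataclass
class PatientRecord:
    """One participant's baseline (and optional follow-up) measurements.

    Invariants are enforced on construction; violations raise
    :class:`RecordValidationError`.  ``kl_grade`` keeps grades 0 and 1
    distinct when known; analyses merge them into one "0/1" category.
    ``comorbidity_count`` is the number of CIRS>=2 conditions and is
    top-coded to 3 ("3 or more") by the analyses.  Optional fields are
    ``None`` where a cohort did not collect the variable.
    """

    patient_id: str
    cohort_id: str
    sex: Sex
    age: float
    kl_grade: int
    bmi: float
    strength_instrument: str
    strength_baseline: float
    pain_baseline_raw: float
    pain_scale: PainScale
    womac_pf_baseline: float
    exercise_arm: bool
    knee_surgery: Optional[bool] = None
    comorbidity_count: Optional[int] = None
    pain_fu_raw: Optional[float] = None
    womac_pf_fu: Optional[float] = None
    strength_fu: Optional[float] = None

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.pain_scale = PainScale(self.pain_scale)
        err = self._invariant_violation()
        if err is not None:
            raise RecordValidationError(err)

    def _invariant_violation(self) -> Optional[str]:
        if self.strength_instrument not in INSTRUMENTS:
            return f"unknown strength instrument {self.strength_instrument!r}"
        if not self.bmi > 0:
            return f"bmi must be > 0, got {self.bmi}"
        if not 0 <= self.kl_grade <= 4:
            return f"kl_grade must be in 0..4, got {self.kl_grade}"
        if self.age <= 0:
            return f"age must be > 0, got {self.age}"
        if self.strength_baseline < 0:
            return f"strength_baseline must be >= 0, got {self.strength_baseline}"
        hi = self.pain_scale.upper
        if not 0 <= self.pain_baseline_raw <= hi:
            return f"pain {self.pain_baseline_raw} outside 0..{hi} ({self.pain_scale.value})"
        if self.pain_fu_raw is not None and not 0 <= self.pain_fu_raw <= hi:
            return f"follow-up pain {self.pain_fu_raw} outside 0..{hi}"
        if not 0 <= self.womac_pf_baseline <= 100:
            return f"womac_pf_baseline {self.womac_pf_baseline} outside 0..100"
        if self.womac_pf_fu is not None and not 0 <= self.womac_pf_fu <= 100:
            return f"follow-up WOMAC {self.womac_pf_fu} outside 0..100"
        if self.strength_fu is not None and self.strength_fu < 0:
            return f"follow-up strength must be >= 0, got {self.strength_fu}"
        if self.comorbidity_count is not None and self.comorbidity_count < 0:
            return f"comorbidity_count must be >= 0, got {self.comorbidity_count}"
        return None

    @property
    def kl_category(self) -> str:
        """Analysis category for radiographic severity: 0/1, 2, 3 or 4."""
        return "0/1" if self.kl_grade <= 1 else str(self.kl_grade)

    @property
    def comorbidity_category(self) -> Optional[str]:
        """Comorbidity count top-coded at 3 ('3+'); None when missing."""
        if self.comorbidity_count is None:
            return None
        return "3+" if self.comorbidity_count >= 3 else str(self.comorbidity_count)

    @property
    def has_followup(self) -> bool:
        return any(
            v is not None for v in (self.pain_fu_raw, self.womac_pf_fu, self.strength_fu)
        )


RECORD_FIELDS = tuple(f.name for f in fields(PatientRecord))
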