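"""The three-subgroup allocation rule and cohort proportion tables.

Allocation is deterministic, from the two baseline stratification
variables only:

1. BMI >= 30 kg/m2  ->  obesity subgroup (checked first, regardless of
   strength; the obesity cutoff takes precedence);
2. otherwise strength at or above the instrument cutoff (1.2 Nm/kg
   isokinetic, 12 repetitions 30s-CST)  ->  high muscle strength;
3. otherwise  ->  low muscle strength.

The rule is exposed both as plain functions (:func:`stratify`,
:func:`stratify_cohorts`) and as a scikit-learn compatible estimator
(:class:`SubgroupStratifier`) so it composes with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .config import RuleConstants
from .model import INSTRUMENTS, KneeMeasurement, PatientRecord, SubgroupLabel

__all__ = [
    "select_index_knee",
    "stratify",
    "stratify_cohorts",
    "SubgroupStratifier",
    "ProportionTable",
]

LABEL_ORDER = [
    SubgroupLabel.LOW_STRENGTH,
    SubgroupLabel.HIGH_STRENGTH,
    SubgroupLabel.OBESITY,
]


def select_index_knee(knees: Sequence[KneeMeasurement]) -> KneeMeasurement:
    """Pick the index knee whose scores enter stratification.

    The index knee is the knee with diagnosed OA; with bilateral OA, the
    knee with the highest K/L grade; on a grade tie, the knee with the
    lowest muscle strength.  A residual strength tie is broken
    deterministically (right before left).  Missing grades / strengths
    sort as worst-case (grade -1, strength +inf) so a knee with known
    scores is preferred.
    """
    diagnosed = [k for k in knees if k.diagnosed_oa]
    if not diagnosed:
        raise ValueError("no knee with diagnosed OA")
    if len(diagnosed) == 1:
        return diagnosed[0]

    def key(k: KneeMeasurement):
        grade = k.kl_grade if k.kl_grade is not None else -1
        strength = k.strength if k.strength is not None else np.inf
        side_rank = 0 if k.side == "right" else 1
        return (-grade, strength, side_rank)

    return min(diagnosed, key=key)


def stratify(
    bmi: float,
    strength: float,
    instrument: str,
    rules: Optional[RuleConstants] = None,
) -> SubgroupLabel:
    """Allocate one person to a subgroup from BMI and muscle strength."""
    rules = rules or RuleConstants()
    if instrument not in INSTRUMENTS:
        raise ValueError(f"unknown strength instrument {instrument!r}")
    if not bmi > 0:
        raise ValueError(f"bmi must be > 0, got {bmi}")
    if strength < 0:
        raise ValueError(f"strength must be >= 0, got {strength}")
    if bmi >= rules.bmi_obesity_cutoff:
        return SubgroupLabel.OBESITY
    if strength >= rules.strength_cutoff(instrument):
        return SubgroupLabel.HIGH_STRENGTH
    return SubgroupLabel.LOW_STRENGTH


class SubgroupStratifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the allocation rule.

    The rule has no free parameters to estimate; ``fit`` only validates
    input and records the class labels, so the estimator slots into
    sklearn pipelines and model-selection utilities.

    Parameters
    ----------
    bmi_cutoff : float, default 30.0
        Inclusive BMI threshold for the obesity subgroup (kg/m2).
    isokinetic_cutoff : float, default 1.2
        Inclusive high-strength threshold for isokinetic dynamometry (Nm/kg).
    cst30_cutoff : float, default 12.0
        Inclusive high-strength threshold for the 30s chair-stand test
        (repetitions).
    instrument : str, default "isokinetic"
        Instrument assumed when ``X`` is a bare numeric array; ignored
        when ``X`` is a DataFrame with a ``strength_instrument`` column.

    Examples
    --------
    >>> import numpy as np
    >>> SubgroupStratifier().fit(np.empty((0, 2))).predict([[35.5, 1.62]])
    array(['obesity'], dtype=object)
    """

    def __init__(
        self,
        bmi_cutoff: float = 30.0,
        isokinetic_cutoff: float = 1.2,
        cst30_cutoff: float = 12.0,
        instrument: str = "isokinetic",
    ):
        self.bmi_cutoff = bmi_cutoff
        self.isokinetic_cutoff = isokinetic_cutoff
        self.cst30_cutoff = cst30_cutoff
        self.instrument = instrument

    def _rules(self) -> RuleConstants:
        return RuleConstants(
            bmi_obesity_cutoff=self.bmi_cutoff,
            isokinetic_cutoff=self.isokinetic_cutoff,
            cst30_cutoff=self.cst30_cutoff,
        )

    def _extract(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            for col in ("bmi", "strength_baseline"):
                if col not in X.columns:
                    raise ValueError(f"missing column {col!r}")
            bmi = X["bmi"].to_numpy(dtype=float)
            strength = X["strength_baseline"].to_numpy(dtype=float)
            if "strength_instrument" in X.columns:
                instr = X["strength_instrument"].astype(str).to_numpy()
            else:
                instr = np.full(len(X), self.instrument, dtype=object)
        else:
            arr = check_array(X, ensure_2d=True, dtype=float, ensure_min_samples=0)
            if arr.shape[1] != 2:
                raise ValueError("expected two columns: bmi, strength")
            bmi, strength = arr[:, 0], arr[:, 1]
            instr = np.full(len(arr), self.instrument, dtype=object)
        unknown = set(np.unique(instr)) - set(INSTRUMENTS)
        if unknown:
            raise ValueError(f"unknown strength instrument(s): {sorted(unknown)}")
        return bmi, strength, instr

    def fit(self, X, y=None) -> "SubgroupStratifier":
        self._extract(X)
        self.classes_ = np.array([lab.value for lab in LABEL_ORDER], dtype=object)
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        bmi, strength, instr = self._extract(X)
        rules = self._rules()
        cutoffs = np.array([rules.strength_cutoff(i) for i in instr])
        out = np.where(
            bmi >= self.bmi_cutoff,
            SubgroupLabel.OBESITY.value,
            np.where(
                strength >= cutoffs,
                SubgroupLabel.HIGH_STRENGTH.value,
                SubgroupLabel.LOW_STRENGTH.value,
            ),
        )
        if np.any(bmi <= 0) or np.any(strength < 0):
            raise ValueError("bmi must be > 0 and strength >= 0")
        return out.astype(object)


@dataclass(frozen=True)
class ProportionTable:
    """Cohort x subgroup counts with pooled totals and deviations.

    ``proportions`` are unrounded percentages (rows sum to 100);
    ``deviations`` are cohort percentage minus pooled percentage, in
    percentage points, on unrounded values.  Display rounds to integer
    points; all comparisons use the unrounded numbers.
    """

    counts: pd.DataFrame  # index: cohort_id, columns: low/high/obesity

    def __post_init__(self) -> None:
        cols = [lab.value for lab in LABEL_ORDER]
        counts = self.counts.reindex(columns=cols)
        if counts.isna().any().any():
            raise ValueError(f"counts must have columns {cols}")
        if (counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ProportionTable":
        return cls(counts=counts)

    @property
    def cohort_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def totals(self) -> pd.Series:
        """Pooled count per subgroup (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def proportions(self) -> pd.DataFrame:
        return 100.0 * self.counts.div(self.cohort_totals, axis=0)

    @property
    def pooled_proportions(self) -> pd.Series:
        return 100.0 * self.totals / self.grand_total

    @property
    def deviations(self) -> pd.DataFrame:
        return self.proportions.sub(self.pooled_proportions, axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per cohort x subgroup."""
        rows = []
        for cohort in self.counts.index:
            for lab in self.counts.columns:
                rows.append(
                    {
                        "cohort_id": cohort,
                        "subgroup": lab,
                        "count": int(self.counts.loc[cohort, lab]),
                        "cohort_n": int(self.cohort_totals[cohort]),
                        "proportion_pct": self.proportions.loc[cohort, lab],
                        "pooled_pct": self.pooled_proportions[lab],
                        "deviation_pp": self.deviations.loc[cohort, lab],
                    }
                )
        return pd.DataFrame(rows)


def stratify_cohorts(
    records: Iterable[PatientRecord],
    rules: Optional[RuleConstants] = None,
) -> tuple[pd.Series, ProportionTable]:
    """Label every record and tabulate per-cohort subgroup proportions.

    Returns the labels (indexed by patient_id, values are
    :class:`SubgroupLabel` strings) and the filled
    :class:`ProportionTable` over all cohorts present, comparing each
    cohort against the pooled sample.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to stratify")
    rules = rules or RuleConstants()
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("patient_id values must be unique")
    labels = pd.Series(
        {
            r.patient_id: stratify(
                r.bmi, r.strength_baseline, r.strength_instrument, rules
            ).value
            for r in records
        },
        name="subgroup",
    )
    cohorts = sorted({r.cohort_id for r in records})
    cols = [lab.value for lab in LABEL_ORDER]
    counts = pd.DataFrame(0, index=cohorts, columns=cols, dtype=int)
    for r in records:
        counts.loc[r.cohort_id, labels[r.patient_id]] += 1
    return labels, ProportionTable.from_counts(counts)
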