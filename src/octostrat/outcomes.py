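"""Outcome harmonization, change scores, effect sizes and MIC responders.

Three outcomes are evaluated at baseline and 3-month follow-up:

* knee pain — NRS 0-10, or VAS 0-100 harmonized to 0-10 by dividing by
  10; lower is better;
* physical function — WOMAC physical-function subscale, 0-100, higher =
  more impaired, so lower is better;
* muscle strength — instrument units (Nm/kg or repetitions); higher is
  better; never pooled across instruments.

The within-group effect size is the mean baseline-to-follow-up
improvement divided by the baseline standard deviation (sample sd,
n-1), on complete cases.  Responder status uses the per-instrument
minimal important change (MIC): pain improves by >=15% of baseline
and/or >=1 point; WOMAC by >=12% of baseline; isokinetic strength by
>=30% of baseline; 30s-CST by >=2 repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RuleConstants
from .model import PainScale, PatientRecord, SubgroupLabel

__all__ = [
    "OUTCOMES",
    "OutcomeSpec",
    "EffectResult",
    "harmonize_pain",
    "improvement",
    "within_group_effect_size",
    "is_mic_responder",
    "responder_rate",
    "compute_effects",
    "effects_to_frame",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome: its harmonized scale and improvement direction."""

    name: str
    scale_min: float
    scale_max: Optional[float]
    improvement_direction: str  # "decrease_good" | "increase_good"


OUTCOMES: dict[str, OutcomeSpec] = {
    "pain": OutcomeSpec("pain", 0.0, 10.0, "decrease_good"),
    "function": OutcomeSpec("function", 0.0, 100.0, "decrease_good"),
    "strength": OutcomeSpec("strength", 0.0, None, "increase_good"),
}


def harmonize_pain(raw: float, scale: PainScale | str) -> float:
    """Re-scale a pain score to the common 0-10 scale (VAS / 10)."""
    scale = PainScale(scale)
    if not 0 <= raw <= scale.upper:
        raise ValueError(f"pain score {raw} outside 0..{scale.upper} ({scale.value})")
    return raw / 10.0 if scale is PainScale.VAS_0_100 else float(raw)


def improvement(baseline: float, followup: float, outcome: str) -> float:
    """Signed improvement, positive = clinical betterment."""
    spec = OUTCOMES.get(outcome)
    if spec is None:
        raise ValueError(f"unknown outcome {outcome!r}")
    if spec.improvement_direction == "decrease_good":
        return baseline - followup
    return followup - baseline


def within_group_effect_size(
    baselines: Sequence[float], followups: Sequence[float], outcome: str
) -> float:
    """Mean improvement divided by baseline sample standard deviation.

    Complete cases only (pairs with either value missing are dropped);
    requires at least two complete pairs and non-degenerate baseline
    spread.
    """
    b = np.asarray(baselines, dtype=float)
    f = np.asarray(followups, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baselines and followups must have equal length")
    keep = ~(np.isnan(b) | np.isnan(f))
    b, f = b[keep], f[keep]
    if b.size < 2:
        raise ValueError(f"need >= 2 complete cases, got {b.size}")
    sd = float(np.std(b, ddof=1))
    if sd == 0:
        raise ValueError("zero baseline standard deviation (degenerate group)")
    imp = np.array([improvement(bi, fi, outcome) for bi, fi in zip(b, f)])
    return float(np.mean(imp) / sd)


def is_mic_responder(
    baseline: float,
    followup: float,
    outcome: str,
    instrument: Optional[str] = None,
    rules: Optional[RuleConstants] = None,
) -> bool:
    """Whether the change reaches the minimal important change.

    Percent rules are relative to the individual's own baseline.  A
    baseline of exactly 0 makes a pure percent rule degenerate; such
    cases are non-responders and raise a warning.
    """
    rules = rules or RuleConstants()
    imp = improvement(baseline, followup, outcome)
    if outcome == "pain":
        absolute = imp >= rules.pain_mic_absolute
        percent = baseline > 0 and imp >= rules.pain_mic_percent * baseline
        return bool(absolute or percent)
    if outcome == "function":
        if baseline == 0:
            warnings.warn("WOMAC baseline 0: percent MIC degenerate, non-responder")
            return False
        return bool(imp >= rules.womac_mic_percent * baseline)
    if outcome == "strength":
        if instrument == "isokinetic":
            if baseline == 0:
                warnings.warn(
                    "strength baseline 0: percent MIC degenerate, non-responder"
                )
                return False
            return bool(imp >= rules.isokinetic_mic_percent * baseline)
        if instrument == "cst30":
            return bool(imp >= rules.cst30_mic_absolute)
        raise ValueError(f"unknown strength instrument {instrument!r}")
    raise ValueError(f"unknown outcome {outcome!r}")


def responder_rate(
    baselines: Sequence[float],
    followups: Sequence[float],
    outcome: str,
    instrument: Optional[str] = None,
    rules: Optional[RuleConstants] = None,
) -> Optional[float]:
    """Percent of complete cases reaching the MIC (unrounded, 0-100).

    Returns ``None`` when there are no complete cases (rate undefined).
    """
    b = np.asarray(baselines, dtype=float)
    f = np.asarray(followups, dtype=float)
    keep = ~(np.isnan(b) | np.isnan(f))
    b, f = b[keep], f[keep]
    if b.size == 0:
        return None
    hits = sum(
        is_mic_responder(bi, fi, outcome, instrument, rules) for bi, fi in zip(b, f)
    )
    return 100.0 * hits / b.size


@dataclass(frozen=True)
class EffectResult:
    """Within-group treatment response for one subgroup x outcome."""

    subgroup: str
    outcome: str
    instrument: Optional[str]
    n_complete: int
    baseline_mean: float
    baseline_sd: float
    followup_mean: float
    effect_size: float
    responder_rate: Optional[float]  # unrounded percent

    @property
    def responder_rate_rounded(self) -> Optional[int]:
        if self.responder_rate is None:
            return None
        return int(round(self.responder_rate))


def _outcome_pairs(
    records: list[PatientRecord], outcome: str, instrument: Optional[str]
) -> tuple[np.ndarray, np.ndarray]:
    b, f = [], []
    for r in records:
        if outcome == "pain":
            if r.pain_fu_raw is None:
                continue
            b.append(harmonize_pain(r.pain_baseline_raw, r.pain_scale))
            f.append(harmonize_pain(r.pain_fu_raw, r.pain_scale))
        elif outcome == "function":
            if r.womac_pf_fu is None:
                continue
            b.append(r.womac_pf_baseline)
            f.append(r.womac_pf_fu)
        else:  # strength, per instrument
            if r.strength_fu is None or r.strength_instrument != instrument:
                continue
            b.append(r.strength_baseline)
            f.append(r.strength_fu)
    return np.array(b, dtype=float), np.array(f, dtype=float)


def compute_effects(
    records: Iterable[PatientRecord],
    labels: pd.Series,
    rules: Optional[RuleConstants] = None,
) -> list[EffectResult]:
    """Effect sizes and responder rates per subgroup x outcome.

    Pools exercise-arm records across cohorts (the trials' exercise
    regimes are grouped together); strength is reported per instrument,
    never pooled across the two instruments.  Subgroups or cells with
    fewer than two complete cases are omitted.
    """
    rules = rules or RuleConstants()
    arm = [r for r in records if r.exercise_arm]
    results: list[EffectResult] = []
    for subgroup in SubgroupLabel:
        members = [r for r in arm if labels.get(r.patient_id) == subgroup.value]
        for outcome, instruments in (
            ("pain", [None]),
            ("function", [None]),
            ("strength", ["isokinetic", "cst30"]),
        ):
            for instrument in instruments:
                b, f = _outcome_pairs(members, outcome, instrument)
                if b.size < 2 or np.std(b, ddof=1) == 0:
                    continue
                results.append(
                    EffectResult(
                        subgroup=subgroup.value,
                        outcome=outcome,
                        instrument=instrument,
                        n_complete=int(b.size),
                        baseline_mean=float(np.mean(b)),
                        baseline_sd=float(np.std(b, ddof=1)),
                        followup_mean=float(np.mean(f)),
                        effect_size=within_group_effect_size(b, f, outcome),
                        responder_rate=responder_rate(b, f, outcome, instrument, rules),
                    )
                )
    return results


def effects_to_frame(results: list[EffectResult]) -> pd.DataFrame:
    """Tabular report of :func:`compute_effects` output."""
    return pd.DataFrame(
        [
            {
                "subgroup": r.subgroup,
                "outcome": r.outcome,
                "instrument": r.instrument if r.instrument else "",
                "n_complete": r.n_complete,
                "baseline_mean": r.baseline_mean,
                "baseline_sd": r.baseline_sd,
                "followup_mean": r.followup_mean,
                "effect_size": r.effect_size,
                "responder_rate_pct": r.responder_rate,
            }
            for r in results
        ]
    )
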