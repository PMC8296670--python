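"""Synthetic five-cohort generator with the structure the analyses assume.

The generator emulates the study conditions: five cohorts with their
published sizes, strength instruments, pain scales, exercise-arm
fractions and structural missingness; per-cohort subgroup mixtures
equal to the published allocation proportions; subgroup-conditional
baseline distributions taken from the published subgroup summaries;
and per-subgroup true standardized treatment effects taken from the
published within-group effect sizes.

Internal consistency with the allocation rule is guaranteed by
construction: BMI and strength are drawn from truncated distributions
confined to the drawn subgroup's decision region, so the stratifier
recovers every generated label.

Follow-up scores are generated so that the configured standardized
improvement delta is exactly the population effect despite bounded
scales: for each subgroup x outcome, individual improvements are drawn
from truncated normals confined to the feasible range (follow-up stays
on-scale) whose common location is solved numerically so the population
mean improvement equals delta times the baseline population sd.  Naive
post-hoc clamping would bias realized effects noticeably at large
delta; see the methods note.

Covariates are drawn independently within subgroup (between-covariate
correlations beyond those induced by the mixture are not modelled).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .model import PainScale, PatientRecord, SubgroupLabel
from .stratify import LABEL_ORDER

__all__ = [
    "TruncatedNormal",
    "DiscretizedTruncatedNormal",
    "SubgroupParams",
    "CohortConfig",
    "EffectParams",
    "SyntheticConfig",
    "generate_baseline",
    "generate_followup",
    "generate_dataset",
]

LOW = SubgroupLabel.LOW_STRENGTH.value
HIGH = SubgroupLabel.HIGH_STRENGTH.value
OBESITY = SubgroupLabel.OBESITY.value

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [lower, upper]."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not self.lower < self.upper:
            raise ValueError("empty truncation region")
        # the region must retain non-negligible mass, otherwise the
        # configured distribution is inconsistent with its region
        if self._dist().cdf(self.upper) - self._dist().cdf(self.lower) < 1e-12:
            raise ValueError(
                f"infeasible truncation region [{self.lower}, {self.upper}] "
                f"for N({self.mean}, {self.sd})"
            )

    def _dist(self):
        return sps.norm(self.mean, self.sd)

    def _ab(self) -> tuple[float, float]:
        return (self.lower - self.mean) / self.sd, (self.upper - self.mean) / self.sd

    @property
    def population_mean(self) -> float:
        a, b = self._ab()
        return float(sps.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    @property
    def population_sd(self) -> float:
        a, b = self._ab()
        return float(sps.truncnorm.std(a, b, loc=self.mean, scale=self.sd))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a, b = self._ab()
        return sps.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


@dataclass(frozen=True)
class DiscretizedTruncatedNormal:
    """Integer-valued score: normal mass binned onto lower..upper.

    Used for the chair-stand test, whose scores are whole repetitions;
    probabilities are the normal mass in (k-1/2, k+1/2], renormalized
    over the allowed integers.
    """

    mean: float
    sd: float
    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.lower > self.upper:
            raise ValueError("empty integer support")
        if self.probabilities.sum() <= 0:
            raise ValueError("infeasible integer truncation region")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.lower, self.upper + 1)

    @property
    def probabilities(self) -> np.ndarray:
        k = self.support
        dist = sps.norm(self.mean, self.sd)
        p = dist.cdf(k + 0.5) - dist.cdf(k - 0.5)
        total = p.sum()
        return p / total if total > 0 else p

    @property
    def population_mean(self) -> float:
        return float(np.sum(self.support * self.probabilities))

    @property
    def population_sd(self) -> float:
        m = self.population_mean
        return float(np.sqrt(np.sum(self.probabilities * (self.support - m) ** 2)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.support, size=n, p=self.probabilities).astype(float)


@dataclass(frozen=True)
class SubgroupParams:
    """Baseline distributions conditional on one subgroup."""

    age: TruncatedNormal
    female_p: float
    bmi: TruncatedNormal
    strength_iso: TruncatedNormal
    strength_cst: DiscretizedTruncatedNormal
    pain: TruncatedNormal  # harmonized 0-10
    womac: TruncatedNormal  # 0-100
    kl_probs: dict[str, float]  # categories 0/1, 2, 3, 4
    surgery_p: float
    comorbidity_probs: dict[str, float]  # categories 0, 1, 2, 3+

    def __post_init__(self) -> None:
        for name, probs in (("kl", self.kl_probs), ("comorbidity", self.comorbidity_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities must sum to 1")

    def strength(self, instrument: str):
        return self.strength_iso if instrument == "isokinetic" else self.strength_cst


@dataclass(frozen=True)
class CohortConfig:
    """One emulated cohort: size, instrument, arms, missingness, mixture."""

    cohort_id: str
    n: int
    strength_instrument: str
    pain_scale: PainScale
    exercise_fraction: float
    has_surgery: bool
    has_comorbidity: bool
    mixture: dict[str, float]  # subgroup label -> weight

    def __post_init__(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")
        if not 0 <= self.exercise_fraction <= 1:
            raise ValueError("exercise fraction must be in [0, 1]")


@dataclass(frozen=True)
class EffectParams:
    """True standardized improvements and change noise.

    ``delta[(subgroup, outcome_key)]`` with outcome keys ``pain``,
    ``function``, ``strength_isokinetic``, ``strength_cst30``.
    ``noise_ratio`` scales the individual change noise sd relative to
    the baseline population sd.
    """

    delta: dict[tuple[str, str], float]
    noise_ratio: float = 0.5

    def get(self, subgroup: str, outcome: str, instrument: Optional[str]) -> float:
        key = (subgroup, f"strength_{instrument}" if outcome == "strength" else outcome)
        if key not in self.delta:
            raise KeyError(f"no true effect configured for {key}")
        return self.delta[key]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator parameterization for the five emulated cohorts."""

    cohorts: tuple[CohortConfig, ...]
    subgroups: dict[str, SubgroupParams]
    effects: EffectParams

    @classmethod
    def default(cls, size_multiplier: float = 1.0) -> "SyntheticConfig":
        """The study conditions: published sizes, mixtures, summaries.

        ``size_multiplier`` scales every cohort n (e.g. for large-n
        parameter-recovery runs or quick smoke runs) while keeping all
        distributions and mixtures fixed.
        """
        mix = {
            "AMS_OA": (167, 79, 307),
            "STABILO": (60, 37, 62),
            "NEXA": (33, 23, 44),
            "CBT": (94, 16, 112),
            "VIDEX": (67, 58, 52),
        }
        instruments = {
            "AMS_OA": "isokinetic",
            "STABILO": "isokinetic",
            "NEXA": "cst30",
            "CBT": "cst30",
            "VIDEX": "isokinetic",
        }
        scales = {
            "AMS_OA": PainScale.NRS_0_10,
            "STABILO": PainScale.NRS_0_10,
            "NEXA": PainScale.VAS_0_100,
            "CBT": PainScale.VAS_0_100,
            "VIDEX": PainScale.NRS_0_10,
        }
        exercise = {"AMS_OA": 0.0, "STABILO": 1.0, "NEXA": 1.0, "CBT": 148 / 222, "VIDEX": 1.0}
        surgery = {"NEXA", "CBT"}
        comorbidity = {"AMS_OA", "VIDEX"}
        cohorts = []
        for cid, counts in mix.items():
            n = sum(counts)
            cohorts.append(
                CohortConfig(
                    cohort_id=cid,
                    n=int(round(n * size_multiplier)),
                    strength_instrument=instruments[cid],
                    pain_scale=scales[cid],
                    exercise_fraction=exercise[cid],
                    has_surgery=cid in surgery,
                    has_comorbidity=cid in comorbidity,
                    mixture={
                        lab.value: c / n for lab, c in zip(LABEL_ORDER, counts)
                    },
                )
            )

        def sg(age, female_p, bmi, bmi_r, iso, iso_r, cst, cst_r, pain, womac, kl, surg, com):
            kl_t = sum(kl)
            com_t = sum(com)
            return SubgroupParams(
                age=TruncatedNormal(*age, 18.0, 100.0),
                female_p=female_p,
                bmi=TruncatedNormal(*bmi, *bmi_r),
                strength_iso=TruncatedNormal(*iso, *iso_r),
                strength_cst=DiscretizedTruncatedNormal(*cst, *cst_r),
                pain=TruncatedNormal(*pain, 0.0, 10.0),
                womac=TruncatedNormal(*womac, 0.0, 100.0),
                kl_probs={
                    c: v / kl_t for c, v in zip(("0/1", "2", "3", "4"), kl)
                },
                surgery_p=surg,
                comorbidity_probs={
                    c: v / com_t for c, v in zip(("0", "1", "2", "3+"), com)
                },
            )

        subgroups = {
            LOW: sg(
                (65.2, 8.4), 310 / 421, (26.4, 2.5), (15.0, 30.0),
                (0.71, 0.31), (0.0, 1.2), (8.5, 2.3), (0, 11),
                (5.6, 2.0), (43.6, 17.3),
                (95, 131, 92, 83), 51 / 127, (142, 61, 13, 14),
            ),
            HIGH: sg(
                (62.3, 8.6), 88 / 213, (25.8, 2.4), (15.0, 30.0),
                (1.62, 0.32), (1.2, np.inf), (13.2, 1.2), (12, 30),
                (4.7, 2.2), (30.6, 18.2),
                (72, 64, 48, 42), 24 / 38, (97, 28, 8, 3),
            ),
            OBESITY: sg(
                (62.7, 8.3), 388 / 577, (35.5, 5.0), (30.0, 70.0),
                (0.78, 0.48), (0.0, np.inf), (9.0, 2.7), (0, 30),
                (5.8, 2.1), (48.7, 18.6),
                (128, 145, 137, 132), 65 / 155, (151, 105, 52, 41),
            ),
        }
        delta = {
            (LOW, "pain"): 1.05,
            (OBESITY, "pain"): 1.10,
            (HIGH, "pain"): 0.82,
            (LOW, "function"): 0.79,
            (OBESITY, "function"): 0.78,
            (HIGH, "function"): 0.49,
            (LOW, "strength_isokinetic"): 0.74,
            (OBESITY, "strength_isokinetic"): 0.27,
            (HIGH, "strength_isokinetic"): 0.19,
            (LOW, "strength_cst30"): 0.73,
            (OBESITY, "strength_cst30"): 0.60,
            (HIGH, "strength_cst30"): 0.32,
        }
        return cls(
            cohorts=tuple(cohorts),
            subgroups=subgroups,
            effects=EffectParams(delta=delta),
        )

    # -- serialization (structured text config) --------------------------

    def to_dict(self) -> dict:
        def tn(d: TruncatedNormal) -> dict:
            out = {"mean": d.mean, "sd": d.sd}
            if np.isfinite(d.lower):
                out["lower"] = float(d.lower)
            if np.isfinite(d.upper):
                out["upper"] = float(d.upper)
            return out

        def sg(p: SubgroupParams) -> dict:
            return {
                "age": tn(p.age),
                "female_p": p.female_p,
                "bmi": tn(p.bmi),
                "strength_iso": tn(p.strength_iso),
                "strength_cst": {
                    "mean": p.strength_cst.mean,
                    "sd": p.strength_cst.sd,
                    "lower": p.strength_cst.lower,
                    "upper": p.strength_cst.upper,
                },
                "pain": tn(p.pain),
                "womac": tn(p.womac),
                "kl_probs": dict(p.kl_probs),
                "surgery_p": p.surgery_p,
                "comorbidity_probs": dict(p.comorbidity_probs),
            }

        return {
            "cohorts": [
                {
                    "cohort_id": c.cohort_id,
                    "n": c.n,
                    "strength_instrument": c.strength_instrument,
                    "pain_scale": c.pain_scale.value,
                    "exercise_fraction": c.exercise_fraction,
                    "has_surgery": c.has_surgery,
                    "has_comorbidity": c.has_comorbidity,
                    "mixture": dict(c.mixture),
                }
                for c in self.cohorts
            ],
            "subgroups": {lab: sg(p) for lab, p in self.subgroups.items()},
            "effects": {
                "noise_ratio": self.effects.noise_ratio,
                "delta": {
                    f"{sub}/{outcome}": v
                    for (sub, outcome), v in self.effects.delta.items()
                },
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticConfig":
        def tn(d: dict) -> TruncatedNormal:
            return TruncatedNormal(
                mean=float(d["mean"]),
                sd=float(d["sd"]),
                lower=float(d.get("lower", -np.inf)),
                upper=float(d.get("upper", np.inf)),
            )

        subgroups = {}
        for lab, p in doc["subgroups"].items():
            cst = p["strength_cst"]
            subgroups[lab] = SubgroupParams(
                age=tn(p["age"]),
                female_p=float(p["female_p"]),
                bmi=tn(p["bmi"]),
                strength_iso=tn(p["strength_iso"]),
                strength_cst=DiscretizedTruncatedNormal(
                    mean=float(cst["mean"]),
                    sd=float(cst["sd"]),
                    lower=int(cst["lower"]),
                    upper=int(cst["upper"]),
                ),
                pain=tn(p["pain"]),
                womac=tn(p["womac"]),
                kl_probs={str(k): float(v) for k, v in p["kl_probs"].items()},
                surgery_p=float(p["surgery_p"]),
                comorbidity_probs={
                    str(k): float(v) for k, v in p["comorbidity_probs"].items()
                },
            )
        cohorts = tuple(
            CohortConfig(
                cohort_id=c["cohort_id"],
                n=int(c["n"]),
                strength_instrument=c["strength_instrument"],
                pain_scale=PainScale(c["pain_scale"]),
                exercise_fraction=float(c["exercise_fraction"]),
                has_surgery=bool(c["has_surgery"]),
                has_comorbidity=bool(c["has_comorbidity"]),
                mixture={str(k): float(v) for k, v in c["mixture"].items()},
            )
            for c in doc["cohorts"]
        )
        eff = doc["effects"]
        delta = {}
        for key, v in eff["delta"].items():
            sub, outcome = key.split("/", 1)
            delta[(sub, outcome)] = float(v)
        return cls(
            cohorts=cohorts,
            subgroups=subgroups,
            effects=EffectParams(delta=delta, noise_ratio=float(eff["noise_ratio"])),
        )


def load_synthetic_config(path: Optional[str] = None) -> SyntheticConfig:
    """Load a generator config from YAML (section ``generator``).

    With no path, returns the default study conditions.
    """
    if path is None:
        return SyntheticConfig.default()
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return SyntheticConfig.from_dict(doc.get("generator", doc))


def dump_synthetic_config(config: SyntheticConfig, path: str) -> None:
    """Write a generator config to YAML under a ``generator`` section."""
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"generator": config.to_dict()}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# baseline generation


def _sample_categorical(rng, probs: dict[str, float], n: int) -> np.ndarray:
    cats = list(probs)
    return rng.choice(np.array(cats, dtype=object), size=n, p=list(probs.values()))


def generate_baseline(
    config: SyntheticConfig, seed: int
) -> tuple[list[PatientRecord], pd.Series]:
    """Draw baseline records for every configured cohort.

    Returns the records and the generated subgroup labels (indexed by
    patient_id) — the ground truth the stratifier must recover.
    Reproducible: identical config and seed give identical output.
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    truth: dict[str, str] = {}
    kl_grade_of = {"2": 2, "3": 3, "4": 4}
    com_of = {"0": 0, "1": 1, "2": 2, "3+": 3}
    for cohort in config.cohorts:
        labels = _sample_categorical(rng, cohort.mixture, cohort.n)
        n_ex = int(round(cohort.n * cohort.exercise_fraction))
        exercise = np.zeros(cohort.n, dtype=bool)
        exercise[rng.permutation(cohort.n)[:n_ex]] = True
        cohort_rows: list[Optional[PatientRecord]] = [None] * cohort.n
        vas = cohort.pain_scale is PainScale.VAS_0_100
        for sub_label in (LOW, HIGH, OBESITY):
            idx = np.flatnonzero(labels == sub_label)
            if idx.size == 0:
                continue
            sub = config.subgroups[sub_label]
            m = idx.size
            age = sub.age.sample(rng, m)
            female = rng.random(m) < sub.female_p
            bmi = sub.bmi.sample(rng, m)
            strength = sub.strength(cohort.strength_instrument).sample(rng, m)
            pain10 = sub.pain.sample(rng, m)
            womac = sub.womac.sample(rng, m)
            kl_cat = _sample_categorical(rng, sub.kl_probs, m)
            kl_split = rng.integers(0, 2, size=m)  # 0/1 category split evenly
            surg = rng.random(m) < sub.surgery_p
            com_cat = _sample_categorical(rng, sub.comorbidity_probs, m)
            for j, i in enumerate(idx):
                pid = f"{cohort.cohort_id}-{i:05d}"
                cat = str(kl_cat[j])
                cohort_rows[i] = PatientRecord(
                    patient_id=pid,
                    cohort_id=cohort.cohort_id,
                    sex="female" if female[j] else "male",
                    age=float(age[j]),
                    kl_grade=int(kl_split[j]) if cat == "0/1" else kl_grade_of[cat],
                    bmi=float(bmi[j]),
                    strength_instrument=cohort.strength_instrument,
                    strength_baseline=float(strength[j]),
                    pain_baseline_raw=float(pain10[j] * 10.0 if vas else pain10[j]),
                    pain_scale=cohort.pain_scale,
                    womac_pf_baseline=float(womac[j]),
                    exercise_arm=bool(exercise[i]),
                    knee_surgery=bool(surg[j]) if cohort.has_surgery else None,
                    comorbidity_count=(
                        com_of[str(com_cat[j])] if cohort.has_comorbidity else None
                    ),
                )
                truth[pid] = sub_label
        records.extend(cohort_rows)  # type: ignore[arg-type]
    return records, pd.Series(truth, name="subgroup")


# ---------------------------------------------------------------------------
# follow-up generation


def _calibrated_improvements(
    rng: np.random.Generator,
    lower: np.ndarray,
    upper: np.ndarray,
    target_mean: float,
    noise_sd: float,
) -> np.ndarray:
    """Sample per-individual improvements with exact population mean.

    Each improvement is drawn from Normal(c, noise_sd) truncated to the
    individual's feasible interval [lower_i, upper_i]; the common
    location ``c`` is solved so that the mean of the per-individual
    expectations equals ``target_mean``.  With noise_sd = 0 the draw
    degenerates to clip(c, lower_i, upper_i).
    """
    lo_mean = float(np.mean(np.where(np.isfinite(lower), lower, -1e12)))
    hi_mean = float(np.mean(np.where(np.isfinite(upper), upper, 1e12)))
    if not lo_mean < target_mean < hi_mean:
        raise ValueError(
            f"target mean improvement {target_mean:.3g} infeasible for the "
            "configured scale bounds"
        )

    if noise_sd == 0:

        def expected(c: float) -> float:
            return float(np.mean(np.clip(c, lower, upper)))

    else:
        # closed-form truncated-normal mean, vectorized over individuals
        # (much faster than scipy's generic moment machinery)
        def expected(c: float) -> float:
            a = (lower - c) / noise_sd
            b = (upper - c) / noise_sd
            phi_a = np.where(np.isfinite(a), np.exp(-0.5 * a**2), 0.0) / _SQRT2PI
            phi_b = np.where(np.isfinite(b), np.exp(-0.5 * b**2), 0.0) / _SQRT2PI
            mass = special.ndtr(b) - special.ndtr(a)
            with np.errstate(divide="ignore", invalid="ignore"):
                means = c + noise_sd * (phi_a - phi_b) / mass
            # negligible-mass intervals: the draw collapses to the interval
            means = np.where(mass > 1e-300, means, np.clip(c, lower, upper))
            return float(np.mean(means))

    # expand a bracket around the target until the sign changes
    span = max(1.0, abs(target_mean), noise_sd)
    lo_c, hi_c = target_mean - span, target_mean + span
    for _ in range(60):
        if expected(lo_c) <= target_mean:
            break
        lo_c -= span
        span *= 2
    span = max(1.0, abs(target_mean), noise_sd)
    for _ in range(60):
        if expected(hi_c) >= target_mean:
            break
        hi_c += span
        span *= 2
    c = optimize.brentq(lambda x: expected(x) - target_mean, lo_c, hi_c, xtol=1e-10)

    if noise_sd == 0:
        return np.clip(c, lower, upper)
    a = (lower - c) / noise_sd
    b = (upper - c) / noise_sd
    return sps.truncnorm.rvs(a, b, loc=c, scale=noise_sd, random_state=rng)


def generate_followup(
    records: Sequence[PatientRecord], config: SyntheticConfig, seed: int
) -> list[PatientRecord]:
    """Add 3-month follow-up outcomes to exercise-arm records.

    Non-arm records are returned unchanged (no follow-up).  For each
    subgroup x outcome (strength per instrument), improvements are
    drawn so that the population standardized improvement equals the
    configured delta; follow-up scores stay within their scale by
    construction.
    """
    from .stratify import stratify  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    out = [dataclasses.replace(r) for r in records]
    arm_idx = [i for i, r in enumerate(out) if r.exercise_arm]
    sub_of = {
        i: stratify(out[i].bmi, out[i].strength_baseline, out[i].strength_instrument).value
        for i in arm_idx
    }

    # deterministic group order: subgroup x outcome/instrument
    for subgroup in (LOW, HIGH, OBESITY):
        params = config.subgroups[subgroup]
        members = [i for i in arm_idx if sub_of[i] == subgroup]
        if not members:
            continue

        # knee pain, harmonized 0-10 internally
        pain_b = np.array(
            [
                out[i].pain_baseline_raw
                / (10.0 if out[i].pain_scale is PainScale.VAS_0_100 else 1.0)
                for i in members
            ]
        )
        sigma = params.pain.population_sd
        imp = _calibrated_improvements(
            rng,
            lower=pain_b - 10.0,
            upper=pain_b.copy(),
            target_mean=config.effects.get(subgroup, "pain", None) * sigma,
            noise_sd=config.effects.noise_ratio * sigma,
        )
        for i, b, d in zip(members, pain_b, imp):
            fu = b - d
            out[i].pain_fu_raw = float(
                fu * 10.0 if out[i].pain_scale is PainScale.VAS_0_100 else fu
            )

        # physical function (WOMAC 0-100, decrease = improvement)
        womac_b = np.array([out[i].womac_pf_baseline for i in members])
        sigma = params.womac.population_sd
        imp = _calibrated_improvements(
            rng,
            lower=womac_b - 100.0,
            upper=womac_b.copy(),
            target_mean=config.effects.get(subgroup, "function", None) * sigma,
            noise_sd=config.effects.noise_ratio * sigma,
        )
        for i, b, d in zip(members, womac_b, imp):
            out[i].womac_pf_fu = float(b - d)

        # muscle strength per instrument (increase = improvement)
        for instrument in ("isokinetic", "cst30"):
            group = [i for i in members if out[i].strength_instrument == instrument]
            if not group:
                continue
            b_arr = np.array([out[i].strength_baseline for i in group])
            dist = params.strength(instrument)
            sigma = dist.population_sd
            imp = _calibrated_improvements(
                rng,
                lower=-b_arr,
                upper=np.full(b_arr.shape, np.inf),
                target_mean=config.effects.get(subgroup, "strength", instrument) * sigma,
                noise_sd=config.effects.noise_ratio * sigma,
            )
            for i, b, d in zip(group, b_arr, imp):
                fu = b + d
                if instrument == "cst30":
                    fu = float(np.round(fu))
                out[i].strength_fu = max(0.0, float(fu))
    return out


def generate_dataset(
    config: Optional[SyntheticConfig] = None, seed: int = 0
) -> tuple[list[PatientRecord], pd.Series]:
    """Baseline plus follow-up in one call (default study conditions)."""
    config = config or SyntheticConfig.default()
    records, truth = generate_baseline(config, seed)
    # derive the follow-up stream from the same master seed
    fu_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    return generate_followup(records, config, fu_seed), truth
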