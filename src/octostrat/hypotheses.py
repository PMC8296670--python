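"""The 63-hypothesis construct-validity framework and its evaluation.

Construct validity of the allocation rule is assessed COSMIN-style, by
formulating hypotheses a priori and counting how many the data confirm.
The registry holds exactly 63 hypotheses in three research questions:

* RQ1 (15): each cohort's subgroup proportion deviates from the pooled
  proportion by at most +/-10 percentage points (3 subgroups x 5
  cohorts);
* RQ2 (30): subgroup characteristics differ pairwise in the direction
  implied by the hypothesized underlying phenotypes (age-induced /
  post-traumatic / metabolic), accepted when p < 0.05 from a chi-square
  (categorical) or pooled-variance t-test (continuous) AND the observed
  difference points the expected way;
* RQ3 (18): within-group effect sizes and MIC responder rates of usual
  exercise therapy fall in the hypothesized bands — large / majority
  for the low-strength subgroup, medium / half for the obesity
  subgroup, small / minority for the high-strength subgroup.

Two evaluation conventions are applied throughout:

* dual-instrument OR — strength is measured by two instruments that are
  never pooled; a strength hypothesis is accepted when at least one
  instrument satisfies the rule;
* shared cell — when two hypotheses map onto the same subgroup-pair x
  variable comparison (e.g. "A weaker than B" and "B weaker than A"),
  the cell is evaluated once with the expected direction of the
  hypothesis registered first, and both hypotheses inherit the verdict.
  This keeps one statistical test per cell; the two strength hypotheses
  between the low-strength and obesity subgroups are mutually
  contradictory and the convention resolves only their bookkeeping, not
  the contradiction (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .config import RuleConstants
from .model import CANONICAL_COHORTS, PatientRecord, SubgroupLabel
from .outcomes import EffectResult, harmonize_pain
from .stratify import ProportionTable

__all__ = [
    "HypothesisSpec",
    "Verdict",
    "ContinuousStat",
    "CategoricalStat",
    "PrintedP",
    "SummaryStats",
    "build_registry",
    "evaluate_rq1",
    "evaluate_rq2",
    "evaluate_rq3",
    "pairwise_t_test",
    "pairwise_chi_square",
    "direction_check",
    "effect_band_check",
    "responder_band_check",
    "aggregate",
    "verdicts_to_frame",
]

LOW = SubgroupLabel.LOW_STRENGTH.value
HIGH = SubgroupLabel.HIGH_STRENGTH.value
OBESITY = SubgroupLabel.OBESITY.value

#: Ordinal scores for direction checks on categorical variables: K/L
#: grades with 0 and 1 merged, comorbidity counts top-coded at 3.
ORDINAL_SCORES: dict[str, dict[str, float]] = {
    "kl": {"0/1": 1.0, "2": 2.0, "3": 3.0, "4": 4.0},
    "comorbidity": {"0": 0.0, "1": 1.0, "2": 2.0, "3+": 3.0},
}

#: For binary variables, the category whose proportion carries the
#: hypothesized direction ("more males", "more surgery history").
BINARY_POSITIVE: dict[str, str] = {"sex": "male", "surgery": "yes"}

#: Strength comparisons run per instrument (dual-instrument OR rule).
STRENGTH_VARIABLES = ("strength_iso", "strength_cst")


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class HypothesisSpec:
    """One a-priori hypothesis and its acceptance rule.

    ``rule_kind`` selects the rule; the relevant parameter fields are:
    ``max_deviation`` (RQ1), ``expected_direction`` for subject vs
    comparator (RQ2), ``measure``/``band`` (RQ3).
    """

    id: str
    research_question: str  # "RQ1" | "RQ2" | "RQ3"
    subject: str  # cohort (RQ1) or subgroup (RQ2/3)
    comparator: str  # "total_sample" or the other subgroup
    variable: str
    rule_kind: str
    max_deviation: Optional[float] = None
    expected_direction: Optional[str] = None  # "greater" | "less"
    measure: Optional[str] = None  # "effect_size" | "mic_rate"
    band: Optional[str] = None  # large/medium/small, majority/half/minority


@dataclass(frozen=True)
class Verdict:
    """Evaluated outcome of one hypothesis."""

    hypothesis_id: str
    research_question: str
    observed: str
    rule: str
    accepted: Optional[bool]  # None = undefined (could not be evaluated)
    note: str = ""


# (subject, comparator, variable, expected direction of subject), in
# registry order; the order matters for the shared-cell convention.
_RQ2_TABLE: list[tuple[str, str, str, str]] = [
    # low-strength subgroup ~ age-induced phenotype
    (LOW, HIGH, "age", "greater"),
    (LOW, OBESITY, "age", "greater"),
    (LOW, HIGH, "strength", "less"),
    (LOW, OBESITY, "strength", "less"),
    # high-strength subgroup ~ post-traumatic phenotype
    (HIGH, LOW, "surgery", "greater"),
    (HIGH, OBESITY, "surgery", "greater"),
    (HIGH, LOW, "strength", "greater"),
    (HIGH, OBESITY, "strength", "greater"),
    (HIGH, LOW, "sex", "greater"),
    (HIGH, OBESITY, "sex", "greater"),
    (HIGH, LOW, "age", "less"),
    (HIGH, OBESITY, "age", "less"),
    (HIGH, LOW, "kl", "greater"),
    (HIGH, OBESITY, "kl", "greater"),
    (HIGH, LOW, "comorbidity", "less"),
    (HIGH, OBESITY, "comorbidity", "less"),
    (HIGH, LOW, "pain", "less"),
    (HIGH, OBESITY, "pain", "less"),
    (HIGH, LOW, "function", "less"),
    (HIGH, OBESITY, "function", "less"),
    # obesity subgroup ~ metabolic phenotype
    (OBESITY, HIGH, "bmi", "greater"),
    (OBESITY, LOW, "bmi", "greater"),
    (OBESITY, HIGH, "comorbidity", "greater"),
    (OBESITY, LOW, "comorbidity", "greater"),
    (OBESITY, HIGH, "strength", "less"),
    (OBESITY, LOW, "strength", "less"),
    (OBESITY, HIGH, "pain", "greater"),
    (OBESITY, LOW, "pain", "greater"),
    (OBESITY, HIGH, "function", "greater"),
    (OBESITY, LOW, "function", "greater"),
]

_RQ3_BANDS = {
    LOW: ("large", "majority"),
    OBESITY: ("medium", "half"),
    HIGH: ("small", "minority"),
}
_RQ3_OUTCOMES = ("pain", "function", "strength")
_RQ3_SUBGROUP_ORDER = (LOW, OBESITY, HIGH)


def build_registry(
    cohorts: Sequence[str] = CANONICAL_COHORTS,
    rules: Optional[RuleConstants] = None,
) -> list[HypothesisSpec]:
    """Construct the full a-priori registry (15 + 30 + 18 = 63)."""
    rules = rules or RuleConstants()
    specs: list[HypothesisSpec] = []
    for label in (LOW, HIGH, OBESITY):
        for cohort in cohorts:
            specs.append(
                HypothesisSpec(
                    id=f"rq1_{label}_{cohort}",
                    research_question="RQ1",
                    subject=cohort,
                    comparator="total_sample",
                    variable=label,
                    rule_kind="deviation_within",
                    max_deviation=rules.max_proportion_deviation,
                )
            )
    for i, (subject, comparator, variable, direction) in enumerate(_RQ2_TABLE, 1):
        specs.append(
            HypothesisSpec(
                id=f"rq2_{i:02d}_{subject}_{variable}_vs_{comparator}",
                research_question="RQ2",
                subject=subject,
                comparator=comparator,
                variable=variable,
                rule_kind="directional_test",
                expected_direction=direction,
            )
        )
    for subgroup in _RQ3_SUBGROUP_ORDER:
        es_band, mic_band = _RQ3_BANDS[subgroup]
        for outcome in _RQ3_OUTCOMES:
            for measure, band in (("effect_size", es_band), ("mic_rate", mic_band)):
                kind = "effect_band" if measure == "effect_size" else "responder_band"
                short = "es" if measure == "effect_size" else "mic"
                specs.append(
                    HypothesisSpec(
                        id=f"rq3_{subgroup}_{outcome}_{short}",
                        research_question="RQ3",
                        subject=subgroup,
                        comparator=band,
                        variable=outcome,
                        rule_kind=kind,
                        measure=measure,
                        band=band,
                    )
                )
    return specs


# ---------------------------------------------------------------------------
# summary statistics container


@dataclass(frozen=True)
class ContinuousStat:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class CategoricalStat:
    counts: dict[str, int]  # category -> count

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class PrintedP:
    """A p-value as printed in a source table, e.g. '<0.001' or '0.55'."""

    value: float
    is_upper_bound: bool = False

    @classmethod
    def parse(cls, text: str) -> "PrintedP":
        text = text.strip()
        if text.startswith("<"):
            return cls(value=float(text[1:]), is_upper_bound=True)
        return cls(value=float(text))

    def significant(self, alpha: float) -> bool:
        # "<0.001" certifies p < 0.001; significant whenever the bound
        # does not exceed alpha.
        if self.is_upper_bound:
            return self.value <= alpha
        return self.value < alpha

    def __str__(self) -> str:
        return f"<{self.value:g}" if self.is_upper_bound else f"{self.value:g}"


Stat = Union[ContinuousStat, CategoricalStat]


@dataclass
class SummaryStats:
    """Per-subgroup summaries feeding the RQ2 pairwise comparisons.

    ``stats[variable][subgroup]`` is a :class:`ContinuousStat` or
    :class:`CategoricalStat`.  ``printed_p[(variable, a, b)]`` carries
    an externally reported p-value for a pair (with ``a`` < ``b``
    lexicographically); when present it takes precedence over
    recomputation — a source table's test may have used patient-level
    information that the summaries alone cannot reconstruct.
    """

    stats: dict[str, dict[str, Stat]]
    printed_p: dict[tuple[str, str, str], PrintedP] = field(default_factory=dict)

    def get(self, variable: str, subgroup: str) -> Optional[Stat]:
        return self.stats.get(variable, {}).get(subgroup)

    def get_printed_p(self, variable: str, a: str, b: str) -> Optional[PrintedP]:
        key = (variable, *sorted((a, b)))
        return self.printed_p.get(key)

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], labels: pd.Series
    ) -> "SummaryStats":
        """Compute the summaries from patient-level data.

        Complete cases per variable: structurally missing surgery /
        comorbidity values simply drop out of their cells.
        """
        records = list(records)
        stats_out: dict[str, dict[str, Stat]] = {}

        def continuous(variable: str, value_of) -> None:
            per: dict[str, Stat] = {}
            for sub in (LOW, HIGH, OBESITY):
                vals = [
                    v
                    for r in records
                    if labels.get(r.patient_id) == sub
                    and (v := value_of(r)) is not None
                ]
                if len(vals) >= 2:
                    per[sub] = ContinuousStat(
                        mean=float(np.mean(vals)),
                        sd=float(np.std(vals, ddof=1)),
                        n=len(vals),
                    )
            stats_out[variable] = per

        def categorical(variable: str, categories: Sequence[str], cat_of) -> None:
            per: dict[str, Stat] = {}
            for sub in (LOW, HIGH, OBESITY):
                counts = {c: 0 for c in categories}
                any_seen = False
                for r in records:
                    if labels.get(r.patient_id) != sub:
                        continue
                    cat = cat_of(r)
                    if cat is None:
                        continue
                    counts[cat] += 1
                    any_seen = True
                if any_seen:
                    per[sub] = CategoricalStat(counts=counts)
            stats_out[variable] = per

        continuous("age", lambda r: r.age)
        continuous("bmi", lambda r: r.bmi)
        continuous("pain", lambda r: harmonize_pain(r.pain_baseline_raw, r.pain_scale))
        continuous("function", lambda r: r.womac_pf_baseline)
        continuous(
            "strength_iso",
            lambda r: r.strength_baseline
            if r.strength_instrument == "isokinetic"
            else None,
        )
        continuous(
            "strength_cst",
            lambda r: r.strength_baseline if r.strength_instrument == "cst30" else None,
        )
        categorical("sex", ("female", "male"), lambda r: r.sex.value)
        categorical(
            "surgery",
            ("yes", "no"),
            lambda r: None if r.knee_surgery is None else ("yes" if r.knee_surgery else "no"),
        )
        categorical("kl", ("0/1", "2", "3", "4"), lambda r: r.kl_category)
        categorical(
            "comorbidity", ("0", "1", "2", "3+"), lambda r: r.comorbidity_category
        )
        return cls(stats=stats_out)


# ---------------------------------------------------------------------------
# statistical primitives


def pairwise_t_test(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Two-sided p from the pooled-variance independent-samples t-test.

    Computed from summary statistics; identical to the raw-vector test
    for the same means, sds and sizes.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be > 0")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return float(res.pvalue)


def pairwise_chi_square(counts) -> float:
    """Two-sided p from Pearson's chi-square, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a 2-d contingency table with >= 2 rows and columns")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero row or column")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue)


def _ordering_statistic(variable: str, stat: Stat) -> float:
    """Scalar whose ordering across groups carries the direction."""
    if isinstance(stat, ContinuousStat):
        return stat.mean
    if variable in BINARY_POSITIVE:
        pos = BINARY_POSITIVE[variable]
        return stat.counts.get(pos, 0) / stat.n
    scores = ORDINAL_SCORES[variable]
    total = sum(stat.counts.get(c, 0) for c in scores)
    return sum(scores[c] * stat.counts.get(c, 0) for c in scores) / total


def direction_check(
    variable: str, stat_subject: Stat, stat_comparator: Stat, expected: str
) -> bool:
    """Whether the observed ordering matches the expected direction.

    Continuous variables compare means; binary ones the positive-class
    proportion; ordinal categoricals a mean category score.  Exactly
    equal statistics have no direction and fail either expectation.
    """
    a = _ordering_statistic(variable, stat_subject)
    b = _ordering_statistic(variable, stat_comparator)
    if expected == "greater":
        return a > b
    if expected == "less":
        return a < b
    raise ValueError(f"unknown expected direction {expected!r}")


def _cell_p_value(
    variable: str, stat_a: Stat, stat_b: Stat, summary: SummaryStats, a: str, b: str
) -> tuple[Optional[PrintedP], Optional[float]]:
    """(printed p, computed p) for one pair; printed takes precedence."""
    printed = summary.get_printed_p(variable, a, b)
    if printed is not None:
        return printed, None
    if isinstance(stat_a, ContinuousStat):
        p = pairwise_t_test(
            stat_a.mean, stat_a.sd, stat_a.n, stat_b.mean, stat_b.sd, stat_b.n
        )
    else:
        cats = [
            c
            for c in stat_a.counts
            if stat_a.counts.get(c, 0) + stat_b.counts.get(c, 0) > 0
        ]
        table = [
            [stat_a.counts.get(c, 0) for c in cats],
            [stat_b.counts.get(c, 0) for c in cats],
        ]
        p = pairwise_chi_square(table)
    return None, p


# ---------------------------------------------------------------------------
# research question evaluators


def evaluate_rq1(
    table: ProportionTable,
    registry: Optional[list[HypothesisSpec]] = None,
    rules: Optional[RuleConstants] = None,
) -> list[Verdict]:
    """Apply the +/-10 percentage-point deviation rule per cohort x subgroup.

    Deviations are compared unrounded; |deviation| <= 10.0 accepts.
    """
    rules = rules or RuleConstants()
    if registry is None:
        registry = build_registry(cohorts=list(table.counts.index), rules=rules)
    verdicts = []
    for spec in registry:
        if spec.research_question != "RQ1":
            continue
        rule_txt = f"|cohort% - pooled%| <= {spec.max_deviation:g} pp"
        if spec.subject not in table.counts.index or (
            table.cohort_totals[spec.subject] == 0
        ):
            verdicts.append(
                Verdict(spec.id, "RQ1", "n/a", rule_txt, None, "cohort empty or absent")
            )
            continue
        dev = float(table.deviations.loc[spec.subject, spec.variable])
        verdicts.append(
            Verdict(
                hypothesis_id=spec.id,
                research_question="RQ1",
                observed=f"{dev:+.1f} pp",
                rule=rule_txt,
                accepted=abs(dev) <= spec.max_deviation,
            )
        )
    return verdicts


def _evaluate_rq2_cell(
    spec: HypothesisSpec, summary: SummaryStats, rules: RuleConstants
) -> tuple[Optional[bool], str, str]:
    """Evaluate one subgroup-pair x variable cell.

    Returns (accepted, observed, note).  Strength applies the
    dual-instrument OR rule; other variables test one cell.
    """
    variables = (
        STRENGTH_VARIABLES if spec.variable == "strength" else (spec.variable,)
    )
    parts: list[str] = []
    any_ok = False
    any_defined = False
    for var in variables:
        stat_a = summary.get(var, spec.subject)
        stat_b = summary.get(var, spec.comparator)
        if stat_a is None or stat_b is None:
            parts.append(f"{var}: missing")
            continue
        try:
            printed, computed = _cell_p_value(
                var, stat_a, stat_b, summary, spec.subject, spec.comparator
            )
        except ValueError:
            parts.append(f"{var}: not testable (degenerate data)")
            continue
        any_defined = True
        if printed is not None:
            sig = printed.significant(rules.alpha)
            p_txt = f"p={printed}"
        else:
            sig = computed < rules.alpha
            p_txt = f"p={computed:.3g}"
        right_way = direction_check(var, stat_a, stat_b, spec.expected_direction)
        ok = sig and right_way
        any_ok = any_ok or ok
        tag = "" if right_way else " (opposite direction)" if sig else ""
        parts.append(f"{var}: {p_txt}{tag}")
    if not any_defined:
        return None, "; ".join(parts), "missing data"
    return any_ok, "; ".join(parts), ""


def evaluate_rq2(
    data: Union[SummaryStats, Iterable[PatientRecord]],
    labels: Optional[pd.Series] = None,
    registry: Optional[list[HypothesisSpec]] = None,
    rules: Optional[RuleConstants] = None,
) -> list[Verdict]:
    """Evaluate the 30 phenotype-characteristic hypotheses.

    ``data`` is either a prebuilt :class:`SummaryStats` (reproduction
    mode) or patient-level records plus their subgroup ``labels``
    (analysis mode).  Shared cells are evaluated once, with the
    expected direction of the first-registered hypothesis, and every
    hypothesis mapping to the cell inherits the verdict.
    """
    rules = rules or RuleConstants()
    registry = registry or build_registry(rules=rules)
    if isinstance(data, SummaryStats):
        summary = data
    else:
        if labels is None:
            raise ValueError("labels are required with patient-level data")
        summary = SummaryStats.from_records(data, labels)

    rule_txt = f"p < {rules.alpha:g} and expected direction"
    verdicts: list[Verdict] = []
    cell_cache: dict[tuple[frozenset, str], tuple[Optional[bool], str, str, str]] = {}
    for spec in registry:
        if spec.research_question != "RQ2":
            continue
        key = (frozenset((spec.subject, spec.comparator)), spec.variable)
        if key in cell_cache:
            accepted, observed, note, first_id = cell_cache[key]
            shared = f"shared cell, inherits verdict of {first_id}"
            note = f"{note}; {shared}" if note else shared
        else:
            accepted, observed, note = _evaluate_rq2_cell(spec, summary, rules)
            cell_cache[key] = (accepted, observed, note, spec.id)
        verdicts.append(
            Verdict(
                hypothesis_id=spec.id,
                research_question="RQ2",
                observed=observed,
                rule=rule_txt,
                accepted=accepted,
                note=note,
            )
        )
    return verdicts


def effect_band_check(
    es_values: Sequence[float], kind: str, rules: Optional[RuleConstants] = None
) -> bool:
    """Whether any of one or two effect sizes lies in the claimed band.

    Bands derive from hypothesized effects of 0.8 / 0.5 / 0.2 with a
    +/-0.2 margin: large >= 0.6 (unbounded above), medium within
    [0.3, 0.7], small <= 0.4 (unbounded below).  Values are compared at
    two-decimal precision; with two instruments, one passing value
    accepts.
    """
    rules = rules or RuleConstants()
    vals = [round(float(v), 2) for v in es_values]
    if not vals:
        raise ValueError("no effect sizes supplied")
    if kind == "large":
        return any(v >= rules.large_es_min for v in vals)
    if kind == "medium":
        return any(rules.medium_es_min <= v <= rules.medium_es_max for v in vals)
    if kind == "small":
        return any(v <= rules.small_es_max for v in vals)
    raise ValueError(f"unknown effect-size band {kind!r}")


def responder_band_check(
    rates: Sequence[float], kind: str, rules: Optional[RuleConstants] = None
) -> bool:
    """Whether any responder rate (percent) lies in the claimed band.

    Rates are integer-rounded first; majority > 67, half within
    [33, 67], minority < 33.  With two instruments, one passing rate
    accepts.
    """
    rules = rules or RuleConstants()
    vals = [int(round(float(r))) for r in rates]
    if not vals:
        raise ValueError("no responder rates supplied")
    if kind == "majority":
        return any(v > rules.majority_min for v in vals)
    if kind == "half":
        return any(rules.half_min <= v <= rules.half_max for v in vals)
    if kind == "minority":
        return any(v < rules.minority_max for v in vals)
    raise ValueError(f"unknown responder band {kind!r}")


def _effects_lookup(
    effects: Union[Sequence[EffectResult], pd.DataFrame],
) -> dict[tuple[str, str], list[tuple[Optional[str], float, Optional[float]]]]:
    """Normalize effects input to {(subgroup, outcome): [(instrument, es, rate)]}."""
    out: dict[tuple[str, str], list] = {}
    if isinstance(effects, pd.DataFrame):
        for _, row in effects.iterrows():
            instr = row.get("instrument")
            instr = None if (pd.isna(instr) or instr == "") else str(instr)
            rate = row.get("mic_rate", row.get("responder_rate_pct"))
            rate = None if pd.isna(rate) else float(rate)
            out.setdefault((row["subgroup"], row["outcome"]), []).append(
                (instr, float(row["effect_size"]), rate)
            )
    else:
        for r in effects:
            out.setdefault((r.subgroup, r.outcome), []).append(
                (r.instrument, r.effect_size, r.responder_rate)
            )
    return out


def evaluate_rq3(
    effects: Union[Sequence[EffectResult], pd.DataFrame],
    registry: Optional[list[HypothesisSpec]] = None,
    rules: Optional[RuleConstants] = None,
) -> list[Verdict]:
    """Evaluate the 18 treatment-response band hypotheses.

    ``effects`` comes from :func:`octostrat.outcomes.compute_effects`
    (analysis mode) or from a printed-effects fixture DataFrame with
    columns subgroup/outcome/instrument/effect_size/mic_rate
    (reproduction mode).
    """
    rules = rules or RuleConstants()
    registry = registry or build_registry(rules=rules)
    lookup = _effects_lookup(effects)
    verdicts: list[Verdict] = []
    for spec in registry:
        if spec.research_question != "RQ3":
            continue
        entries = lookup.get((spec.subject, spec.variable), [])
        if spec.measure == "effect_size":
            values = [es for _, es, _ in entries]
            check = effect_band_check
            fmt = "{:.2f}"
        else:
            values = [rate for _, _, rate in entries if rate is not None]
            check = responder_band_check
            fmt = "{:.0f}%"
        rule_txt = f"{spec.measure} in band '{spec.band}'"
        if not values:
            verdicts.append(
                Verdict(spec.id, "RQ3", "n/a", rule_txt, None, "missing outcome")
            )
            continue
        observed = " / ".join(fmt.format(v) for v in values)
        verdicts.append(
            Verdict(
                hypothesis_id=spec.id,
                research_question="RQ3",
                observed=observed,
                rule=rule_txt,
                accepted=check(values, spec.band, rules),
            )
        )
    return verdicts


# ---------------------------------------------------------------------------
# aggregation


def aggregate(verdicts: Sequence[Verdict]) -> dict:
    """Per-question and overall acceptance counts for a full 63-run."""
    verdicts = list(verdicts)
    if len(verdicts) != 63:
        raise ValueError(f"expected 63 verdicts, got {len(verdicts)}")
    out: dict = {}
    total_accepted = 0
    for rq, expected_n in (("RQ1", 15), ("RQ2", 30), ("RQ3", 18)):
        subset = [v for v in verdicts if v.research_question == rq]
        if len(subset) != expected_n:
            raise ValueError(f"expected {expected_n} {rq} verdicts, got {len(subset)}")
        accepted = sum(1 for v in subset if v.accepted is True)
        undefined = sum(1 for v in subset if v.accepted is None)
        out[rq.lower()] = {
            "accepted": accepted,
            "total": expected_n,
            "undefined": undefined,
        }
        total_accepted += accepted
    out["overall"] = {
        "accepted": total_accepted,
        "total": 63,
        "percent": int(round(100.0 * total_accepted / 63)),
    }
    return out


def verdicts_to_frame(verdicts: Sequence[Verdict]) -> pd.DataFrame:
    """Verdict ledger: one row per hypothesis."""
    return pd.DataFrame(
        [
            {
                "hypothesis_id": v.hypothesis_id,
                "research_question": v.research_question,
                "observed": v.observed,
                "rule": v.rule,
                "accepted": "" if v.accepted is None else bool(v.accepted),
                "note": v.note,
            }
            for v in verdicts
        ]
    )
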