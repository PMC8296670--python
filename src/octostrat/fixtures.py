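"""Packaged fixtures: the published summary tables as delimited files.

The five cohorts' raw patient data are not redistributable; what the
original report prints are cohort profiles, per-cohort subgroup counts,
per-subgroup baseline summaries with pairwise p-values, and
per-subgroup treatment effects.  Those printed values are shipped here
as small CSVs and drive "reproduction mode": the decision arithmetic
(deviation rule, directional-significance rule, band rules) is
re-executed on them.

Notes on provenance of derived fixture entries:

* the pooled obesity subgroup count is carried as the sum of the
  printed per-cohort counts (577); the source table prints a pooled
  547 that contradicts its own column and its own 48% share, and is
  treated as a typo;
* per-variable group sizes that the source does not print (surgery
  denominators, per-instrument strength ns) are reconstructed from the
  printed percentages and the per-cohort subgroup counts; they matter
  only to the recomputation path, not to the printed p-values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .hypotheses import CategoricalStat, ContinuousStat, PrintedP, SummaryStats
from .model import CohortProfile
from .stratify import ProportionTable

__all__ = [
    "DATA_DIR",
    "load_cohort_profiles",
    "load_proportion_table",
    "load_table4_summary",
    "load_table5_effects",
]

DATA_DIR = Path(__file__).parent / "data"


def load_cohort_profiles() -> list[CohortProfile]:
    """Cohort sizes, instruments and structural data availability."""
    df = pd.read_csv(DATA_DIR / "table2_cohort_profiles.csv")
    return [
        CohortProfile(
            cohort_id=row.cohort_id,
            strength_instrument=row.strength_instrument,
            has_surgery_data=bool(row.has_surgery),
            has_comorbidity_data=bool(row.has_comorbidity),
            has_followup=bool(row.has_followup),
            n=int(row.n),
        )
        for row in df.itertuples()
    ]


def load_cohort_profiles_frame() -> pd.DataFrame:
    """Raw cohort-profile table (includes exercise-arm sizes)."""
    return pd.read_csv(DATA_DIR / "table2_cohort_profiles.csv")


def load_proportion_table() -> ProportionTable:
    """Per-cohort subgroup counts as a filled :class:`ProportionTable`."""
    df = pd.read_csv(DATA_DIR / "table3_subgroup_counts.csv").set_index("cohort_id")
    return ProportionTable.from_counts(df)


def load_table4_summary() -> SummaryStats:
    """Subgroup baseline summaries plus printed pairwise p-values."""
    df = pd.read_csv(
        DATA_DIR / "table4_subgroup_summaries.csv", dtype={"category": str}
    )
    stats: dict[str, dict] = {}
    for (variable, kind), grp in df.groupby(["variable", "kind"], sort=False):
        per: dict = {}
        if kind == "continuous":
            for _, row in grp.iterrows():
                per[row["subgroup"]] = ContinuousStat(
                    mean=float(row["mean"]), sd=float(row["sd"]), n=int(row["n"])
                )
        else:
            for subgroup, sub in grp.groupby("subgroup", sort=False):
                per[subgroup] = CategoricalStat(
                    counts={
                        row["category"]: int(row["count"])
                        for _, row in sub.iterrows()
                    }
                )
        stats[variable] = per

    pvals = pd.read_csv(DATA_DIR / "table4_printed_pvalues.csv")
    printed = {
        (row.variable, *sorted((row.group_a, row.group_b))): PrintedP.parse(row.p)
        for row in pvals.itertuples()
    }
    return SummaryStats(stats=stats, printed_p=printed)


def load_table5_effects() -> pd.DataFrame:
    """Printed per-subgroup effect sizes and MIC responder rates."""
    return pd.read_csv(DATA_DIR / "table5_treatment_effects.csv")
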