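"""Rule constants for stratification and hypothesis evaluation.

Every decision constant of the pipeline lives here so that it can be
inspected, logged and overridden from a single structured config file:
the BMI and strength cutoffs of the allocation rule, the +/-10
percentage-point proportion-deviation band, the alpha level of the
pairwise tests, the effect-size bands (large/medium/small) and the
responder-rate bands (majority/half/minority), and the per-instrument
minimal important changes.  The defaults are the values the validity
framework was formulated with.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["RuleConstants", "load_rules", "dump_rules", "DEFAULT_CONFIG_PATH"]

DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "default_config.yaml"


@dataclass(frozen=True)
class RuleConstants:
    """All tunable decision constants with their a-priori defaults."""

    # --- allocation rule -------------------------------------------------
    bmi_obesity_cutoff: float = 30.0  # kg/m2, inclusive
    isokinetic_cutoff: float = 1.2  # Nm/kg, inclusive
    cst30_cutoff: float = 12.0  # repetitions, inclusive

    # --- subgroup-proportion consistency (research question 1) ----------
    max_proportion_deviation: float = 10.0  # percentage points, inclusive

    # --- pairwise phenotype comparisons (research question 2) -----------
    alpha: float = 0.05  # strict: accept requires p < alpha

    # --- effect-size bands, hypothesized 0.8 / 0.5 / 0.2 each +/- 0.2 ----
    # "large" is a lower bound only and "small" an upper bound only: an
    # effect larger than hypothesized cannot refute a "large" claim, nor
    # a smaller one a "small" claim.
    large_es_min: float = 0.6
    medium_es_min: float = 0.3
    medium_es_max: float = 0.7
    small_es_max: float = 0.4

    # --- responder-rate bands (percent, evaluated on integer-rounded) ---
    majority_min: float = 67.0  # strict: rate > 67
    half_min: float = 33.0  # inclusive both sides
    half_max: float = 67.0
    minority_max: float = 33.0  # strict: rate < 33

    # --- minimal important changes ---------------------------------------
    pain_mic_percent: float = 0.15  # of baseline, OR ...
    pain_mic_absolute: float = 1.0  # ... 1 point on the 0-10 scale
    womac_mic_percent: float = 0.12
    isokinetic_mic_percent: float = 0.30
    cst30_mic_absolute: float = 2.0

    def strength_cutoff(self, instrument: str) -> float:
        try:
            return {
                "isokinetic": self.isokinetic_cutoff,
                "cst30": self.cst30_cutoff,
            }[instrument]
        except KeyError:
            raise ValueError(f"unknown strength instrument {instrument!r}") from None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RuleConstants":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rule constants: {sorted(unknown)}")
        return cls(**d)


def load_rules(path: Optional[str | Path] = None) -> RuleConstants:
    """Load rule constants from a YAML config (section ``rules``).

    With no path, returns the defaults.  A config file may override any
    subset of constants; unknown keys are an error.
    """
    if path is None:
        return RuleConstants()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    section = doc.get("rules", doc)
    base = RuleConstants().to_dict()
    base.update(section or {})
    return RuleConstants.from_dict(base)


def dump_rules(rules: RuleConstants, path: str | Path) -> None:
    """Write ``rules`` to a YAML file under a ``rules`` section."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"rules": rules.to_dict()}, fh, sort_keys=False)
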