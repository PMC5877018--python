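"""Study exclusion rules with conserved accounting.

Three rules are applied in a fixed order — clinically underweight, then
race outside the black/white study population, then missing values in any
modeled column — and each row is attributed to the first rule it trips, so
the per-rule counts always sum back to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import INDIVIDUAL_COLS, OUTCOME_COL, RACE_COL

#: BMI-for-age 5th percentile expressed on the z-score scale
UNDERWEIGHT_Z_CUTOFF = float(stats.norm.ppf(0.05))

#: race codes retained in the study population
RETAINED_RACE_CODES = ("white", "black")

#: columns in which a missing value triggers exclusion
MODELED_COLS = (OUTCOME_COL,) + INDIVIDUAL_COLS


@dataclass
class ExclusionReport:
    """Accounting of the sequential exclusion rules."""

    n_input: int
    n_underweight: int
    n_race_excluded: int
    n_missing: int
    n_retained: int
    rows_underweight: list = field(default_factory=list, repr=False)
    rows_race_excluded: list = field(default_factory=list, repr=False)
    rows_missing: list = field(default_factory=list, repr=False)

    def check_conservation(self) -> bool:
        return (
            self.n_input
            == self.n_underweight + self.n_race_excluded + self.n_missing + self.n_retained
        )

    def to_text(self) -> str:
        lines = [
            f"observations in:        {self.n_input}",
            f"excluded underweight:   {self.n_underweight}",
            f"excluded race:          {self.n_race_excluded}",
            f"excluded missing:       {self.n_missing}",
            f"retained for analysis:  {self.n_retained}",
        ]
        return "\n".join(lines)


def flag_underweight(
    cohort: pd.DataFrame, z_cutoff: float = UNDERWEIGHT_Z_CUTOFF
) -> np.ndarray:
    """Flag clinically underweight visits: BMI z-score strictly below the
    5th-percentile cutoff.  Missing BMIZ is not flagged here (it is caught by
    the missingness rule)."""
    z = cohort[OUTCOME_COL].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        return (z < z_cutoff) & ~np.isnan(z)


def flag_race_excluded(cohort: pd.DataFrame) -> np.ndarray:
    """Flag visits whose race code is outside the retained study population.

    Unknown or unparseable codes are excluded (and therefore counted) under
    this rule."""
    race = cohort[RACE_COL].astype(str).str.lower()
    return (~race.isin(RETAINED_RACE_CODES)).to_numpy()


def flag_missing(cohort: pd.DataFrame, columns: tuple[str, ...] = MODELED_COLS) -> np.ndarray:
    present = [c for c in columns if c in cohort.columns]
    return cohort[present].isna().any(axis=1).to_numpy()


def apply_exclusions(
    cohort: pd.DataFrame, z_cutoff: float = UNDERWEIGHT_Z_CUTOFF
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion rules sequentially and return the analysis table.

    Order: underweight, then race, then missingness.  A row tripping several
    rules is counted once, under the first rule, so the report conserves the
    input count exactly.
    """
    n_input = len(cohort)
    under = flag_underweight(cohort, z_cutoff)
    race = flag_race_excluded(cohort) & ~under
    missing = flag_missing(cohort) & ~under & ~race
    keep = ~(under | race | missing)
    report = ExclusionReport(
        n_input=n_input,
        n_underweight=int(under.sum()),
        n_race_excluded=int(race.sum()),
        n_missing=int(missing.sum()),
        n_retained=int(keep.sum()),
        rows_underweight=cohort.index[under].tolist(),
        rows_race_excluded=cohort.index[race].tolist(),
        rows_missing=cohort.index[missing].tolist(),
    )
    return cohort.loc[keep].copy(), report
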