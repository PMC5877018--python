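"""Hierarchical data structures and the multi-scale candidate design matrix.

The analysis operates on a cohort of patient visits nested in census
geography (census block CBK -> block group CBG -> tract CT).  Area-level
covariates are observed at one or more of these scales; each substantive
covariate ("concept", e.g. median household income) therefore appears in the
candidate design as several scale-specific columns.  This module builds that
design, validates the geography nesting, and implements the two predictor
standardization schemes used downstream:

* full standardization (outcome and predictors to mean 0, SD 1) so the path
  algorithms can run without an intercept, and
* the Gelman convention (binary predictors centered, continuous predictors
  divided by two standard deviations) so main effects and interactions are on
  a comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INDIVIDUAL = "individual"
CBK = "CBK"
CBG = "CBG"
CT = "CT"
AREA_SCALES = (CBK, CBG, CT)

#: cohort columns required for modeling (outcome + individual covariates)
OUTCOME_COL = "BMIZ"
INDIVIDUAL_COLS = ("VisitAge", "Male", "Black", "MCVdist")
GEO_ID_COLS = ("cbk_id", "cbg_id", "ct_id")
RACE_COL = "race_code"


class DataModelError(ValueError):
    """Raised for structurally invalid inputs (bad nesting, missing units)."""


@dataclass(frozen=True)
class GeoHierarchy:
    """Explicit nesting maps between census geography identifiers.

    Identifiers are opaque strings; nesting is never inferred from identifier
    prefixes, so synthetic IDs work exactly like FIPS codes.
    """

    cbk_to_cbg: dict[str, str]
    cbg_to_ct: dict[str, str]

    def ct_of_cbk(self, cbk: str) -> str:
        return self.cbg_to_ct[self.cbk_to_cbg[cbk]]

    @property
    def cts(self) -> list[str]:
        return sorted(set(self.cbg_to_ct.values()))

    @property
    def cbgs(self) -> list[str]:
        return sorted(self.cbg_to_ct)

    @property
    def cbks(self) -> list[str]:
        return sorted(self.cbk_to_cbg)

    @classmethod
    def from_frames(cls, cbk_map: pd.DataFrame, cbg_map: pd.DataFrame) -> "GeoHierarchy":
        """Build from two mapping tables with columns (cbk_id, cbg_id) and
        (cbg_id, ct_id)."""
        return cls(
            cbk_to_cbg=dict(zip(cbk_map["cbk_id"].astype(str), cbk_map["cbg_id"].astype(str))),
            cbg_to_ct=dict(zip(cbg_map["cbg_id"].astype(str), cbg_map["ct_id"].astype(str))),
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cbk = pd.DataFrame(
            {"cbk_id": list(self.cbk_to_cbg), "cbg_id": list(self.cbk_to_cbg.values())}
        )
        cbg = pd.DataFrame(
            {"cbg_id": list(self.cbg_to_ct), "ct_id": list(self.cbg_to_ct.values())}
        )
        return cbk, cbg


@dataclass(frozen=True)
class AreaCovariateTable:
    """Area covariates for one spatial scale: one row per unit identifier."""

    scale: str
    table: pd.DataFrame  # indexed by unit id (str)

    def __post_init__(self) -> None:
        if self.scale not in AREA_SCALES:
            raise DataModelError(f"unknown scale label {self.scale!r}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise DataModelError(f"duplicate unit IDs at scale {self.scale}: {dupes[:5]}")


@dataclass(frozen=True)
class ColumnInfo:
    """Metadata for one design column: which concept, at which scale."""

    concept: str
    scale: str  # 'individual' | 'CBK' | 'CBG' | 'CT'
    name: str
    variable_number: int


@dataclass(frozen=True)
class ConceptSpec:
    """Declaration of one conceptual variable and the scales it is observed at.

    For an individual-level concept ``scales`` maps 'individual' to the cohort
    column name; for an area-level concept it maps each scale label to the
    column name in that scale's :class:`AreaCovariateTable`.
    """

    concept: str
    scales: dict[str, str]
    variable_numbers: dict[str, int]

    @property
    def is_individual(self) -> bool:
        return INDIVIDUAL in self.scales


def table1_variable_spec() -> list[ConceptSpec]:
    """The study's candidate-variable pool: 4 individual covariates plus 13
    area-level concepts, one of which (population density) is observed at
    three scales and the rest at two — 31 columns in total."""
    specs: list[ConceptSpec] = []
    for i, name in enumerate(INDIVIDUAL_COLS, start=1):
        specs.append(ConceptSpec(name, {INDIVIDUAL: name}, {INDIVIDUAL: i}))
    specs.append(
        ConceptSpec(
            "POPDENS",
            {CBK: "POPDENS", CBG: "POPDENS", CT: "POPDENS"},
            {CBK: 5, CBG: 6, CT: 7},
        )
    )
    two_scale = [
        "PBLACK",
        "PHWHITE",
        "PHBLACK",
        "MEDHINC",
        "PRENTER",
        "PVACANT",
        "CRMCYTOTC",
        "CRMCYPERC",
        "CRMCYPROC",
        "PARKDENS",
        "RESTDENS",
        "EX_EQ",
    ]
    num = 8
    for name in two_scale:
        specs.append(
            ConceptSpec(name, {CBG: name, CT: name}, {CBG: num, CT: num + 1})
        )
        num += 2
    return specs


@dataclass
class CandidateDesign:
    """An n x p predictor matrix whose columns carry (concept, scale) metadata."""

    X: pd.DataFrame
    columns: list[ColumnInfo]

    def __post_init__(self) -> None:
        if list(self.X.columns) != [c.name for c in self.columns]:
            raise DataModelError("design matrix columns and metadata disagree")
        seen = set()
        for c in self.columns:
            key = (c.concept, c.scale)
            if key in seen:
                raise DataModelError(f"duplicate (concept, scale) pair {key}")
            seen.add(key)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return len(self.columns)

    def info(self, name: str) -> ColumnInfo:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def siblings(self, name: str) -> list[str]:
        """Other columns carrying the same concept at a different scale."""
        concept = self.info(name).concept
        return [c.name for c in self.columns if c.concept == concept and c.name != name]

    def concepts(self) -> list[str]:
        out: list[str] = []
        for c in self.columns:
            if c.concept not in out:
                out.append(c.concept)
        return out

    def subset(self, names: list[str]) -> "CandidateDesign":
        cols = [self.info(n) for n in names]
        return CandidateDesign(self.X[names].copy(), cols)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


@dataclass(frozen=True)
class StandardizationRecipe:
    """Per-column affine transform ``(x - center) / divisor`` with enough
    information to invert it.  ``divisor`` is None for centered-only columns
    (Gelman-scheme binaries)."""

    centers: dict[str, float]
    divisors: dict[str, float | None]
    outcome_center: float | None = None
    outcome_scale: float | None = None

    @property
    def outcome_standardized(self) -> bool:
        return self.outcome_center is not None

    def invert_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        raw = X.copy()
        for name in X.columns:
            d = self.divisors.get(name)
            raw[name] = X[name] * (1.0 if d is None else d) + self.centers[name]
        return raw

    def invert_outcome(self, y: np.ndarray) -> np.ndarray:
        if not self.outcome_standardized:
            return np.asarray(y, dtype=float)
        return np.asarray(y, dtype=float) * self.outcome_scale + self.outcome_center


def validate_hierarchy(cohort: pd.DataFrame, geo: GeoHierarchy) -> list[str]:
    """Check that every cohort row's geography IDs are mutually consistent.

    Returns a list of human-readable violations; an empty list means the
    cohort is consistent with the declared nesting.  Violations are data,
    not exceptions: callers decide whether to abort.
    """
    violations: list[str] = []
    for idx, row in cohort[list(GEO_ID_COLS)].astype(str).iterrows():
        cbk, cbg, ct = row["cbk_id"], row["cbg_id"], row["ct_id"]
        if cbk not in geo.cbk_to_cbg:
            violations.append(f"row {idx}: CBK {cbk!r} not in hierarchy")
            continue
        if geo.cbk_to_cbg[cbk] != cbg:
            violations.append(
                f"row {idx}: CBK {cbk!r} maps to CBG {geo.cbk_to_cbg[cbk]!r}, row says {cbg!r}"
            )
        if cbg not in geo.cbg_to_ct:
            violations.append(f"row {idx}: CBG {cbg!r} not in hierarchy")
            continue
        if geo.cbg_to_ct[cbg] != ct:
            violations.append(
                f"row {idx}: CBG {cbg!r} maps to CT {geo.cbg_to_ct[cbg]!r}, row says {ct!r}"
            )
    return violations


_SCALE_ID_COL = {CBK: "cbk_id", CBG: "cbg_id", CT: "ct_id"}


def build_candidate_design(
    cohort: pd.DataFrame,
    area_tables: list[AreaCovariateTable],
    variable_spec: list[ConceptSpec] | None = None,
) -> CandidateDesign:
    """Join each cohort row to its unit's area covariates at every declared
    scale and assemble the candidate design matrix.

    Individual-level concepts are copied from the cohort; each area-level
    concept contributes one column per declared scale, named
    ``<concept>_<scale>``.  A unit missing from an area table is an error.
    """
    if variable_spec is None:
        variable_spec = table1_variable_spec()
    by_scale = {t.scale: t for t in area_tables}
    cols: dict[str, np.ndarray] = {}
    infos: list[ColumnInfo] = []
    for spec in variable_spec:
        for scale, src_col in spec.scales.items():
            if scale == INDIVIDUAL:
                if src_col not in cohort.columns:
                    raise DataModelError(f"cohort lacks individual column {src_col!r}")
                name = spec.concept
                vals = cohort[src_col].to_numpy(dtype=float)
            else:
                if scale not in by_scale:
                    raise DataModelError(
                        f"concept {spec.concept!r} declared at scale {scale} "
                        f"but no area table for that scale was provided"
                    )
                table = by_scale[scale].table
                if src_col not in table.columns:
                    raise DataModelError(
                        f"area table at scale {scale} lacks column {src_col!r}"
                    )
                ids = cohort[_SCALE_ID_COL[scale]].astype(str)
                missing = set(ids) - set(table.index.astype(str))
                if missing:
                    raise DataModelError(
                        f"units missing from {scale} area table: {sorted(missing)[:5]}"
                    )
                name = f"{spec.concept}_{scale}"
                vals = table[src_col].reindex(ids).to_numpy(dtype=float)
            cols[name] = vals
            infos.append(
                ColumnInfo(spec.concept, scale, name, spec.variable_numbers[scale])
            )
    X = pd.DataFrame(cols, index=cohort.index)
    return CandidateDesign(X, infos)


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def standardize_full(
    design: CandidateDesign, outcome: np.ndarray
) -> tuple[CandidateDesign, np.ndarray, StandardizationRecipe]:
    """Standardize every design column and the outcome to mean 0 and sample
    SD 1 (denominator n - 1), removing the need for an intercept."""
    X = design.X.copy()
    centers: dict[str, float] = {}
    divisors: dict[str, float | None] = {}
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        sd = _sample_sd(x)
        if sd == 0.0 or not np.isfinite(sd):
            raise DataModelError(f"zero-variance column {name!r} cannot be standardized")
        mu = float(np.mean(x))
        X[name] = (x - mu) / sd
        centers[name] = mu
        divisors[name] = sd
    y = np.asarray(outcome, dtype=float)
    y_mu, y_sd = float(np.mean(y)), _sample_sd(y)
    if y_sd == 0.0:
        raise DataModelError("zero-variance outcome cannot be standardized")
    y_std = (y - y_mu) / y_sd
    recipe = StandardizationRecipe(centers, divisors, outcome_center=y_mu, outcome_scale=y_sd)
    return CandidateDesign(X, list(design.columns)), y_std, recipe


def standardize_gelman(
    design: CandidateDesign, binary_flags: dict[str, bool] | None = None
) -> tuple[CandidateDesign, StandardizationRecipe]:
    """Rescale predictors following the two-SD convention: binary (0/1)
    columns are centered only; continuous columns are centered and divided by
    twice their sample SD, so all coefficients measure a low-to-high contrast.
    The outcome is left untouched."""
    X = design.X.copy()
    if binary_flags is None:
        binary_flags = {
            name: set(np.unique(X[name].to_numpy())) <= {0.0, 1.0} for name in X.columns
        }
    centers: dict[str, float] = {}
    divisors: dict[str, float | None] = {}
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        mu = float(np.mean(x))
        if binary_flags.get(name, False):
            levels = np.unique(x)
            if len(levels) > 2 or not set(levels) <= {0.0, 1.0}:
                raise DataModelError(
                    f"column {name!r} flagged binary but has levels {levels[:4]}"
                )
            X[name] = x - mu
            centers[name] = mu
            divisors[name] = None
        else:
            sd = _sample_sd(x)
            if sd == 0.0:
                raise DataModelError(f"zero-variance column {name!r}")
            X[name] = (x - mu) / (2.0 * sd)
            centers[name] = mu
            divisors[name] = 2.0 * sd
    recipe = StandardizationRecipe(centers, divisors)
    return CandidateDesign(X, list(design.columns)), recipe
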