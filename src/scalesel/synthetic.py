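"""Synthetic nested-geography cohorts with known truth.

The study's patient records are not public, so every downstream module is
exercised on simulated data that reproduces the structure of the real
dataset: patient visits nested in census blocks within block groups within
tracts; area covariates observed at two or three scales, where the
finer-scale version is a noisy refinement of its parent value with a
controllable cross-scale correlation rho; a linear BMI z-score outcome with
standardized effects at known scales, Gaussian random intercepts at the CBG
and/or CT, and residual noise; and a configurable number of rows that trip
each exclusion rule (underweight, out-of-population race, missing values).

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
generator seeded from the scenario, so a scenario is fully reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_filter import UNDERWEIGHT_Z_CUTOFF
from .data_model import (
    AreaCovariateTable,
    CandidateDesign,
    ConceptSpec,
    GeoHierarchy,
    INDIVIDUAL,
    INDIVIDUAL_COLS,
    build_candidate_design,
)

#: area concepts of the study's candidate pool and the scales each is
#: observed at (population density alone reaches down to the census block)
DEFAULT_AREA_CONCEPTS: dict[str, tuple[str, ...]] = {
    "POPDENS": ("CBK", "CBG", "CT"),
    "PBLACK": ("CBG", "CT"),
    "PHWHITE": ("CBG", "CT"),
    "PHBLACK": ("CBG", "CT"),
    "MEDHINC": ("CBG", "CT"),
    "PRENTER": ("CBG", "CT"),
    "PVACANT": ("CBG", "CT"),
    "CRMCYTOTC": ("CBG", "CT"),
    "CRMCYPERC": ("CBG", "CT"),
    "CRMCYPROC": ("CBG", "CT"),
    "PARKDENS": ("CBG", "CT"),
    "RESTDENS": ("CBG", "CT"),
    "EX_EQ": ("CBG", "CT"),
}

#: standardized effects emulating the study's selected main-effects model
DEFAULT_EFFECTS: dict[str, tuple[str, float]] = {
    "VisitAge": (INDIVIDUAL, 0.08),
    "Black": (INDIVIDUAL, 0.04),
    "MCVdist": (INDIVIDUAL, 0.013),
    "POPDENS": ("CT", -0.033),
    "PHWHITE": ("CBG", 0.03),
    "PHBLACK": ("CT", 0.02),
    "MEDHINC": ("CT", -0.055),
    "PRENTER": ("CT", -0.035),
    "PVACANT": ("CT", 0.015),
    "CRMCYPERC": ("CBG", -0.02),
    "PARKDENS": ("CT", 0.01),
    "EX_EQ": ("CBG", -0.04),
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of one simulated study.

    Defaults emulate the pediatric cohort: 29,471 visits, exclusion counts
    of 1,482 underweight / 449 out-of-population race / 2 missing, area
    covariates correlated rho = 0.7 across scales, small standardized
    effects at mixed scales, and unit-scale residual noise.
    """

    n_ct: int = 100
    cbgs_per_ct: int = 3
    cbks_per_cbg: int = 3
    n_total: int = 29_471
    rho: float = 0.7
    area_concepts: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_AREA_CONCEPTS)
    )
    effects: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    sigma_cbg: float = 0.0
    sigma_ct: float = 0.0
    sigma_eps: float = 0.95
    n_underweight: int = 1_482
    n_race_excluded: int = 449
    n_missing: int = 2
    p_black: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if min(self.n_ct, self.cbgs_per_ct, self.cbks_per_cbg, self.n_total) <= 0:
            raise ValueError("counts must be positive")
        if min(self.sigma_cbg, self.sigma_ct, self.sigma_eps) < 0:
            raise ValueError("standard deviations must be nonnegative")
        for concept, (scale, _) in self.effects.items():
            if scale == INDIVIDUAL:
                if concept not in INDIVIDUAL_COLS:
                    raise ValueError(f"unknown individual concept {concept!r}")
            elif scale not in self.area_concepts.get(concept, ()):
                raise ValueError(
                    f"effect for {concept!r} declared at scale {scale} "
                    f"but the concept is not observed there"
                )

    def variable_spec(self) -> list[ConceptSpec]:
        """Concept declarations matching this scenario's covariate pool,
        numbered individual-first then area concepts scale-by-scale."""
        specs: list[ConceptSpec] = []
        num = 1
        for name in INDIVIDUAL_COLS:
            specs.append(ConceptSpec(name, {INDIVIDUAL: name}, {INDIVIDUAL: num}))
            num += 1
        for concept, scales in self.area_concepts.items():
            specs.append(
                ConceptSpec(
                    concept,
                    {s: concept for s in scales},
                    {s: num + i for i, s in enumerate(scales)},
                )
            )
            num += len(scales)
        return specs


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to score a fitted model against the simulation."""

    effects: dict[str, tuple[str, float]]
    sigma_cbg: float
    sigma_ct: float
    sigma_eps: float
    seed: int

    @property
    def icc_cbg(self) -> float:
        tot = self.sigma_cbg**2 + self.sigma_ct**2 + self.sigma_eps**2
        return self.sigma_cbg**2 / tot if tot > 0 else 0.0


def generate_geography(scenario: SyntheticScenario) -> GeoHierarchy:
    """Strictly nested geography with opaque identifiers, sized exactly as
    configured."""
    cbk_to_cbg: dict[str, str] = {}
    cbg_to_ct: dict[str, str] = {}
    g = b = 0
    for t in range(scenario.n_ct):
        ct = f"T{t:05d}"
        for _ in range(scenario.cbgs_per_ct):
            cbg = f"G{g:06d}"
            cbg_to_ct[cbg] = ct
            g += 1
            for _ in range(scenario.cbks_per_cbg):
                cbk_to_cbg[f"B{b:07d}"] = cbg
                b += 1
    return GeoHierarchy(cbk_to_cbg, cbg_to_ct)


def generate_area_covariates(
    geo: GeoHierarchy, scenario: SyntheticScenario, rng: np.random.Generator
) -> list[AreaCovariateTable]:
    """Draw each concept top-down through the hierarchy.

    The tract value is standard normal; each child unit's value is
    rho * parent + sqrt(1 - rho^2) * independent noise, so every scale is
    marginally N(0,1) and corr(child, parent) = rho in expectation.
    """
    rho = scenario.rho
    mix = float(np.sqrt(1.0 - rho * rho))
    cts, cbgs, cbks = geo.cts, geo.cbgs, geo.cbks
    ct_pos = {u: i for i, u in enumerate(cts)}
    cbg_pos = {u: i for i, u in enumerate(cbgs)}
    data: dict[str, dict[str, np.ndarray]] = {"CT": {}, "CBG": {}, "CBK": {}}
    for concept, scales in scenario.area_concepts.items():
        u_ct = rng.standard_normal(len(cts))
        parent_ct = np.array([ct_pos[geo.cbg_to_ct[g]] for g in cbgs])
        u_cbg = rho * u_ct[parent_ct] + mix * rng.standard_normal(len(cbgs))
        parent_cbg = np.array([cbg_pos[geo.cbk_to_cbg[k]] for k in cbks])
        u_cbk = rho * u_cbg[parent_cbg] + mix * rng.standard_normal(len(cbks))
        for scale, vals, units in (
            ("CT", u_ct, cts),
            ("CBG", u_cbg, cbgs),
            ("CBK", u_cbk, cbks),
        ):
            if scale in scales:
                data[scale][concept] = vals
    tables = []
    for scale, units in (("CBK", cbks), ("CBG", cbgs), ("CT", cts)):
        if data[scale]:
            tables.append(
                AreaCovariateTable(
                    scale, pd.DataFrame(data[scale], index=pd.Index(units, name="unit_id"))
                )
            )
    return tables


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(
    geo: GeoHierarchy,
    area_tables: list[AreaCovariateTable],
    scenario: SyntheticScenario,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate the analysis-ready cohort.

    Visits are allocated to census blocks uniformly at random; the outcome is
    a linear combination of the (empirically standardized) true-scale
    covariate columns, plus random intercepts drawn per CBG and per CT, plus
    residual noise.
    """
    n = scenario.n_total
    cbks = geo.cbks
    cbk_ids = [cbks[i] for i in rng.integers(0, len(cbks), size=n)]
    cbg_ids = [geo.cbk_to_cbg[k] for k in cbk_ids]
    ct_ids = [geo.cbg_to_ct[g] for g in cbg_ids]

    black = (rng.random(n) < scenario.p_black).astype(float)
    cohort = pd.DataFrame(
        {
            "VisitAge": rng.uniform(2.0, 17.0, size=n),
            "Male": (rng.random(n) < 0.5).astype(float),
            "Black": black,
            "MCVdist": np.abs(rng.standard_normal(n)) * 5.0,
            "cbk_id": cbk_ids,
            "cbg_id": cbg_ids,
            "ct_id": ct_ids,
        }
    )
    cohort["race_code"] = np.where(black == 1.0, "black", "white")

    by_scale = {t.scale: t.table for t in area_tables}
    id_col = {"CBK": "cbk_id", "CBG": "cbg_id", "CT": "ct_id"}
    linear = np.zeros(n)
    for concept, (scale, beta) in scenario.effects.items():
        if scale == INDIVIDUAL:
            x = cohort[concept].to_numpy(dtype=float)
        else:
            x = by_scale[scale][concept].reindex(cohort[id_col[scale]]).to_numpy(dtype=float)
        linear += beta * _standardize(x)

    cbg_levels = geo.cbgs
    ct_levels = geo.cts
    b_cbg = dict(zip(cbg_levels, scenario.sigma_cbg * rng.standard_normal(len(cbg_levels))))
    b_ct = dict(zip(ct_levels, scenario.sigma_ct * rng.standard_normal(len(ct_levels))))
    re = np.array([b_cbg[g] for g in cbg_ids]) + np.array([b_ct[t] for t in ct_ids])
    cohort["BMIZ"] = linear + re + scenario.sigma_eps * rng.standard_normal(n)

    truth = TruthRecord(
        effects=dict(scenario.effects),
        sigma_cbg=scenario.sigma_cbg,
        sigma_ct=scenario.sigma_ct,
        sigma_eps=scenario.sigma_eps,
        seed=scenario.seed,
    )
    return cohort, truth


def inject_exclusions(
    cohort: pd.DataFrame, scenario: SyntheticScenario, rng: np.random.Generator
) -> pd.DataFrame:
    """Produce the raw pre-filter table tripping each exclusion rule an exact
    number of times, disjointly.

    The configured count of rows is pushed below the underweight cutoff (the
    naturally lowest z-scores are used first); any other row that happens to
    fall below the cutoff is reflected just above it so the underweight rule
    trips exactly ``n_underweight`` times.  Race and missingness markers are
    then placed on disjoint rows.  The result is an input for the exclusion
    workflow; the clean cohort remains the modeling truth.
    """
    k_u, k_r, k_m = scenario.n_underweight, scenario.n_race_excluded, scenario.n_missing
    n = len(cohort)
    if k_u + k_r + k_m > n:
        raise ValueError("requested exclusion counts exceed cohort size")
    raw = cohort.copy().reset_index(drop=True)
    z = raw["BMIZ"].to_numpy(dtype=float).copy()
    cutoff = UNDERWEIGHT_Z_CUTOFF
    order = np.argsort(z)
    under_idx = order[:k_u]
    # make the marked rows underweight and everything else not
    need = z[under_idx] >= cutoff
    z[under_idx[need]] = cutoff - 0.05 - np.abs(rng.standard_normal(int(need.sum()))) * 0.3
    rest = order[k_u:]
    low = z[rest] < cutoff
    z[rest[low]] = 2.0 * cutoff - z[rest[low]] + 1e-6  # reflect above the cutoff
    raw["BMIZ"] = z

    remaining = rest.copy()
    rng.shuffle(remaining)
    race_idx = remaining[:k_r]
    miss_idx = remaining[k_r : k_r + k_m]
    raw.loc[race_idx, "race_code"] = "other"
    raw.loc[miss_idx, "VisitAge"] = np.nan
    return raw


def simulate_study(
    scenario: SyntheticScenario,
) -> tuple[GeoHierarchy, list[AreaCovariateTable], pd.DataFrame, pd.DataFrame, TruthRecord]:
    """One-call convenience: geography, area tables, clean cohort, raw
    (exclusion-bearing) cohort, and the truth record."""
    rng = np.random.default_rng(scenario.seed)
    geo = generate_geography(scenario)
    tables = generate_area_covariates(geo, scenario, rng)
    cohort, truth = generate_cohort(geo, tables, scenario, rng)
    raw = inject_exclusions(cohort, scenario, rng)
    return geo, tables, cohort, raw, truth


def scenario_design(
    scenario: SyntheticScenario,
    cohort: pd.DataFrame,
    area_tables: list[AreaCovariateTable],
) -> CandidateDesign:
    """Candidate design for a generated cohort under the scenario's pool."""
    return build_candidate_design(cohort, area_tables, scenario.variable_spec())
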