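"""Simulation studies validating the method's operating characteristics.

Each function runs a replicated experiment on the synthetic-data generator
and reduces it to a headline number: how often the algorithms recover the
true spatial scale, how often the scale-selected model beats the single-scale
comparison fits on AIC, how often the random effect lands at the level where
the truth put it, and how well the variance component is recovered.  These
are the package's own calibration results; they are recomputed from scratch
on every run.
"""

from __future__ import annotations

import numpy as np

from .data_model import INDIVIDUAL, standardize_full
from .inference_ols import constrained_scale_refit, refit_ols
from .mixed_models import compare_re_specs, fit_random_intercept
from .ss_select import ALGORITHMS, SSConfig, final_model
from .synthetic import SyntheticScenario, scenario_design, simulate_study

#: standardized effects (all at least 0.1 in magnitude) at designated mixed
#: scales, used by the recovery and AIC-ordering experiments
RECOVERY_EFFECTS: dict[str, tuple[str, float]] = {
    "VisitAge": (INDIVIDUAL, 0.15),
    "Black": (INDIVIDUAL, 0.10),
    "POPDENS": ("CT", -0.15),
    "PHWHITE": ("CBG", 0.12),
    "MEDHINC": ("CT", -0.20),
    "PRENTER": ("CT", -0.10),
    "PVACANT": ("CT", 0.10),
    "PARKDENS": ("CBG", 0.10),
    "EX_EQ": ("CBG", -0.15),
}


def recovery_scenario(seed: int, n: int = 5_000, rho: float = 0.7) -> SyntheticScenario:
    """Mixed-true-scale scenario: full 31-column candidate pool,
    cross-scale correlation 0.7, standardized effects of 0.1-0.2."""
    return SyntheticScenario(
        n_ct=100,
        cbgs_per_ct=3,
        cbks_per_cbg=2,
        n_total=n,
        rho=rho,
        effects=dict(RECOVERY_EFFECTS),
        sigma_eps=0.9,
        n_underweight=0,
        n_race_excluded=0,
        n_missing=0,
        seed=seed,
    )


def _prepare(scenario: SyntheticScenario):
    geo, tables, cohort, _, _ = simulate_study(scenario)
    design = scenario_design(scenario, cohort, tables)
    y_raw = cohort["BMIZ"].to_numpy()
    Xs, ys, _ = standardize_full(design, y_raw)
    return Xs, ys, cohort, y_raw


def scale_recovery_rates(
    n_replicates: int = 50,
    seed: int = 0,
    n: int = 5_000,
    rho: float = 0.7,
    algorithms: tuple[str, ...] = ("stepwise", "stagewise", "lars", "lasso"),
    cfg: SSConfig = SSConfig(),
) -> dict[str, float]:
    """Median (over replicates) fraction of effect-bearing area concepts that
    each algorithm selects at the true scale."""
    per_algo: dict[str, list[float]] = {a: [] for a in algorithms}
    for rep in range(n_replicates):
        scenario = recovery_scenario(seed * 100_003 + rep, n=n, rho=rho)
        Xs, ys, _, _ = _prepare(scenario)
        truth = {
            c: s
            for c, (s, _) in scenario.effects.items()
            if s != INDIVIDUAL
        }
        for algo in algorithms:
            path = ALGORITHMS[algo](Xs, ys, cfg)
            model = final_model(path, Xs, ys)
            chosen = {Xs.info(t).concept: Xs.info(t).scale for t in model.active}
            hits = sum(1 for c, s in truth.items() if chosen.get(c) == s)
            per_algo[algo].append(hits / len(truth))
    return {a: float(np.median(v)) for a, v in per_algo.items()}


def constraint_violation_count(
    n_scenarios: int = 50, seed: int = 0, cfg: SSConfig = SSConfig()
) -> int:
    """Number of (scenario, algorithm, path step) records where a model holds
    a concept at two scales simultaneously; the design invariant says zero."""
    violations = 0
    for rep in range(n_scenarios):
        scenario = SyntheticScenario(
            n_ct=10,
            cbgs_per_ct=2,
            cbks_per_cbg=2,
            n_total=250,
            rho=0.8,
            area_concepts={
                "A": ("CBK", "CBG", "CT"),
                "B": ("CBG", "CT"),
                "C": ("CBG", "CT"),
                "D": ("CBG", "CT"),
            },
            effects={
                "A": ("CT", 0.3),
                "B": ("CBG", 0.25),
                "VisitAge": (INDIVIDUAL, 0.2),
            },
            sigma_eps=0.8,
            n_underweight=0,
            n_race_excluded=0,
            n_missing=0,
            seed=seed * 99_991 + rep,
        )
        Xs, ys, _, _ = _prepare(scenario)
        for algo in ALGORITHMS:
            path = ALGORITHMS[algo](Xs, ys, cfg)
            for step in path.steps:
                concepts = [Xs.info(a).concept for a in step.active]
                violations += len(concepts) - len(set(concepts))
            model = final_model(path, Xs, ys)
            concepts = [Xs.info(a).concept for a in model.active]
            violations += len(concepts) - len(set(concepts))
    return violations


def aic_ordering_rates(
    n_seeds: int = 20,
    seed: int = 0,
    n: int = 4_000,
    algorithms: tuple[str, ...] = ("stepwise", "stagewise", "lars", "lasso"),
    cfg: SSConfig = SSConfig(),
) -> dict[str, float]:
    """Fraction of seeds in which the scale-selected model's OLS AIC is no
    larger than both single-scale (all-CBG, all-CT) constrained refits."""
    wins = {a: 0 for a in algorithms}
    for rep in range(n_seeds):
        scenario = recovery_scenario(seed * 7_919 + rep, n=n)
        Xs, ys, _, _ = _prepare(scenario)
        for algo in algorithms:
            path = ALGORITHMS[algo](Xs, ys, cfg)
            model = final_model(path, Xs, ys)
            ss_fit = refit_ols(Xs, ys, list(model.active))
            cbg = constrained_scale_refit(model, Xs, ys, "CBG")
            ct = constrained_scale_refit(model, Xs, ys, "CT")
            if ss_fit.aic <= cbg.aic and ss_fit.aic <= ct.aic:
                wins[algo] += 1
    return {a: w / n_seeds for a, w in wins.items()}


RE_TERMS = ["VisitAge", "Black", "MEDHINC_CT", "PHWHITE_CBG"]


def re_placement_scenario(seed: int, n: int = 2_000) -> SyntheticScenario:
    """Truth with CBG-level intercepts only (sigma_CT = 0)."""
    return SyntheticScenario(
        n_ct=50,
        cbgs_per_ct=4,
        cbks_per_cbg=2,
        n_total=n,
        rho=0.7,
        area_concepts={"MEDHINC": ("CBG", "CT"), "PHWHITE": ("CBG", "CT")},
        effects={
            "VisitAge": (INDIVIDUAL, 0.15),
            "Black": (INDIVIDUAL, 0.10),
            "MEDHINC": ("CT", -0.2),
            "PHWHITE": ("CBG", 0.15),
        },
        sigma_cbg=0.35,
        sigma_ct=0.0,
        sigma_eps=0.95,
        n_underweight=0,
        n_race_excluded=0,
        n_missing=0,
        seed=seed,
    )


def re_placement_rate(n_seeds: int = 20, seed: int = 0, n: int = 2_000) -> float:
    """Fraction of seeds where the RE-at-CBG specification attains the
    smallest AIC among {none, CBG, CT, CBG+CT} when the truth has CBG-level
    intercepts."""
    wins = 0
    for rep in range(n_seeds):
        scenario = re_placement_scenario(seed * 104_729 + rep, n=n)
        Xs, ys, cohort, _ = _prepare(scenario)
        table, _ = compare_re_specs(
            Xs, ys, RE_TERMS, cohort[["cbg_id", "ct_id"]]
        )
        best = table.loc[table["aic"].idxmin(), "re_spec"]
        wins += best == "CBG"
    return wins / n_seeds


def variance_recovery(
    n_replicates: int = 50,
    seed: int = 0,
    sigma_cbg: float = 0.5,
    n_groups: int = 200,
    group_size: int = 20,
) -> dict[str, float]:
    """Median estimated sigma^2_CBG across replicates of a balanced design
    (200 groups x 20 by default), fit by ML on the raw outcome."""
    truth = sigma_cbg**2
    estimates = []
    for rep in range(n_replicates):
        scenario = SyntheticScenario(
            n_ct=n_groups // 4,
            cbgs_per_ct=4,
            cbks_per_cbg=1,
            n_total=n_groups * group_size,
            rho=0.7,
            area_concepts={"MEDHINC": ("CBG", "CT")},
            effects={"VisitAge": (INDIVIDUAL, 0.15), "MEDHINC": ("CT", -0.2)},
            sigma_cbg=sigma_cbg,
            sigma_ct=0.0,
            sigma_eps=1.0,
            n_underweight=0,
            n_race_excluded=0,
            n_missing=0,
            seed=seed * 15_485_863 + rep,
        )
        Xs, _, cohort, y_raw = _prepare(scenario)
        fit = fit_random_intercept(
            Xs,
            y_raw,
            ["VisitAge", "MEDHINC_CT"],
            cohort[["cbg_id", "ct_id"]],
            {"CBG"},
            add_intercept=True,
        )
        estimates.append(fit.vc["sigma2_CBG"])
    med = float(np.median(estimates))
    return {
        "truth": truth,
        "median_estimate": med,
        "relative_error": abs(med - truth) / truth,
    }
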