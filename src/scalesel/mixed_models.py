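"""Random-intercept linear mixed models at the block-group and tract levels.

Children visiting from the same block group (CBG) or tract (CT) share
unmeasured neighborhood influences, so the selected fixed-effect models are
refit with Gaussian random intercepts at the CBG, the CT, or both (CBG
nested within CT — geography is strictly nested, so crossed effects are not
offered).  Estimation is maximum likelihood (not REML) so that AIC
comparisons across fixed-effect sets are coherent; fixed-effect p-values are
Wald tests, the conventional companion of ML estimates.

Estimation is delegated to statsmodels' MixedLM; this module owns the
specification (grouping, nesting checks, AIC parameter count) and the
extraction of variance components and predicted group intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data_model import CandidateDesign
from .inference_ols import FittedModel, refit_ols, significance_mark

VALID_GROUPINGS = ({"CBG"}, {"CT"}, {"CBG", "CT"})


@dataclass
class MixedFit:
    """A random-intercept fit: fixed effects, variance components, EBLUPs."""

    terms: list[str]
    grouping: frozenset[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series  # Wald (z) for fixed effects
    vc: dict[str, float]  # sigma2_CBG / sigma2_CT (subset) + sigma2_residual
    loglik: float
    aic: float
    n: int
    ranef: pd.DataFrame  # columns: unit_id, scale, predicted_intercept

    @property
    def marks(self) -> dict[str, str]:
        return {t: significance_mark(self.pvalues[t]) for t in self.pvalues.index}


def _check_nesting(groups: pd.DataFrame) -> None:
    per_cbg = groups.groupby("cbg_id")["ct_id"].nunique()
    bad = per_cbg[per_cbg > 1]
    if len(bad):
        raise ValueError(
            f"grouping is not nested: CBGs mapping to multiple CTs: {bad.index.tolist()[:5]}"
        )


def fit_random_intercept(
    design: CandidateDesign,
    outcome: np.ndarray,
    terms: list[str] | tuple[str, ...],
    groups: pd.DataFrame,
    grouping: set[str] | frozenset[str],
    add_intercept: bool = False,
) -> MixedFit:
    """ML fit of a linear mixed model with random intercepts at the
    requested scales.

    ``groups`` carries per-row 'cbg_id' and 'ct_id'.  With both scales
    requested the CBG intercept is nested within the CT intercept, and the
    grouping must be strictly nested.  Group-level intercept predictions
    (empirical best linear unbiased predictors) are returned per unit.
    """
    grouping = set(grouping)
    if grouping not in [set(g) for g in VALID_GROUPINGS]:
        raise ValueError(f"grouping must be one of {VALID_GROUPINGS}, got {grouping}")
    terms = list(terms)
    data = design.X[terms].copy()
    data["_y"] = np.asarray(outcome, dtype=float)
    data["cbg_id"] = groups["cbg_id"].astype(str).to_numpy()
    data["ct_id"] = groups["ct_id"].astype(str).to_numpy()
    if data[terms + ["_y"]].isna().any().any():
        raise ValueError("missing values in modeled columns")

    safe = {t: f"x{i}" for i, t in enumerate(terms)}
    data = data.rename(columns=safe)
    rhs = " + ".join(safe.values()) if terms else "1"
    fixed = f"_y ~ {'1 + ' if add_intercept else '0 + '}{rhs}" if terms else (
        "_y ~ 1" if add_intercept else "_y ~ 0"
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary sigma^2 ~ 0 is legitimate
        if grouping == {"CBG", "CT"}:
            _check_nesting(data)
            model = smf.mixedlm(
                fixed,
                data,
                groups="ct_id",
                re_formula="1",
                vc_formula={"cbg": "0 + C(cbg_id)"},
            )
        else:
            col = "cbg_id" if grouping == {"CBG"} else "ct_id"
            model = smf.mixedlm(fixed, data, groups=col)
        # lbfgs is fastest but occasionally collapses onto a degenerate
        # boundary (infinite reported likelihood) or stops short of the
        # optimum; take the best finite converged fit across optimizers,
        # stopping early when lbfgs converges cleanly
        res = None
        best_llf = -np.inf
        for method in ("lbfgs", "bfgs", "powell"):
            candidate = model.fit(reml=False, method=method, maxiter=500)
            if np.isfinite(candidate.llf) and candidate.llf > best_llf:
                res, best_llf = candidate, float(candidate.llf)
            if candidate.converged and np.isfinite(candidate.llf):
                break
        if res is None:
            raise RuntimeError("mixed-model likelihood failed to converge to a finite value")

    inv = {v: k for k, v in safe.items()}
    fe_names = [inv.get(name, name) for name in res.fe_params.index]
    params = pd.Series(res.fe_params.to_numpy(), index=fe_names)
    fe_idx = res.fe_params.index
    bse = pd.Series(res.bse[fe_idx].to_numpy(), index=fe_names)
    pvalues = pd.Series(res.pvalues[fe_idx].to_numpy(), index=fe_names)

    sigma2_resid = float(res.scale)
    vc: dict[str, float] = {"sigma2_residual": sigma2_resid}
    if grouping == {"CBG", "CT"}:
        vc["sigma2_CT"] = float(res.cov_re.iloc[0, 0])
        vc["sigma2_CBG"] = float(res.vcomp[0])
    elif grouping == {"CBG"}:
        vc["sigma2_CBG"] = float(res.cov_re.iloc[0, 0])
    else:
        vc["sigma2_CT"] = float(res.cov_re.iloc[0, 0])

    ranef = _extract_ranef(res, grouping)
    n_var_comp = len(vc) - 1  # residual counted separately
    aic = -2.0 * float(res.llf) + 2.0 * (len(fe_names) + n_var_comp + 1)
    return MixedFit(
        terms=terms,
        grouping=frozenset(grouping),
        params=params,
        bse=bse,
        pvalues=pvalues,
        vc=vc,
        loglik=float(res.llf),
        aic=aic,
        n=len(data),
        ranef=ranef,
    )


def _extract_ranef(res, grouping: set[str]) -> pd.DataFrame:
    rows: list[dict] = []
    top_scale = "CT" if "CT" in grouping else "CBG"
    try:
        random_effects = res.random_effects
    except (ValueError, np.linalg.LinAlgError):
        # variance component estimated at the zero boundary: the BLUPs
        # shrink all the way to 0
        random_effects = {
            g: pd.Series(0.0, index=["Group"]) for g in res.model.group_labels
        }
    vc_sums: dict[str, float] = {}
    for group, effects in random_effects.items():
        for key, val in effects.items():
            if "[" not in key:
                # the group-level intercept (keyed 'Group' or the grouping
                # column name, depending on how the model was specified)
                rows.append(
                    {"unit_id": str(group), "scale": top_scale, "predicted_intercept": float(val)}
                )
            else:
                # variance-component labels look like cbg[C(cbg_id)[unit]];
                # every CBG level appears in every CT group, with zeros for
                # units outside the group, so sum across groups
                unit = key.split("[")[-1].rstrip("]")
                if unit.startswith("T."):
                    unit = unit[2:]
                vc_sums[unit] = vc_sums.get(unit, 0.0) + float(val)
    for unit, val in vc_sums.items():
        rows.append({"unit_id": unit, "scale": "CBG", "predicted_intercept": val})
    return pd.DataFrame(rows, columns=["unit_id", "scale", "predicted_intercept"])


def compare_re_specs(
    design: CandidateDesign,
    outcome: np.ndarray,
    terms: list[str] | tuple[str, ...],
    groups: pd.DataFrame,
    add_intercept: bool = False,
) -> tuple[pd.DataFrame, dict[str, FittedModel | MixedFit]]:
    """AIC table over random-effect specifications {none, CBG, CT, CBG+CT}
    for one fixed-effect set; the 'none' row is the plain OLS refit."""
    fits: dict[str, FittedModel | MixedFit] = {}
    fits["none"] = refit_ols(design, outcome, list(terms), add_intercept=add_intercept)
    for label, spec in [("CBG", {"CBG"}), ("CT", {"CT"}), ("CBG+CT", {"CBG", "CT"})]:
        fits[label] = fit_random_intercept(
            design, outcome, terms, groups, spec, add_intercept=add_intercept
        )
    # the OLS row is put on the full-likelihood scale so its AIC is
    # comparable with the mixed-model AICs
    table = pd.DataFrame(
        {
            "re_spec": list(fits),
            "aic": [
                f.aic_full if isinstance(f, FittedModel) else f.aic
                for f in fits.values()
            ],
        }
    )
    return table, fits
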