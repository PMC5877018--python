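"""OLS refits of selected covariate sets and effect comparisons.

After a path algorithm selects a covariate set, approximate p-values and AIC
come from refitting the set by ordinary least squares.  Single-scale
comparison models swap every selected area-level term to one fixed scale
(all-CBG or all-CT) so the goodness-of-fit cost of assuming a common scale
can be measured, and percent-change summaries quantify how much an effect
estimate moves between scale assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import INDIVIDUAL, CandidateDesign
from .ss_select import SelectedModel, ols_aic


class CollinearityError(ValueError):
    pass


def significance_mark(p: float) -> str:
    """'*' for p < 0.05, '+' for p < 0.1, empty otherwise."""
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


@dataclass
class FittedModel:
    """An OLS fit annotated with (concept, scale) term metadata."""

    terms: list[str]
    scales: dict[str, str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    n: int
    k: int
    rss: float
    has_intercept: bool = False

    @property
    def aic_full(self) -> float:
        """AIC on the full Gaussian log-likelihood scale (includes the
        n(1 + ln 2*pi) constant that cancels in OLS-vs-OLS comparisons);
        needed when comparing against mixed-model AICs."""
        return self.aic + self.n * (1.0 + math.log(2.0 * math.pi))

    @property
    def marks(self) -> dict[str, str]:
        return {t: significance_mark(self.pvalues[t]) for t in self.pvalues.index}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.pvalues.index,
                "scale": [self.scales.get(t, "") for t in self.pvalues.index],
                "estimate": self.params.values,
                "std_error": self.bse.values,
                "p_value": self.pvalues.values,
                "mark": [self.marks[t] for t in self.pvalues.index],
            }
        )


def refit_ols(
    design: CandidateDesign,
    outcome: np.ndarray,
    terms: list[str] | tuple[str, ...],
    add_intercept: bool = False,
) -> FittedModel:
    """Least-squares fit of the named design columns.

    On fully standardized data no intercept is used and the residual degrees
    of freedom are n - k; with ``add_intercept`` an explicit constant column
    is prepended (used for the interaction models, whose outcome is raw).
    """
    terms = list(terms)
    X = design.X[terms].to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["Intercept"] + terms
    else:
        names = terms
    rank = np.linalg.matrix_rank(X) if X.size else 0
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design columns are collinear (rank {rank} < {X.shape[1]}): {names}"
        )
    res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    rss = float(res.ssr)
    k = len(names)
    scales = {t: design.info(t).scale for t in terms}
    if add_intercept:
        scales["Intercept"] = ""
    return FittedModel(
        terms=terms,
        scales=scales,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        aic=ols_aic(rss, len(y), k),
        n=len(y),
        k=k,
        rss=rss,
        has_intercept=add_intercept,
    )


def constrained_scale_refit(
    selected: SelectedModel,
    design: CandidateDesign,
    outcome: np.ndarray,
    scale: str,
) -> FittedModel:
    """Refit the selected covariate set with every area-level term forced to
    one spatial scale.

    Individual-level terms are unchanged; each area-level term is swapped for
    its same-concept column at the requested scale.  A concept with no column
    at that scale (e.g. a block-only covariate when the tract level is
    requested) is an error.
    """
    new_terms: list[str] = []
    for name in selected.active:
        info = design.info(name)
        if info.scale == INDIVIDUAL or info.scale == scale:
            new_terms.append(name)
            continue
        sibling = next(
            (
                c.name
                for c in design.columns
                if c.concept == info.concept and c.scale == scale
            ),
            None,
        )
        if sibling is None:
            raise ValueError(
                f"concept {info.concept!r} has no column at scale {scale}"
            )
        new_terms.append(sibling)
    return refit_ols(design, outcome, new_terms)


def percent_change(coef_a: float, coef_b: float) -> float | None:
    """Percent change in effect magnitude from ``coef_a`` to ``coef_b``,
    rounded to the nearest integer percent; None when the reference is 0."""
    if coef_a == 0:
        return None
    return float(round(100.0 * (abs(coef_b) - abs(coef_a)) / abs(coef_a)))


def scale_comparison_table(
    selected: SelectedModel,
    design: CandidateDesign,
    outcome: np.ndarray,
) -> tuple[pd.DataFrame, dict[str, FittedModel]]:
    """AIC and coefficients for the all-CBG, all-CT, and model-selected fits.

    Returns a tidy frame (one row per concept, columns for each scale
    assumption) plus the three fits keyed 'CBG', 'CT', 'SS'.
    """
    fits = {
        "CBG": constrained_scale_refit(selected, design, outcome, "CBG"),
        "CT": constrained_scale_refit(selected, design, outcome, "CT"),
        "SS": refit_ols(design, outcome, list(selected.active)),
    }
    rows = []
    for name in selected.active:
        info = design.info(name)
        row = {"concept": info.concept, "selected_scale": info.scale}
        for label, fit in fits.items():
            term = next(
                t for t in fit.terms if design.info(t).concept == info.concept
            )
            row[label] = float(fit.params[term])
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["aic"] = {label: fit.aic for label, fit in fits.items()}
    return table, fits
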