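"""Clinician-specified interaction terms on two-SD-rescaled predictors.

Nine interactions are examined: sex and race (Male, Black) each crossed with
population density, median household income, park density, and exercise
equipment expenditures, plus distance-to-clinic crossed with income.
Products are built after the Gelman rescaling (binaries centered, continuous
divided by two SDs) so the interaction coefficients are on a scale
comparable with the main effects; the outcome stays raw, so these models
carry an intercept.  After one full fit, interactions are pruned to the
significant ones and the model is refit — a single pass, no iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CandidateDesign, ColumnInfo, DataModelError
from .inference_ols import FittedModel, refit_ols
from .mixed_models import MixedFit, compare_re_specs

#: (modifier concept, base concept) pairs examined on clinical recommendation
DEFAULT_INTERACTION_CONCEPTS: tuple[tuple[str, str], ...] = (
    ("Male", "POPDENS"),
    ("Male", "MEDHINC"),
    ("Male", "PARKDENS"),
    ("Male", "EX_EQ"),
    ("Black", "POPDENS"),
    ("Black", "MEDHINC"),
    ("Black", "PARKDENS"),
    ("Black", "EX_EQ"),
    ("MCVdist", "MEDHINC"),
)

#: concepts force-included in interaction models regardless of selection
FORCED_CONCEPTS = ("Male",)


@dataclass(frozen=True)
class InteractionSpec:
    """Resolved interaction pairs: (modifier column, base column)."""

    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    @staticmethod
    def term_name(modifier: str, base: str) -> str:
        return f"{modifier}:{base}"

    @property
    def term_names(self) -> list[str]:
        return [self.term_name(m, b) for m, b in self.pairs]


def resolve_interactions(
    design: CandidateDesign,
    concept_pairs: tuple[tuple[str, str], ...] = DEFAULT_INTERACTION_CONCEPTS,
) -> InteractionSpec:
    """Map concept-level interaction requests onto the working design.

    Each concept resolves to the single column present at its selected scale;
    a pair whose base concept was not selected by the algorithm is skipped
    (that interaction cannot be formed for this model).
    """
    by_concept: dict[str, str] = {}
    for c in design.columns:
        by_concept.setdefault(c.concept, c.name)
    pairs = [
        (by_concept[m], by_concept[b])
        for m, b in concept_pairs
        if m in by_concept and b in by_concept
    ]
    return InteractionSpec(tuple(pairs))


def build_interaction_design(
    design: CandidateDesign, spec: InteractionSpec
) -> CandidateDesign:
    """Append product columns for every pair in ``spec``.

    Parents must already be present (main effects are forced in) and already
    centered/rescaled; the products themselves are not re-centered, so
    removing an interaction never changes a parent column.
    """
    X = design.X.copy()
    columns = list(design.columns)
    next_num = max(c.variable_number for c in columns) + 1
    for modifier, base in spec.pairs:
        for parent in (modifier, base):
            if parent not in X.columns:
                raise DataModelError(f"interaction parent {parent!r} missing from design")
        name = InteractionSpec.term_name(modifier, base)
        X[name] = X[modifier].to_numpy() * X[base].to_numpy()
        columns.append(ColumnInfo(name, "interaction", name, next_num))
        next_num += 1
    return CandidateDesign(X, columns)


def prune_to_significant(
    fit: FittedModel, spec: InteractionSpec, alpha: float = 0.05
) -> InteractionSpec:
    """Keep the interaction pairs whose term is significant at ``alpha``;
    main effects are never pruned.  One pass only."""
    kept = []
    for modifier, base in spec.pairs:
        term = InteractionSpec.term_name(modifier, base)
        if term not in fit.pvalues.index:
            raise ValueError(f"fit does not include interaction term {term!r}")
        if fit.pvalues[term] < alpha:
            kept.append((modifier, base))
    return InteractionSpec(tuple(kept))


def final_interaction_models(
    design: CandidateDesign,
    outcome: np.ndarray,
    main_terms: list[str],
    reduced: InteractionSpec,
    groups: pd.DataFrame | None = None,
) -> tuple[FittedModel, pd.DataFrame | None, dict[str, FittedModel | MixedFit] | None]:
    """Refit with only the retained interactions, with an intercept (raw
    outcome), and — when grouping IDs are supplied — repeat under the four
    random-effect specifications, returning the AIC table."""
    ext = build_interaction_design(design, reduced)
    terms = list(main_terms) + reduced.term_names
    ols_fit = refit_ols(ext, outcome, terms, add_intercept=True)
    if groups is None:
        return ols_fit, None, None
    table, fits = compare_re_specs(ext, outcome, terms, groups, add_intercept=True)
    return ols_fit, table, fits
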