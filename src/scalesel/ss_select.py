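"""Spatial-scale (SS) selection path algorithms.

Four variable-selection path algorithms — forward stepwise, incremental
forward stagewise, least angle regression (LARS), and the lasso — modified so
that each conceptual covariate may enter the model at only one of its
candidate spatial scales.  Once a column for a concept is active, that
concept's sibling columns at other scales are ineligible; if the lasso later
drops the column, the siblings become eligible again.

All algorithms run on a fully standardized design and outcome (mean 0,
sample SD 1) with no intercept.  Model choice along a LARS/lasso path uses
the minimum OLS-based AIC over the knots; stepwise stops when the best
candidate no longer improves AIC by at least epsilon; stagewise stops when no
eligible column is correlated with the residual beyond a tolerance.

Ties in correlation or AIC are broken by the smallest variable number in the
candidate pool, which makes every path deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import CandidateDesign


class SingularDesignError(ValueError):
    """Active design matrix is rank deficient."""


@dataclass(frozen=True)
class SSConfig:
    """Tuning parameters shared by the SS algorithms.

    epsilon : minimum AIC improvement (AIC units) for stepwise to accept a
        candidate; the study used 1, well below the 4-7 gap considered a
        substantial difference between models.
    step_size : stagewise coefficient increment (delta), default 0.001.
    tolerance : stagewise stopping threshold on the maximum absolute
        residual correlation, default 0.01.
    alpha : significance level used by downstream inference, default 0.05.
    max_steps : cap on stagewise increments (safety net; a truncated path is
        flagged, not an error).
    """

    epsilon: float = 1.0
    step_size: float = 0.001
    tolerance: float = 0.01
    alpha: float = 0.05
    max_steps: int = 200_000
    tie_break: str = "variable_number"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be in (0, 1)")


@dataclass(frozen=True)
class PathStep:
    """One knot of a selection path."""

    event: str  # 'enter' | 'drop' | 'increment'
    column: str | None
    active: tuple[str, ...]
    coef: dict[str, float]
    aic: float


@dataclass
class SelectionPath:
    algorithm: str
    steps: list[PathStep] = field(default_factory=list)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def terminal(self) -> PathStep:
        return self.steps[-1]


@dataclass(frozen=True)
class SelectedModel:
    algorithm: str
    step_index: int
    active: tuple[str, ...]
    coef: dict[str, float]
    aic: float


def ols_aic(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC for a least-squares fit: n*ln(rss/n) + 2(k+1).

    ``k`` counts regression coefficients; the error variance contributes the
    extra parameter.  A zero RSS (interpolating fit) yields -inf with a
    warning rather than an error so path scans can proceed.
    """
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    if rss <= 0.0:
        warnings.warn("zero residual sum of squares; AIC is -inf", RuntimeWarning)
        return float("-inf")
    return n * float(np.log(rss / n)) + 2.0 * (k + 1)


def eligible_columns(
    design: CandidateDesign,
    active: set[str] | frozenset[str],
    excluded: set[str] | frozenset[str] = frozenset(),
) -> list[str]:
    """Columns that may enter: not active, not excluded, and with no active
    sibling (same concept at another scale).  Returned in variable-number
    order, which is also the deterministic tie-break order."""
    if set(active) & set(excluded):
        raise ValueError("active and excluded sets overlap")
    active_concepts = {design.info(a).concept for a in active}
    out = [
        c
        for c in design.columns
        if c.name not in active
        and c.name not in excluded
        and c.concept not in active_concepts
    ]
    return [c.name for c in sorted(out, key=lambda c: c.variable_number)]


def _ols_rss_coef(X: np.ndarray, y: np.ndarray, names: list[str]) -> tuple[dict[str, float], float]:
    """No-intercept OLS on the given columns; raises on rank deficiency."""
    if not names:
        return {}, float(y @ y)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"active design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"columns: {names}"
        )
    resid = y - X @ beta
    return dict(zip(names, beta.tolist())), float(resid @ resid)


class _Workspace:
    """Column-ordered numpy view of a standardized design."""

    def __init__(self, design: CandidateDesign, y: np.ndarray):
        order = sorted(design.columns, key=lambda c: c.variable_number)
        self.names = [c.name for c in order]
        self.design = design
        self.X = design.X[self.names].to_numpy(dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.n = self.X.shape[0]
        self.idx = {name: j for j, name in enumerate(self.names)}

    def cols(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        return self.X[:, [self.idx[a] for a in names]]

    def ols(self, names: list[str] | tuple[str, ...]) -> tuple[dict[str, float], float]:
        return _ols_rss_coef(self.cols(list(names)), self.y, list(names))

    def aic_of(self, names: list[str] | tuple[str, ...]) -> float:
        _, rss = self.ols(names)
        return ols_aic(rss, self.n, len(names))


def ss_forward_stepwise(
    design: CandidateDesign, y: np.ndarray, cfg: SSConfig = SSConfig()
) -> SelectionPath:
    """Greedy forward selection under the one-scale-per-concept constraint.

    Every eligible column is tried by OLS alongside the current active set;
    the candidate giving the smallest AIC is accepted if it improves on the
    current model's AIC by at least ``cfg.epsilon``, otherwise the path
    terminates.
    """
    ws = _Workspace(design, y)
    path = SelectionPath("stepwise")
    active: list[str] = []
    current_aic = ols_aic(float(ws.y @ ws.y), ws.n, 0)
    while True:
        candidates = eligible_columns(design, set(active))
        if not candidates or len(active) + 1 >= ws.n:
            break
        best: tuple[float, str, dict[str, float]] | None = None
        for cand in candidates:  # variable-number order => deterministic ties
            coef, rss = ws.ols(active + [cand])
            aic = ols_aic(rss, ws.n, len(active) + 1)
            if best is None or aic < best[0]:
                best = (aic, cand, coef)
        assert best is not None
        aic, cand, coef = best
        if current_aic - aic < cfg.epsilon:
            break
        active.append(cand)
        current_aic = aic
        path.steps.append(PathStep("enter", cand, tuple(active), coef, aic))
    return path


def ss_forward_stagewise(
    design: CandidateDesign, y: np.ndarray, cfg: SSConfig = SSConfig()
) -> SelectionPath:
    """Incremental forward stagewise under the scale constraint.

    Repeatedly finds the eligible column most correlated with the current
    residual and nudges its coefficient by ``step_size`` toward the
    correlation's sign; a concept's sibling scales become ineligible at the
    column's first increment.  Stops when no eligible correlation exceeds
    ``tolerance`` in absolute value.

    The recorded path keeps every first-entry event and every 100th
    increment; the terminal step always carries the final coefficients.
    """
    ws = _Workspace(design, y)
    n, p = ws.n, len(ws.names)
    G = ws.X.T @ ws.X
    inner = ws.X.T @ ws.y  # x_j' r, updated incrementally
    rss = float(ws.y @ ws.y)
    beta = np.zeros(p)
    owner: dict[str, str] = {}  # concept -> owning column
    concept = {name: design.info(name).concept for name in ws.names}
    path = SelectionPath("stagewise")
    delta = cfg.step_size

    def eligible_mask() -> np.ndarray:
        mask = np.zeros(p, dtype=bool)
        for j, name in enumerate(ws.names):
            own = owner.get(concept[name])
            mask[j] = own is None or own == name
        return mask

    mask = eligible_mask()
    for it in range(cfg.max_steps):
        # corr(x_j, r) = x_j'r / sqrt(x_j'x_j * r'r); columns are standardized
        with np.errstate(invalid="ignore"):
            corr = inner / np.sqrt(np.diag(G) * max(rss, 1e-300))
        corr = np.where(mask, corr, 0.0)
        j = int(np.argmax(np.abs(corr)))  # first max => smallest variable number
        if abs(corr[j]) < cfg.tolerance:
            break
        s = np.sign(corr[j])
        first = beta[j] == 0.0 and ws.names[j] not in owner.values()
        beta[j] += delta * s
        rss += -2.0 * delta * s * inner[j] + delta * delta * G[j, j]
        inner -= delta * s * G[:, j]
        if first:
            owner[concept[ws.names[j]]] = ws.names[j]
            mask = eligible_mask()
        if first or (it + 1) % 100 == 0:
            active = tuple(ws.names[k] for k in range(p) if beta[k] != 0.0)
            path.steps.append(
                PathStep(
                    "enter" if first else "increment",
                    ws.names[j],
                    active,
                    {ws.names[k]: float(beta[k]) for k in range(p) if beta[k] != 0.0},
                    ws.aic_of(active) if active else ols_aic(float(ws.y @ ws.y), n, 0),
                )
            )
    else:
        path.truncated = True
    active = tuple(ws.names[k] for k in range(p) if beta[k] != 0.0)
    coef = {ws.names[k]: float(beta[k]) for k in range(p) if beta[k] != 0.0}
    if not path.steps or path.terminal.coef != coef:
        aic = ws.aic_of(active) if active else ols_aic(float(ws.y @ ws.y), n, 0)
        path.steps.append(PathStep("increment", None, active, coef, aic))
    return path


def _lars_engine(
    design: CandidateDesign, y: np.ndarray, cfg: SSConfig, lasso: bool
) -> SelectionPath:
    ws = _Workspace(design, y)
    n, p = ws.n, len(ws.names)
    concept = {name: design.info(name).concept for name in ws.names}
    path = SelectionPath("lasso" if lasso else "lars")
    beta = np.zeros(p)
    mu = np.zeros(n)
    active: list[int] = []
    owner: dict[str, str] = {}
    tiny = 1e-12
    max_knots = 8 * p + 10  # drops can revisit; bound the loop

    for _ in range(max_knots):
        c = ws.X.T @ (ws.y - mu)
        elig = [
            j
            for j in range(p)
            if j not in active
            and owner.get(concept[ws.names[j]]) in (None, ws.names[j])
        ]
        event = None
        entered = None
        if active:
            C = float(np.max(np.abs(c[np.array(active)])))
        else:
            C = 0.0
        if elig:
            cmax_j = max(elig, key=lambda j: (abs(c[j]), -j))  # smaller index wins ties
            if not active or abs(c[cmax_j]) >= C - tiny:
                active.append(cmax_j)
                owner[concept[ws.names[cmax_j]]] = ws.names[cmax_j]
                C = float(abs(c[cmax_j]))
                event = "enter"
                entered = cmax_j
        if not active or C < tiny:
            break

        A = np.array(active)
        s = np.sign(c[A])
        XA = ws.X[:, A] * s
        G = XA.T @ XA
        try:
            invG1 = np.linalg.solve(G, np.ones(len(A)))
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(
                f"active set {[ws.names[j] for j in active]} is rank deficient"
            ) from exc
        denom = float(np.sum(invG1))
        if denom <= 0:
            raise SingularDesignError(
                f"active set {[ws.names[j] for j in active]} has a non-positive-definite Gram matrix"
            )
        AA = 1.0 / np.sqrt(denom)
        w = AA * invG1  # in the sign-flipped basis
        u = XA @ w  # equiangular direction
        a = ws.X.T @ u

        # distance to the next entry tie among eligible non-active columns
        gamma = C / AA  # full OLS on the active set
        elig_out = [
            j
            for j in range(p)
            if j not in active
            and owner.get(concept[ws.names[j]]) in (None, ws.names[j])
        ]
        for j in elig_out:
            for val in ((C - c[j]) / (AA - a[j]), (C + c[j]) / (AA + a[j])):
                if tiny < val < gamma:
                    gamma = float(val)

        drop_j = None
        if lasso:
            d = s * w  # coefficient direction in the original basis
            drops = [
                (-beta[j] / d[pos], j)
                for pos, j in enumerate(active)
                if (entered is None or j != entered)
                and d[pos] != 0.0
                and tiny < -beta[j] / d[pos] < gamma - tiny
            ]
            if drops:
                g_min = min(g for g, _ in drops)
                # smallest variable number on (numerically) tied zero crossings
                drop_j = min(j for g, j in drops if g <= g_min + 1e-12)
                gamma = g_min

        beta[A] += gamma * s * w
        mu += gamma * u

        if drop_j is not None:
            beta[drop_j] = 0.0
            active.remove(drop_j)
            owner.pop(concept[ws.names[drop_j]], None)
            event = "drop"
            knot_col = ws.names[drop_j]
        else:
            knot_col = ws.names[entered] if entered is not None else None

        names_active = tuple(ws.names[j] for j in sorted(active, key=lambda j: j))
        coef = {ws.names[j]: float(beta[j]) for j in active}
        aic = ws.aic_of(names_active) if names_active else ols_aic(float(ws.y @ ws.y), n, 0)
        path.steps.append(PathStep(event or "enter", knot_col, names_active, coef, aic))

        if gamma >= C / AA - tiny and drop_j is None:
            # reached the OLS solution of the active set; check for more entries
            c_next = ws.X.T @ (ws.y - mu)
            remaining = [
                j
                for j in range(p)
                if j not in active
                and owner.get(concept[ws.names[j]]) in (None, ws.names[j])
            ]
            if not remaining or float(np.max(np.abs(c_next[remaining]))) < max(
                1e-8, 1e-10 * n
            ):
                break
        if len(active) >= min(n - 1, p):
            break
    else:
        path.truncated = True
    return path


def ss_lars(
    design: CandidateDesign, y: np.ndarray, cfg: SSConfig = SSConfig()
) -> SelectionPath:
    """Least angle regression with one-scale-per-concept eligibility.

    At each knot the most-correlated eligible column joins the active set and
    the coefficients move along the equiangular direction until another
    eligible column ties the active absolute correlation.  Per-knot OLS-based
    AIC is recorded for model choice.
    """
    return _lars_engine(design, y, cfg, lasso=False)


def ss_lasso(
    design: CandidateDesign, y: np.ndarray, cfg: SSConfig = SSConfig()
) -> SelectionPath:
    """The lasso modification of :func:`ss_lars`: an active coefficient whose
    path crosses zero is dropped at that knot and the equiangular direction
    is recomputed.  A dropped concept's sibling scales regain eligibility."""
    return _lars_engine(design, y, cfg, lasso=True)


def choose_min_aic(
    path: SelectionPath, design: CandidateDesign, y: np.ndarray
) -> SelectedModel:
    """Pick the path knot whose active set minimizes the OLS-based AIC
    (earliest knot on ties), refitting OLS at every knot."""
    if not path.steps:
        raise ValueError("empty path")
    ws = _Workspace(design, y)
    best_i, best_aic = 0, float("inf")
    for i, step in enumerate(path.steps):
        aic = ws.aic_of(step.active) if step.active else ols_aic(float(ws.y @ ws.y), ws.n, 0)
        if aic < best_aic:
            best_i, best_aic = i, aic
    step = path.steps[best_i]
    return SelectedModel(path.algorithm, best_i, step.active, dict(step.coef), best_aic)


def final_model(
    path: SelectionPath, design: CandidateDesign, y: np.ndarray
) -> SelectedModel:
    """Apply each algorithm's model-choice rule to its path.

    LARS and lasso paths are scanned for the minimum OLS-based AIC knot;
    stepwise is epsilon-stopped so its last accepted step is the model;
    stagewise returns the nonzero coefficients at termination.
    """
    if path.algorithm in ("lars", "lasso"):
        return choose_min_aic(path, design, y)
    if not path.steps:
        return SelectedModel(path.algorithm, -1, (), {}, ols_aic(float(np.asarray(y) @ np.asarray(y)), len(y), 0))
    step = path.terminal
    return SelectedModel(path.algorithm, len(path.steps) - 1, step.active, dict(step.coef), step.aic)


ALGORITHMS = {
    "stepwise": ss_forward_stepwise,
    "stagewise": ss_forward_stagewise,
    "lars": ss_lars,
    "lasso": ss_lasso,
}
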