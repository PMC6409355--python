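"""Temporal-interaction regression models of gene expression.

The expression of a gene over the developmental time course is modelled as a
linear combination of *derived combination variables*: products of a peak
characteristic (H, D or W) with a function of time t in days.  The candidate
set V holds the 18 products of {H, D, W} with
{t, t^2, t^3, e^t, 0.5^t, log10(t+1)}.  The four named models share the
H*exp(t) and W*log10(t+1) terms and differ only in the time function applied
to the distance D:

    Model 1:  Exp = b1*H*e^t + b2*D*t     + b3*W*log10(t+1) + eps
    Model 2:  Exp = b1*H*e^t + b2*D*t^2   + b3*W*log10(t+1) + eps
    Model 3:  Exp = b1*H*e^t + b2*D*t^3   + b3*W*log10(t+1) + eps
    Model 4:  Exp = b1*H*e^t + b2*D*0.5^t + b3*W*log10(t+1) + eps

The disturbance eps is normal; its location is estimated as the fitted
intercept and its dispersion as the residual standard deviation.

Design columns span a huge dynamic range (e^t is ~6.6e7 at day 18), so the
fit normalises columns internally and back-transforms the coefficients;
the least-squares solve goes through an orthogonal decomposition, never the
normal equations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .genomic_io import TimeCourseRecord

logger = logging.getLogger(__name__)

# Time basis functions, keyed by their ASCII term-name suffix.
TIME_FUNCTIONS: dict[str, Callable[[float], float]] = {
    "t": lambda t: t,
    "t^2": lambda t: t ** 2,
    "t^3": lambda t: t ** 3,
    "exp(t)": lambda t: math.exp(t),
    "0.5^t": lambda t: 0.5 ** t,
    "log10(t+1)": lambda t: math.log10(t + 1.0),
}

_VARIABLES = ("H", "D", "W")

#: The 18 candidate derived combination variables, in deterministic order.
CANDIDATE_TERMS: tuple[str, ...] = tuple(
    f"{v}*{fname}" for v in _VARIABLES for fname in TIME_FUNCTIONS
)

#: Time function applied to D in each named model.
MODEL_D_FUNCTIONS: dict[int, str] = {1: "t", 2: "t^2", 3: "t^3", 4: "0.5^t"}


def term_value(term: str, record: TimeCourseRecord) -> float:
    """Evaluate one derived combination variable on a record."""
    var, fname = term.split("*", 1)
    base = {"H": record.height, "D": record.distance, "W": record.width}[var]
    return base * TIME_FUNCTIONS[fname](float(record.day))


def build_candidate_set(record: TimeCourseRecord) -> dict[str, float]:
    """All 18 candidate term values for one record, keyed by term name.

    At t=0 the exp(t) and 0.5^t terms equal the bare variable and the
    log10(t+1) terms are exactly zero.
    """
    if record.day < 0:
        raise ValueError("day must be >= 0")
    return {term: term_value(term, record) for term in CANDIDATE_TERMS}


@dataclass(frozen=True)
class ModelSpec:
    """A chosen basis of derived terms.

    ``model_id`` 1-4 fixes the distance time-function; ``"general"`` leaves
    it to ``f_t``.  The ordered basis is [H*exp(t), D*f(t), W*log10(t+1)].
    """

    model_id: int | str = 4
    f_t: str | None = None
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if self.model_id in MODEL_D_FUNCTIONS:
            expected = MODEL_D_FUNCTIONS[self.model_id]  # type: ignore[index]
            if self.f_t is not None and self.f_t != expected:
                raise ValueError(
                    f"Model {self.model_id} fixes f(t)={expected}, got {self.f_t}")
            object.__setattr__(self, "f_t", expected)
        elif self.model_id == "general":
            if self.f_t not in ("t", "t^2", "t^3", "0.5^t"):
                raise ValueError("general model needs f_t in {t, t^2, t^3, 0.5^t}")
        else:
            raise ValueError(f"unknown model_id {self.model_id!r}")

    @property
    def terms(self) -> tuple[str, str, str]:
        return ("H*exp(t)", f"D*{self.f_t}", "W*log10(t+1)")


@dataclass
class FitResult:
    """Least-squares estimate of one expression model.

    ``intercept`` is the fitted location of the normal disturbance;
    ``residual_sd`` its estimated dispersion (RSS/(n-k-1) under the root).
    """

    beta: np.ndarray
    intercept: float
    se_beta: np.ndarray
    se_intercept: float
    residual_sd: float
    n: int
    k: int
    fitted: np.ndarray
    residuals: np.ndarray
    term_names: tuple[str, ...] = ()
    include_intercept: bool = True

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def dof(self) -> int:
        return self.n - self.k - (1 if self.include_intercept else 0)


def design_matrix(
    records: Sequence[TimeCourseRecord],
    spec: ModelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (n x 3, intercept excluded) and response vector."""
    return terms_matrix(records, spec.terms)


def terms_matrix(
    records: Sequence[TimeCourseRecord],
    terms: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[term_value(t, r) for t in terms] for r in records], dtype=float)
    X = X.reshape(len(records), len(terms))
    y = np.array([r.expression for r in records], dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entry in design matrix")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response value")
    if len(records) < len(terms) + 2:
        logger.warning("n=%d < k+2=%d: fit possible but inference disabled",
                       len(records), len(terms) + 2)
    return X, y


class RankDeficientDesign(np.linalg.LinAlgError):
    pass


def fit_lsm(
    X: np.ndarray,
    y: np.ndarray,
    include_intercept: bool = True,
    term_names: Sequence[str] | None = None,
) -> FitResult:
    """Ordinary least squares via QR on column-normalised data.

    Coefficients minimise the residual sum of squares; standard errors are
    ``residual_sd * sqrt(diag((X'X)^-1))`` computed from the R factor, and
    everything is reported on the raw column scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    names = tuple(term_names) if term_names is not None else tuple(
        f"x{j + 1}" for j in range(k))
    if len(names) != k:
        raise ValueError("term_names length must match design columns")

    if include_intercept:
        A = np.column_stack([np.ones(n), X])
        all_names = ("intercept",) + names
    else:
        A = X
        all_names = names
        logger.warning("no-intercept fit: the TSS = ESS + RSS decomposition "
                       "is not guaranteed")
    p = A.shape[1]

    scales = np.linalg.norm(A, axis=0)
    scales[scales == 0.0] = 1.0
    As = A / scales

    Q, R = np.linalg.qr(As)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.nonzero(diag <= tol)[0]
    if bad.size:
        raise RankDeficientDesign(
            f"design is rank deficient at column '{all_names[bad[0]]}'")

    coef_s = np.linalg.solve(R, Q.T @ y)
    coef = coef_s / scales
    fitted = A @ coef
    residuals = y - fitted
    rss = float(residuals @ residuals)

    dof = n - p
    if dof > 0:
        residual_var = rss / dof
    else:
        residual_var = math.nan
        logger.warning("zero residual degrees of freedom: no dispersion estimate")
    Rinv = np.linalg.solve(R, np.eye(p))
    se_scaled = np.sqrt(np.sum(Rinv ** 2, axis=1) * residual_var)
    se = se_scaled / scales

    if include_intercept:
        beta, intercept = coef[1:], float(coef[0])
        se_beta, se_intercept = se[1:], float(se[0])
        n_terms = k
    else:
        beta, intercept = coef, 0.0
        se_beta, se_intercept = se, math.nan
        n_terms = k

    return FitResult(
        beta=beta, intercept=intercept, se_beta=se_beta, se_intercept=se_intercept,
        residual_sd=math.sqrt(residual_var) if residual_var == residual_var else math.nan,
        n=n, k=n_terms, fitted=fitted, residuals=residuals,
        term_names=names, include_intercept=include_intercept,
    )


def fit_model(records: Sequence[TimeCourseRecord], spec: ModelSpec) -> FitResult:
    """Convenience: build the design for ``spec`` and fit it."""
    X, y = design_matrix(records, spec)
    return fit_lsm(X, y, include_intercept=spec.include_intercept,
                   term_names=spec.terms)


def predict(
    fit: FitResult,
    records: Sequence[TimeCourseRecord],
    spec: ModelSpec | None = None,
    terms: Sequence[str] | None = None,
) -> np.ndarray:
    """Predicted expression X beta + intercept for new records."""
    use_terms = spec.terms if spec is not None else tuple(terms or fit.term_names)
    if tuple(use_terms) != tuple(fit.term_names):
        raise ValueError("prediction terms do not match the fitted basis")
    X, _ = terms_matrix(records, use_terms)
    return X @ fit.beta + fit.intercept


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def _aic(rss: float, n: int, n_params: int) -> float:
    # Gaussian log-likelihood up to a constant; floor guards exact fits.
    return n * math.log(max(rss, 1e-300) / n) + 2 * (n_params + 1)


def _coef_tstat(fit: FitResult, term: str) -> float:
    j = fit.term_names.index(term)
    se = fit.se_beta[j]
    if not (se > 0):
        return math.inf if abs(fit.beta[j]) > 0 else 0.0
    return abs(fit.beta[j] / se)


def _coef_pvalue(fit: FitResult, term: str) -> float:
    from scipy import stats

    t = _coef_tstat(fit, term)
    if math.isinf(t):
        return 0.0
    return 2.0 * float(stats.t.sf(t, fit.dof))


def stepwise_select(
    records: Sequence[TimeCourseRecord],
    candidates: Sequence[str] | None = None,
    criterion: str = "aic",
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_steps: int = 50,
) -> list[str]:
    """Bidirectional stepwise selection over the candidate term set.

    Starts from the intercept-only model; each step adds the candidate that
    most improves the criterion, then tests the selected terms for removal.
    Ties break alphabetically, so the outcome is deterministic in the input.

    With ``criterion="pvalue"`` the entry test Bonferroni-adjusts the best
    candidate's p-value for the number of candidates examined at that step,
    holding the familywise false-entry rate near ``alpha_enter``; removal
    uses the unadjusted p against ``alpha_remove``.  ``criterion="aic"``
    compares Akaike's criterion directly and is deliberately more liberal.
    """
    if criterion not in ("aic", "pvalue"):
        raise ValueError(f"unknown criterion {criterion!r}")
    pool = sorted(set(candidates if candidates is not None else CANDIDATE_TERMS))
    if len(pool) < 1:
        raise ValueError("need at least one candidate")
    n = len(records)
    if n < 5:
        raise ValueError("need at least 5 records for stepwise selection")

    values = {term: np.array([term_value(term, r) for r in records]) for term in pool}
    y = np.array([r.expression for r in records])

    def fit_terms(terms: list[str]) -> FitResult:
        X = np.column_stack([values[t] for t in terms]) if terms else np.empty((n, 0))
        return fit_lsm(X, y, include_intercept=True, term_names=terms)

    selected: list[str] = []
    current = fit_terms(selected)
    current_aic = _aic(current.rss, n, len(selected))
    seen_states: set[tuple[str, ...]] = {tuple(selected)}

    for _ in range(max_steps):
        moved = False

        # --- entry ---
        remaining = [t for t in pool if t not in selected]
        best_term, best_fit, best_score = None, None, None
        for term in remaining:
            try:
                trial = fit_terms(selected + [term])
            except RankDeficientDesign:
                continue
            if criterion == "aic":
                # smaller is better; first (alphabetical) candidate wins ties
                score = _aic(trial.rss, n, len(selected) + 1)
            else:
                # |t| avoids p-value underflow when the signal is strong
                score = -_coef_tstat(trial, term)
            if best_score is None or score < best_score - 1e-12:
                best_term, best_fit, best_score = term, trial, score
        if best_term is not None:
            if criterion == "aic":
                accept = best_score < current_aic - 1e-9
            else:
                p = _coef_pvalue(best_fit, best_term)
                adj_p = min(1.0, p * len(remaining))
                accept = adj_p < alpha_enter
            if accept:
                selected = sorted(selected + [best_term],
                                  key=lambda t: pool.index(t))
                current = fit_terms(selected)
                current_aic = _aic(current.rss, n, len(selected))
                moved = True

        # --- removal ---
        if selected:
            if criterion == "aic":
                best_drop, best_drop_aic = None, current_aic
                for term in selected:
                    rest = [t for t in selected if t != term]
                    trial = fit_terms(rest)
                    a = _aic(trial.rss, n, len(rest))
                    if a < best_drop_aic - 1e-9:
                        best_drop, best_drop_aic = term, a
                if best_drop is not None:
                    selected = [t for t in selected if t != best_drop]
                    current = fit_terms(selected)
                    current_aic = best_drop_aic
                    moved = True
            else:
                pvals = {t: _coef_pvalue(current, t) for t in selected}
                worst = max(sorted(pvals), key=lambda t: pvals[t])
                if pvals[worst] > alpha_remove:
                    selected = [t for t in selected if t != worst]
                    current = fit_terms(selected)
                    moved = True

        state = tuple(selected)
        if not moved or state in seen_states:
            break
        seen_states.add(state)

    return selected
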