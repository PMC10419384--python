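"""Contingency diagnostics, logistic regression via IRLS, and the two
nonparametric tests used downstream (chi-square, Mann-Whitney U).

The diagnostic workflow mirrors a standard case-control screen: for each
disease x response-combination pair, a 2x2 table (a = exposed & diseased,
b = exposed & not, c = unexposed & diseased, d = unexposed & not) yields

* odds ratio OR = ad / (bc), with Wald 95% CI
  exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d));
* sensitivity a / (a + c) and specificity d / (b + d).

Univariable logistic fits (one predictor plus intercept) screen candidates at
Wald p < alpha before a multivariable fit — the selection rule used in the
clinical analysis. The logistic likelihood is maximized by Newton-Raphson /
iteratively reweighted least squares written out in full here; scipy supplies
only the reference distributions for p-values, and statsmodels is used solely
as a cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import PatientRecord
from .exceptions import (
    RankDeficientError,
    SeparationError,
    UndefinedDiagnosticError,
    ValidationError,
)
from .scoring import Combo

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-disease counts."""

    a: int  # exposed & disease
    b: int  # exposed & no disease
    c: int  # unexposed & disease
    d: int  # unexposed & no disease

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table must contain at least one count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class DiagnosticStats:
    odds_ratio: float
    log_or: float
    ci95_low: float
    ci95_high: float
    sensitivity: float
    specificity: float
    continuity_corrected: bool


@dataclass(frozen=True)
class LogitFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_iterations: int
    converged: bool
    log_likelihood: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Optional[float]
    p_value: float
    method: str


def make_table(cohort: Sequence[PatientRecord], disease, combo) -> ContingencyTable:
    """Marginalize a cohort into the 2x2 table for one disease x combination pair.

    Exposure is membership in the combination category; disease status is the
    given diagnosis versus all others.
    """
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    combo = Combo(combo)
    a = b = c = d = 0
    for r in cohort:
        exposed = r.combo is combo
        diseased = r.disease == disease
        if exposed and diseased:
            a += 1
        elif exposed:
            b += 1
        elif diseased:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def diagnostics(table: ContingencyTable, haldane: bool = False) -> DiagnosticStats:
    """Odds ratio with Wald 95% CI, sensitivity and specificity of a 2x2 table.

    ``haldane`` adds the Haldane-Anscombe 0.5 continuity correction to every
    cell for the OR and its CI only (sensitivity/specificity always use raw
    counts); without it, any zero cell is an error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + c == 0 or b + d == 0:
        raise UndefinedDiagnosticError(
            "sensitivity/specificity undefined: a zero disease margin"
        )
    if min(a, b, c, d) == 0 and not haldane:
        raise UndefinedDiagnosticError(
            "zero cell: odds ratio undefined (pass haldane=True for the "
            "0.5-continuity-corrected estimate)"
        )
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if haldane else (a, b, c, d)
    )
    log_or = math.log((aa * dd) / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return DiagnosticStats(
        odds_ratio=math.exp(log_or),
        log_or=log_or,
        ci95_low=math.exp(log_or - Z95 * se),
        ci95_high=math.exp(log_or + Z95 * se),
        sensitivity=a / (a + c),
        specificity=d / (b + d),
        continuity_corrected=haldane,
    )


# ---------------------------------------------------------------------------
# Logistic regression (Newton-Raphson / IRLS)
# ---------------------------------------------------------------------------

def add_intercept(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    return np.column_stack([np.ones(x.shape[0]), x])


def fit_logistic_irls(
    design: np.ndarray,
    outcome: np.ndarray,
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_bound: float = 15.0,
) -> LogitFit:
    """Maximize the Bernoulli log-likelihood by Newton-Raphson (IRLS).

    Parameters
    ----------
    design
        n x p predictor matrix including the intercept column.
    outcome
        Binary 0/1 vector of length n.
    tol
        Convergence tolerance on the max-norm of the score (gradient).
    separation_bound
        A coefficient magnitude exceeding this during iteration is declared
        (quasi-)complete separation.

    Standard errors come from the inverse observed information at the optimum;
    Wald z and two-sided p-values per coefficient.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("design and outcome dimensions do not match")
    if not np.all(np.isfinite(X)):
        raise ValidationError("design matrix contains non-finite values")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValidationError("outcome must be coded 0/1")
    if uniq.size < 2:
        raise SeparationError("outcome is constant: likelihood is degenerate")

    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RankDeficientError(
                "observed information is singular (collinear design)"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > separation_bound:
            raise SeparationError(
                f"coefficient magnitude exceeded {separation_bound}: complete or "
                "quasi-complete separation"
            )
        if np.max(np.abs(grad)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError("observed information is singular") from exc
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    if names is None:
        names = ["intercept"] + [f"x{i}" for i in range(1, p)]
    return LogitFit(
        names=tuple(names),
        coef=beta,
        se=se,
        z=z,
        p=pvals,
        n_iterations=it,
        converged=converged,
        log_likelihood=loglik,
    )


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of a univariable logistic screen."""

    fits: dict  # predictor name -> LogitFit
    errors: dict  # predictor name -> error message
    selected: tuple[str, ...]  # Wald p < alpha, in input order
    alpha: float


def univariable_screen(
    predictors: dict,
    outcome: np.ndarray,
    alpha: float = 0.05,
) -> ScreenResult:
    """Fit each candidate predictor alone (with intercept); select Wald p < alpha.

    Fit failures (separation, rank deficiency) are recorded per predictor and do
    not abort the screen. Output ordering follows the input mapping order.
    """
    if not predictors:
        raise ValidationError("at least one candidate predictor is required")
    y = np.asarray(outcome, dtype=float).ravel()
    fits: dict = {}
    errors: dict = {}
    selected: list[str] = []
    for name, x in predictors.items():
        try:
            fit = fit_logistic_irls(
                add_intercept(np.asarray(x, dtype=float)), y,
                names=("intercept", name),
            )
        except (SeparationError, RankDeficientError, ValidationError) as exc:
            errors[name] = f"{type(exc).__name__}: {exc}"
            continue
        fits[name] = fit
        if fit.p[1] < alpha:
            selected.append(name)
    return ScreenResult(fits=fits, errors=errors, selected=tuple(selected), alpha=alpha)


def combo_indicators(cohort: Sequence[PatientRecord]) -> dict:
    """0/1 indicator vectors for each response combination, ordered PP, PN, NP, NN."""
    return {
        c.value: np.array([1.0 if r.combo is c else 0.0 for r in cohort])
        for c in Combo
    }


def disease_indicator(cohort: Sequence[PatientRecord], disease) -> np.ndarray:
    return np.array([1.0 if r.disease == disease else 0.0 for r in cohort])


# ---------------------------------------------------------------------------
# Chi-square test
# ---------------------------------------------------------------------------

def chi_square_test(table: Iterable, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Statistic sum (O-E)^2 / E with E from the product of margins; the Yates
    continuity correction ((|O-E|-0.5)^2) applies to 2x2 tables only, when
    requested. p-value from the upper tail of chi-square with (r-1)(c-1) df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("chi-square test needs an r x c table, r, c >= 2")
    if np.any(obs < 0):
        raise ValidationError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValidationError("all row and column margins must be positive")
    expected = np.outer(rows, cols) / n
    dev = np.abs(obs - expected)
    if yates and obs.shape == (2, 2):
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    label = "chi-square" + (" (Yates)" if yates and obs.shape == (2, 2) else "")
    return TestResult(statistic=stat, df=df, p_value=p, method=label)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple:
    """Number of (n, m) label arrangements yielding each U value 0..n*m.

    Classic recurrence for the tie-free null distribution:
    N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1).
    """
    if n == 0 or m == 0:
        return (1.0,)
    a = _u_counts(n - 1, m)
    b = _u_counts(n, m - 1)
    out = [0.0] * (n * m + 1)
    for u, v in enumerate(a):
        out[u + m] += v
    for u, v in enumerate(b):
        out[u] += v
    return tuple(out)


EXACT_MWU_LIMIT = 400  # exact enumeration when n_x * n_y <= this and no ties


def mann_whitney_u(
    sample_x: Sequence[float],
    sample_y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    U is the number of (x, y) pairs with x > y, counting ties as 1/2 (computed
    via midranks). For tie-free samples with n_x * n_y <= 400 the p-value is
    exact (full null distribution by counting); otherwise the normal
    approximation with tie-corrected variance is used. ``alternative`` is one
    of 'two-sided', 'greater' (x tends larger), 'less'.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and nx * ny <= EXACT_MWU_LIMIT:
        counts = np.array(_u_counts(nx, ny))
        total = counts.sum()
        u_int = int(round(u_x))
        p_ge = counts[u_int:].sum() / total
        p_le = counts[: u_int + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(statistic=u_x, df=None, p_value=float(p),
                          method="Mann-Whitney U (exact)")

    n = nx + ny
    mean_u = nx * ny / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        # all observations identical: no evidence either way
        return TestResult(statistic=u_x, df=None, p_value=1.0,
                          method="Mann-Whitney U (normal, tie-corrected)")
    z = (u_x - mean_u) / math.sqrt(var_u)
    if alternative == "greater":
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        p = float(sps.norm.cdf(z))
    else:
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(statistic=u_x, df=None, p_value=p,
                      method="Mann-Whitney U (normal, tie-corrected)")
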