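"""Test-retest reliability and exploratory correlation/factor analysis.

Reliability is summarized per outcome by the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1) and
the standard error of measurement SEM = SD * sqrt(1 - ICC).  The
absolute-agreement form is used because it penalizes systematic
test-retest biases, which consistency forms ignore.

The exploratory stage computes the Spearman correlation matrix of the
26-variable outcome table (pairwise deletion, significance at
p < 1e-5), selects the number of factors by parallel analysis against
normal surrogate data, and extracts maximum-likelihood factors with
varimax rotation (via statsmodels), reporting loadings above a 0.65
threshold and per-factor variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .outcomes import ANALYSIS_VARIABLES, BEAR3_VARIABLES

__all__ = [
    "ReliabilityReport",
    "FactorReport",
    "icc_agreement",
    "sem_measure",
    "reliability_report",
    "spearman_matrix",
    "parallel_analysis",
    "factor_analysis_ml",
    "read_bear3_dataset",
    "write_bear3_dataset",
]


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-outcome test-retest reliability summary."""

    outcome: str
    icc: float
    sem: float
    mean_bias: float
    n: int


def icc_agreement(test: Sequence[float], retest: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares for n subjects by k=2
    sessions:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-session, and MSE the
    residual mean square.  Undefined (NaN) when the data carry no
    variance at all.
    """
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    ok = ~np.any(np.isnan(x), axis=1)
    x = x[ok]
    n, k = x.shape
    if n < 3:
        raise ValueError("at least three complete pairs are required")
    grand = x.mean()
    if np.allclose(x, grand):
        return float("nan")
    ms_rows = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        return float("nan")
    return float((ms_rows - ms_err) / denom)


def sem_measure(test: Sequence[float], retest: Sequence[float],
                icc: float) -> float:
    """Standard error of measurement: pooled between-subject SD * sqrt(1-ICC)."""
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    ok = ~np.any(np.isnan(x), axis=1)
    x = x[ok]
    sd = np.sqrt(0.5 * (np.var(x[:, 0], ddof=1) + np.var(x[:, 1], ddof=1)))
    return float(sd * np.sqrt(max(0.0, 1.0 - icc)))


def reliability_report(
    table_test: pd.DataFrame, table_retest: pd.DataFrame,
    outcomes: Sequence[str] | None = None,
) -> list[ReliabilityReport]:
    """ICC/SEM/bias per outcome column for paired session tables."""
    if outcomes is None:
        outcomes = [c for c in table_test.columns if c in BEAR3_VARIABLES]
    reports = []
    for col in outcomes:
        a = pd.to_numeric(table_test[col], errors="coerce").to_numpy(float)
        b = pd.to_numeric(table_retest[col], errors="coerce").to_numpy(float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3:
            continue
        icc = icc_agreement(a[ok], b[ok])
        sem = sem_measure(a[ok], b[ok], icc) if np.isfinite(icc) else float("nan")
        reports.append(
            ReliabilityReport(col, icc, sem,
                              float(np.mean(b[ok] - a[ok])), int(ok.sum()))
        )
    return reports


# ---------------------------------------------------------------------------
# Correlation matrix
# ---------------------------------------------------------------------------


def spearman_matrix(
    table: pd.DataFrame, alpha: float = 1e-5,
    variables: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho matrix with a significance mask at ``alpha``.

    Uses pairwise deletion; each pair needs at least three complete
    rows.  Returns ``(rho, significant)`` DataFrames.
    """
    if variables is None:
        variables = [c for c in table.columns if c in ANALYSIS_VARIABLES]
    data = table[list(variables)].apply(pd.to_numeric, errors="coerce")
    p = len(variables)
    rho = np.eye(p)
    pval = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = data.iloc[:, i], data.iloc[:, j]
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                r, pv = np.nan, np.nan
            else:
                r, pv = spearmanr(a[ok], b[ok])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = pv
    rho_df = pd.DataFrame(rho, index=variables, columns=variables)
    sig = pd.DataFrame(pval < alpha, index=variables, columns=variables)
    np.fill_diagonal(sig.values, False)
    return rho_df, sig


# ---------------------------------------------------------------------------
# Factor machinery
# ---------------------------------------------------------------------------


def parallel_analysis(
    table: pd.DataFrame | np.ndarray,
    n_sim: int = 500,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> int:
    """Number of factors by Horn's parallel analysis.

    Counts the leading eigenvalues of the observed correlation matrix
    that exceed the ``quantile`` of the corresponding eigenvalues of
    standard-normal surrogate tables of the same shape.  Complete cases
    only.
    """
    x = np.asarray(table, dtype=float)
    x = x[~np.any(np.isnan(x), axis=1)]
    n, p = x.shape
    if n < p + 1:
        raise ValueError("parallel analysis needs more rows than columns")
    rng = np.random.default_rng(seed)
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    sims = np.empty((n_sim, p))
    for s in range(n_sim):
        surrogate = rng.standard_normal((n, p))
        sims[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(surrogate, rowvar=False)))[::-1]
    ref = np.quantile(sims, quantile, axis=0)
    exceed = obs > ref
    # count the leading run only: a later crossing after a failure is noise
    k = 0
    for e in exceed:
        if not e:
            break
        k += 1
    return k


@dataclass(frozen=True)
class FactorReport:
    """ML + varimax factor solution for the outcome table."""

    n_factors: int
    loadings: pd.DataFrame            # variables x factors
    variance_explained: tuple[float, ...]   # percent per factor
    cumulative_variance: float        # percent
    rotation: str
    loading_threshold: float
    n_obs: int
    heywood: bool

    def salient(self) -> pd.DataFrame:
        """Loadings with |value| above the threshold (others masked)."""
        return self.loadings.where(self.loadings.abs() > self.loading_threshold)


def factor_analysis_ml(
    table: pd.DataFrame,
    n_factors: int,
    rotation: str = "varimax",
    loading_threshold: float = 0.65,
) -> FactorReport:
    """Maximum-likelihood factor analysis with orthogonal rotation.

    Columns are standardized; complete cases only.  Per-factor variance
    explained is the sum of squared rotated loadings over the number of
    variables, with factors ordered by explained variance.
    """
    from statsmodels.multivariate.factor import Factor

    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    data = table.apply(pd.to_numeric, errors="coerce").dropna()
    x = (data - data.mean()) / data.std(ddof=1)
    model = Factor(x.to_numpy(), n_factor=n_factors, method="ml")
    res = model.fit(maxiter=200, em_iter=20)
    if rotation:
        res.rotate(rotation)
    load = np.asarray(res.loadings)
    communal = (load**2).sum(axis=1)
    heywood = bool(np.any(communal > 1.0 + 1e-6))
    var_per = (load**2).sum(axis=0) / load.shape[0] * 100.0
    order = np.argsort(var_per)[::-1]
    load = load[:, order]
    var_per = var_per[order]
    # orient each factor so its largest-magnitude loading is positive
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] *= -1
    loadings = pd.DataFrame(
        load, index=data.columns,
        columns=[f"F{j+1}" for j in range(load.shape[1])],
    )
    return FactorReport(
        n_factors=n_factors,
        loadings=loadings,
        variance_explained=tuple(float(v) for v in var_per),
        cumulative_variance=float(var_per.sum()),
        rotation=rotation or "none",
        loading_threshold=loading_threshold,
        n_obs=len(data),
        heywood=heywood,
    )


# ---------------------------------------------------------------------------
# Outcome-table I/O
# ---------------------------------------------------------------------------


def read_bear3_dataset(path: str, strict: bool = True) -> pd.DataFrame:
    """Read a reduced outcome table (CSV, one row per listener).

    Validates the column set against the battery's variable list and
    raises a schema error naming missing/extra columns; empty cells are
    missing values.
    """
    df = pd.read_csv(path)
    meta = {"listener_id", "group", "seed"}
    cols = set(df.columns) - meta
    expected = set(BEAR3_VARIABLES)
    missing, extra = expected - cols, cols - expected
    if strict and (missing or extra):
        raise ValueError(
            "outcome-table schema mismatch: "
            f"missing columns {sorted(missing)}, unexpected columns {sorted(extra)}"
        )
    for c in expected & cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def write_bear3_dataset(table: pd.DataFrame, path: str) -> None:
    """Write the outcome table as CSV with empty cells for missing values."""
    table.to_csv(path, index=False)
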