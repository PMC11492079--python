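"""Scan-rescan reliability statistics for lesion volume and count.

Measurements arrive in long format — one row per (subject, scanner, run,
metric) — and feed:

* **ICC-AA**: two-way random-effects, single-measurement, absolute-
  agreement intraclass correlation for run 1 vs run 2 within one scanner
  (penalizes systematic offsets), with the standard F-based 95 % CI.
* **ICC-C**: two-way mixed, single-measurement, consistency ICC for
  run-1 values of a scanner pair (invariant to per-scanner offsets).
* **Variance components** by method-of-moments (EMS) estimators, with
  negative estimates truncated at zero. Within-scanner the residual is
  estimated from scan-rescan run differences inside each subject x
  scanner cell; between-scanner a two-way subject x scanner ANOVA on
  run-1 values yields subject, scanner and residual components.
* **SEM / SDC**: SEM_within = sqrt(sigma2_error);
  SEM_between = sqrt(sigma2_scanner + sigma2_error);
  SDC = 1.96 * sqrt(2) * SEM. Both are also expressed as percentages of
  the grand mean of the values entering the respective decomposition.
* **RM-ANOVA** (volumes) and **Friedman** (counts) across scanners on
  run-1 values, with Bonferroni-corrected pairwise post hoc tests.
  RM-ANOVA p-values are sphericity-uncorrected and flagged as such.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "SDC_FACTOR",
    "ICCResult",
    "VarianceComponents",
    "ReliabilityReport",
    "TestResult",
    "read_measurement_table",
    "check_balanced",
    "icc_absolute_agreement",
    "icc_consistency",
    "variance_components_within",
    "variance_components_between",
    "sem_sdc",
    "rm_anova",
    "friedman",
    "posthoc_pairwise",
]

REQUIRED_COLUMNS = ["subject", "scanner", "run", "metric", "value"]

#: SDC = 1.96 * sqrt(2) * SEM — the smallest change in an individual that
#: exceeds measurement noise at 95 % confidence.
SDC_FACTOR = 1.96 * np.sqrt(2.0)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str  # absolute_agreement_2way_random | consistency_2way_mixed
    n_subjects: int
    k_conditions: int


@dataclass
class VarianceComponents:
    sigma2_subject: float
    sigma2_condition: float
    sigma2_error: float
    grand_mean: float
    design: str  # within_scanner | between_scanner


@dataclass
class ReliabilityReport:
    sem_abs: float
    sdc_abs: float
    sem_pct: float
    sdc_pct: float
    design: str


@dataclass
class TestResult:
    statistic: float
    df1: float
    df2: float | None
    p: float
    name: str
    notes: str = ""


# ---------------------------------------------------------------------------
# Table handling


def read_measurement_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    dup = df.duplicated(subset=["subject", "scanner", "run", "metric"])
    if dup.any():
        raise ValueError("duplicate (subject, scanner, run, metric) rows")
    return df


def check_balanced(df: pd.DataFrame, metric: str | None = None) -> None:
    """Verify every subject x scanner x run cell is present exactly once."""
    if metric is not None:
        df = df[df["metric"] == metric]
    subjects = sorted(df["subject"].unique())
    scanners = sorted(df["scanner"].unique())
    runs = sorted(df["run"].unique())
    expected = set(itertools.product(subjects, scanners, runs))
    present = set(map(tuple, df[["subject", "scanner", "run"]].itertuples(index=False)))
    missing = expected - present
    if missing:
        sample = sorted(missing)[:10]
        raise ValueError(f"unbalanced design; {len(missing)} missing cells, e.g. {sample}")


def _wide(df: pd.DataFrame, columns: str) -> pd.DataFrame:
    """Pivot to a complete subjects x conditions value matrix (complete cases)."""
    w = df.pivot_table(index="subject", columns=columns, values="value", aggfunc="first")
    return w.dropna(axis=0, how="any")


# ---------------------------------------------------------------------------
# Two-way ANOVA mean squares (subjects x conditions, one observation/cell)


def _mean_squares(x: np.ndarray):
    """Return (MSR, MSC, MSE, n, k) for an n x k matrix."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def _require_matrix(x: np.ndarray, what: str) -> None:
    if x.shape[0] < 3:
        raise ValueError(f"{what} requires >= 3 subjects with complete data, got {x.shape[0]}")


def icc_absolute_agreement(df: pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, single measurement, absolute agreement.

    ``df`` holds one scanner's values in long format with a ``run``
    column; rows with missing runs are dropped (complete cases).
    """
    x = _wide(df, "run").to_numpy(dtype=float)
    _require_matrix(x, "ICC")
    msr, msc, mse, n, k = _mean_squares(x)
    if np.isclose(msr, 0.0) and np.isclose(mse, 0.0):
        warnings.warn("zero between-subject variance; ICC undefined")
        return ICCResult(np.nan, np.nan, np.nan, "absolute_agreement_2way_random", n, k)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom
    lo, hi = _icc2_ci(msr, msc, mse, n, k, icc, alpha)
    return ICCResult(icc, lo, hi, "absolute_agreement_2way_random", n, k)


def _icc2_ci(msr, msc, mse, n, k, icc, alpha):
    # McGraw & Wong F-based interval for ICC(A,1); Satterthwaite df for
    # the numerator mixture of MSC and MSE.
    if np.isclose(icc, 1.0):
        return 1.0, 1.0
    a = (k * icc) / (n * (1 - icc))
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(lo), float(hi)


def icc_consistency(df: pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1): two-way mixed effects, single measurement, consistency.

    ``df`` holds run-1 values of a pair (or more) of scanners in long
    format with a ``scanner`` column.
    """
    x = _wide(df, "scanner").to_numpy(dtype=float)
    _require_matrix(x, "ICC")
    msr, msc, mse, n, k = _mean_squares(x)
    if np.isclose(msr, 0.0) and np.isclose(mse, 0.0):
        warnings.warn("zero between-subject variance; ICC undefined")
        return ICCResult(np.nan, np.nan, np.nan, "consistency_2way_mixed", n, k)
    icc = (msr - mse) / (msr + (k - 1) * mse)
    if np.isclose(mse, 0.0):
        lo, hi = 1.0, 1.0
    else:
        f = msr / mse
        df2 = (n - 1) * (k - 1)
        fl = f / stats.f.ppf(1 - alpha / 2, n - 1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(lo), float(hi), "consistency_2way_mixed", n, k)


# ---------------------------------------------------------------------------
# Variance components, SEM, SDC


def variance_components_within(df: pd.DataFrame) -> VarianceComponents:
    """Scan-rescan residual variance, pooled over subject x scanner cells.

    Model: value = mu + cell(subject x scanner) + error(run). With two
    runs per cell the moment estimator of the residual variance is the
    mean over cells of (run difference)^2 / 2.
    """
    check_balanced(df)
    runs = sorted(df["run"].unique())
    if len(runs) != 2:
        raise ValueError(f"within-scanner decomposition needs exactly 2 runs, got {runs}")
    piv = df.pivot_table(index=["subject", "scanner"], columns="run", values="value")
    d = piv[runs[1]].to_numpy(dtype=float) - piv[runs[0]].to_numpy(dtype=float)
    sigma2_error = float(np.mean(d**2) / 2.0)
    cell_means = piv.mean(axis=1)
    sigma2_subject = float(max(cell_means.groupby("subject").mean().var(ddof=1), 0.0))
    return VarianceComponents(
        sigma2_subject=sigma2_subject,
        sigma2_condition=0.0,
        sigma2_error=sigma2_error,
        grand_mean=float(df["value"].mean()),
        design="within_scanner",
    )


def variance_components_between(df: pd.DataFrame) -> VarianceComponents:
    """Subject x scanner decomposition of run-1 values.

    EMS moment estimators from the two-way ANOVA mean squares:
    sigma2_scanner = (MSC - MSE)/n, sigma2_subject = (MSR - MSE)/k,
    sigma2_error = MSE; negative estimates truncated at zero.
    """
    if "run" in df.columns and df["run"].nunique() > 1:
        raise ValueError("between-scanner decomposition expects run-1 values only")
    w = df.pivot_table(index="subject", columns="scanner", values="value", aggfunc="first")
    if w.isna().any().any():
        missing = [(s, c) for (s, c) in zip(*np.where(w.isna()))]
        raise ValueError(f"unbalanced subject x scanner grid; missing cells at {missing[:10]}")
    x = w.to_numpy(dtype=float)
    msr, msc, mse, n, k = _mean_squares(x)
    return VarianceComponents(
        sigma2_subject=float(max((msr - mse) / k, 0.0)),
        sigma2_condition=float(max((msc - mse) / n, 0.0)),
        sigma2_error=float(mse),
        grand_mean=float(x.mean()),
        design="between_scanner",
    )


def sem_sdc(vc: VarianceComponents, components: str | None = None) -> ReliabilityReport:
    """SEM and SDC, absolute and as % of the grand mean.

    ``components`` selects what enters the SEM: "error" (scan-rescan
    residual only; the within-scanner default) or "condition+error"
    (scanner plus residual; the between-scanner default).
    """
    if vc.grand_mean <= 0:
        raise ValueError(f"grand mean must be positive, got {vc.grand_mean}")
    if components is None:
        components = "error" if vc.design == "within_scanner" else "condition+error"
    if components == "error":
        var = vc.sigma2_error
    elif components == "condition+error":
        var = vc.sigma2_condition + vc.sigma2_error
    else:
        raise ValueError(f"unknown components selection {components!r}")
    sem_abs = float(np.sqrt(var))
    sem_pct = 100.0 * sem_abs / vc.grand_mean
    # derive both SDCs from their SEM so the 1.96*sqrt(2) ratio is bit-exact
    return ReliabilityReport(
        sem_abs=sem_abs,
        sdc_abs=SDC_FACTOR * sem_abs,
        sem_pct=sem_pct,
        sdc_pct=SDC_FACTOR * sem_pct,
        design=vc.design,
    )


# ---------------------------------------------------------------------------
# Omnibus tests and post hocs


def rm_anova(df: pd.DataFrame, factor: str = "scanner") -> TestResult:
    """One-way repeated-measures ANOVA: F = MS_condition / MS_residual.

    The p-value is uncorrected for sphericity and flagged as such.
    """
    x = _wide(df, factor).to_numpy(dtype=float)
    _require_matrix(x, "RM-ANOVA")
    msr, msc, mse, n, k = _mean_squares(x)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if np.isclose(mse, 0.0):
        f = 0.0 if np.isclose(msc, 0.0) else np.inf
    else:
        f = msc / mse
    p = 1.0 if f == 0.0 else float(stats.f.sf(f, df1, df2))
    return TestResult(float(f), df1, df2, p, "rm_anova", notes="sphericity-uncorrected")


def friedman(df: pd.DataFrame, factor: str = "scanner") -> TestResult:
    """Friedman chi-square across conditions with midrank tie correction."""
    x = _wide(df, factor).to_numpy(dtype=float)
    _require_matrix(x, "Friedman test")
    n, k = x.shape
    if k < 3:
        raise ValueError("Friedman test requires >= 3 conditions")
    if np.allclose(x, x[:, [0]]):
        return TestResult(0.0, k - 1, None, 1.0, "friedman")
    stat, p = stats.friedmanchisquare(*(x[:, j] for j in range(k)))
    return TestResult(float(stat), k - 1, None, float(p), "friedman")


def posthoc_pairwise(
    df: pd.DataFrame,
    factor: str = "scanner",
    method: str = "paired_t",
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """All pairwise paired tests between conditions, Bonferroni-corrected.

    ``method`` is "paired_t" or "wilcoxon". Degenerate pairs (zero
    variance of differences) yield missing p-values with a warning.
    """
    w = _wide(df, factor)
    conditions = list(w.columns)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions for pairwise tests")
    pairs = list(itertools.combinations(conditions, 2))
    rows = []
    for a, b in pairs:
        xa, xb = w[a].to_numpy(dtype=float), w[b].to_numpy(dtype=float)
        diffs = xa - xb
        if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
            warnings.warn(f"degenerate pair ({a}, {b}): zero variance of differences")
            stat, p = np.nan, np.nan
        elif method == "paired_t":
            stat, p = stats.ttest_rel(xa, xb)
        elif method == "wilcoxon":
            stat, p = stats.wilcoxon(xa, xb)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((a, b, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["condition_a", "condition_b", "statistic", "p_raw"])
    if correction == "bonferroni":
        out["p_corrected"] = np.minimum(out["p_raw"] * len(pairs), 1.0)
    elif correction in (None, "none"):
        out["p_corrected"] = out["p_raw"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out
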