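"""Group-comparison battery for single- versus multiple-lesion patients.

Continuous variables are compared with two-sample t-tests (Welch by
default), binary variables with two-sided Fisher exact tests, and the raw
p-values of the whole battery are jointly adjusted with the
Benjamini–Hochberg step-up false-discovery-rate procedure. Significance is
declared at adjusted p < 0.05. Multi-level categorical variables (stroke
etiology) are dichotomized one-vs-rest, one test per level, mirroring the
per-row presentation of clinical baseline tables.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mal_profiler.errors import ConfigurationError, InsufficientDataError, ValidationError

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonSpec:
    """One variable of the battery.

    ``kind`` is ``"continuous"`` (t-test) or ``"binary"`` (Fisher exact).
    ``summary`` selects the printed descriptive: ``mean_sd`` or
    ``median_iqr`` for continuous, ``proportion`` for binary.
    ``level``: for a categorical source column, the level whose one-vs-rest
    indicator is tested (e.g. etiology == "cardioembolic").
    """

    variable: str
    kind: str = "continuous"
    summary: str = "mean_sd"
    level: str | None = None
    label: str | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValidationError(f"unknown spec kind: {self.kind}")
        if self.kind == "binary" and self.summary != "proportion":
            object.__setattr__(self, "summary", "proportion")

    @property
    def display(self) -> str:
        if self.label:
            return self.label
        return f"{self.variable}={self.level}" if self.level else self.variable


@dataclass
class ComparisonResult:
    """One variable's group contrast with raw and FDR-adjusted p-values."""

    variable: str
    test: str
    n_single: int
    n_multiple: int
    summary_single: str
    summary_multiple: str
    statistic: float
    p_raw: float
    p_fdr: float = float("nan")
    significant: bool = False
    warnings: list[str] = field(default_factory=list)


def two_sample_t(x: Sequence[float], y: Sequence[float], welch: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test; returns (statistic, p).

    Non-finite values are dropped within each sample. Welch (unequal
    variance) by default; ``welch=False`` uses the pooled-variance test.
    If both samples have zero variance the comparison is degenerate:
    identical constants give p = 1 with a warning rather than an error, so
    one pathological variable cannot abort a whole battery.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError(
            f"two_sample_t needs >= 2 finite values per group (got {len(x)}, {len(y)})"
        )
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        warnings.warn("zero variance in both groups; reporting p=1", stacklevel=2)
        return (0.0 if np.mean(x) == np.mean(y) else np.inf, 1.0)
    stat, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(stat), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The two-sided p is the sum of hypergeometric probabilities, over all
    tables with the observed margins, that are no more probable than the
    observed table.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"fisher_exact_2x2 expects a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValidationError("fisher_exact_2x2 requires non-negative integer counts")
    if t.sum() < 1:
        raise ValidationError("fisher_exact_2x2 requires a non-empty table")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    adjusted_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted
    p-values, mapped back to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=ALPHA, method="fdr_bh")
    return p_adj


def _summarize(values: np.ndarray, style: str) -> str:
    if style == "mean_sd":
        return f"{np.mean(values):.1f} ({np.std(values, ddof=1):.1f})"
    if style == "median_iqr":
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return f"{med:.1f} ({q3 - q1:.1f})"
    raise ValidationError(f"unknown summary style: {style}")


def compare_groups(
    cohort: pd.DataFrame,
    specs: Sequence[ComparisonSpec],
    group_col: str = "mal",
    welch: bool = True,
) -> pd.DataFrame:
    """Run the whole comparison battery and adjust p-values jointly.

    ``cohort`` must carry the boolean grouping column (typically ``mal``
    from :func:`mal_profiler.constellation.label_cohort`). Missingness is
    handled complete-case within each variable, and the analysed n per
    group is reported per variable.

    Returns a frame with one row per spec: variable, n per group, group
    summaries, test name, statistic, ``p_raw``, ``p_fdr`` and
    ``significant`` (p_fdr < 0.05).
    """
    if len(specs) == 0:
        raise ConfigurationError("battery needs at least one comparison spec")
    if group_col not in cohort.columns:
        raise ConfigurationError(f"grouping column {group_col!r} not in cohort")

    grp = cohort[group_col].astype(bool)
    results: list[ComparisonResult] = []
    for spec in specs:
        if spec.variable not in cohort.columns:
            raise ConfigurationError(f"unknown battery variable: {spec.variable!r}")
        col = cohort[spec.variable]
        if spec.level is not None:
            values = (col == spec.level).astype(float).where(col.notna())
        else:
            values = pd.to_numeric(col, errors="coerce")
        mask = values.notna()
        x = values[mask & ~grp].to_numpy(dtype=float)  # single-lesion group
        y = values[mask & grp].to_numpy(dtype=float)  # multiple-lesion group

        caught: list[str] = []
        if spec.kind == "continuous":
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                stat, p = two_sample_t(x, y, welch=welch)
                caught = [str(w.message) for w in wlist]
            test = "welch_t" if welch else "pooled_t"
            summaries = (_summarize(x, spec.summary), _summarize(y, spec.summary))
        else:
            table = np.array(
                [
                    [int(x.sum()), len(x) - int(x.sum())],
                    [int(y.sum()), len(y) - int(y.sum())],
                ]
            )
            p = fisher_exact_2x2(table)
            stat = float("nan")
            test = "fisher_exact"
            summaries = (
                f"{100.0 * x.mean():.1f}%" if len(x) else "NA",
                f"{100.0 * y.mean():.1f}%" if len(y) else "NA",
            )
        results.append(
            ComparisonResult(
                variable=spec.display,
                test=test,
                n_single=len(x),
                n_multiple=len(y),
                summary_single=summaries[0],
                summary_multiple=summaries[1],
                statistic=stat,
                p_raw=p,
                warnings=caught,
            )
        )

    p_adj = bh_fdr([r.p_raw for r in results])
    for r, q in zip(results, p_adj):
        r.p_fdr = float(q)
        r.significant = bool(q < ALPHA)

    frame = pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "n_single": [r.n_single for r in results],
            "n_multiple": [r.n_multiple for r in results],
            "summary_single": [r.summary_single for r in results],
            "summary_multiple": [r.summary_multiple for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
    frame.attrs["fdr_method"] = "benjamini-hochberg"
    frame.attrs["alpha"] = ALPHA
    return frame


#: Etiology levels of the causative classification of stroke system (CCS).
ETIOLOGY_LEVELS = (
    "cardioembolic",
    "large_artery",
    "small_vessel",
    "other",
    "undetermined",
)


def default_battery() -> list[ComparisonSpec]:
    """The standard baseline-table battery for a labelled cohort.

    Age, sex, five comorbidity/risk-factor flags, the five CCS etiology
    levels one-vs-rest, DWI and WMH volumes, NIHSS, and mRS.
    """
    specs = [
        ComparisonSpec("age", "continuous", "mean_sd"),
        ComparisonSpec("sex", "binary", label="sex_female"),
        ComparisonSpec("htn", "binary", label="hypertension"),
        ComparisonSpec("dm", "binary", label="diabetes"),
        ComparisonSpec("af", "binary", label="atrial_fibrillation"),
        ComparisonSpec("cad", "binary", label="coronary_artery_disease"),
        ComparisonSpec("smoker", "binary", label="smoking_never"),
    ]
    specs += [
        ComparisonSpec("etiology", "binary", level=level, label=f"etiology_{level}")
        for level in ETIOLOGY_LEVELS
    ]
    specs += [
        ComparisonSpec("dwi_vol_ml", "continuous", "median_iqr"),
        ComparisonSpec("wmh_vol_ml", "continuous", "median_iqr"),
        ComparisonSpec("nihss", "continuous", "mean_sd"),
        ComparisonSpec("mrs", "continuous", "median_iqr"),
    ]
    return specs
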