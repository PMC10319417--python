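"""Group-level statistics and report aggregation.

Subject-level quantities (per-dataset accuracy/F1, per-channel mean
ERD, E_min and arrival times) are aggregated with plain arithmetic
means; significance is assessed with two-sided paired and one-sample
t-tests, gated by a Shapiro-Wilk normality check.  Data failing the
gate are routed to a Wilcoxon signed-rank fallback and flagged, since
the parametric result would not be trustworthy there.  Rounding to the
report's one-decimal convention happens only at the reporting boundary;
full precision is kept internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from lmbci.errors import ConfigError


def load_reference_f1() -> pd.DataFrame:
    """Published per-subject F1 table (subjects x {Class1, Class2, Class3}, %)."""
    with resources.files("lmbci.data").joinpath("reference_f1.csv").open() as fh:
        return pd.read_csv(fh, comment="#", index_col="subject")


def load_subject_groups() -> dict:
    """Named subject subsets used in the report aggregation."""
    with resources.files("lmbci.data").joinpath("subject_groups.json").open() as fh:
        return json.load(fh)


def aggregate(
    values: pd.Series | dict[str, float],
    subset: list[str] | None = None,
    decimals: int | None = None,
) -> tuple[float, float]:
    """Mean and SD over subjects, optionally restricted to a named subset.

    ``decimals`` applies report-boundary rounding; pass None to get full
    precision.  Missing subjects in the subset raise a named error.
    """
    s = pd.Series(values, dtype=float)
    if subset is not None:
        missing = [x for x in subset if x not in s.index]
        if missing:
            raise ConfigError(f"subjects missing from table: {missing}")
        s = s.loc[subset]
    if len(s) == 0:
        raise ConfigError("empty subject subset")
    mean = float(s.mean())
    sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
    if decimals is not None:
        mean, sd = round(mean, decimals), round(sd, decimals)
    return mean, sd


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    test: str
    degenerate: bool = False
    normality_p: float | None = None
    normality_pass: bool | None = None

    @property
    def stars(self) -> str:
        if np.isnan(self.p):
            return ""
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < thr:
                return s
        return ""


def paired_ttest(a, b) -> TTestResult:
    """Two-sided paired t-test of two per-subject vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("paired t-test requires equal-length vectors")
    if len(a) < 3:
        raise ConfigError("paired t-test needs n >= 3")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        # identical vectors -> t = 0, p = 1; constant nonzero shift -> undefined t
        if np.allclose(diff, 0.0):
            return TTestResult(0.0, 1.0, len(a) - 1, "paired-t", degenerate=True)
        return TTestResult(float("nan"), float("nan"), len(a) - 1, "paired-t",
                           degenerate=True)
    res = sps.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue), len(a) - 1, "paired-t")


def one_sample_ttest(values, mu0: float = 50.0) -> TTestResult:
    """Two-sided one-sample t-test, default against the 50 % chance level."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ConfigError("one-sample t-test needs n >= 3")
    if np.allclose(values.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(values, mu0) else float("nan")
        p = 1.0 if t == 0.0 else float("nan")
        return TTestResult(t, p, len(values) - 1, "one-sample-t", degenerate=True)
    res = sps.ttest_1samp(values, mu0)
    return TTestResult(float(res.statistic), float(res.pvalue), len(values) - 1,
                       "one-sample-t")


def normality_gate(values, alpha: float = 0.05) -> tuple[bool, float]:
    """Shapiro-Wilk gate: True (pass) when p > alpha; degenerate data fail."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ConfigError("normality test needs n >= 3")
    if np.allclose(values.std(ddof=0), 0.0):
        return False, float("nan")
    w, p = sps.shapiro(values)
    return bool(p > alpha), float(p)


def paired_test_with_gate(a, b, alpha: float = 0.05) -> TTestResult:
    """Paired comparison routed through the normality gate.

    Differences passing Shapiro-Wilk get the paired t-test; otherwise a
    Wilcoxon signed-rank test is used and flagged via ``test``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a - b
    if np.allclose(diff.std(ddof=0), 0.0):
        return paired_ttest(a, b)
    passed, p_norm = normality_gate(diff, alpha)
    if passed:
        res = paired_ttest(a, b)
    else:
        w = sps.wilcoxon(a, b)
        res = TTestResult(float(w.statistic), float(w.pvalue), len(a) - 1,
                          "wilcoxon-fallback")
    res.normality_p = p_norm
    res.normality_pass = passed
    return res


def f1_report(table: pd.DataFrame | None = None, decimals: int = 1) -> pd.DataFrame:
    """Per-subject F1 table with an appended row-average ('Ave') row.

    With no argument, reproduces the packaged reference table's
    aggregation: row means over the 16 subjects at one-decimal rounding.
    """
    if table is None:
        table = load_reference_f1()
    out = table.copy()
    out.loc["Ave"] = [round(float(table[c].mean()), decimals) for c in table.columns]
    return out


def holm_correct(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjusted p-values (optional; off by default in reports)."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted, running = {}, 0.0
    for rank, (name, p) in enumerate(items):
        running = max(running, min((m - rank) * p, 1.0))
        adjusted[name] = running
    return adjusted
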