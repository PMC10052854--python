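"""Validation statistics for paired true vs IRT-derived vital rates.

Accuracy is summarized by the mean absolute error (MAE, per-minute units)
and the mean absolute percent error (MAPE, percent of the true value);
agreement by a paired two-tailed t-test on d = true - IRT and by ordinary
least squares of the IRT value on the true value (slope, intercept, R^2).
Success-rate contrasts between groups (sedation status, taxa, integument
thickness, video quality, subcutaneous fat) use the Pearson chi-squared
statistic on 2x2 tables *without* Yates continuity correction - the
convention that reproduces the published values from the group sizes and
percentages.

The "validation set" for group tables is every session with a reference
measurement; "success" means a clear IRT peak was extracted for that vital
sign, whether or not a reference value exists to compare against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io_video import SessionRecord, packaged_table1_path, packaged_table2_path, read_session_table
from .pipeline import HIGH_QUALITY_MIN

__all__ = [
    "PairedErrorSummary",
    "TestResult",
    "RegressionResult",
    "ValidationSummary",
    "paired_errors",
    "paired_t",
    "ols",
    "chisq_2x2",
    "success_table",
    "implied_counts",
    "table2_chisq_tests",
    "validate_all",
    "load_packaged_records",
]

GROUPINGS = ("sedation", "taxa", "integument", "quality", "fat")


@dataclass
class PairedErrorSummary:
    n: int
    mae: float
    mape: float
    err_min: float
    err_max: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int
    kind: str  # "paired_t" | "chisq_2x2"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)


def _pairs(
    records: Iterable[SessionRecord], which: str
) -> tuple[np.ndarray, np.ndarray, list[SessionRecord]]:
    which = which.upper()
    if which not in ("RR", "HR"):
        raise ValueError("which must be 'RR' or 'HR'")
    t_attr, i_attr = (("true_rr", "irt_rr") if which == "RR" else ("true_hr", "irt_hr"))
    kept = [
        r
        for r in records
        if getattr(r, t_attr) is not None and getattr(r, i_attr) is not None
    ]
    true = np.array([getattr(r, t_attr) for r in kept], dtype=float)
    irt = np.array([getattr(r, i_attr) for r in kept], dtype=float)
    return true, irt, kept


def paired_errors(records: Sequence[SessionRecord], which: str) -> PairedErrorSummary:
    """MAE and MAPE over sessions with both a true and an IRT value.

    MAPE uses the true value as denominator; pairs with true <= 0 are
    excluded from the MAPE mean (but kept in the MAE).
    """
    true, irt, _ = _pairs(records, which)
    if true.size < 2:
        raise ValueError(f"need >= 2 complete {which} pairs")
    err = np.abs(irt - true)
    pos = true > 0
    mape = float((err[pos] / true[pos]).mean() * 100) if pos.any() else float("nan")
    return PairedErrorSummary(
        n=int(true.size),
        mae=float(err.mean()),
        mape=mape,
        err_min=float(err.min()),
        err_max=float(err.max()),
    )


def paired_t(records: Sequence[SessionRecord], which: str) -> TestResult:
    """Paired two-tailed t-test on d = true - IRT (closed form).

    t = mean(d) / (sd(d)/sqrt(n)) with the sample standard deviation
    (n-1 denominator); p from Student's t with n-1 degrees of freedom.
    """
    true, irt, _ = _pairs(records, which)
    n = true.size
    if n < 2:
        raise ValueError(f"need >= 2 complete {which} pairs")
    d = true - irt
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), df=n - 1))
    return TestResult(statistic=t, p_value=p, df=n - 1, kind="paired_t")


def ols(
    records: Sequence[SessionRecord],
    which: str,
    subset: Optional[str] = None,
) -> RegressionResult:
    """Least-squares fit of the IRT value on the true value, with intercept.

    ``subset`` restricts to one taxon (e.g. ``"mammal"``).  Residuals are
    retained for descriptive by-group summaries.
    """
    recs = list(records)
    if subset is not None:
        recs = [r for r in recs if r.taxa == subset]
    true, irt, _ = _pairs(recs, which)
    if true.size < 3:
        raise ValueError(f"need >= 3 complete {which} pairs")
    if np.ptp(true) == 0:
        raise ValueError("constant true values: singular fit")
    model = sm.OLS(irt, sm.add_constant(true)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(true.size),
        residuals=np.asarray(model.resid),
    )


def chisq_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-squared for a 2x2 table, no continuity correction.

    Rows are groups, columns success/failure: X^2 = n(ad-bc)^2 /
    (r1*r2*c1*c2); p from the chi-squared distribution with 1 df.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate table: zero margin")
    n = a + b + c + d
    x2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return TestResult(
        statistic=float(x2), p_value=float(sps.chi2.sf(x2, df=1)), df=1, kind="chisq_2x2"
    )


def _group_key(record: SessionRecord, grouping: str) -> str:
    if grouping == "sedation":
        return "immobilized" if record.immobilized else "voluntary"
    if grouping == "taxa":
        return record.taxa
    if grouping == "integument":
        return "thick" if record.integument_thick else "thin"
    if grouping == "quality":
        if record.quality_score is None:
            raise ValueError(f"quality grouping undefined for {record.species}")
        return "high" if record.quality_score >= HIGH_QUALITY_MIN else "low"
    if grouping == "fat":
        return "significant" if record.subcutaneous_fat else "none"
    raise ValueError(f"unknown grouping {grouping!r}")


def success_table(
    records: Sequence[SessionRecord], grouping: str
) -> pd.DataFrame:
    """Per-group counts and success percentages over the validation set.

    Returns a DataFrame with group, n, rr/hr success counts and
    percentages (1 decimal; NaN for empty groups).
    """
    in_scope = [r for r in records if r.in_validation_set]
    rows = []
    order: list[str] = []
    for r in in_scope:
        key = _group_key(r, grouping)
        if key not in order:
            order.append(key)
    for key in order:
        members = [r for r in in_scope if _group_key(r, grouping) == key]
        n = len(members)
        rr_n = sum(r.rr_success for r in members)
        hr_n = sum(r.hr_success for r in members)
        rows.append(
            {
                "group": key,
                "n": n,
                "rr_successes": rr_n,
                "rr_pct": round(100 * rr_n / n, 1) if n else float("nan"),
                "hr_successes": hr_n,
                "hr_pct": round(100 * hr_n / n, 1) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def implied_counts(n: int, pct: float) -> tuple[int, int]:
    """(successes, failures) implied by a group size and printed percentage."""
    k = int(round(n * pct / 100.0))
    return k, n - k


def table2_chisq_tests(path=None) -> dict[str, TestResult]:
    """Chi-squared tests from the published group sizes and percentages.

    For each two-level grouping the 2x2 table is reconstructed from the
    printed n and success percentage (e.g. thick-integument RR: 66.7% of
    21 vs 95.7% of 23) and tested without continuity correction.
    """
    df = pd.read_csv(path or packaged_table2_path())
    out: dict[str, TestResult] = {}
    for grouping, sub in df.groupby("grouping", sort=False):
        if len(sub) != 2:
            continue  # taxa is 3-level; its published test is not a 2x2
        for which, col in (("rr", "rr_success_pct"), ("hr", "hr_success_pct")):
            (n1, p1), (n2, p2) = zip(sub["n"], sub[col])
            a, b = implied_counts(int(n1), float(p1))
            c, d = implied_counts(int(n2), float(p2))
            out[f"{which}_by_{grouping}"] = chisq_2x2(a, b, c, d)
    return out


def _outlier_flagged(r: SessionRecord) -> bool:
    return "outlier" in (r.transcription_notes or "").lower()


@dataclass
class ValidationSummary:
    """Every accuracy/agreement/success statistic, traceable to its subset."""

    rr_errors: PairedErrorSummary
    hr_errors: PairedErrorSummary
    hr_errors_no_outlier: PairedErrorSummary
    rr_t: TestResult
    hr_t: TestResult
    rr_reg_all: RegressionResult
    rr_reg_mammal: RegressionResult
    hr_reg_all: RegressionResult
    hr_reg_mammal: RegressionResult
    success_tables: dict[str, pd.DataFrame]
    chisq_tests: dict[str, TestResult]
    n_validation_sessions: int

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, (PairedErrorSummary, TestResult)):
                return asdict(x)
            if isinstance(x, RegressionResult):
                d = asdict(x)
                d["residuals"] = None if x.residuals is None else list(np.round(x.residuals, 6))
                return d
            if isinstance(x, pd.DataFrame):
                return x.to_dict(orient="records")
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x

        return {k: conv(v) for k, v in self.__dict__.items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def load_packaged_records() -> list[SessionRecord]:
    """The packaged 58-session validation table."""
    return read_session_table(packaged_table1_path())


def validate_all(records: Optional[Sequence[SessionRecord]] = None) -> ValidationSummary:
    """Compute the full deterministic validation summary.

    HR error summaries are reported both over all pairs and with
    transcription-flagged outliers removed, because the published error
    range singles out one extreme bird value whose inclusion is ambiguous.
    """
    records = list(records) if records is not None else load_packaged_records()
    no_outlier = [r for r in records if not _outlier_flagged(r)]
    chisq = dict(table2_chisq_tests())
    return ValidationSummary(
        rr_errors=paired_errors(records, "RR"),
        hr_errors=paired_errors(records, "HR"),
        hr_errors_no_outlier=paired_errors(no_outlier, "HR"),
        rr_t=paired_t(records, "RR"),
        hr_t=paired_t(records, "HR"),
        rr_reg_all=ols(records, "RR"),
        rr_reg_mammal=ols(records, "RR", subset="mammal"),
        hr_reg_all=ols(records, "HR"),
        hr_reg_mammal=ols(records, "HR", subset="mammal"),
        success_tables={g: success_table(records, g) for g in GROUPINGS},
        chisq_tests=chisq,
        n_validation_sessions=sum(r.in_validation_set for r in records),
    )
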