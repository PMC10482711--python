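"""Disproportionality statistics for the case/non-case design.

For an exposure (one drug, one class, or all antidepressants pooled) and a
comparator arm, the 2x2 table is

=============  ========  ===========
               exposed   comparator
=============  ========  ===========
cases            a           c
non-cases        b           d
=============  ========  ===========

Two measures are computed per contrast:

* **Reporting odds ratio** ``ROR = (a*d)/(b*c)`` with a 95% Woolf
  (log-normal) confidence interval
  ``exp(ln ROR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d))``.  With the Haldane
  correction, 0.5 is added to every cell when any cell is zero.
* **Information component** ``IC = log2((a + 0.5)/(E + 0.5))`` where
  ``E = (a+b)(a+c)/N`` is the expected exposed-case count inside the
  comparator frame; 95% credibility bounds are the log2-transformed
  0.025/0.975 quantiles of a Gamma(a + 0.5, rate E + 0.5) posterior for the
  observed-to-expected ratio.  The +0.5 shrinkage pulls estimates for rare
  pairs toward the null.

A contrast is flagged as a potential signal only when *both* measures are
significant: lower ROR bound > 1 and lower IC bound > 0.

Three comparator schemes mirror the study design: ``main`` (comparator =
reports with no antidepressant exposure), ``positive_control`` (comparator =
reports on the positive-control drug) and ``intraclass`` (comparator = other
antidepressants of the same class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy import stats

from .casedef import CLASS_LABELS, AnalysisSet, DrugClassMap

__all__ = [
    "ContingencyTable",
    "RorEstimate",
    "IcEstimate",
    "DisproportionalityResult",
    "contingency_table",
    "ror",
    "information_component",
    "expected_count",
    "run_analysis_suite",
    "results_to_frame",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile

POOLED_LABEL = "antidepressants"
SCHEMES = ("main", "positive_control", "intraclass")


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Report-level 2x2 counts for one exposure/comparator contrast."""

    a: int  # cases, exposed
    b: int  # non-cases, exposed
    c: int  # cases, comparator
    d: int  # non-cases, comparator
    exposure_label: str = ""
    comparator_label: str = ""

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("contingency cells must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True, slots=True)
class RorEstimate:
    """ROR point estimate with 95% Woolf CI; ``estimate`` is None when the
    table has a zero cell and no correction was applied (``reason`` says
    why)."""

    estimate: Optional[float]
    lo: Optional[float]
    hi: Optional[float]
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.estimate is not None


@dataclass(frozen=True, slots=True)
class IcEstimate:
    ic: float
    lo: float
    hi: float


def ror(table: ContingencyTable, correction: str = "none") -> RorEstimate:
    """Reporting odds ratio with 95% Woolf confidence interval.

    ``correction='haldane'`` adds 0.5 to every cell when any cell is zero;
    with ``'none'`` a zero cell yields an undefined estimate (never an
    exception).
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    a, b, c, d = (float(x) for x in table.cells())
    if a == b == c == d == 0:
        return RorEstimate(None, None, None, reason="empty table")
    if min(a, b, c, d) == 0:
        if correction == "none":
            zero = ("a", "b", "c", "d")[[a, b, c, d].index(0.0)]
            return RorEstimate(None, None, None, reason=f"zero cell {zero}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(est)
    return RorEstimate(
        estimate=est,
        lo=math.exp(log_est - Z95 * se),
        hi=math.exp(log_est + Z95 * se),
    )


def expected_count(table: ContingencyTable) -> float:
    """Expected exposed-case count E = (a+b)(a+c)/N inside the table's
    comparator frame."""
    n = table.n
    if n == 0:
        return 0.0
    return (table.a + table.b) * (table.a + table.c) / n


def information_component(a: int, expected: float, method: str = "gamma") -> IcEstimate:
    """Shrunk information component with 95% credibility bounds.

    ``IC = log2((a + 0.5)/(E + 0.5))``.  With ``method='gamma'`` (default)
    the bounds are log2 quantiles of Gamma(shape a + 0.5, rate E + 0.5);
    ``method='wald'`` uses the normal approximation
    ``IC +/- 1.96 / (ln 2 * sqrt(a + 0.5))``.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if a < 0 or int(a) != a:
        raise ValueError("observed count must be a non-negative integer")
    shape = a + 0.5
    rate = expected + 0.5
    ic = math.log2(shape / rate)
    if method == "gamma":
        lo = math.log2(stats.gamma.ppf(0.025, shape, scale=1.0 / rate))
        hi = math.log2(stats.gamma.ppf(0.975, shape, scale=1.0 / rate))
    elif method == "wald":
        half = Z95 / (math.log(2) * math.sqrt(shape))
        lo, hi = ic - half, ic + half
    else:
        raise ValueError(f"unknown ic method {method!r}")
    return IcEstimate(ic=ic, lo=lo, hi=hi)


@dataclass(frozen=True, slots=True)
class DisproportionalityResult:
    """ROR and IC for one contrast, with the dual-significance signal flag."""

    table: ContingencyTable
    ror: RorEstimate
    ic: IcEstimate
    analysis_tag: str  # main | class | drug | positive_control | intraclass

    @property
    def n_cases(self) -> int:
        return self.table.a

    @property
    def signal(self) -> bool:
        """Signal iff both the ROR and the IC are significant (lower ROR
        bound > 1 and lower IC bound > 0)."""
        return (
            self.ror.defined
            and self.ror.lo is not None
            and self.ror.lo > 1.0
            and self.ic.lo > 0.0
        )


def _exposure_mask(aset: AnalysisSet, exposure: str) -> pd.Series:
    t = aset.table
    if exposure == POOLED_LABEL:
        return t["any_antidepressant"]
    if exposure in CLASS_LABELS:
        return t[f"class_{exposure}"]
    col = f"exp_{exposure}"
    if col not in t.columns:
        raise KeyError(f"unknown exposure {exposure!r}")
    return t[col]


def contingency_table(
    aset: AnalysisSet,
    exposure: str,
    scheme: str = "main",
) -> ContingencyTable:
    """Build the report-level 2x2 for ``exposure`` under a comparator scheme.

    ``exposure`` is a drug name, a class label, or ``"antidepressants"``
    (pooled).  Schemes: ``main`` compares against reports with no
    antidepressant exposure; ``positive_control`` against reports exposed to
    the positive-control drug; ``intraclass`` against reports exposed to
    another antidepressant of the same class.  A report qualifying for both
    arms counts in the exposed arm only; each report counts once.
    """
    t = aset.table
    exposed = _exposure_mask(aset, exposure)
    if scheme == "main":
        comparator = ~t["any_antidepressant"]
        comp_label = "all other drugs (no antidepressant)"
    elif scheme == "positive_control":
        comparator = t["positive_control"] & ~exposed
        comp_label = aset.class_map.positive_control
    elif scheme == "intraclass":
        if exposure in CLASS_LABELS or exposure == POOLED_LABEL:
            raise ValueError("intraclass scheme applies to individual drugs")
        label = None
        for cls in CLASS_LABELS:
            if exposure in aset.class_map.drugs_in_class(cls):
                label = cls
                break
        if label is None:
            raise KeyError(f"{exposure!r} is not a mapped antidepressant")
        if len(aset.class_map.drugs_in_class(label)) < 2:
            raise ValueError(f"class {label!r} has a single member; no intraclass comparator")
        comparator = t[f"class_{label}"] & ~exposed
        comp_label = f"other {label}"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    comparator = comparator & ~exposed  # exposed arm wins ties
    case = t["is_case"]
    return ContingencyTable(
        a=int((case & exposed).sum()),
        b=int((~case & exposed).sum()),
        c=int((case & comparator).sum()),
        d=int((~case & comparator).sum()),
        exposure_label=exposure,
        comparator_label=comp_label,
    )


def _result(
    aset: AnalysisSet,
    exposure: str,
    scheme: str,
    tag: str,
    correction: str,
    ic_method: str,
) -> DisproportionalityResult:
    table = contingency_table(aset, exposure, scheme)
    e = expected_count(table)
    if e > 0:
        ic = information_component(table.a, e, method=ic_method)
    else:  # empty frame: shrinkage alone, no information
        ic = IcEstimate(ic=0.0, lo=0.0, hi=0.0)
    return DisproportionalityResult(
        table=table, ror=ror(table, correction=correction), ic=ic, analysis_tag=tag
    )


def run_analysis_suite(
    aset: AnalysisSet,
    class_map: Optional[DrugClassMap] = None,
    min_cases: int = 4,
    correction: str = "haldane",
    ic_method: str = "gamma",
) -> list:
    """Run the full battery of contrasts.

    Under the main scheme: all antidepressants pooled, each class, and each
    drug with at least ``min_cases`` exposed cases (default 4, i.e. more
    than three reports).  The same exposures are then contrasted against the
    positive control, and each qualifying drug against its own class
    (intraclass).  Returns a list of :class:`DisproportionalityResult`.
    """
    class_map = class_map or aset.class_map
    results: list = []

    results.append(_result(aset, POOLED_LABEL, "main", "main", correction, ic_method))
    for cls in CLASS_LABELS:
        results.append(_result(aset, cls, "main", "class", correction, ic_method))

    qualifying: list = []
    for drug in class_map.all_drugs():
        table = contingency_table(aset, drug, "main")
        if table.a >= min_cases:
            qualifying.append(drug)
            e = expected_count(table)
            ic = (
                information_component(table.a, e, method=ic_method)
                if e > 0
                else IcEstimate(0.0, 0.0, 0.0)
            )
            results.append(
                DisproportionalityResult(
                    table=table, ror=ror(table, correction=correction), ic=ic, analysis_tag="drug"
                )
            )

    for exposure in [POOLED_LABEL, *CLASS_LABELS, *qualifying]:
        results.append(
            _result(aset, exposure, "positive_control", "positive_control", correction, ic_method)
        )
    for drug in qualifying:
        results.append(_result(aset, drug, "intraclass", "intraclass", correction, ic_method))
    return results


def results_to_frame(results: Iterable[DisproportionalityResult]) -> pd.DataFrame:
    """Flatten results into a signals table (one row per contrast)."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.table.exposure_label,
                "comparator": r.table.comparator_label,
                "analysis": r.analysis_tag,
                "n_cases": r.table.a,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": r.ror.estimate,
                "ror_lo": r.ror.lo,
                "ror_hi": r.ror.hi,
                "ror_undefined_reason": r.ror.reason,
                "ic": r.ic.ic,
                "ic_lo": r.ic.lo,
                "ic_hi": r.ic.hi,
                "signal": r.signal,
            }
        )
    return pd.DataFrame(rows)
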