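"""Semiquantitative clinical-priority scoring of disproportionality signals.

Each drug with a qualifying number of withdrawal reports is rated on four
criteria:

1. share of withdrawal reports among all its ADR reports
   (>10%: 2, 5-10%: 1, <5%: 0);
2. share of withdrawal reports free of confounding psychotropic
   co-medication (>=71%: 2, >50%: 1, <=50%: 0 — the published thresholds
   contain a typographical inversion; see docs/methods.md);
3. consistency of dual ROR/IC significance across the three comparator
   schemes (all three: 2, two: 1, at most one: 0);
4. magnitude of the lower 95% ROR bound in the main analysis (>10: 1,
   otherwise 0).

Totals 0-7 map to traffic-light bands: 0-1 weak (green), 2-5 moderate
(yellow), 6-7 strong (red).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .casedef import AnalysisSet
from .disprop import DisproportionalityResult

__all__ = [
    "PriorityInputs",
    "PriorityScore",
    "score_criterion1",
    "score_criterion2",
    "score_criterion3",
    "score_criterion4",
    "classify_priority",
    "priority_inputs_from_results",
    "score_priorities",
    "BANDS",
]

BANDS = {"weak": "green", "moderate": "yellow", "strong": "red"}


@dataclass(frozen=True, slots=True)
class PriorityInputs:
    """Raw ingredients of the four criteria for one drug."""

    drug: str
    n_withdrawal_reports: int
    n_total_adr_reports_for_drug: int
    n_withdrawal_reports_confounder_free: int
    significant_main: bool
    significant_intraclass: bool
    significant_positive_control: bool
    ror_lower_ci_main: float

    def __post_init__(self) -> None:
        if not (
            0
            <= self.n_withdrawal_reports_confounder_free
            <= self.n_withdrawal_reports
            <= self.n_total_adr_reports_for_drug
        ):
            raise ValueError(
                "expected 0 <= confounder-free <= withdrawal <= total ADR report counts"
            )


@dataclass(frozen=True, slots=True)
class PriorityScore:
    points: tuple  # (p1, p2, p3, p4)
    total: int
    band: str
    light: str

    def __post_init__(self) -> None:
        assert self.total == sum(self.points)


def score_criterion1(n_withdrawal: int, n_total_adr: int) -> int:
    """Withdrawal share of the drug's ADR reports: >10% -> 2, 5-10% -> 1,
    <5% -> 0."""
    if n_total_adr <= 0:
        raise ValueError("total ADR report count must be positive")
    pct = 100.0 * n_withdrawal / n_total_adr
    if pct > 10.0:
        return 2
    if pct >= 5.0:
        return 1
    return 0


def score_criterion2(n_confounder_free: int, n_withdrawal: int) -> int:
    """Confounder-free share of withdrawal reports: >=71% -> 2, >50% -> 1,
    <=50% -> 0."""
    if n_withdrawal <= 0:
        raise ValueError("withdrawal report count must be positive")
    pct = 100.0 * n_confounder_free / n_withdrawal
    if pct >= 71.0:
        return 2
    if pct > 50.0:
        return 1
    return 0


def score_criterion3(sig_main: bool, sig_intraclass: bool, sig_positive_control: bool) -> int:
    """Dual ROR/IC significance in all three analyses -> 2, two -> 1,
    at most one -> 0."""
    n = int(sig_main) + int(sig_intraclass) + int(sig_positive_control)
    if n == 3:
        return 2
    if n == 2:
        return 1
    return 0


def score_criterion4(ror_lower_ci: float) -> int:
    """Lower 95% ROR bound above 10 -> 1, otherwise 0."""
    if ror_lower_ci < 0:
        raise ValueError("lower CI bound must be non-negative")
    return 1 if ror_lower_ci > 10.0 else 0


def _band(total: int) -> str:
    if total <= 1:
        return "weak"
    if total <= 5:
        return "moderate"
    return "strong"


def classify_priority(inputs: PriorityInputs) -> PriorityScore:
    """Compose the four criteria into a total and traffic-light band."""
    points = (
        score_criterion1(inputs.n_withdrawal_reports, inputs.n_total_adr_reports_for_drug),
        score_criterion2(
            inputs.n_withdrawal_reports_confounder_free, inputs.n_withdrawal_reports
        ),
        score_criterion3(
            inputs.significant_main,
            inputs.significant_intraclass,
            inputs.significant_positive_control,
        ),
        score_criterion4(inputs.ror_lower_ci_main),
    )
    total = sum(points)
    band = _band(total)
    return PriorityScore(points=points, total=total, band=band, light=BANDS[band])


def priority_inputs_from_results(
    aset: AnalysisSet,
    results: Iterable[DisproportionalityResult],
) -> list:
    """Assemble :class:`PriorityInputs` for every drug with a drug-level main
    result, reading counts from the analysis set and significance flags from
    the three comparator schemes."""
    by_drug: dict = {}
    for r in results:
        drug = r.table.exposure_label
        if r.analysis_tag == "drug":
            by_drug.setdefault(drug, {})["main"] = r
        elif r.analysis_tag == "intraclass":
            by_drug.setdefault(drug, {})["intraclass"] = r
        elif r.analysis_tag == "positive_control":
            by_drug.setdefault(drug, {})["positive_control"] = r

    t = aset.table
    inputs = []
    for drug, res in sorted(by_drug.items()):
        main = res.get("main")
        if main is None:  # classes/pooled appear under positive_control too
            continue
        exposed = t[f"exp_{drug}"]
        n_total = int(exposed.sum())
        n_withdrawal = int((exposed & t["is_case"]).sum())
        n_conf_free = int((exposed & t["is_case"] & t["confounder_free"]).sum())
        sig_ic = res.get("intraclass")
        sig_pc = res.get("positive_control")
        inputs.append(
            PriorityInputs(
                drug=drug,
                n_withdrawal_reports=n_withdrawal,
                n_total_adr_reports_for_drug=n_total,
                n_withdrawal_reports_confounder_free=n_conf_free,
                significant_main=main.signal,
                significant_intraclass=bool(sig_ic and sig_ic.signal),
                significant_positive_control=bool(sig_pc and sig_pc.signal),
                ror_lower_ci_main=main.ror.lo if main.ror.lo is not None else 0.0,
            )
        )
    return inputs


def score_priorities(
    aset: AnalysisSet,
    results: Iterable[DisproportionalityResult],
) -> pd.DataFrame:
    """Score every qualifying drug; one row per drug with points, total,
    band and light."""
    rows = []
    for inp in priority_inputs_from_results(aset, results):
        score = classify_priority(inp)
        rows.append(
            {
                "drug": inp.drug,
                "n_withdrawal_reports": inp.n_withdrawal_reports,
                "n_total_adr_reports": inp.n_total_adr_reports_for_drug,
                "n_confounder_free": inp.n_withdrawal_reports_confounder_free,
                "criterion1": score.points[0],
                "criterion2": score.points[1],
                "criterion3": score.points[2],
                "criterion4": score.points[3],
                "total": score.total,
                "band": score.band,
                "light": score.light,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "n_withdrawal_reports",
            "n_total_adr_reports",
            "n_confounder_free",
            "criterion1",
            "criterion2",
            "criterion3",
            "criterion4",
            "total",
            "band",
            "light",
        ],
    )
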