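"""Descriptive cohort summaries and serious vs non-serious comparisons.

``summarize_cohort`` produces the demographic/clinical characterization of
the withdrawal cases (counts at report and at patient level, symptom
category frequencies, medians with quartiles for durations and dose,
co-medication shares, seriousness).  Percent denominators are explicit:
sex/symptom/seriousness shares use the full patient (or report) count as
published summaries of this design do, while medians and the group
comparisons silently skip missing values.

``compare_serious`` contrasts serious against non-serious cases with
non-parametric tests: two-sided Wilcoxon rank-sum (Mann-Whitney U) for
continuous variables and Fisher's exact test with a Woolf odds-ratio CI for
binary ones.  Reports with unknown seriousness, or missing the variable
under test, are excluded per variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .casedef import AnalysisSet

__all__ = [
    "CohortSummary",
    "GroupComparison",
    "CONTINUOUS_VARIABLES",
    "BINARY_VARIABLES",
    "summarize_cohort",
    "compare_serious",
    "monotherapy_comparison",
]

Z95 = 1.959963984540054

CONTINUOUS_VARIABLES = (
    "age_days",
    "symptom_duration_days",
    "daily_dose_ddd",
    "treatment_duration_weeks",
)
# binary variables resolve to boolean columns; sex compares female vs male
BINARY_VARIABLES = (
    "sex",
    "comed_benzodiazepine",
    "comed_antipsychotic",
    "comed_opioid",
    "comed_mood_stabilizer",
)


@dataclass(frozen=True)
class Quartiles:
    median: float
    q1: float
    q3: float
    n: int  # non-missing observations


@dataclass(frozen=True)
class CohortSummary:
    """Characterization of a cohort of reports/patients."""

    n_reports: int
    n_patients: int
    n_female: int
    pct_female: Optional[float]
    n_sex_known: int
    n_serious: int
    pct_serious: Optional[float]
    n_serious_known: int
    symptom_counts: dict  # category -> count of reports
    symptom_pcts: dict  # category -> percent of reports
    comed_counts: dict  # class -> count of patients
    comed_pcts: dict
    pct_any_psychotropic: Optional[float]
    symptom_duration_days: Optional[Quartiles]
    treatment_duration_weeks: Optional[Quartiles]
    daily_dose_ddd: Optional[Quartiles]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_reports", self.n_reports, None),
            ("n_patients", self.n_patients, None),
            ("female", self.n_female, self.pct_female),
            ("serious", self.n_serious, self.pct_serious),
            ("any_psychotropic_comedication", None, self.pct_any_psychotropic),
        ]
        for cat, n in self.symptom_counts.items():
            rows.append((f"symptom:{cat}", n, self.symptom_pcts[cat]))
        for cls, n in self.comed_counts.items():
            rows.append((f"comedication:{cls}", n, self.comed_pcts[cls]))
        for name, q in [
            ("symptom_duration_days", self.symptom_duration_days),
            ("treatment_duration_weeks", self.treatment_duration_weeks),
            ("daily_dose_ddd", self.daily_dose_ddd),
        ]:
            if q is not None:
                rows.append((f"median:{name}", q.median, None))
                rows.append((f"q1:{name}", q.q1, None))
                rows.append((f"q3:{name}", q.q3, None))
        return pd.DataFrame(rows, columns=["variable", "value", "percent"])


def _quartiles(series: pd.Series) -> Optional[Quartiles]:
    vals = pd.to_numeric(series, errors="coerce").dropna()
    if vals.empty:
        return None
    return Quartiles(
        median=float(vals.median()),
        q1=float(vals.quantile(0.25)),
        q3=float(vals.quantile(0.75)),
        n=int(len(vals)),
    )


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den else None


def summarize_cohort(aset: AnalysisSet, case_only: bool = True) -> CohortSummary:
    """Summarize the analysis set (by default, the withdrawal cases only).

    Counts are taken at report level; patient-level counts collapse on
    ``patient_id`` (which equals the report id when no patient linkage is
    present, making the distinction vanish).  Sex, seriousness and
    co-medication shares are patient-level; symptom shares are report-level
    as symptom coding is per report.
    """
    t = aset.table
    if case_only:
        t = t[t["is_case"]]
    n_reports = len(t)

    patients = t.drop_duplicates(subset="patient_id")
    n_patients = len(patients)

    n_female = int((patients["sex"] == "female").sum())
    n_sex_known = int((patients["sex"] != "unknown").sum())
    serious_known = patients["serious"].map(lambda v: v is True or v is False)
    n_serious = int(patients["serious"].map(lambda v: v is True).sum())
    n_serious_known = int(serious_known.sum())

    symptom_counts: dict = {}
    if n_reports:
        for cats in t["symptom_categories"]:
            for cat in cats:
                symptom_counts[cat] = symptom_counts.get(cat, 0) + 1
    symptom_counts = dict(sorted(symptom_counts.items(), key=lambda kv: -kv[1]))
    symptom_pcts = {c: _pct(n, n_reports) for c, n in symptom_counts.items()}

    comed_cols = [c for c in t.columns if c.startswith("comed_")]
    comed_counts = {c[len("comed_"):]: int(patients[c].sum()) for c in comed_cols}
    comed_pcts = {c: _pct(n, n_patients) for c, n in comed_counts.items()}
    any_psy = (
        _pct(int(patients[comed_cols].any(axis=1).sum()), n_patients) if comed_cols else None
    )

    return CohortSummary(
        n_reports=n_reports,
        n_patients=n_patients,
        n_female=n_female,
        pct_female=_pct(n_female, n_patients),
        n_sex_known=n_sex_known,
        n_serious=n_serious,
        pct_serious=_pct(n_serious, n_patients),
        n_serious_known=n_serious_known,
        symptom_counts=symptom_counts,
        symptom_pcts=symptom_pcts,
        comed_counts=comed_counts,
        comed_pcts=comed_pcts,
        pct_any_psychotropic=any_psy,
        symptom_duration_days=_quartiles(t["symptom_duration_days"]) if n_reports else None,
        treatment_duration_weeks=_quartiles(t["treatment_duration_weeks"]) if n_reports else None,
        daily_dose_ddd=_quartiles(t["daily_dose_ddd"]) if n_reports else None,
    )


@dataclass(frozen=True)
class GroupComparison:
    """One serious-vs-non-serious contrast."""

    variable: str
    test: str
    n_serious: int
    n_non_serious: int
    statistic: Optional[float]
    p_value: Optional[float]
    odds_ratio: Optional[float] = None
    or_lo: Optional[float] = None
    or_hi: Optional[float] = None
    serious_summary: dict = field(default_factory=dict)
    non_serious_summary: dict = field(default_factory=dict)
    computable: bool = True
    note: str = ""


def _continuous_comparison(name: str, x: pd.Series, y: pd.Series) -> GroupComparison:
    xv = pd.to_numeric(x, errors="coerce").dropna().to_numpy()
    yv = pd.to_numeric(y, errors="coerce").dropna().to_numpy()
    if len(xv) == 0 or len(yv) == 0:
        return GroupComparison(
            variable=name,
            test="wilcoxon_rank_sum",
            n_serious=len(xv),
            n_non_serious=len(yv),
            statistic=None,
            p_value=None,
            computable=False,
            note="empty group after missing-data exclusion",
        )
    res = stats.mannwhitneyu(xv, yv, alternative="two-sided")
    summ = lambda v: {
        "median": float(np.median(v)),
        "q1": float(np.quantile(v, 0.25)),
        "q3": float(np.quantile(v, 0.75)),
    }
    return GroupComparison(
        variable=name,
        test="wilcoxon_rank_sum",
        n_serious=len(xv),
        n_non_serious=len(yv),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        serious_summary=summ(xv),
        non_serious_summary=summ(yv),
    )


def _binary_comparison(name: str, x: pd.Series, y: pd.Series) -> GroupComparison:
    """Fisher exact on the 2x2 (group x variable) with Woolf OR CI."""
    a, b = int(x.sum()), int((~x).sum())  # serious: positive / negative
    c, d = int(y.sum()), int((~y).sum())
    if (a + b) == 0 or (c + d) == 0:
        return GroupComparison(
            variable=name,
            test="fisher_exact",
            n_serious=a + b,
            n_non_serious=c + d,
            statistic=None,
            p_value=None,
            computable=False,
            note="empty group after missing-data exclusion",
        )
    oddsratio, p = stats.fisher_exact([[a, b], [c, d]])
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_w = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = math.exp(math.log(or_w) - Z95 * se)
    hi = math.exp(math.log(or_w) + Z95 * se)
    return GroupComparison(
        variable=name,
        test="fisher_exact",
        n_serious=a + b,
        n_non_serious=c + d,
        statistic=float(oddsratio),
        p_value=float(p),
        odds_ratio=or_w,
        or_lo=lo,
        or_hi=hi,
        serious_summary={"n_positive": a, "n": a + b},
        non_serious_summary={"n_positive": c, "n": c + d},
    )


def compare_serious(
    aset: AnalysisSet,
    variables: Optional[Iterable[str]] = None,
    case_only: bool = True,
) -> list:
    """Serious vs non-serious comparisons on the (case) reports.

    Reports with unknown seriousness are excluded; within each variable,
    reports missing that variable are excluded.  ``sex`` compares female
    against male (unknown sex excluded); ``comed_*`` columns are compared
    as binary exposure indicators.
    """
    t = aset.table
    if case_only:
        t = t[t["is_case"]]
    known = t[t["serious"].map(lambda v: v is True or v is False)]
    serious = known[known["serious"].map(lambda v: v is True)]
    non_serious = known[known["serious"].map(lambda v: v is False)]

    if variables is None:
        variables = list(CONTINUOUS_VARIABLES) + [
            v for v in BINARY_VARIABLES if v == "sex" or v in t.columns
        ]

    out = []
    for var in variables:
        if var == "sex":
            s = serious[serious["sex"] != "unknown"]["sex"] == "female"
            n = non_serious[non_serious["sex"] != "unknown"]["sex"] == "female"
            out.append(_binary_comparison("sex_female", s, n))
        elif var in CONTINUOUS_VARIABLES:
            out.append(_continuous_comparison(var, serious[var], non_serious[var]))
        elif var in t.columns:
            out.append(_binary_comparison(var, serious[var].astype(bool), non_serious[var].astype(bool)))
        else:
            raise KeyError(f"unknown comparison variable {var!r}")
    return out


def monotherapy_comparison(
    aset: AnalysisSet,
    variables: Optional[Iterable[str]] = None,
) -> list:
    """Serious vs non-serious comparisons restricted to the antidepressant
    monotherapy subgroup (no psychotropic co-medication)."""
    sub = AnalysisSet(
        table=aset.table[aset.table["monotherapy"]],
        class_map=aset.class_map,
    )
    if variables is None:
        variables = list(CONTINUOUS_VARIABLES) + ["sex"]
    return compare_serious(sub, variables=variables)


def comparisons_to_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "variable": c.variable,
                "test": c.test,
                "n_serious": c.n_serious,
                "n_non_serious": c.n_non_serious,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "odds_ratio": c.odds_ratio,
                "or_lo": c.or_lo,
                "or_hi": c.or_hi,
                "computable": c.computable,
                "note": c.note,
            }
        )
    return pd.DataFrame(rows)
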