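"""Case definition, drug-class exposure flagging and analysis-set assembly.

The case/non-case design needs three deterministic filters on a deduplicated
report set:

* **case flag** — the report describes withdrawal symptoms (by PT or by
  standardized-query tag) in a neonate (age window, default 1-27 days
  inclusive; reports without a recorded age cannot be confirmed neonates and
  are non-cases);
* **exposure flags** — per-drug and per-class indicators from drugs in the
  ``suspected`` or ``interacting`` role only (concomitant mentions do not
  count as exposure);
* **monotherapy / confounder flags** — whether the report is free of
  psychotropic co-medication (any role), used for the confounder-free
  subgroup analyses and the co-occurrence network.

The annotated result is an :class:`AnalysisSet`: the reports plus a pandas
DataFrame with one row per report carrying every flag the downstream
modules need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .icsr import DrugEntry, IcsrReport, ReportSet

__all__ = [
    "TermDictionary",
    "DrugClassMap",
    "ConfounderList",
    "SymptomCategoryMap",
    "ExposureFlags",
    "AnalysisSet",
    "is_case",
    "exposure_flags",
    "build_analysis_set",
    "default_term_dictionary",
    "default_class_map",
    "default_confounders",
    "default_symptom_categories",
]

DEFAULT_AGE_WINDOW = (1, 27)

CLASS_LABELS = ("tca", "ssri", "other_antidepressant")


def _load_resource(name: str) -> dict:
    with resources.files("nwsignal.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class TermDictionary:
    """Reaction terms that define the withdrawal event."""

    case_pts: frozenset
    case_smqs: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "case_pts", frozenset(p.lower() for p in self.case_pts))
        object.__setattr__(self, "case_smqs", frozenset(s.lower() for s in self.case_smqs))
        if not (self.case_pts | self.case_smqs):
            raise ValueError("term dictionary must contain at least one PT or SMQ")

    @classmethod
    def from_yaml(cls, path: str) -> "TermDictionary":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(case_pts=frozenset(raw["case_pts"]), case_smqs=frozenset(raw.get("case_smqs", [])))


def default_term_dictionary() -> TermDictionary:
    raw = _load_resource("term_dictionary.yaml")
    return TermDictionary(
        case_pts=frozenset(raw["case_pts"]), case_smqs=frozenset(raw.get("case_smqs", []))
    )


@dataclass(frozen=True)
class DrugClassMap:
    """Maps drug names (and ATC prefixes) to antidepressant classes.

    ``classes`` maps class label -> {drug name -> ATC code}; lookups
    normalize names through ``synonyms``.  ``positive_control`` names the
    active comparator drug.
    """

    classes: dict
    positive_control: str = "methadone"
    synonyms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        name_to_class: dict = {}
        atc_to_class: dict = {}
        for label, members in self.classes.items():
            for name, atc in members.items():
                low = name.lower()
                if low in name_to_class:
                    raise ValueError(f"drug {name!r} mapped to more than one class")
                name_to_class[low] = label
                if atc:
                    atc_to_class[atc.upper()] = label
        object.__setattr__(self, "_name_to_class", name_to_class)
        object.__setattr__(self, "_atc_to_class", atc_to_class)
        object.__setattr__(
            self, "synonyms", {k.lower(): v.lower() for k, v in self.synonyms.items()}
        )

    def canonical_name(self, name: str) -> str:
        low = name.strip().lower()
        return self.synonyms.get(low, low)

    def class_of(self, drug: DrugEntry) -> Optional[str]:
        """Antidepressant class of a drug entry, or None."""
        label = self._name_to_class.get(self.canonical_name(drug.name))
        if label is None and drug.atc_code:
            label = self._atc_to_class.get(drug.atc_code.upper())
        return label

    def is_antidepressant(self, name: str) -> bool:
        return self.canonical_name(name) in self._name_to_class

    def is_positive_control(self, drug: DrugEntry) -> bool:
        return self.canonical_name(drug.name) == self.positive_control

    def drugs_in_class(self, label: str) -> tuple:
        return tuple(sorted(self.classes[label]))

    def all_drugs(self) -> tuple:
        return tuple(sorted(self._name_to_class))

    @classmethod
    def from_yaml(cls, path: str) -> "DrugClassMap":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            classes=raw["classes"],
            positive_control=raw.get("positive_control", "methadone"),
            synonyms=raw.get("synonyms", {}),
        )


def default_class_map() -> DrugClassMap:
    raw = _load_resource("drug_classes.yaml")
    return DrugClassMap(
        classes=raw["classes"],
        positive_control=raw.get("positive_control", "methadone"),
        synonyms=raw.get("synonyms", {}),
    )


@dataclass(frozen=True)
class ConfounderList:
    """Psychotropic co-medication classes that can themselves cause the
    withdrawal event (class label -> drug names)."""

    classes: dict

    def __post_init__(self) -> None:
        lookup: dict = {}
        for label, names in self.classes.items():
            for n in names:
                lookup.setdefault(n.lower(), set()).add(label)
        object.__setattr__(self, "_lookup", lookup)

    @property
    def class_labels(self) -> tuple:
        return tuple(self.classes)

    def classes_of(self, name: str) -> frozenset:
        return frozenset(self._lookup.get(name.strip().lower(), ()))

    @classmethod
    def from_yaml(cls, path: str) -> "ConfounderList":
        with open(path, encoding="utf-8") as fh:
            return cls(classes=yaml.safe_load(fh))


def default_confounders() -> ConfounderList:
    return ConfounderList(classes=_load_resource("confounders.yaml"))


@dataclass(frozen=True)
class SymptomCategoryMap:
    """PT -> clinical symptom category mapping for co-reported symptoms."""

    categories: dict  # category -> list of PTs

    def __post_init__(self) -> None:
        lookup = {}
        for cat, pts in self.categories.items():
            for pt in pts:
                lookup[pt.lower()] = cat
        object.__setattr__(self, "_lookup", lookup)

    def category_of(self, pt: str) -> Optional[str]:
        return self._lookup.get(pt.strip().lower())

    @property
    def category_labels(self) -> tuple:
        return tuple(self.categories)

    @classmethod
    def from_yaml(cls, path: str) -> "SymptomCategoryMap":
        with open(path, encoding="utf-8") as fh:
            return cls(categories=yaml.safe_load(fh))


def default_symptom_categories() -> SymptomCategoryMap:
    return SymptomCategoryMap(categories=_load_resource("symptom_categories.yaml"))


def is_case(
    report: IcsrReport,
    term_dict: TermDictionary,
    age_window: tuple = DEFAULT_AGE_WINDOW,
) -> bool:
    """True iff the report is a neonatal withdrawal case.

    Requires a qualifying reaction (PT in ``case_pts`` or any tag in
    ``case_smqs``) AND a recorded age inside ``age_window`` (inclusive).
    Reports with no recorded age are non-cases: they cannot be confirmed
    neonates.
    """
    age = report.patient.age_days
    if age is None or not (age_window[0] <= age <= age_window[1]):
        return False
    for reaction in report.reactions:
        if reaction.pt in term_dict.case_pts or (reaction.smq_tags & term_dict.case_smqs):
            return True
    return False


@dataclass(frozen=True)
class ExposureFlags:
    """Exposure of one report: antidepressant drugs/classes (suspected or
    interacting role only) and the positive-control comparator."""

    drugs: frozenset
    classes: frozenset
    positive_control: bool

    @property
    def any_antidepressant(self) -> bool:
        return bool(self.drugs)


def exposure_flags(report: IcsrReport, class_map: DrugClassMap) -> ExposureFlags:
    """Per-drug and per-class exposure booleans for one report.

    A drug counts as exposure only in the ``suspected`` or ``interacting``
    role; concomitant-only mentions never set a flag.
    """
    drugs: set = set()
    classes: set = set()
    pc = False
    for drug in report.drugs:
        if drug.role not in ("suspected", "interacting"):
            continue
        label = class_map.class_of(drug)
        if label is not None:
            drugs.add(class_map.canonical_name(drug.name))
            classes.add(label)
        if class_map.is_positive_control(drug):
            pc = True
    return ExposureFlags(drugs=frozenset(drugs), classes=frozenset(classes), positive_control=pc)


@dataclass
class AnalysisSet:
    """Deduplicated reports annotated with every flag the analyses need.

    ``table`` has one row per report:
    ``report_id, patient_id, is_case, age_days, sex, serious, country,
    any_antidepressant, class_<label>, exp_<drug>, positive_control,
    n_antidepressants, has_confounder, confounder_free, monotherapy,
    comed_<class>, symptom_categories (frozenset), n_symptom_categories,
    daily_dose_ddd, treatment_duration_weeks, symptom_duration_days``.
    """

    table: pd.DataFrame
    class_map: DrugClassMap
    reports: Optional[list] = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_cases(self) -> int:
        return int(self.table["is_case"].sum())

    def to_csv(self, path: str) -> None:
        out = self.table.copy()
        out["symptom_categories"] = out["symptom_categories"].map(
            lambda s: ";".join(sorted(s))
        )
        out.to_csv(path, index=False)


def build_analysis_set(
    rs: ReportSet,
    term_dict: Optional[TermDictionary] = None,
    class_map: Optional[DrugClassMap] = None,
    confounders: Optional[ConfounderList] = None,
    symptom_map: Optional[SymptomCategoryMap] = None,
    age_window: tuple = DEFAULT_AGE_WINDOW,
) -> AnalysisSet:
    """Annotate a deduplicated ReportSet into an :class:`AnalysisSet`.

    All filters are deterministic; defaults come from the packaged term
    dictionary, class map, confounder list and symptom-category map.
    Assembly is column-wise: the flag columns for the ~30 mapped drugs are
    filled from index lists so annotating 10^5-report sets stays cheap.
    """
    term_dict = term_dict or default_term_dictionary()
    class_map = class_map or default_class_map()
    confounders = confounders or default_confounders()
    symptom_map = symptom_map or default_symptom_categories()

    n = len(rs)
    base: dict = {
        name: [None] * n
        for name in (
            "report_id", "patient_id", "is_case", "age_days", "sex", "serious", "country",
            "any_antidepressant", "positive_control", "n_antidepressants", "has_confounder",
            "confounder_free", "monotherapy", "symptom_categories", "n_symptom_categories",
            "daily_dose_ddd", "treatment_duration_weeks", "symptom_duration_days",
        )
    }
    exp_idx: dict = {name: [] for name in class_map.all_drugs()}
    class_idx: dict = {label: [] for label in CLASS_LABELS}
    comed_idx: dict = {label: [] for label in confounders.class_labels}

    for i, report in enumerate(rs):
        flags = exposure_flags(report, class_map)
        case = is_case(report, term_dict, age_window)

        # confounders and extra antidepressants count in ANY role
        comed_classes: set = set()
        ad_names_any_role: set = set()
        for drug in report.drugs:
            comed_classes |= confounders.classes_of(drug.name)
            canon = class_map.canonical_name(drug.name)
            if class_map.is_antidepressant(canon):
                ad_names_any_role.add(canon)
        extra_ad = bool(ad_names_any_role - flags.drugs) or len(flags.drugs) > 1
        has_confounder = bool(comed_classes) or extra_ad
        monotherapy = len(flags.drugs) == 1 and not comed_classes and not extra_ad

        cats: set = set()
        symptom_duration = None
        withdrawal_duration = None
        for reaction in report.reactions:
            cat = symptom_map.category_of(reaction.pt)
            if cat is not None:
                cats.add(cat)
            if reaction.duration_days is not None:
                if reaction.pt in term_dict.case_pts or (
                    reaction.smq_tags & term_dict.case_smqs
                ):
                    withdrawal_duration = reaction.duration_days
                elif symptom_duration is None or reaction.duration_days > symptom_duration:
                    symptom_duration = reaction.duration_days
        # prefer the duration coded on the withdrawal reaction itself
        duration = withdrawal_duration if withdrawal_duration is not None else symptom_duration

        dose = None
        treat_weeks = None
        for drug in report.drugs:
            if drug.role not in ("suspected", "interacting"):
                continue
            if class_map.is_antidepressant(class_map.canonical_name(drug.name)):
                if dose is None and drug.daily_dose_ddd is not None:
                    dose = drug.daily_dose_ddd
                if treat_weeks is None and drug.treatment_duration_weeks is not None:
                    treat_weeks = drug.treatment_duration_weeks

        base["report_id"][i] = report.report_id
        base["patient_id"][i] = report.patient.patient_id or report.report_id
        base["is_case"][i] = case
        base["age_days"][i] = report.patient.age_days
        base["sex"][i] = report.patient.sex
        base["serious"][i] = report.serious
        base["country"][i] = report.country
        base["any_antidepressant"][i] = flags.any_antidepressant
        base["positive_control"][i] = flags.positive_control
        base["n_antidepressants"][i] = len(flags.drugs)
        base["has_confounder"][i] = has_confounder
        base["confounder_free"][i] = not has_confounder
        base["monotherapy"][i] = monotherapy
        base["symptom_categories"][i] = frozenset(cats)
        base["n_symptom_categories"][i] = len(cats)
        base["daily_dose_ddd"][i] = dose
        base["treatment_duration_weeks"][i] = treat_weeks
        base["symptom_duration_days"][i] = duration

        for name in flags.drugs:
            exp_idx[name].append(i)
        for label in flags.classes:
            class_idx[label].append(i)
        for label in comed_classes:
            comed_idx[label].append(i)

    table = pd.DataFrame(base)
    for label in CLASS_LABELS:
        col = np.zeros(n, dtype=bool)
        col[class_idx[label]] = True
        table[f"class_{label}"] = col
    for name in class_map.all_drugs():
        col = np.zeros(n, dtype=bool)
        col[exp_idx[name]] = True
        table[f"exp_{name}"] = col
    for label in confounders.class_labels:
        col = np.zeros(n, dtype=bool)
        col[comed_idx[label]] = True
        table[f"comed_{label}"] = col
    for col in ("is_case", "any_antidepressant", "positive_control", "has_confounder",
                "confounder_free", "monotherapy"):
        table[col] = table[col].astype(bool)
    return AnalysisSet(table=table, class_map=class_map, reports=list(rs.reports))
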