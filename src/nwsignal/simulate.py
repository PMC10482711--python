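"""Synthetic spontaneous-report database with planted disproportionality.

The generator emulates a deduplicated ICSR database well enough to exercise
every stage of the case/non-case pipeline: each report draws one index drug
from a configurable formulary, and the probability that the report describes
neonatal withdrawal is the odds transform of the background odds multiplied
by the drug's planted reporting odds ratio.  Because effects are planted on
the odds scale, the ROR estimated downstream recovers the planted value in
expectation — parameter recovery is exact by construction, not approximate.

Withdrawal cases are neonates (age 1-27 days) carrying a withdrawal reaction
term plus 1-4 co-reported symptom PTs whose category frequencies follow the
clinical ordering seen in spontaneous data (respiratory > irritability >
tremor > feeding problems > seizures).  Non-cases carry unrelated reaction
terms; a configurable fraction are neonates with other ADRs.  Psychotropic
co-medications (benzodiazepines, antipsychotics, opioids, a second
antidepressant, mood stabilizers) are sampled independently per class, and a
configurable fraction of reports is cloned to exercise deduplication.

Everything is driven by one integer seed; the same seed reproduces the same
ReportSet byte for byte.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .casedef import default_class_map, default_confounders, default_symptom_categories
from .icsr import DrugEntry, IcsrReport, PatientInfo, ReactionEntry, ReportSet

__all__ = [
    "DrugSpec",
    "SimulationConfig",
    "TruthTable",
    "ConfigError",
    "generate_reports",
    "planted_truth",
    "default_drug_specs",
    "default_config",
    "recovery_config",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


CLASS_CHOICES = ("tca", "ssri", "other_antidepressant", "comparator_positive", "background")

WITHDRAWAL_PTS = (
    "drug withdrawal syndrome neonatal",
    "drug withdrawal syndrome",
    "withdrawal syndrome",
    "drug withdrawal convulsions",
)
WITHDRAWAL_PT_WEIGHTS = (0.60, 0.20, 0.15, 0.05)
# some cases are identified only through the standardized-query tag on an
# otherwise non-specific PT, exercising the SMQ arm of the case definition
SMQ_ONLY_FRACTION = 0.05
SMQ_TAG = "drug withdrawal"

BACKGROUND_PTS = (
    "rash", "nausea", "headache", "dizziness", "diarrhoea", "urticaria",
    "pruritus", "fatigue", "anaemia", "hepatotoxicity", "renal impairment",
    "hypotension", "tachycardia", "cough", "insomnia", "arthralgia",
    "myalgia", "oedema peripheral", "dyspepsia", "syncope",
)

COUNTRIES = ("US", "GB", "DE", "FR", "IT", "SE", "NO", "AU", "CA", "NL")
COUNTRY_WEIGHTS = (0.30, 0.12, 0.10, 0.09, 0.08, 0.07, 0.06, 0.06, 0.06, 0.06)

DEFAULT_SYMPTOM_WEIGHTS = {
    "respiratory symptoms": 0.28,
    "irritability/agitation": 0.20,
    "tremor": 0.15,
    "feeding problems": 0.11,
    "seizures": 0.09,
    "muscle symptoms": 0.08,
    "somnolence": 0.06,
    "pyrexia": 0.03,
}
N_SYMPTOM_WEIGHTS = {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15}

DEFAULT_MISSINGNESS = {
    "age_days": 0.0,  # the neonatal age window is part of the case query
    "sex": 0.08,
    "country": 0.02,
    "daily_dose_ddd": 0.50,
    "treatment_duration_weeks": 0.55,
    "symptom_duration_days": 0.70,
}

DEFAULT_COMEDICATION_RATES = {
    "benzodiazepine": 0.301,
    "antipsychotic": 0.232,
    "opioid": 0.135,
    "second_antidepressant": 0.119,
    "mood_stabilizer": 0.095,
}


@dataclass(frozen=True, slots=True)
class DrugSpec:
    """One drug in the simulated formulary.

    ``background_report_weight`` is the drug's relative share of reports;
    ``withdrawal_ror`` the planted reporting odds ratio of the withdrawal
    event for reports indexed on this drug, relative to background.
    """

    name: str
    atc_code: Optional[str]
    class_label: str
    background_report_weight: float
    withdrawal_ror: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_CHOICES:
            raise ConfigError(f"unknown class_label {self.class_label!r}")
        if self.background_report_weight <= 0:
            raise ConfigError("background_report_weight must be positive")
        if self.withdrawal_ror <= 0:
            raise ConfigError("withdrawal_ror must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated database."""

    n_reports: int
    drug_specs: tuple
    baseline_withdrawal_rate: float = 0.01
    neonate_fraction: float = 0.05
    comedication_rates: dict = field(default_factory=lambda: dict(DEFAULT_COMEDICATION_RATES))
    serious_fraction: float = 0.839
    non_case_serious_fraction: float = 0.45
    female_fraction_cases: float = 0.367
    female_fraction_other: float = 0.49
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    symptom_category_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_SYMPTOM_WEIGHTS)
    )
    duplicate_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        if not self.drug_specs:
            raise ConfigError("drug_specs must be non-empty")
        object.__setattr__(self, "drug_specs", tuple(self.drug_specs))
        probs = {
            "baseline_withdrawal_rate": self.baseline_withdrawal_rate,
            "neonate_fraction": self.neonate_fraction,
            "serious_fraction": self.serious_fraction,
            "non_case_serious_fraction": self.non_case_serious_fraction,
            "female_fraction_cases": self.female_fraction_cases,
            "female_fraction_other": self.female_fraction_other,
            "duplicate_fraction": self.duplicate_fraction,
            **{f"comedication_rates[{k}]": v for k, v in self.comedication_rates.items()},
            **{f"missingness[{k}]": v for k, v in self.missingness.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not (0.0 < self.baseline_withdrawal_rate < 1.0):
            raise ConfigError("baseline_withdrawal_rate must be in (0, 1)")

    def weights(self) -> np.ndarray:
        w = np.array([s.background_report_weight for s in self.drug_specs], dtype=float)
        return w / w.sum()

    def event_probabilities(self) -> np.ndarray:
        """Per-drug case probability: odds transform of baseline odds times
        the planted ROR."""
        base_odds = self.baseline_withdrawal_rate / (1.0 - self.baseline_withdrawal_rate)
        odds = base_odds * np.array([s.withdrawal_ror for s in self.drug_specs])
        return odds / (1.0 + odds)


@dataclass(frozen=True)
class TruthTable:
    """Closed-form expected 2x2 counts and planted RORs, one row per drug.

    Columns: ``drug, class_label, weight, p_event, expected_a, expected_b,
    expected_c, expected_d, planted_ror, implied_ror`` (plus
    ``realized_a/realized_b`` when produced by :func:`generate_reports`).
    The comparator frame is every non-antidepressant drug (background plus
    the positive control), exactly the main-scheme comparator downstream; a
    drug row's exposed cells sum to ``n * weight`` and its comparator cells
    to ``n * comparator weight``.  ``implied_ror`` is the odds ratio of the
    expected cells; it equals ``planted_ror`` whenever the comparator drugs
    sit at the null.
    """

    frame: pd.DataFrame

    def row(self, drug: str) -> pd.Series:
        return self.frame.set_index("drug").loc[drug]

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)


def planted_truth(config: SimulationConfig) -> TruthTable:
    """Expected per-drug 2x2 counts from the mixture weights and rates."""
    w = config.weights()
    p = config.event_probabilities()
    n = config.n_reports
    bg = np.array(
        [s.class_label in ("background", "comparator_positive") for s in config.drug_specs]
    )
    bg_weight = float(w[bg].sum())
    exp_c = float(n * (w[bg] * p[bg]).sum())
    exp_d = float(n * (w[bg] * (1.0 - p[bg])).sum())
    comp_odds = exp_c / exp_d
    rows = []
    for i, spec in enumerate(config.drug_specs):
        exp_a = float(n * w[i] * p[i])
        exp_b = float(n * w[i] * (1.0 - p[i]))
        rows.append(
            {
                "drug": spec.name,
                "class_label": spec.class_label,
                "weight": float(w[i]),
                "p_event": float(p[i]),
                "expected_a": exp_a,
                "expected_b": exp_b,
                "expected_c": exp_c,
                "expected_d": exp_d,
                "comparator_weight": bg_weight,
                "planted_ror": spec.withdrawal_ror,
                "implied_ror": (exp_a / exp_b) / comp_odds,
            }
        )
    return TruthTable(frame=pd.DataFrame(rows))


def default_drug_specs() -> tuple:
    """Default formulary: the 27 antidepressants (class-level planted RORs
    matching spontaneous-report estimates for this event; bupropion null),
    methadone as a strongly positive comparator, and 12 common background
    drugs at the null."""
    class_map = default_class_map()
    specs = []
    class_ror = {"tca": 10.55, "ssri": 4.68, "other_antidepressant": 5.90}
    for label in ("tca", "ssri", "other_antidepressant"):
        for name in class_map.drugs_in_class(label):
            atc = class_map.classes[label][name]
            ror = 1.0 if name == "bupropion" else class_ror[label]
            specs.append(DrugSpec(name, atc, label, 0.008, ror))
    specs.append(DrugSpec("methadone", "N07BC02", "comparator_positive", 0.002, 40.0))
    background = [
        ("paracetamol", "N02BE01", 0.180),
        ("ibuprofen", "M01AE01", 0.100),
        ("amoxicillin", "J01CA04", 0.090),
        ("omeprazole", "A02BC01", 0.080),
        ("metformin", "A10BA02", 0.070),
        ("atorvastatin", "C10AA05", 0.060),
        ("salbutamol", "R03AC02", 0.060),
        ("lisinopril", "C09AA03", 0.050),
        ("warfarin", "B01AA03", 0.050),
        ("prednisolone", "H02AB06", 0.040),
        ("insulin", "A10AB01", 0.040),
        ("ondansetron", "A04AA01", 0.022),
    ]
    for name, atc, weight in background:
        specs.append(DrugSpec(name, atc, "background", weight, 1.0))
    return tuple(specs)


def default_config(n_reports: int = 200_000, seed: int = 0, **overrides) -> SimulationConfig:
    return SimulationConfig(
        n_reports=n_reports, drug_specs=default_drug_specs(), seed=seed, **overrides
    )


def recovery_config(
    planted_drug: Optional[str] = "paroxetine",
    planted_ror: float = 10.0,
    n_reports: int = 200_000,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Parameter-recovery conditions: every drug at the null except one.

    With the whole comparator frame at the null, the planted ROR is exactly
    the estimand of the main-scheme contrast, making this the reference
    setup for coverage and recovery studies.  ``planted_drug=None`` puts
    every drug at the null.
    """
    specs = tuple(
        replace(
            s,
            withdrawal_ror=planted_ror if s.name == planted_drug else 1.0,
        )
        for s in default_drug_specs()
    )
    return SimulationConfig(n_reports=n_reports, drug_specs=specs, seed=seed, **overrides)


def _sample_dates(rng: np.random.Generator, n: int) -> list:
    start = datetime.date(2000, 1, 1).toordinal()
    end = datetime.date(2021, 8, 31).toordinal()
    ordinals = rng.integers(start, end + 1, size=n)
    return [datetime.date.fromordinal(int(o)).isoformat() for o in ordinals]


def generate_reports(config: SimulationConfig):
    """Generate a synthetic ReportSet and its truth table.

    Returns ``(report_set, truth)``.  The set contains
    ``round(n_reports * (1 + duplicate_fraction))`` reports: ``n_reports``
    originals followed by exact clones (new report ids) so that
    deduplication recovers exactly the originals.  ``truth`` carries the
    closed-form expected counts plus the realized per-drug event counts of
    this draw.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    specs = config.drug_specs
    weights = config.weights()
    p_event = config.event_probabilities()

    confounders = default_confounders()
    symptom_map = default_symptom_categories()
    symptom_cats = list(config.symptom_category_weights)
    cat_w = np.array([config.symptom_category_weights[c] for c in symptom_cats], dtype=float)
    cat_w = cat_w / cat_w.sum()
    cat_pts = {c: symptom_map.categories[c] for c in symptom_cats}

    ad_indices = [
        i for i, s in enumerate(specs)
        if s.class_label in ("tca", "ssri", "other_antidepressant")
    ]

    # immutable entries reused across reports (validation runs once)
    comed_entry_cache = {
        cls: [DrugEntry(name=m, role="concomitant") for m in confounders.classes[cls]]
        for cls in config.comedication_rates
        if cls in confounders.classes
    }
    second_ad_cache = {
        i: DrugEntry(name=specs[i].name, atc_code=specs[i].atc_code, role="concomitant")
        for i in ad_indices
    }
    symptom_entry_cache = {
        cat: [ReactionEntry(pt=pt) for pt in pts] for cat, pts in cat_pts.items()
    }
    bg_entry_cache = [ReactionEntry(pt=pt) for pt in BACKGROUND_PTS]

    # vectorized draws -----------------------------------------------------
    drug_idx = rng.choice(len(specs), size=n, p=weights)
    event = rng.random(n) < p_event[drug_idx]

    age = np.empty(n, dtype=np.int64)
    n_cases = int(event.sum())
    age[event] = rng.integers(1, 28, size=n_cases)
    noncase = ~event
    n_non = int(noncase.sum())
    neonate_non = rng.random(n_non) < config.neonate_fraction
    age_non = rng.integers(28, 30_000, size=n_non)
    age_non[neonate_non] = rng.integers(1, 28, size=int(neonate_non.sum()))
    age[noncase] = age_non

    female_p = np.where(event, config.female_fraction_cases, config.female_fraction_other)
    female = rng.random(n) < female_p
    serious_p = np.where(event, config.serious_fraction, config.non_case_serious_fraction)
    serious = rng.random(n) < serious_p

    comed_classes = list(config.comedication_rates)
    comed_draws = {
        cls: rng.random(n) < rate for cls, rate in config.comedication_rates.items()
    }
    comed_pick = {
        cls: rng.integers(0, len(confounders.classes[cls]), size=n)
        for cls in comed_classes
        if cls in confounders.classes
    }
    second_ad_pick = rng.integers(0, len(ad_indices), size=n)

    country_idx = rng.choice(len(COUNTRIES), size=n, p=np.array(COUNTRY_WEIGHTS))
    dates = _sample_dates(rng, n)

    ddd = np.exp(rng.normal(0.0, 0.73, size=n))
    treat_weeks = np.clip(rng.normal(36.7, 7.0, size=n), 1.0, 42.0)
    sym_duration = np.exp(rng.normal(np.log(7.0), 0.96, size=n))

    miss = {f: (rng.random(n) < p).tolist() for f, p in config.missingness.items()}

    wd_pt_idx = rng.choice(len(WITHDRAWAL_PTS), size=n, p=np.array(WITHDRAWAL_PT_WEIGHTS))
    smq_only = rng.random(n) < SMQ_ONLY_FRACTION
    smq_extra = rng.random(n) < 0.5
    n_sym = rng.choice(
        list(N_SYMPTOM_WEIGHTS), size=n, p=np.array(list(N_SYMPTOM_WEIGHTS.values()))
    )
    bg_pt_idx = rng.integers(0, len(BACKGROUND_PTS), size=n)
    bg_pt_idx2 = rng.integers(0, len(BACKGROUND_PTS), size=n)
    two_bg = rng.random(n) < 0.3

    # scalar indexing into plain lists is much cheaper than numpy scalars
    # in the assembly loop below
    drug_idx_l = drug_idx.tolist()
    event_l = event.tolist()
    age_l = age.tolist()
    female_l = female.tolist()
    serious_l = serious.tolist()
    country_l = country_idx.tolist()
    ddd_l = ddd.tolist()
    treat_l = treat_weeks.tolist()
    symdur_l = sym_duration.tolist()
    wd_pt_l = wd_pt_idx.tolist()
    smq_only_l = smq_only.tolist()
    smq_extra_l = smq_extra.tolist()
    n_sym_l = n_sym.tolist()
    bg1_l = bg_pt_idx.tolist()
    bg2_l = bg_pt_idx2.tolist()
    two_bg_l = two_bg.tolist()
    comed_draws_l = {cls: arr.tolist() for cls, arr in comed_draws.items()}
    comed_pick_l = {cls: arr.tolist() for cls, arr in comed_pick.items()}
    second_ad_l = second_ad_pick.tolist()

    # assembly -------------------------------------------------------------
    reports: list = []
    seen_keys: dict = {}
    realized_a = np.zeros(len(specs), dtype=np.int64)
    realized_b = np.zeros(len(specs), dtype=np.int64)

    miss_age = miss["age_days"]
    miss_sex = miss["sex"]
    miss_country = miss["country"]
    miss_ddd = miss["daily_dose_ddd"]
    miss_treat = miss["treatment_duration_weeks"]
    miss_symdur = miss["symptom_duration_days"]
    hosp = frozenset(["hospitalization"])
    empty = frozenset()
    smq_set = frozenset([SMQ_TAG])
    wd_entries = {  # (pt index, tagged) -> duration-free cached entry
        (j, tagged): ReactionEntry(
            pt=WITHDRAWAL_PTS[j], smq_tags=smq_set if tagged else empty
        )
        for j in range(len(WITHDRAWAL_PTS))
        for tagged in (False, True)
    }
    smq_only_entry = ReactionEntry(pt="pyrexia", smq_tags=smq_set)

    for i in range(n):
        si = drug_idx_l[i]
        spec = specs[si]
        is_event = event_l[i]
        if is_event:
            realized_a[si] += 1
        else:
            realized_b[si] += 1

        drugs = [
            DrugEntry(
                name=spec.name,
                atc_code=spec.atc_code,
                role="suspected",
                daily_dose_ddd=None if miss_ddd[i] else round(ddd_l[i], 2),
                treatment_duration_weeks=None if miss_treat[i] else round(treat_l[i], 1),
            )
        ]
        for cls in comed_classes:
            if not comed_draws_l[cls][i]:
                continue
            if cls == "second_antidepressant":
                aj = ad_indices[second_ad_l[i] % len(ad_indices)]
                if aj == si:
                    aj = ad_indices[(second_ad_l[i] + 1) % len(ad_indices)]
                drugs.append(second_ad_cache[aj])
            elif cls in comed_entry_cache:
                drugs.append(comed_entry_cache[cls][comed_pick_l[cls][i]])

        reactions: list = []
        if is_event:
            dur = None if miss_symdur[i] else round(symdur_l[i], 1)
            if smq_only_l[i]:
                entry = smq_only_entry
            else:
                entry = wd_entries[(wd_pt_l[i], smq_extra_l[i])]
            if dur is not None:
                entry = replace(entry, duration_days=dur)
            reactions.append(entry)
            picked = rng.choice(len(symptom_cats), size=n_sym_l[i], replace=False, p=cat_w)
            for ci in picked:
                entries = symptom_entry_cache[symptom_cats[int(ci)]]
                reactions.append(entries[int(rng.integers(0, len(entries)))])
        else:
            reactions.append(bg_entry_cache[bg1_l[i]])
            if two_bg_l[i] and bg2_l[i] != bg1_l[i]:
                reactions.append(bg_entry_cache[bg2_l[i]])

        patient = PatientInfo(
            age_days=None if miss_age[i] else age_l[i],
            sex="unknown" if miss_sex[i] else ("female" if female_l[i] else "male"),
        )
        report = IcsrReport(
            report_id=f"R{i:07d}",
            patient=patient,
            drugs=drugs,
            reactions=reactions,
            serious=serious_l[i],
            seriousness_criteria=hosp if serious_l[i] else empty,
            country=None if miss_country[i] else COUNTRIES[country_l[i]],
            received_date=dates[i],
        )

        # resolve accidental dedup-key collisions between independent
        # originals so planted clones are exactly recoverable
        key = report.dedup_key()
        attempts = 0
        while key in seen_keys:
            attempts += 1
            if attempts > 50:
                raise RuntimeError("could not resolve duplicate-key collision")
            extra_pt = BACKGROUND_PTS[int(rng.integers(0, len(BACKGROUND_PTS)))]
            if any(r.pt == extra_pt for r in report.reactions):
                continue
            report = replace(
                report, reactions=report.reactions + (ReactionEntry(pt=extra_pt),)
            )
            key = report.dedup_key()
        seen_keys[key] = i
        reports.append(report)

    n_dup = int(round(n * config.duplicate_fraction))
    if n_dup:
        dup_sources = rng.choice(n, size=n_dup, replace=False)
        for j, src in enumerate(dup_sources):
            reports.append(replace(reports[int(src)], report_id=f"D{j:07d}"))

    truth = planted_truth(config)
    frame = truth.frame.copy()
    frame["realized_a"] = realized_a
    frame["realized_b"] = realized_b
    rs = ReportSet(
        reports=reports,
        provenance=f"nwsignal.simulate(seed={config.seed}, n={n}, duplicates={n_dup})",
    )
    return rs, TruthTable(frame=frame)
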