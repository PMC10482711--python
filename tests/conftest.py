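"""Shared fixtures: hand-built report sets and small simulated databases."""

import pytest

from nwsignal.casedef import build_analysis_set
from nwsignal.icsr import DrugEntry, IcsrReport, PatientInfo, ReactionEntry, deduplicate
from nwsignal.simulate import default_config, generate_reports


def make_report(
    report_id="R1",
    drug="paroxetine",
    role="suspected",
    pt="drug withdrawal syndrome neonatal",
    age_days=5,
    sex="female",
    serious=True,
    smq_tags=(),
    country="US",
    extra_drugs=(),
    extra_pts=(),
    **kwargs,
):
    """One-liner report factory for unit tests."""
    drugs = [DrugEntry(name=drug, role=role)] + [
        d if isinstance(d, DrugEntry) else DrugEntry(name=d, role="concomitant")
        for d in extra_drugs
    ]
    reactions = [ReactionEntry(pt=pt, smq_tags=frozenset(smq_tags))] + [
        ReactionEntry(pt=p) for p in extra_pts
    ]
    return IcsrReport(
        report_id=report_id,
        patient=PatientInfo(age_days=age_days, sex=sex),
        drugs=drugs,
        reactions=reactions,
        serious=serious,
        country=country,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated database shared by read-only tests."""
    config = default_config(n_reports=20_000, seed=11)
    rs, truth = generate_reports(config)
    return config, rs, truth


@pytest.fixture(scope="session")
def small_aset(small_sim):
    _, rs, _ = small_sim
    return build_analysis_set(deduplicate(rs))
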