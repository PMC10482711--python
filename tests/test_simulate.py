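"""Generator determinism, construction counts, closed-form truth and
law-of-large-numbers calibration."""

import math

import numpy as np
import pytest

from nwsignal.icsr import deduplicate, write_reports
from nwsignal.simulate import (
    ConfigError,
    DrugSpec,
    SimulationConfig,
    default_config,
    generate_reports,
    planted_truth,
    recovery_config,
)


def _single_drug_config(**kwargs):
    spec = DrugSpec("drugx", "X01AA01", "background", 1.0, kwargs.pop("ror", 5.0))
    return SimulationConfig(
        n_reports=kwargs.pop("n_reports", 5000),
        drug_specs=(spec,),
        duplicate_fraction=kwargs.pop("duplicate_fraction", 0.0),
        **kwargs,
    )


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigError):
            default_config(n_reports=10, neonate_fraction=1.5)

    def test_bad_ror_rejected(self):
        with pytest.raises(ConfigError):
            DrugSpec("x", None, "background", 1.0, withdrawal_ror=0.0)

    def test_empty_formulary_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_reports=10, drug_specs=())


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        cfg = default_config(n_reports=2000, seed=42)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_reports(generate_reports(cfg)[0], str(p1), "long")
        write_reports(generate_reports(cfg)[0], str(p2), "long")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        rs1, _ = generate_reports(default_config(n_reports=2000, seed=1))
        rs2, _ = generate_reports(default_config(n_reports=2000, seed=2))
        assert rs1 != rs2


class TestConstruction:
    def test_duplicate_fraction_counts(self):
        """10% clones on 1000 reports: 1100 pre-dedup, 1000 post-dedup."""
        cfg = default_config(n_reports=1000, seed=5, duplicate_fraction=0.1)
        rs, _ = generate_reports(cfg)
        assert len(rs) == 1100
        assert len(deduplicate(rs)) == 1000

    def test_case_reports_are_neonates_with_qualifying_terms(self):
        from nwsignal.casedef import default_term_dictionary, is_case

        cfg = recovery_config(planted_ror=20.0, n_reports=5000, seed=7)
        rs, truth = generate_reports(cfg)
        term = default_term_dictionary()
        n_cases = sum(is_case(r, term) for r in rs.reports[: cfg.n_reports])
        assert n_cases == truth.frame["realized_a"].sum()


class TestPlantedTruth:
    def test_null_config_truth_ror_one(self):
        cfg = recovery_config(planted_drug=None, n_reports=1000)
        frame = planted_truth(cfg).frame
        assert np.allclose(frame["planted_ror"], 1.0)
        assert np.allclose(frame["implied_ror"], 1.0)

    def test_exposed_cells_sum_to_drug_share(self):
        cfg = default_config(n_reports=100_000)
        frame = planted_truth(cfg).frame
        assert np.allclose(
            frame["expected_a"] + frame["expected_b"], cfg.n_reports * frame["weight"]
        )
        comp = frame["expected_c"] + frame["expected_d"]
        assert np.allclose(comp, cfg.n_reports * frame["comparator_weight"])

    def test_single_drug_closed_form_matches_monte_carlo(self):
        """Expected case fraction = inverse odds transform of baseline odds
        times the planted ROR, checked against a direct simulation."""
        baseline, ror = 0.01, 5.0
        cfg = _single_drug_config(ror=ror, baseline_withdrawal_rate=baseline, n_reports=200_000)
        expected_p = planted_truth(cfg).frame["p_event"].iloc[0]
        odds = baseline / (1 - baseline) * ror
        assert expected_p == pytest.approx(odds / (1 + odds))
        rng = np.random.default_rng(0)
        mc = (rng.random(10**6) < expected_p).mean()
        se = math.sqrt(expected_p * (1 - expected_p) / 10**6)
        assert abs(mc - expected_p) < 4 * se


@pytest.fixture(scope="module")
def big_run():
    cfg = default_config(n_reports=100_000, seed=23, duplicate_fraction=0.0)
    rs, truth = generate_reports(cfg)
    return cfg, rs, truth


class TestMarginalRates:
    """Empirical rates converge to the configured conditions (3 SE bands,
    one draw at n = 10^5)."""

    def test_event_rate_matches_truth(self, big_run):
        cfg, rs, truth = big_run
        expected = truth.frame["expected_a"].sum()
        observed = truth.frame["realized_a"].sum()
        assert abs(observed - expected) < 3 * math.sqrt(expected)

    def test_serious_fraction_among_cases(self, big_run):
        from nwsignal.casedef import default_term_dictionary, is_case

        cfg, rs, truth = big_run
        term = default_term_dictionary()
        cases = [r for r in rs if is_case(r, term)]
        n_cases = len(cases)
        assert n_cases == int(truth.frame["realized_a"].sum())
        serious = sum(1 for r in cases if r.serious)
        p = cfg.serious_fraction
        se = math.sqrt(p * (1 - p) * n_cases)
        assert abs(serious - p * n_cases) < 3 * se

    def test_comedication_rates(self, big_run):
        cfg, rs, _ = big_run
        n = len(rs)
        benzo_drugs = {"diazepam", "lorazepam", "clonazepam", "oxazepam", "alprazolam",
                       "zolpidem", "zopiclone"}
        observed = sum(1 for r in rs if any(d.name in benzo_drugs for d in r.drugs))
        p = cfg.comedication_rates["benzodiazepine"]
        se = math.sqrt(p * (1 - p) * n)
        assert abs(observed - p * n) < 3 * se

    def test_missingness_rate(self, big_run):
        cfg, rs, _ = big_run
        n = len(rs)
        p = cfg.missingness["sex"]
        observed = sum(1 for r in rs if r.patient.sex == "unknown")
        se = math.sqrt(p * (1 - p) * n)
        assert abs(observed - p * n) < 3 * se
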