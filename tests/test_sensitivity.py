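"""One-way sweeps, sequential-bifurcation screening, and the PSA."""

import numpy as np
import pytest

from odtcea.parameters import CATEGORIES, validate_parameters
from odtcea.sensitivity import (
    _draw_beta,
    default_wtp_grid,
    get_param,
    list_parameter_ids,
    owsa,
    psa_draw_parameters,
    run_psa,
    screen_parameters,
    set_param,
)
from odtcea.simulation import evaluate_expected, evaluate_name

SMALL_IDS = [
    "utilities.non.stable",
    "strategies.olanzapine_odt.daily_drug_cost",
    "strategies.risperidone_sot.p_relapse_hosp.partial",
    "unit_costs.hospital_day",
]


def test_parameter_paths_round_trip(fresh_params):
    for pid in list_parameter_ids(fresh_params):
        v = get_param(fresh_params, pid)
        set_param(fresh_params, pid, v)
    assert validate_parameters(fresh_params).ok


def test_setting_adherence_share_renormalizes(fresh_params):
    set_param(fresh_params, "strategies.olanzapine_sot.adherence.p_compliant", 0.5)
    a = fresh_params.strategy("olanzapine_sot").adherence
    assert a.p_compliant == 0.5
    assert a.p_compliant + a.p_partial + a.p_non == pytest.approx(1.0)
    # the other two shares keep their relative proportions (43:34)
    assert a.p_partial / a.p_non == pytest.approx(43 / 34)


def test_owsa_zero_range_means_zero_spread(params):
    entries = owsa(params, ("olanzapine_odt", "olanzapine_sot"),
                   parameter_ids=SMALL_IDS, range_fraction=0.0)
    assert all(e.spread == 0.0 for e in entries)
    assert all(e.low_value == e.base_value == e.high_value for e in entries)


def test_owsa_untouched_parameter_has_zero_spread(params):
    """A parameter outside the compared strategies cannot move their ICER."""
    entries = owsa(params, ("olanzapine_odt", "risperidone_odt"),
                   parameter_ids=["strategies.aripiprazole_sot.daily_drug_cost"])
    assert entries[0].spread == 0.0


def test_owsa_sorted_by_spread(params):
    entries = owsa(params, ("olanzapine", "risperidone"),
                   parameter_ids=SMALL_IDS)
    spreads = [e.spread for e in entries]
    assert spreads == sorted(spreads, reverse=True)
    for e in entries:
        assert e.low_value <= e.base_value <= e.high_value


class TestScreening:
    COMPARISON = ("olanzapine", "risperidone")
    IDS = (
        ["utilities.non.stable", "utilities.partial.stable",
         "utilities.compliant.relapse_hosp"]
        + [f"strategies.olanzapine_odt.p_relapse_hosp.{c}" for c in CATEGORIES]
        + [f"strategies.risperidone_sot.p_relapse_hosp.{c}" for c in CATEGORIES]
        + ["strategies.olanzapine_odt.daily_drug_cost",
           "strategies.aripiprazole_sot.daily_drug_cost",
           "unit_costs.hospital_day", "unit_costs.ambulatory_care_centre",
           "unit_costs.nutritionist_visit",
           "strategies.olanzapine_sot.ae_probs.eps",
           "strategies.olanzapine_sot.adherence.p_compliant"],
    )[0]

    def _oat_oracle(self, params, threshold):
        """Brute-force one-at-a-time screening at the same threshold."""
        f = params.config.owsa_range_fraction

        def metric(p):
            return (evaluate_name(self.COMPARISON[0], p).mean_cost
                    + evaluate_name(self.COMPARISON[1], p).mean_cost)

        base = metric(params)
        out = []
        for pid in self.IDS:
            direction = -1.0 if ".adherence.p_compliant" in pid else 1.0
            q = params.copy()
            set_param(q, pid, get_param(params, pid) * (1 + direction * f))
            eff = abs(metric(q) - base)
            if eff > threshold:
                out.append((pid, eff))
        return sorted(out, key=lambda t: (-t[1], t[0]))

    @pytest.mark.parametrize("threshold", [0.0, 100.0, 500.0])
    def test_matches_one_at_a_time_oracle(self, params, threshold):
        got = screen_parameters(params, self.COMPARISON, threshold,
                                parameter_ids=self.IDS)
        expected = self._oat_oracle(params, threshold)
        assert [g[0] for g in got] == [e[0] for e in expected]
        assert [g[1] for g in got] == pytest.approx([e[1] for e in expected])

    def test_unreachable_threshold_empties_shortlist(self, params):
        assert screen_parameters(params, self.COMPARISON, 1e12,
                                 parameter_ids=self.IDS) == []

    def test_zero_threshold_drops_only_zero_effect_parameters(self, params):
        got = dict(screen_parameters(params, self.COMPARISON, 0.0,
                                     parameter_ids=self.IDS))
        # utilities and out-of-comparison parameters have no cost effect
        assert "utilities.non.stable" not in got
        assert "strategies.aripiprazole_sot.daily_drug_cost" not in got
        assert "unit_costs.hospital_day" in got
        assert "strategies.olanzapine_odt.daily_drug_cost" in got


class TestPSADraws:
    def test_zero_se_returns_base_values(self, params):
        p = params.copy()
        p.config.psa_se_fraction_prob = 0.0
        p.config.psa_se_fraction_cost = 0.0
        rng = np.random.default_rng(0)
        drawn = psa_draw_parameters(p, rng)
        assert drawn == p

    def test_draws_always_valid(self, params):
        rng = np.random.default_rng(123)
        for _ in range(50):
            drawn = psa_draw_parameters(params, rng)
            assert validate_parameters(drawn).ok

    def test_beta_moments(self):
        """Method-of-moments beta: sample mean within 3 SEs of the target."""
        rng = np.random.default_rng(7)
        mean, se = 0.23, 0.023
        draws = np.array([_draw_beta(rng, mean, se) for _ in range(10_000)])
        assert abs(draws.mean() - mean) <= 3 * se / np.sqrt(10_000)
        assert draws.std() == pytest.approx(se, rel=0.1)

    def test_formulations_share_clinical_draws(self, params):
        """ODT and SOT arms of one molecule share relapse/AE draws (the
        model treats them as the same clinical parameters)."""
        rng = np.random.default_rng(5)
        drawn = psa_draw_parameters(params, rng)
        odt = drawn.strategy("olanzapine_odt")
        sot = drawn.strategy("olanzapine_sot")
        assert odt.p_relapse_hosp == sot.p_relapse_hosp
        assert odt.ae_probs == sot.ae_probs
        # adherence and drug cost remain formulation-specific
        assert odt.daily_drug_cost != sot.daily_drug_cost


class TestRunPSA:
    def test_degenerate_psa_collapses_to_base_case(self, params):
        p = params.copy()
        p.config.psa_se_fraction_prob = 0.0
        p.config.psa_se_fraction_cost = 0.0
        res = run_psa(p, ["olanzapine_odt", "risperidone_sot"],
                      n_iterations=1, seed=9)
        base = evaluate_expected(p.strategy("olanzapine_odt"), p)
        row = res.draws[res.draws.strategy == "olanzapine_odt"].iloc[0]
        assert row.cost == pytest.approx(base.mean_cost)
        assert row.qaly == pytest.approx(base.mean_qaly)

    def test_ceac_normalized_and_bounded(self, params):
        res = run_psa(params, params.strategy_names[:3], n_iterations=40,
                      seed=2)
        for wtp, sub in res.ceac.groupby("wtp"):
            probs = sub["probability"].to_numpy()
            assert ((probs >= 0) & (probs <= 1)).all()
            assert probs.sum() == pytest.approx(1.0)

    def test_wtp_grid_contains_threshold(self, params):
        grid = default_wtp_grid(params)
        assert params.config.wtp in grid
        res = run_psa(params, ["olanzapine_odt", "olanzapine_sot"],
                      n_iterations=5, seed=3)
        assert (res.ceac["wtp"] == params.config.wtp).any()

    def test_seeded_reproducibility(self, params):
        a = run_psa(params, ["olanzapine_odt", "olanzapine_sot"],
                    n_iterations=25, seed=11)
        b = run_psa(params, ["olanzapine_odt", "olanzapine_sot"],
                    n_iterations=25, seed=11)
        assert a.draws.equals(b.draws)
        assert a.ceac.equals(b.ceac)

    def test_converges_to_base_case_as_se_shrinks(self, params):
        """PSA means approach the deterministic base case as spreads -> 0."""
        base = evaluate_expected(params.strategy("olanzapine_odt"), params)
        errs = []
        for f in (0.10, 0.03, 0.01):
            p = params.copy()
            p.config.psa_se_fraction_prob = f
            p.config.psa_se_fraction_cost = 2 * f
            res = run_psa(p, ["olanzapine_odt"], n_iterations=60, seed=4)
            sub = res.draws[res.draws.strategy == "olanzapine_odt"]
            errs.append(abs(sub.cost.mean() - base.mean_cost)
                        + 1e5 * abs(sub.qaly.mean() - base.mean_qaly))
        assert errs[2] < errs[0]
        assert errs[2] < errs[1] * 2  # monotone up to Monte Carlo noise
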