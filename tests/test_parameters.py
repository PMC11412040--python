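"""Input tables: fixture coverage, validation, and round-trip serialization."""

import pytest

from odtcea.parameters import (
    AE_TYPES,
    CATEGORIES,
    STATES,
    USAGE_COLUMNS,
    ParameterError,
    load_parameters,
    save_parameters,
    validate_parameters,
)

# Printed input tables, enumerated cell by cell (percent / MAD as printed).
ADHERENCE = {  # medication -> (compliant, partial, non) %
    "olanzapine_sot": (23, 43, 34),
    "risperidone_sot": (21, 39, 40),
    "aripiprazole_sot": (19, 35, 46),
    "olanzapine_odt": (37, 29, 34),
    "risperidone_odt": (35, 25, 40),
    "aripiprazole_odt": (33, 21, 46),
}
RELAPSE_HOSP = {  # % per cycle, (compliant, partial, non)
    "olanzapine_sot": (2, 4, 5), "risperidone_sot": (4, 6, 9),
    "aripiprazole_sot": (5, 9, 12), "olanzapine_odt": (2, 4, 5),
    "risperidone_odt": (4, 6, 9), "aripiprazole_odt": (5, 9, 12),
}
RELAPSE_OUTPT = {
    "olanzapine_sot": (2, 3, 5), "risperidone_sot": (4, 6, 9),
    "aripiprazole_sot": (5, 8, 11), "olanzapine_odt": (2, 3, 5),
    "risperidone_odt": (4, 6, 9), "aripiprazole_odt": (5, 8, 11),
}
ADVERSE = {  # (EPS, weight gain, diabetes) %
    "olanzapine_sot": (16, 30, 3), "risperidone_sot": (25, 14, 3),
    "aripiprazole_sot": (2, 17, 2), "olanzapine_odt": (16, 30, 3),
    "risperidone_odt": (25, 14, 3), "aripiprazole_odt": (2, 17, 2),
}
UTILITIES = {  # state -> (compliant, partial, non)
    "stable": (0.88, 0.75, 0.75),
    "relapse_outpt": (0.74, 0.63, 0.63),
    "relapse_hosp": (0.53, 0.53, 0.42),
}
DRUG_COSTS = {  # MAD / day
    "olanzapine_sot": 9.7, "risperidone_sot": 9.6, "aripiprazole_sot": 10.6,
    "olanzapine_odt": 11.0, "risperidone_odt": 19.4, "aripiprazole_odt": 13.7,
}
RESOURCE_USE = {  # resource -> (stable/mo, outpt/ev, hosp/ev, eps/ev, wg/ev)
    "hospital_day": (0, 0, 11.7, 0, 0),
    "ambulatory_care_centre": (0, 1.25, 1.25, 0, 0),
    "emergency_department": (0, 1, 1, 0, 0),
    "doctor_visit": (1, 1, 1, 1, 0.5),
    "psychiatric_clinic_visit": (1.5, 2, 2, 1, 2.5),
    "home_care_hour": (0, 2.75, 2.75, 0, 0),
    "group_counselling_hour": (0.5, 1.5, 1.5, 0, 5),
    "nutritionist_visit": (0, 0, 0, 0, 2.5),
}
UNIT_COSTS = {  # MAD / unit
    "hospital_day": 1058.30, "ambulatory_care_centre": 5220.42,
    "emergency_department": 550.00, "extra_admission_day": 265.00,
    "doctor_visit": 571, "psychiatric_clinic_visit": 550,
    "home_care_hour": 854, "group_counselling_hour": 740,
    "nutritionist_visit": 250, "other_medication": 229,
}


def test_builtin_set_is_valid(params):
    assert validate_parameters(params).ok


def test_fixture_covers_every_printed_cell(params):
    """Each numeric cell of the published input tables appears exactly once
    in the fixture: 6x3 adherence, 6x3x2 relapse, 6x3 adverse events,
    3x3 utilities, 6 drug costs, 8x5 resource quantities, 10 unit costs."""
    assert set(params.strategy_names) == set(ADHERENCE)
    for s in params.strategies:
        c, p, n = ADHERENCE[s.name]
        assert s.adherence.p_compliant == pytest.approx(c / 100)
        assert s.adherence.p_partial == pytest.approx(p / 100)
        assert s.adherence.p_non == pytest.approx(n / 100)
        for i, cat in enumerate(CATEGORIES):
            assert s.p_relapse_hosp[cat] == pytest.approx(RELAPSE_HOSP[s.name][i] / 100)
            assert s.p_relapse_outpt[cat] == pytest.approx(RELAPSE_OUTPT[s.name][i] / 100)
        for i, ae in enumerate(AE_TYPES):
            assert s.ae_probs[ae] == pytest.approx(ADVERSE[s.name][i] / 100)
        assert s.daily_drug_cost == pytest.approx(DRUG_COSTS[s.name])
    for state, row in UTILITIES.items():
        for cat, val in zip(CATEGORIES, row):
            assert params.utilities.value(cat, state) == pytest.approx(val)
    for res, row in RESOURCE_USE.items():
        for col, val in zip(USAGE_COLUMNS, row):
            assert params.resource_use.get(res, col) == pytest.approx(val)
    assert params.unit_costs.cost_per_unit == pytest.approx(UNIT_COSTS)


def test_group_definitions_cover_formulation_pairs(params):
    assert params.group_definitions == {
        "olanzapine": ["olanzapine_odt", "olanzapine_sot"],
        "risperidone": ["risperidone_odt", "risperidone_sot"],
        "aripiprazole": ["aripiprazole_odt", "aripiprazole_sot"],
    }


def test_save_load_round_trip(params, tmp_path):
    yaml_path = save_parameters(params, tmp_path / "bundle")
    reloaded = load_parameters(yaml_path)
    assert reloaded == params


def test_round_trip_preserves_synthetic_sets(tmp_path):
    from odtcea.synthetic_data import SyntheticSpec, generate_parameter_set

    generated, _ = generate_parameter_set(SyntheticSpec(seed=5))
    reloaded = load_parameters(save_parameters(generated, tmp_path))
    assert len(reloaded.strategies) == len(generated.strategies)
    for a, b in zip(reloaded.strategies, generated.strategies):
        assert a.name == b.name
        assert a.daily_drug_cost == pytest.approx(b.daily_drug_cost)
        for cat in CATEGORIES:
            assert a.p_relapse_hosp[cat] == pytest.approx(b.p_relapse_hosp[cat])


def test_load_rejects_invalid_adherence(params, tmp_path):
    save_parameters(params, tmp_path)
    text = (tmp_path / "adherence.csv").read_text().splitlines()
    text[1] = "olanzapine_sot,50,50,50"
    (tmp_path / "adherence.csv").write_text("\n".join(text) + "\n")
    with pytest.raises(ParameterError, match="sum to 1"):
        load_parameters(tmp_path)


def test_load_reports_missing_table(params, tmp_path):
    save_parameters(params, tmp_path)
    (tmp_path / "resources.csv").unlink()
    with pytest.raises(ParameterError, match="resources"):
        load_parameters(tmp_path)


def test_load_reports_malformed_number_with_position(params, tmp_path):
    save_parameters(params, tmp_path)
    text = (tmp_path / "utilities.csv").read_text().replace("0.53", "oops", 1)
    (tmp_path / "utilities.csv").write_text(text)
    with pytest.raises(ParameterError, match=r"row|column"):
        load_parameters(tmp_path)


def test_load_rejects_unknown_keys(params, tmp_path):
    yaml_path = save_parameters(params, tmp_path)
    yaml_path.write_text(yaml_path.read_text() + "\nbogus_section: 1\n")
    with pytest.raises(ParameterError, match="bogus_section"):
        load_parameters(tmp_path)


@pytest.mark.parametrize("mutate, code", [
    (lambda p: p.utilities.u.__setitem__(("compliant", "stable"), 1.2),
     "UTILITY_RANGE"),
    (lambda p: p.strategy("olanzapine_sot").p_relapse_hosp.__setitem__(
        "partial", 0.6) or p.strategy("olanzapine_sot").p_relapse_outpt
     .__setitem__("partial", 0.5), "COMPETING_RISK_SUM"),
    (lambda p: setattr(p.strategy("olanzapine_sot").adherence, "p_non", 0.9),
     "ADHERENCE_SUM"),
    (lambda p: p.strategy("olanzapine_sot").adherence.mpr_by_category
     .__setitem__("non", 0.95), "MPR_ORDER"),
    (lambda p: p.utilities.u.__setitem__(("non", "stable"), 0.1),
     "UTILITY_ORDER"),
    (lambda p: p.unit_costs.cost_per_unit.pop("doctor_visit"),
     "MISSING_UNIT_COST"),
    (lambda p: setattr(p.strategy("olanzapine_odt"), "daily_drug_cost", -1.0),
     "DRUG_COST_NEGATIVE"),
    (lambda p: p.resource_use.quantity.__setitem__(
        ("hospital_day", "stable_per_month"), 2.0), "HOSP_QUANTITY_COLUMN"),
])
def test_validate_flags_each_invariant_breach(fresh_params, mutate, code):
    mutate(fresh_params)
    assert code in validate_parameters(fresh_params).codes()


def test_violations_are_data_not_exceptions(fresh_params):
    fresh_params.utilities.u[("compliant", "stable")] = 1.5
    fresh_params.strategy("olanzapine_sot").daily_drug_cost = -3
    report = validate_parameters(fresh_params)
    assert not report.ok and len(report) >= 2
    for v in report:
        assert v.code and v.path and v.message
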