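"""Rule compilation, scoring arithmetic and report rendering."""

import pytest

from helpers import brute_force_checks
from oncoharmonizer import (
    QualityReport,
    aggregate_report,
    compile_rules,
    generate_cohort,
    inject_errors,
    render_report,
    round_half_up,
    run_qc,
    score_dimension,
)
from oncoharmonizer.dictionary_model import (
    OntologyCoding,
    SchemaDefinition,
    ValueSetEntry,
    VariableDefinition,
)
from oncoharmonizer.errors import ConfigurationError
from oncoharmonizer.qc_engine import DimensionTally, RULE_DIMENSION
from oncoharmonizer.terminology import SNOMED_CT

REFERENCE_TALLIES = [
    ("Completeness", "minimal_req", 2, 16, 50),
    ("Completeness", "mandatory_req", 3, 32, 10),
    ("Conformance", "length", 1, 10, 10),
    ("Conformance", "datatype", 0, 40, 10),
    ("Conformance", "permissible", 3, 52, 10),
    ("Plausibility", "range", 1, 3, 10),
]


def _tiny_schema(**var_kwargs):
    defaults = dict(
        name="v", requirement_level="minimal", datatype="code",
        resource_kind="Observation", element_path="Observation.valueCodeableConcept",
        value_set=[ValueSetEntry(internal_code="1",
                                 coding=OntologyCoding(system=SNOMED_CT, code="111"))],
    )
    defaults.update(var_kwargs)
    return SchemaDefinition(
        schema_id="t",
        variables=[
            VariableDefinition(name="patient_id", identifier=True, datatype="string",
                               resource_kind="Patient", element_path="Patient.identifier"),
            VariableDefinition(**defaults),
        ],
    )


def test_minimal_coded_variable_rule_set():
    # a coded variable's type conformance is subsumed by the
    # permissible-value check, so no separate datatype rule is compiled
    rules = compile_rules(_tiny_schema())
    assert {(r.rule_type, r.variable) for r in rules} == {
        ("minimal_req", "v"), ("mandatory_req", "v"), ("permissible", "v"),
    }


def test_recommended_decimal_with_range_rule_set():
    schema = _tiny_schema(requirement_level="recommended", datatype="decimal",
                          value_set=[], range=(0, 10),
                          element_path="Observation.valueQuantity")
    rules = compile_rules(schema)
    assert {(r.rule_type, r.variable) for r in rules} == {
        ("datatype", "v"), ("range", "v"),
    }


def test_demo_schema_rule_count_matches_hand_tally(demo_schema):
    # hand tally over the 12 data variables of the demo dictionary:
    # 4 minimal + 8 mandatory(incl. minimal) + 6 permissible +
    # 5 datatype (2 int, 1 dec, 2 interval) + 1 length + 3 range
    rules = compile_rules(demo_schema)
    by_type = {}
    for r in rules:
        by_type[r.rule_type] = by_type.get(r.rule_type, 0) + 1
    assert by_type == {
        "minimal_req": 4, "mandatory_req": 8, "permissible": 6,
        "datatype": 5, "length": 1, "range": 3,
    }


@pytest.mark.parametrize(
    "fail,pass_,weight,expected",
    [
        (2, 16, 50, 44.44),
        (3, 32, 10, 9.14),
        (1, 10, 10, 9.09),
        (0, 40, 10, 10.00),
        (3, 52, 10, 9.45),
        (1, 3, 10, 7.50),
        (0, 0, 10, 10.00),  # vacuous pass: absent defect class keeps full weight
    ],
)
def test_score_dimension_rows(fail, pass_, weight, expected):
    assert round_half_up(score_dimension(fail, pass_, weight)) == expected


def test_aggregate_uses_unrounded_terms():
    tallies = [DimensionTally(d, rt, f, p, w) for d, rt, f, p, w in REFERENCE_TALLIES]
    report = aggregate_report(tallies)
    # the rounded row scores sum to 89.62; only unrounded aggregation
    # followed by display rounding yields 89.63
    assert round_half_up(report.total_score) == 89.63
    assert (report.total_fail, report.total_pass, report.total_checks) == (10, 153, 163)


def test_aggregate_rejects_bad_weight_sum():
    with pytest.raises(ConfigurationError):
        aggregate_report([DimensionTally("Plausibility", "range", 0, 5, 60)])


def test_aggregate_single_full_weight_tally():
    report = aggregate_report([DimensionTally("Plausibility", "range", 0, 7, 100)])
    assert round_half_up(report.total_score) == 100.00


def test_aggregate_matches_brute_force_summation():
    import random

    rng = random.Random(4)
    rows = [(d, rt, rng.randint(0, 5), rng.randint(1, 60)) for d, rt, *_ in REFERENCE_TALLIES]
    weights = [50, 10, 10, 10, 10, 10]
    tallies = [DimensionTally(d, rt, f, p, w)
               for (d, rt, f, p), w in zip(rows, weights)]
    report = aggregate_report(tallies)
    naive = sum(w * p / (f + p) for (_, _, f, p), w in zip(rows, weights))
    assert report.total_score == pytest.approx(naive)


def test_render_report_reference_layout():
    report = aggregate_report(
        [DimensionTally(d, rt, f, p, w) for d, rt, f, p, w in REFERENCE_TALLIES]
    )
    text = render_report(report)
    for token in ["44.44%", "9.14%", "9.09%", "10.00%", "9.45%", "7.50%", "89.63%"]:
        assert token in text
    header, *rows = text.splitlines()
    assert header.split()[:2] == ["Dimension", "Type"]
    assert rows[-1].startswith("Total:")


def test_report_json_round_trip():
    report = aggregate_report(
        [DimensionTally(d, rt, f, p, w) for d, rt, f, p, w in REFERENCE_TALLIES]
    )
    again = QualityReport.from_dict(report.to_dict())
    assert again.to_dict() == report.to_dict()


def test_clean_cohort_scores_100(demo_schema):
    records = generate_cohort(demo_schema, 10, seed=2)
    report = run_qc(records, compile_rules(demo_schema))
    assert report.total_fail == 0
    assert round_half_up(report.total_score) == 100.00


def test_single_missing_minimal_cell_isolated(demo_schema):
    records = generate_cohort(demo_schema, 4, seed=3)
    records, _ = inject_errors(records, {"minimal_req": 1}, demo_schema, seed=0)
    report = run_qc(records, compile_rules(demo_schema))
    fails = {t.rule_type: t.fail for t in report.tallies}
    # the blank also fails the mandatory check (minimal is a fortiori
    # mandatory) but never leaks into conformance or plausibility
    assert fails == {"minimal_req": 1, "mandatory_req": 1, "length": 0,
                     "datatype": 0, "permissible": 0, "range": 0}


def test_missing_weight_configuration_errors(demo_schema):
    records = generate_cohort(demo_schema, 2, seed=0)
    with pytest.raises(ConfigurationError):
        run_qc(records, compile_rules(demo_schema), weights={"minimal_req": 100})


def test_engine_equals_brute_force_oracle(demo_schema):
    records = generate_cohort(demo_schema, 30, seed=6)
    records, _ = inject_errors(
        records, {"minimal_req": 3, "permissible": 4, "range": 2, "datatype": 2, "length": 1},
        demo_schema, seed=7,
    )
    report = run_qc(records, compile_rules(demo_schema))
    engine = {(f.patient_id, f.variable, f.rule_type, f.outcome) for f in report.findings}
    assert engine == brute_force_checks(records, demo_schema)


def test_monotonicity_fail_to_pass_never_decreases_score():
    for d, rt, f, p, w in REFERENCE_TALLIES:
        if f == 0:
            continue
        before = aggregate_report(
            [DimensionTally(a, b, x, y, z) for a, b, x, y, z in REFERENCE_TALLIES]
        ).total_score
        improved = [
            (a, b, x - 1 if b == rt else x, y + 1 if b == rt else y, z)
            for a, b, x, y, z in REFERENCE_TALLIES
        ]
        after = aggregate_report(
            [DimensionTally(a, b, x, y, z) for a, b, x, y, z in improved]
        ).total_score
        assert after >= before


def test_total_score_bounds_and_zero_fail_equivalence(demo_schema):
    records = generate_cohort(demo_schema, 12, seed=8)
    dirty, _ = inject_errors(records, {"permissible": 2}, demo_schema, seed=1)
    for cohort in (records, dirty):
        report = run_qc(cohort, compile_rules(demo_schema))
        assert 0 <= report.total_score <= 100 + 1e-9
        assert (report.total_fail == 0) == (round_half_up(report.total_score) == 100.00)


def test_record_level_scores_present(demo_schema):
    records = generate_cohort(demo_schema, 3, seed=1)
    report = run_qc(records, compile_rules(demo_schema))
    assert set(report.record_scores) == {r.patient_id for r in records}
    for per_dim in report.record_scores.values():
        assert set(per_dim) == set(RULE_DIMENSION.values())
        assert all(v == pytest.approx(sum(
            w for rt, w in
            [("minimal_req", 50), ("mandatory_req", 10), ("length", 10),
             ("datatype", 10), ("permissible", 10), ("range", 10)]
            if RULE_DIMENSION[rt] == dim
        )) for dim, v in per_dim.items())
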