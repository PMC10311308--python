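import json

import pytest

from mvntrap.formats import (
    BmaExpression,
    ModelParseError,
    QualTermList,
    eval_bma,
    export_sbml_qual,
    load_model,
    normalize_level,
    parse_bma,
    parse_bma_expression,
    parse_sbml_qual,
    terms_to_series,
)
from mvntrap.model import MVN, parse_native
from mvntrap.series import check_partition, series_from_table

MINIMAL_QUAL = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1"
      level="3" version="1" qual:required="true">
 <model id="m">
  <qual:listOfQualitativeSpecies>
   <qual:qualitativeSpecies qual:id="a" qual:maxLevel="1" qual:constant="false"/>
   <qual:qualitativeSpecies qual:id="b" qual:maxLevel="2" qual:constant="false"/>
  </qual:listOfQualitativeSpecies>
  <qual:listOfTransitions>
   <qual:transition qual:id="t_b">
    <qual:listOfOutputs>
     <qual:output qual:qualitativeSpecies="b" qual:transitionEffect="assignmentLevel"/>
    </qual:listOfOutputs>
    <qual:listOfFunctionTerms>
     <qual:defaultTerm qual:resultLevel="0"/>
     <qual:functionTerm qual:resultLevel="2">
      <math xmlns="http://www.w3.org/1998/Math/MathML">
       <apply><and/>
        <apply><eq/><ci>a</ci><cn type="integer">1</cn></apply>
        <apply><geq/><ci>b</ci><cn type="integer">1</cn></apply>
       </apply>
      </math>
     </qual:functionTerm>
    </qual:listOfFunctionTerms>
   </qual:transition>
  </qual:listOfTransitions>
 </model>
</sbml>
"""


class TestParseSbmlQual:
    def test_domains_and_terms(self):
        mvn, terms = parse_sbml_qual(MINIMAL_QUAL)
        assert mvn.variables == ("a", "b")
        assert dict(mvn.domains) == {"a": (0, 1), "b": (0, 2)}
        assert terms["b"].default_level == 0
        # b jumps to 2 exactly when a=1 and b>=1
        assert mvn.functions["b"]((1, 1)) == 2
        assert mvn.functions["b"]((1, 0)) == 0
        assert mvn.functions["b"]((0, 2)) == 0

    def test_species_without_transition_keeps_its_value(self):
        mvn, _ = parse_sbml_qual(MINIMAL_QUAL)
        assert all(mvn.functions["a"](x) == x[0] for x in mvn.states())

    def test_result_level_above_max_rejected(self):
        bad = MINIMAL_QUAL.replace('qual:resultLevel="2"', 'qual:resultLevel="9"')
        with pytest.raises(ModelParseError, match="maxLevel"):
            parse_sbml_qual(bad)

    def test_missing_max_level_rejected(self):
        bad = MINIMAL_QUAL.replace(' qual:maxLevel="2"', "")
        with pytest.raises(ModelParseError, match="maxLevel"):
            parse_sbml_qual(bad)

    def test_unsupported_mathml_names_the_species(self):
        bad = MINIMAL_QUAL.replace("<and/>", "<csymbol/>")
        with pytest.raises(ModelParseError, match="'b'"):
            parse_sbml_qual(bad)


class TestTermsToSeries:
    @staticmethod
    def _boolean_var():
        return parse_native("v: 0..1\nv(0) = 0\nv(1) = 1\n")

    def test_single_term_with_default_gives_two_entries(self):
        mvn = self._boolean_var()
        terms = QualTermList(0, ((1, ("cmp", "eq", "v", 1)),))
        series = terms_to_series(terms, mvn, "v")
        assert [lvl for lvl, _ in series.entries] == [0, 1]
        assert check_partition(series)

    def test_overlapping_terms_first_listed_wins(self):
        mvn = self._boolean_var()
        terms = QualTermList(
            0,
            ((1, ("cmp", "geq", "v", 0)), (0, ("cmp", "eq", "v", 1))),
        )
        series = terms_to_series(terms, mvn, "v")
        for x in mvn.states():
            assert series.evaluate(mvn, x) == 1

    def test_exhaustive_terms_leave_no_default_entry(self):
        mvn = self._boolean_var()
        terms = QualTermList(
            0, ((1, ("cmp", "eq", "v", 0)), (1, ("cmp", "eq", "v", 1)))
        )
        series = terms_to_series(terms, mvn, "v")
        assert [lvl for lvl, _ in series.entries] == [1]


class TestRoundTrips:
    def test_sbml_export_reparse_is_table_identical(self, example):
        series = {v: series_from_table(example, v) for v in example.variables}
        back, _ = parse_sbml_qual(export_sbml_qual(example, series))
        for v in example.variables:
            assert back.function_table(v) == example.function_table(v)

    def test_parse_export_parse_is_a_fixed_point(self):
        mvn, _ = parse_sbml_qual(MINIMAL_QUAL)
        series = {v: series_from_table(mvn, v) for v in mvn.variables}
        once = export_sbml_qual(mvn, series)
        again, _ = parse_sbml_qual(once)
        series2 = {v: series_from_table(again, v) for v in again.variables}
        final, _ = parse_sbml_qual(export_sbml_qual(again, series2))
        for v in mvn.variables:
            assert final.function_table(v) == mvn.function_table(v)

    def test_bma_to_sbml_preserves_tables(self):
        bma = json.dumps(
            {
                "Model": {
                    "Variables": [
                        {"Id": 1, "Name": "x", "RangeFrom": 0, "RangeTo": 2,
                         "Formula": "2 - var(x)"},
                    ],
                    "Relationships": [],
                }
            }
        )
        mvn, _ = parse_bma(bma)
        series = {v: series_from_table(mvn, v) for v in mvn.variables}
        back, _ = parse_sbml_qual(export_sbml_qual(mvn, series))
        for v in mvn.variables:
            assert back.function_table(v) == mvn.function_table(v)

    def test_constant_function_exports_single_default_term(self):
        mvn = parse_native("a: 0..2\na(*) = 1\n")
        series = {"a": series_from_table(mvn, "a")}
        xml = export_sbml_qual(mvn, series)
        assert xml.count("functionTerm") == 0  # default term only
        back, _ = parse_sbml_qual(xml)
        assert back.function_table("a") == mvn.function_table("a")


class TestNormalizeLevel:
    def test_printed_examples(self):
        assert normalize_level(2, (0, 4), (0, 2)) == 1
        assert normalize_level(3, (0, 4), (0, 2)) == 2  # 1.5 rounds half-up

    def test_endpoints_map_exactly(self):
        for src, tgt in [((0, 4), (0, 2)), ((1, 3), (0, 7)), ((0, 2), (0, 2))]:
            assert normalize_level(src[0], src, tgt) == tgt[0]
            assert normalize_level(src[1], src, tgt) == tgt[1]

    def test_degenerate_source_maps_to_target_lo(self):
        assert normalize_level(3, (3, 3), (0, 5)) == 0

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            normalize_level(9, (0, 4), (0, 2))


class TestParseBma:
    def test_constant_formula(self):
        mvn, _ = parse_bma(json.dumps({
            "Model": {"Variables": [
                {"Id": 1, "Name": "x", "RangeFrom": 0, "RangeTo": 2,
                 "Formula": "2"}], "Relationships": []}}))
        assert all(y == 2 for y in mvn.function_table("x").values())

    def test_normalized_input_table(self):
        mvn, _ = parse_bma(json.dumps({
            "Model": {"Variables": [
                {"Id": 1, "Name": "a", "RangeFrom": 0, "RangeTo": 4,
                 "Formula": "0"},
                {"Id": 2, "Name": "b", "RangeFrom": 0, "RangeTo": 2,
                 "Formula": "var(a)"}], "Relationships": []}}))
        by_a = {x[0]: y for x, y in mvn.function_table("b").items() if x[1] == 0}
        assert by_a == {0: 0, 1: 1, 2: 1, 3: 2, 4: 2}

    def test_default_function_is_activator_minus_inhibitor_average(self):
        mvn, _ = parse_bma(json.dumps({
            "Model": {"Variables": [
                {"Id": 1, "Name": "act", "RangeFrom": 0, "RangeTo": 2,
                 "Formula": "2"},
                {"Id": 2, "Name": "inh", "RangeFrom": 0, "RangeTo": 2,
                 "Formula": "0"},
                {"Id": 3, "Name": "out", "RangeFrom": 0, "RangeTo": 2,
                 "Formula": ""}],
             "Relationships": [
                {"Id": 10, "FromVariable": 1, "ToVariable": 3,
                 "Type": "Activator"},
                {"Id": 11, "FromVariable": 2, "ToVariable": 3,
                 "Type": "Inhibitor"}]}}))
        # out(act, inh, out): avg(act) - avg(inh)
        assert mvn.functions["out"]((2, 0, 0)) == 2
        assert mvn.functions["out"]((2, 2, 0)) == 0
        assert mvn.functions["out"]((1, 0, 0)) == 1

    def test_malformed_json_rejected(self):
        with pytest.raises(ModelParseError, match="JSON"):
            parse_bma("{not json")

    def test_empty_range_rejected(self):
        with pytest.raises(ModelParseError, match="range"):
            parse_bma(json.dumps({
                "Model": {"Variables": [
                    {"Id": 1, "Name": "x", "RangeFrom": 2, "RangeTo": 0,
                     "Formula": "0"}], "Relationships": []}}))

    def test_unknown_variable_reference_rejected(self):
        with pytest.raises(ModelParseError, match="unknown"):
            parse_bma(json.dumps({
                "Model": {"Variables": [
                    {"Id": 1, "Name": "x", "RangeFrom": 0, "RangeTo": 1,
                     "Formula": "var(ghost)"}], "Relationships": []}}))

    def test_bma_xml_layout(self):
        xml = """<AnalysisInput>
          <Variables>
            <Variable Id="1"><Name>x</Name><RangeFrom>0</RangeFrom>
              <RangeTo>1</RangeTo><Function>1 - var(x)</Function></Variable>
          </Variables>
          <Relationships/>
        </AnalysisInput>"""
        mvn, _ = parse_bma(xml)
        assert mvn.function_table("x") == {(0,): 1, (1,): 0}


class TestEvalBma:
    @staticmethod
    def _two_var():
        return parse_native(
            "v1: 0..2\nv2: 0..2\n"
            + "".join(f"v1({a},{b}) = 0\nv2({a},{b}) = 0\n"
                      for a in range(3) for b in range(3))
        )

    def test_average_then_round(self):
        mvn = self._two_var()
        expr = parse_bma_expression("avg(v1, v2)")
        assert eval_bma(expr, (2, 0), "v1", mvn) == 1

    def test_negative_result_clamps_to_lo(self):
        mvn = self._two_var()
        expr = parse_bma_expression("v1 - v2")
        assert eval_bma(expr, (0, 2), "v1", mvn) == 0

    def test_constant_beyond_hi_clamps(self):
        mvn = self._two_var()
        assert eval_bma(parse_bma_expression("9"), (0, 0), "v1", mvn) == 2

    def test_division_by_zero_clamps_to_lo_with_warning(self):
        mvn = self._two_var()
        expr = parse_bma_expression("2 / v2")
        with pytest.warns(UserWarning, match="division"):
            assert eval_bma(expr, (0, 0), "v1", mvn) == 0

    def test_syntactic_zero_division_rejected_at_parse(self):
        with pytest.raises(ModelParseError, match="zero"):
            parse_bma_expression("1 / 0")

    def test_ceil_floor_min_max(self):
        mvn = self._two_var()
        assert eval_bma(parse_bma_expression("ceil(v1 / 2)"), (1, 0), "v1", mvn) == 1
        assert eval_bma(parse_bma_expression("floor(v1 / 2)"), (1, 0), "v1", mvn) == 0
        assert eval_bma(parse_bma_expression("min(v1, v2)"), (2, 1), "v1", mvn) == 1
        assert eval_bma(parse_bma_expression("max(v1, v2)"), (2, 1), "v1", mvn) == 2


class TestLoadModel:
    def test_sniffing_by_extension_and_content(self, tmp_path, example):
        from mvntrap.model import format_native

        native = tmp_path / "m.mvn"
        native.write_text(format_native(example))
        assert load_model(native).variables == example.variables

        sbml = tmp_path / "m.sbml"
        series = {v: series_from_table(example, v) for v in example.variables}
        sbml.write_text(export_sbml_qual(example, series))
        assert load_model(sbml).variables == example.variables

        bma = tmp_path / "m.json"
        bma.write_text(json.dumps({
            "Model": {"Variables": [
                {"Id": 1, "Name": "x", "RangeFrom": 0, "RangeTo": 1,
                 "Formula": "0"}], "Relationships": []}}))
        assert load_model(bma).variables == ("x",)

    def test_unknown_format_rejected(self, tmp_path):
        f = tmp_path / "m.mvn"
        f.write_text("a: 0..1\na(*) = 0\n")
        with pytest.raises(ModelParseError):
            load_model(f, fmt="bogus")
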