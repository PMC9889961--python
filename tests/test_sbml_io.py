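"""SBML subset reading, writing and structural validation."""

from __future__ import annotations

import pytest

from hybkit.expressions import parse_infix
from hybkit.fixtures import TOY_KINDS, make_toy_model
from hybkit.hmod import serialize_hmod
from hybkit.model import AssignmentRule, Parameter
from hybkit.sbml import SbmlError, read_sbml, validate_sbml_structure, write_sbml

NS = "http://www.sbml.org/sbml/level3/version2/core"

MINIMAL = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="{NS}" level="3" version="2">
 <model id="mini">
  <listOfCompartments><compartment id="cell" size="1" constant="true"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="cell" initialConcentration="1.0"
            hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
  </listOfSpecies>
  <listOfParameters><parameter id="k" value="0.5" constant="true"/></listOfParameters>
  <listOfReactions>
   <reaction id="decay" reversible="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>k</ci><ci>A</ci></apply></math></kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


class TestReadSbml:
    def test_minimal_document_maps_directly(self):
        m, rep = read_sbml(MINIMAL)
        assert rep.is_empty()
        assert m.species_ids() == ["A"]
        assert m.get_species("A").initial_concentration == 1.0
        assert m.get_parameter("k").value == 0.5
        assert m.get_reaction("decay").kinetic_law == parse_infix("k*A")

    def test_event_is_warned_and_dropped(self):
        xml = MINIMAL.replace("</model>", "<listOfEvents><event/></listOfEvents></model>")
        m, rep = read_sbml(xml)
        assert m.species_ids() == ["A"]
        assert rep.codes() == {"UNSUPPORTED_DROPPED"}
        assert not rep.has_errors()

    def test_initial_amount_converts_via_compartment_size(self):
        xml = (MINIMAL.replace('size="1"', 'size="2.0"')
               .replace('initialConcentration="1.0"', 'initialAmount="4.0"'))
        m, _ = read_sbml(xml)
        assert m.get_species("A").initial_concentration == 2.0

    def test_local_parameters_are_hoisted_and_renamed(self):
        xml = MINIMAL.replace(
            "<kineticLaw>",
            '<kineticLaw><listOfLocalParameters>'
            '<localParameter id="k" value="0.25"/></listOfLocalParameters>')
        m, rep = read_sbml(xml)
        assert rep.is_empty()
        assert "decay__k" in m.parameter_ids()
        assert m.get_parameter("decay__k").value == 0.25
        assert m.get_reaction("decay").kinetic_law == parse_infix("decay__k*A")

    def test_level2_document_reads(self):
        xml = MINIMAL.replace(NS, "http://www.sbml.org/sbml/level2/version4") \
                     .replace(' hasOnlySubstanceUnits="false"', "") \
                     .replace(' constant="false"/>', "/>") \
                     .replace(' level="3" version="2"', ' level="2" version="4"')
        m, rep = read_sbml(xml)
        assert not rep.has_errors()
        assert m.get_reaction("decay").kinetic_law == parse_infix("k*A")

    def test_not_sbml_is_fatal(self):
        with pytest.raises(SbmlError, match="not SBML"):
            read_sbml('<foo xmlns="http://example.org"/>')

    def test_missing_required_attribute_is_fatal_with_path(self):
        xml = MINIMAL.replace('species id="A" ', "species ")
        with pytest.raises(SbmlError, match="listOfSpecies"):
            read_sbml(xml)


class TestWriteSbml:
    @pytest.mark.parametrize("kind", TOY_KINDS)
    def test_roundtrip_is_identity_on_toys(self, kind):
        m = make_toy_model(kind, seed=3)
        m2, rep = read_sbml(write_sbml(m))
        assert rep.is_empty()
        # canonical HMOD text is the equality witness across formats
        assert serialize_hmod(m2) == serialize_hmod(m)

    def test_tanh_rule_emits_tanh_mathml(self, mm_model):
        m = mm_model
        m.parameters.append(Parameter(id="act", constant=False))
        m.assignment_rules.append(AssignmentRule("act", parse_infix("tanh(S)")))
        assert b"<tanh/>" in write_sbml(m)

    def test_every_written_document_validates_cleanly(self):
        for kind in TOY_KINDS:
            assert validate_sbml_structure(write_sbml(make_toy_model(kind, seed=5))).is_empty()

    def test_ml_origin_parameter_round_trips_through_notes(self, mm_model):
        m = mm_model
        m.parameters.append(Parameter(id="w11", value=0.3, origin="ml-weight"))
        m2, _ = read_sbml(write_sbml(m))
        assert m2.get_parameter("w11").origin == "ml-weight"

    def test_inconsistent_model_is_refused(self, mm_model):
        mm_model.species[0].compartment = "nowhere"
        with pytest.raises(SbmlError, match="DANGLING_REF"):
            write_sbml(mm_model)

    def test_assignment_rules_written_in_topological_order(self, mm_model):
        m = mm_model
        m.parameters += [Parameter(id="late", constant=False),
                         Parameter(id="early", constant=False)]
        # declared out of order: 'late' reads 'early'
        m.assignment_rules.insert(0, AssignmentRule("late", parse_infix("early+1")))
        m.assignment_rules.append(AssignmentRule("early", parse_infix("S")))
        xml = write_sbml(m)
        assert xml.index(b'variable="early"') < xml.index(b'variable="late"')


class TestValidateStructure:
    def test_duplicate_species_id(self):
        xml = MINIMAL.replace("</listOfSpecies>",
                              '<species id="A" compartment="cell" initialConcentration="2"'
                              ' hasOnlySubstanceUnits="false" boundaryCondition="false"'
                              ' constant="false"/></listOfSpecies>')
        assert "DUPLICATE_ID" in validate_sbml_structure(xml).codes()

    def test_kinetic_law_with_undefined_symbol(self):
        xml = MINIMAL.replace("<ci>k</ci>", "<ci>ghost</ci>")
        assert "DANGLING_REF" in validate_sbml_structure(xml).codes()

    def test_pristine_fixture_is_clean(self):
        assert validate_sbml_structure(MINIMAL).is_empty()
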