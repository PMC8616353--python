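"""Composition parsing, classification, mass computation, annotation checks."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from glycotraits.glycan_model import (
    ALDITOL_TERMINUS,
    GlycanComposition,
    GlycanParseError,
    StructureAnnotation,
    GlycanRecord,
    alditol_mass,
    classify_by_composition,
    emit_glycan_name,
    parse_glycan_name,
    validate_annotation,
)

# Published monoisotopic residue masses, summed by hand independently of the
# package's constant table.
HEX, HEXNAC, FUC, NEUAC = 162.0528234315, 203.0793725337, 146.0579088094, 291.0954165066
REDUCED_END = 18.0105646863 + 2.0156500642


class TestParser:
    @pytest.mark.parametrize(
        "name,expect,isomer",
        [
            ("H5N4S2a", dict(hex=5, hexnac=4, neuac=2), "a"),
            ("H9N2", dict(hex=9, hexnac=2), None),
            ("H1N1S2", dict(hex=1, hexnac=1, neuac=2), None),
            ("H4N3F1S1c", dict(hex=4, hexnac=3, fuc=1, neuac=1), "c"),
            ("H2N2S1Su1", dict(hex=2, hexnac=2, neuac=1, sulfo=1), None),
            ("H5N2P1", dict(hex=5, hexnac=2, phospho=1), None),
            ("S2N4H5", dict(hex=5, hexnac=4, neuac=2), None),  # order-free
        ],
    )
    def test_parses_compositions(self, name, expect, isomer):
        rec = parse_glycan_name(name)
        assert rec.composition == GlycanComposition(**expect)
        assert rec.isomer == isomer

    @pytest.mark.parametrize(
        "bad", ["X5N2", "H5N4H2", "H0N2", "H5N4ab", "", "H", "h5n2", "H5N4Q1"]
    )
    def test_rejects_malformed_names(self, bad):
        with pytest.raises(GlycanParseError):
            parse_glycan_name(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(GlycanParseError, match="duplicated token 'N'"):
            parse_glycan_name("H5N4N2")

    @settings(derandomize=True, max_examples=200)
    @given(
        hex=st.integers(0, 12), hexnac=st.integers(1, 8), fuc=st.integers(0, 4),
        neuac=st.integers(0, 5), phospho=st.integers(0, 2), sulfo=st.integers(0, 2),
        isomer=st.one_of(st.none(), st.sampled_from("abcde")),
    )
    def test_round_trip(self, hex, hexnac, fuc, neuac, phospho, sulfo, isomer):
        comp = GlycanComposition(hex, hexnac, fuc, neuac, phospho, sulfo)
        name = emit_glycan_name(comp, isomer)
        rec = parse_glycan_name(name)
        assert rec.composition == comp
        assert rec.isomer == isomer
        assert emit_glycan_name(rec.composition, rec.isomer) == name


class TestAlditolMass:
    def test_empty_composition_is_terminus_only(self):
        assert alditol_mass(GlycanComposition()) == pytest.approx(ALDITOL_TERMINUS)

    def test_sialyl_t_alditol_hand_sum(self):
        # H1N1S1: Hex + HexNAc + NeuAc + reduced-end terminus
        expected = HEX + HEXNAC + NEUAC + REDUCED_END  # 676.2538 Da
        got = alditol_mass(parse_glycan_name("H1N1S1").composition)
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(676.2538272223, abs=1e-6)

    def test_man9_hand_sum(self):
        expected = 9 * HEX + 2 * HEXNAC + REDUCED_END  # 1884.6604 Da
        got = alditol_mass(parse_glycan_name("H9N2").composition)
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(1884.6603707014, abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.builds(GlycanComposition, st.integers(0, 9), st.integers(0, 9),
                    st.integers(0, 3), st.integers(0, 3)),
        b=st.builds(GlycanComposition, st.integers(0, 9), st.integers(0, 9),
                    st.integers(0, 3), st.integers(0, 3)),
    )
    def test_additivity(self, a, b):
        lhs = alditol_mass(a + b) - ALDITOL_TERMINUS
        rhs = (alditol_mass(a) - ALDITOL_TERMINUS) + (alditol_mass(b) - ALDITOL_TERMINUS)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "name,cls,expected",
        [
            ("H9N2", "N", "oligomannose"),
            ("H4N2", "N", "oligomannose"),   # Man4 above the paucimannose boundary
            ("H3N2F1", "N", "paucimannose"),
            ("H2N2", "N", "paucimannose"),
            ("H5N2P1", "N", "oligomannose"),  # phosphorylation does not change the type
            ("H4N3S1", "N", "hybrid"),
            ("H3N3S1", "N", "complex"),       # HexNAc3 with Hex<4
            ("H5N4S2", "N", "complex"),
            ("H1N1S1", "O", "core1"),
            ("H2N2S2", "O", "core2"),
        ],
    )
    def test_examples(self, name, cls, expected):
        comp = parse_glycan_name(name).composition
        assert classify_by_composition(comp, cls) == expected

    def test_total_and_single_valued(self):
        """Every composition with a valid class maps to exactly one type."""
        n_types = {"oligomannose", "paucimannose", "hybrid", "complex"}
        o_types = {"core1", "core2"}
        for hexnac, hex_, fuc, neuac in itertools.product(
            range(0, 9), range(0, 13), range(0, 2), range(0, 2)
        ):
            comp = GlycanComposition(hex=hex_, hexnac=hexnac, fuc=fuc, neuac=neuac)
            if hexnac >= 2:
                assert classify_by_composition(comp, "N") in n_types
            if hexnac >= 1:
                assert classify_by_composition(comp, "O") in o_types

    def test_invalid_class_composition_raises(self):
        with pytest.raises(ValueError):
            classify_by_composition(GlycanComposition(hex=5, hexnac=1), "N")


class TestValidateAnnotation:
    def _record(self, name, cls, **ann):
        rec = parse_glycan_name(name, glycan_class=cls)
        return GlycanRecord(rec.name, rec.composition, cls, rec.isomer,
                            StructureAnnotation(**ann))

    def test_consistent_record_is_clean(self):
        rec = self._record("H5N4S2", "N", glycan_type="complex", antennae=2,
                           sia_a23=1, sia_a26_gal=1)
        assert validate_annotation(rec) == []

    def test_sialic_linkage_sum_violation(self):
        rec = self._record("H5N4S2", "N", glycan_type="complex", antennae=2, sia_a23=1)
        violations = validate_annotation(rec)
        assert len(violations) == 1 and "sialic-linkage" in violations[0]

    def test_o_glycan_cannot_be_bisected(self):
        rec = self._record("H2N2S2", "O", glycan_type="core2", bisecting=True,
                           sia_a23=1, sia_a26_core=1)
        assert any("bisected" in v for v in validate_annotation(rec))

    def test_all_violations_reported(self):
        rec = self._record("H2N2S2", "O", glycan_type="core2", bisecting=True,
                           antennae=2, sia_a23=1)
        assert len(validate_annotation(rec)) >= 3

    def test_curator_type_disagreement_is_warning(self):
        rec = self._record("H9N2", "N", glycan_type="complex")
        violations = validate_annotation(rec)
        assert any("warning" in v and "oligomannose" in v for v in violations)


def test_packaged_library_is_valid_and_covers_all_types(library):
    from glycotraits.glycan_model import validate_library
    assert validate_library(library) == []
    n = [r for r in library if r.glycan_class == "N"]
    o = [r for r in library if r.glycan_class == "O"]
    assert len(n) >= 30 and len(o) >= 15
    assert {r.annotation.glycan_type for r in n} == {"oligomannose", "paucimannose", "hybrid", "complex"}
    assert {r.annotation.glycan_type for r in o} == {"core1", "core2"}
    # every headline epitope is represented
    assert any(r.annotation.has_sLex_a for r in n)
    assert any(r.annotation.bisecting for r in n)
    assert any(r.annotation.sia_a28 for r in o)
    assert any(r.annotation.has_T_antigen for r in o)
    assert any(r.annotation.has_H_antigen for r in o)
    assert any(r.composition.sulfo for r in o)
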