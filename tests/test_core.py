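"""Grammar, composition, mass and ion m/z calculus."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xgox.core import (
    MONOISOTOPIC,
    Composition,
    IonSpecies,
    OxForm,
    XGParseError,
    XGStructure,
    enumerate_structures,
    fits_xxxg_repeat,
    flag_mass_ambiguities,
    generate_mass_list,
    parse_code,
)

M = MONOISOTOPIC

unit_strings = st.text(alphabet="GXLF", min_size=1, max_size=8)


class TestMassTable:
    def test_keto_shift_is_two_hydrogens(self):
        assert abs(M.keto_shift - 2.01565) < 1e-5

    def test_hexose_pentose_differ_by_ch2o(self):
        assert abs((M.hexose_residue - M.pentose_residue) - 30.01057) < 1e-4


class TestParsing:
    @pytest.mark.parametrize(
        "code,n_units,comp",
        [
            ("XXXG", 4, (4, 3, 0)),
            ("GXXF", 4, (5, 3, 1)),
            ("G", 1, (1, 0, 0)),
            ("O4k:LGX", 3, (4, 2, 0)),
            ("_O=G_LGX", 3, (4, 2, 0)),  # literature-style prefix
            ("O1a:XXXG", 4, (4, 3, 0)),
        ],
    )
    def test_parse_composition(self, code, n_units, comp):
        s = parse_code(code)
        assert len(s.units) == n_units
        assert tuple(s.composition) == comp

    def test_literature_prefix_means_c4_keto(self):
        assert parse_code("_O=G_GXXX").oxidation is OxForm.C4_KETO

    @pytest.mark.parametrize("bad", ["", "XXZ", "Q", "O4k:", "xxxg"])
    def test_parse_errors_name_problem(self, bad):
        with pytest.raises(XGParseError):
            parse_code(bad)

    def test_unknown_symbol_named_in_error(self):
        with pytest.raises(XGParseError, match="Z"):
            parse_code("XXZ")

    @given(unit_strings, st.sampled_from(list(OxForm)))
    @settings(max_examples=60, deadline=None)
    def test_roundtrip_through_formatter(self, units, form):
        s = XGStructure(tuple(units), form)
        assert parse_code(s.code) == s


class TestNeutralMass:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("XXX", 900.296),
            ("G", 180.063),  # glucose
            ("O4k:GXXX", 1060.333),
        ],
    )
    def test_reference_masses(self, code, expected):
        assert parse_code(code).neutral_mass == pytest.approx(expected, abs=1e-3)

    @given(unit_strings, st.integers(min_value=1, max_value=7))
    @settings(max_examples=80, deadline=None)
    def test_mass_additivity_over_splits(self, units, cut):
        """Splitting releases one water: m(whole) = m(prefix)+m(suffix)-water."""
        s = XGStructure(tuple(units))
        cut = min(cut, len(units))
        if cut == len(units):
            return
        pre = XGStructure(tuple(units[:cut]))
        suf = XGStructure(tuple(units[cut:]))
        assert s.neutral_mass == pytest.approx(
            pre.neutral_mass + suf.neutral_mass - M.water, abs=1e-6
        )


class TestIonMz:
    @pytest.mark.parametrize(
        "code,ion,expected",
        [
            ("XXG", IonSpecies.M_PLUS_LI, 775.3),
            ("XXX", IonSpecies.M_MINUS_H, 899.3),
            ("O4k:LGX", IonSpecies.M_MINUS_H, 927.3),
        ],
    )
    def test_published_mz_values(self, code, ion, expected):
        assert round(parse_code(code).mz(ion), 1) == expected

    @given(unit_strings)
    @settings(max_examples=40, deadline=None)
    def test_oxidation_shift_identities(self, units):
        """+16 forms sit +15.99491 and keto forms -2.01565 vs non-oxidized,
        for every singly charged ion kind."""
        plain = XGStructure(tuple(units))
        for ion in (
            IonSpecies.M_MINUS_H,
            IonSpecies.M_PLUS_LI,
            IonSpecies.M_PLUS_FORMATE_MINUS_H,
        ):
            base = plain.mz(ion)
            assert plain.with_oxidation(OxForm.C1_ALDONIC).mz(ion) - base == (
                pytest.approx(15.99491, abs=1e-5)
            )
            assert plain.with_oxidation(OxForm.C4_KETO).mz(ion) - base == (
                pytest.approx(-2.01565, abs=1e-5)
            )

    @given(unit_strings)
    @settings(max_examples=40, deadline=None)
    def test_doubly_charged_consistency(self, units):
        s = XGStructure(tuple(units))
        assert s.mz(IonSpecies.M_MINUS_2H) == pytest.approx(
            (s.neutral_mass - 2 * M.proton) / 2, abs=1e-6
        )


def _brute_force_structures(comp, max_len=6):
    found = set()
    for n in range(1, max_len + 1):
        for units in itertools.product("GXLF", repeat=n):
            if tuple(XGStructure(units).composition) == tuple(comp):
                found.add(units)
    return found


class TestEnumeration:
    def test_oxidized_h2p1_isomers(self):
        got = {s.code for s in enumerate_structures((2, 1, 0), OxForm.C4_KETO)}
        assert got == {"O4k:L", "O4k:XG", "O4k:GX"}

    def test_h4p3_unconstrained_has_seven(self):
        assert len(enumerate_structures((4, 3, 0))) == 7

    def test_infeasible_composition_is_empty(self):
        assert enumerate_structures((0, 1, 0)) == ()

    @pytest.mark.parametrize(
        "comp",
        [(1, 0, 0), (2, 1, 0), (3, 2, 0), (4, 3, 0), (4, 2, 0), (5, 3, 1), (6, 3, 0)],
    )
    def test_agrees_with_brute_force(self, comp):
        got = {s.units for s in enumerate_structures(comp)}
        assert got == _brute_force_structures(comp)

    def test_xxxg_grammar_filters(self):
        free = {s.units for s in enumerate_structures((4, 2, 0))}
        constrained = {s.units for s in enumerate_structures((4, 2, 0), grammar="xxxg")}
        assert constrained == {u for u in free if fits_xxxg_repeat(u)}
        assert ("G", "G", "X", "X") in free - constrained


class TestMassList:
    def test_h5p3_lithium_series(self):
        table = generate_mass_list(
            (1, 6),
            (OxForm.NONE, OxForm.C4_KETO, OxForm.C1_ALDONIC),
            (IonSpecies.M_PLUS_LI,),
        )
        sub = table[table.composition == "H5P3"]
        got = {row["form"]: round(row["mz"], 1) for _, row in sub.iterrows()}
        assert got == {"none": 1231.4, "C4_keto": 1229.4, "C1_aldonic": 1247.4}

    def test_empty_form_list_gives_empty_table(self):
        assert generate_mass_list((1, 3), (), (IonSpecies.M_MINUS_H,)).empty

    def test_rows_sorted_by_mz(self):
        table = generate_mass_list((1, 5))
        assert table["mz"].is_monotonic_increasing

    def test_formate_adduct_coincides_with_c1_oxidized(self):
        """[M+HCOOH-H]- of H4P3 is isobaric with [M+16-H]- of H5P2."""
        formate = Composition(4, 3).residue_mass + M.water + M.formic_acid - M.proton
        aldonic = Composition(5, 2).residue_mass + M.water + M.oxygen - M.proton
        assert abs(formate - aldonic) < 0.01


class TestAmbiguities:
    def _table(self):
        return generate_mass_list(
            (1, 5),
            (OxForm.NONE, OxForm.C4_KETO, OxForm.C1_LACTONE, OxForm.C1_ALDONIC),
            (IonSpecies.M_MINUS_H, IonSpecies.M_PLUS_FORMATE_MINUS_H),
        )

    def test_formate_vs_c1_grouped_with_loss_rule(self):
        groups = flag_mass_ambiguities(self._table(), 0.05)
        hit = [
            g
            for g in groups
            if any(abs(v - 1107.35) < 0.05 for v in g.mz_values)
        ]
        assert hit and hit[0].rule == "check -46 formic acid loss fragment"

    def test_keto_lactone_grouped_as_mass_identical(self):
        groups = flag_mass_ambiguities(self._table(), 0.05)
        assert any("mass-identical" in g.rule for g in groups)

    def test_singleton_table_has_no_groups(self):
        table = generate_mass_list((4, 4), (OxForm.NONE,), (IonSpecies.M_MINUS_H,))
        assert flag_mass_ambiguities(table.iloc[:1], 0.05) == []

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            flag_mass_ambiguities(self._table(), -0.1)
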