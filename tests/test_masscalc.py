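"""Mass engine: glycan parsing, peptide/fragment masses, oxonium table."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxoscreen import masscalc as mc

# independent element table for oracle computations (NIST monoisotopic)
ELEM = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.99491461956}


def formula_mass(**counts):
    return sum(ELEM[e] * n for e, n in counts.items())


# --- glycan composition parsing -------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("N1", dict(hexnac=1)),
        ("H1N3F1S1", dict(hexnac=3, hexose=1, fuc=1, neuac=1)),
        ("", dict()),
        ("h1n1s2", dict(hexnac=1, hexose=1, neuac=2)),
        ("HexNAc(1)Hex(3)NeuAc(1)Fuc(1)", dict(hexnac=1, hexose=3, fuc=1, neuac=1)),
        ("HexNAc(2)", dict(hexnac=2)),
        ("dHex(1)HexNAc(1)", dict(hexnac=1, fuc=1)),
    ],
)
def test_parse_glycan_composition(text, expected):
    assert mc.parse_glycan_composition(text) == mc.GlycanComposition(**expected)


def test_compact_and_long_forms_parse_identically():
    assert mc.parse_glycan_composition("H1N3F1S1") == mc.parse_glycan_composition(
        "HexNAc(3)Hex(1)Fuc(1)NeuAc(1)"
    )


@pytest.mark.parametrize("bad", ["X9", "N", "N-1", "HexNAc(1", "Hex(a)", "N1 garbage", "NeuGc(1)"])
def test_parse_glycan_rejects_malformed(bad):
    with pytest.raises(mc.GlycanParseError):
        mc.parse_glycan_composition(bad)


# --- glycan masses ---------------------------------------------------------


def test_glycan_masses_against_element_oracle():
    # HexNAc residue = C8H13NO5
    assert mc.glycan_mass(mc.GlycanComposition(hexnac=1)) == pytest.approx(
        formula_mass(C=8, H=13, N=1, O=5), abs=5e-5
    )
    assert mc.glycan_mass(mc.GlycanComposition()) == 0.0
    # H1N3F1S1 = 3xHexNAc + Hex(C6H10O5) + Fuc(C6H10O4) + NeuAc(C11H17NO8)
    expected = (
        3 * formula_mass(C=8, H=13, N=1, O=5)
        + formula_mass(C=6, H=10, O=5)
        + formula_mass(C=6, H=10, O=4)
        + formula_mass(C=11, H=17, N=1, O=8)
    )
    g = mc.parse_glycan_composition("H1N3F1S1")
    assert mc.glycan_mass(g) == pytest.approx(expected, abs=2e-4)
    assert round(mc.glycan_mass(g), 4) == 1208.4443


glycan_counts = st.integers(min_value=0, max_value=6)
glycans = st.builds(mc.GlycanComposition, glycan_counts, glycan_counts, glycan_counts, glycan_counts)


@given(glycans, glycans)
def test_glycan_mass_additivity(a, b):
    assert mc.glycan_mass(a) + mc.glycan_mass(b) == pytest.approx(
        mc.glycan_mass(a + b), abs=1e-9
    )


# --- peptide masses --------------------------------------------------------


def test_unmodified_glycine_mass():
    p = mc.LabeledPeptide("G", tmt=False, carbamidomethyl=False)
    assert mc.peptide_neutral_mass(p) == pytest.approx(75.0320, abs=1e-3)


def test_tmt_peptide_mass():
    # N-terminus + 2 Lys = 3 TMT labels
    p = mc.LabeledPeptide("RDTTVKPGAK")
    assert p.n_tmt == 3
    assert mc.peptide_neutral_mass(p) == pytest.approx(1759.0925, abs=1e-3)


def test_glycopeptide_mass_adds_hexnac():
    bare = mc.LabeledPeptide("RDTTVKPGAK")
    glyco = mc.LabeledPeptide("RDTTVKPGAK", {3: mc.GlycanComposition(hexnac=1)})
    delta = mc.peptide_neutral_mass(glyco) - mc.peptide_neutral_mass(bare)
    assert delta == pytest.approx(203.079373, abs=1e-9)


def test_invalid_peptides_rejected():
    with pytest.raises(ValueError):
        mc.LabeledPeptide("")
    with pytest.raises(ValueError):
        mc.LabeledPeptide("PEPTIDEZ1")
    with pytest.raises(ValueError):  # glycan on Val
        mc.LabeledPeptide("RDTTVKPGAK", {4: mc.GlycanComposition(hexnac=1)})


# --- precursor m/z ---------------------------------------------------------


def test_agr2_precursor_values():
    tn = mc.LabeledPeptide("RDTTVKPGAK", {3: mc.GlycanComposition(hexnac=1)})
    assert mc.precursor_mz(tn, 4) == pytest.approx(491.550, abs=1e-3)
    extended = mc.LabeledPeptide(
        "RDTTVKPGAK", {3: mc.parse_glycan_composition("H1N3F1S1")}
    )
    assert mc.precursor_mz(extended, 4) == pytest.approx(742.891, abs=1e-3)


def test_precursor_charge_errors():
    p = mc.LabeledPeptide("SAMPLER")
    with pytest.raises(ValueError):
        mc.precursor_mz(p, 0)


sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25)


@given(sequences, st.integers(min_value=1, max_value=6), st.integers(min_value=1, max_value=6))
def test_precursor_charge_consistency(seq, z1, z2):
    """Neutral mass recovered from any charge state agrees to 1e-9."""
    p = mc.LabeledPeptide(seq)
    m1 = mc.precursor_mz(p, z1) * z1 - z1 * mc.PROTON_MASS
    m2 = mc.precursor_mz(p, z2) * z2 - z2 * mc.PROTON_MASS
    assert m1 == pytest.approx(m2, abs=1e-8)


# --- oxonium reference table ----------------------------------------------


def test_oxonium_table_reproduces_printed_values():
    ions = mc.oxonium_reference_table()
    assert len(ions) == 6
    printed = {126.055, 138.055, 144.066, 168.066, 186.076, 204.087}
    assert {round(i.mz, 3) for i in ions} == printed
    for ion in ions:
        assert abs(ion.mz - ion.nominal_mz) <= 0.002


def test_oxonium_table_matches_element_oracle():
    # [HexNAc]+ cation C8H14NO5 minus one electron
    base = formula_mass(C=8, H=14, N=1, O=5) - 0.00054858
    by_label = {i.label: i.mz for i in mc.oxonium_reference_table()}
    assert by_label["HexNAc"] == pytest.approx(base, abs=1e-5)
    assert by_label["HexNAc-C2H4O2"] == pytest.approx(
        base - formula_mass(C=2, H=4, O=2), abs=1e-5
    )
    assert by_label["HexNAc-CH6O3"] == pytest.approx(
        base - formula_mass(C=1, H=6, O=3), abs=1e-5
    )


# --- backbone fragments ----------------------------------------------------


def _frag_map(peptide, series=("c", "z"), max_charge=2):
    return {
        (f.series, f.ordinal, f.charge): f
        for f in mc.backbone_fragments(peptide, series, max_charge)
    }


def test_ethcd_ions_for_thr4_glycoform():
    p = mc.LabeledPeptide("RDTTVKPGAK", {3: mc.GlycanComposition(hexnac=1)})
    frags = _frag_map(p)
    assert frags[("c", 3, 1)].mz == pytest.approx(619.372, abs=1e-3)
    assert frags[("z", 7, 2)].mz == pytest.approx(673.414, abs=1e-3)
    # c3 does not span the glycan at index 3; z7 does
    assert not frags[("c", 3, 1)].glycan
    assert frags[("z", 7, 2)].glycan == mc.GlycanComposition(hexnac=1)


def test_ethcd_ions_for_thr3_glycoform():
    p = mc.LabeledPeptide("RDTTVKPGAK", {2: mc.GlycanComposition(hexnac=1)})
    frags = _frag_map(p)
    assert frags[("c", 3, 1)].mz == pytest.approx(822.452, abs=1e-3)
    assert frags[("z", 7, 2)].mz == pytest.approx(571.875, abs=1e-3)


@settings(max_examples=200)
@given(sequences.filter(lambda s: len(s) >= 2))
def test_c_zdot_mass_conservation(seq):
    """neutral(c_i) + neutral(z-dot_(n-i)) = neutral peptide + mass of H."""
    p = mc.LabeledPeptide(seq)
    total = mc.peptide_neutral_mass(p)
    frags = _frag_map(p, ("c", "z"), 1)
    n = len(seq)
    for i in range(1, n):
        s = frags[("c", i, 1)].neutral_mass + frags[("z", n - i, 1)].neutral_mass
        assert s - total == pytest.approx(1.007825, abs=1e-6)


def test_b_y_complementarity():
    p = mc.LabeledPeptide("SAMPLEK")
    frags = _frag_map(p, ("b", "y"), 1)
    total = mc.peptide_neutral_mass(p)
    for i in range(1, 7):
        s = frags[("b", i, 1)].neutral_mass + frags[("y", 7 - i, 1)].neutral_mass
        assert s == pytest.approx(total, abs=1e-9)


# --- glycan Y ladder -------------------------------------------------------


def test_y_ladder_reproduces_ms3_values():
    p = mc.LabeledPeptide("RDTTVKPGAK", {3: mc.parse_glycan_composition("H1N3F1S1")})
    ladder = {f.ordinal: f for f in mc.glycan_y_ladder(p, charges=(3,))}
    assert ladder["HexNAc(1)Hex(1)"].mz == pytest.approx(709.082, abs=1e-3)
    assert ladder["HexNAc(3)"].mz == pytest.approx(790.450, abs=1e-3)


def test_y_ladder_base_is_bare_precursor():
    p = mc.LabeledPeptide("RDTTVKPGAK", {3: mc.GlycanComposition(hexnac=1)})
    ladder = {(f.ordinal, f.charge): f for f in mc.glycan_y_ladder(p, charges=(4,))}
    bare = mc.precursor_mz(p.deglycosylated(), 4)
    assert ladder[("peptide", 4)].mz == pytest.approx(bare, abs=1e-9)


@given(glycans.filter(bool))
def test_y_ladder_size(g):
    """Ladder size is prod(count_i + 1) over monosaccharide types."""
    p = mc.LabeledPeptide("DTTVKPGAK", {1: g})
    expected = (g.hexnac + 1) * (g.hexose + 1) * (g.fuc + 1) * (g.neuac + 1)
    assert len(list(g.subsets())) == expected
    # single charge, compositions with distinct masses -> no deduplication
    ladder = mc.glycan_y_ladder(p, charges=(1,))
    assert len(ladder) <= expected


def test_y_ladder_requires_glycan():
    with pytest.raises(ValueError):
        mc.glycan_y_ladder(mc.LabeledPeptide("DTTVKPGAK"), charges=(1,))


# --- elemental composition -------------------------------------------------


def test_elemental_composition_mass_additive():
    a = mc.ElementalComposition.from_formula("C2H6O3")
    b = mc.ElementalComposition.from_formula("CH4")
    assert (a + b).mass == pytest.approx(a.mass + b.mass, abs=1e-12)
    with pytest.raises(ValueError):
        mc.ElementalComposition.from_formula("C2X5")
    with pytest.raises(ValueError):
        mc.ElementalComposition(C=-1)
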