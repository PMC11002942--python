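"""Mass engine: residue masses, sodiated m/z, enumeration, isotope patterns."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycotraits.chem import (
    ISOTOPE_SPACING,
    SODIUM_CATION_MASS,
    WATER_MASS,
    CompositionBounds,
    GlycanComposition,
    enumerate_compositions,
    interpret_losses,
    isotope_pattern,
    ppm_error,
    rank_candidates,
    residue_mass,
    theoretical_mz,
    write_residue_table,
)

# Independent atomic monoisotopic masses (CODATA/IUPAC), used only by oracles.
_H = 1.00782503207
_C = 12.0
_N = 14.0030740048
_O = 15.9949146196
_NA = 22.9897692809
_E = 5.48579909e-4

_ORACLE_RESIDUES = {
    "Hex": 6 * _C + 10 * _H + 5 * _O,
    "HexNAc": 8 * _C + 13 * _H + _N + 5 * _O,
    "Fuc": 6 * _C + 10 * _H + 4 * _O,
    "ENeuAc": 13 * _C + 21 * _H + _N + 8 * _O,
    "LNeuAc": 11 * _C + 15 * _H + _N + 7 * _O,
}


def _oracle_mz(h, n, f, e, l):
    return (
        h * _ORACLE_RESIDUES["Hex"]
        + n * _ORACLE_RESIDUES["HexNAc"]
        + f * _ORACLE_RESIDUES["Fuc"]
        + e * _ORACLE_RESIDUES["ENeuAc"]
        + l * _ORACLE_RESIDUES["LNeuAc"]
        + (2 * _H + _O)
        + (_NA - _E)
    )


class TestResidueMasses:
    @pytest.mark.parametrize(
        "residue,printed",
        [("Fuc", 146.06), ("ENeuAc", 319.13), ("LNeuAc", 273.08)],
    )
    def test_derivatized_residue_increments(self, residue, printed):
        """Fucose / ethyl-ester / lactone residue deltas at two decimals."""
        assert round(residue_mass(residue), 2) == printed

    def test_hexose_from_elemental_formula(self):
        assert residue_mass("Hex") == pytest.approx(_ORACLE_RESIDUES["Hex"], abs=1e-6)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="NeuGc"):
            residue_mass("NeuGc")

    def test_table_export(self, tmp_path):
        path = tmp_path / "residues.tsv"
        write_residue_table(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["residue", "formula", "monoisotopic_mass"]
        assert len(lines) == 6


class TestComposition:
    def test_canonical_text_form(self):
        assert str(GlycanComposition(3, 4, 1)) == "H3N4F1"
        assert str(GlycanComposition(5, 2)) == "H5N2"
        assert str(GlycanComposition(5, 4, 1, 1, 2)) == "H5N4F1E1L2"

    def test_zero_counts_omitted_except_h_and_n(self):
        assert str(GlycanComposition(hex=3, hexnac=0, fuc=0)) == "H3N0"

    @given(
        st.integers(0, 12), st.integers(0, 10), st.integers(0, 5),
        st.integers(0, 4), st.integers(0, 4),
    )
    def test_text_round_trip(self, h, n, f, e, l):
        if h + n + f + e + l == 0:
            with pytest.raises(ValueError):
                GlycanComposition(h, n, f, e, l)
            return
        comp = GlycanComposition(h, n, f, e, l)
        assert GlycanComposition.from_string(str(comp)) == comp

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            GlycanComposition(hex=-1, hexnac=2)

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            GlycanComposition.from_string("Hex5HexNAc2")


class TestTheoreticalMz:
    # printed reference values for the di-/triantennary series
    PRINTED = {
        "H3N4": 1339.476, "H4N4": 1501.529, "H5N4": 1663.581,
        "H4N5": 1704.608, "H5N5": 1866.661, "H6N5": 2028.714,
        "H3N4F1": 1485.533, "H4N4F1": 1647.586, "H5N4F1": 1809.639,
        "H4N5F1": 1850.666, "H5N5F1": 2012.719, "H6N5F1": 2174.771,
    }

    @pytest.mark.parametrize("text,printed", sorted(PRINTED.items()))
    def test_printed_sodiated_masses(self, text, printed):
        # one printing ulp of slack: H3N4F1 computes to 1485.5337, which the
        # reference value rounds down by one unit in the last digit
        assert theoretical_mz(text) == pytest.approx(printed, abs=0.0011)

    def test_matches_independent_arithmetic(self):
        for h, n, f, e, l in itertools.product(range(4), range(1, 4), range(2), range(2), range(2)):
            comp = GlycanComposition(h, n, f, e, l)
            assert theoretical_mz(comp) == pytest.approx(_oracle_mz(h, n, f, e, l), abs=1e-6)

    def test_mass_additivity(self):
        base = theoretical_mz("H5N4")
        assert theoretical_mz("H5N4F1") - base == pytest.approx(residue_mass("Fuc"), abs=1e-9)
        assert theoretical_mz("H5N4E1") - base == pytest.approx(residue_mass("ENeuAc"), abs=1e-9)

    def test_water_and_sodium_terms(self):
        assert theoretical_mz("H1N0") == pytest.approx(
            residue_mass("Hex") + WATER_MASS + SODIUM_CATION_MASS, abs=1e-9
        )


class TestPpmError:
    def test_equal_inputs_zero(self):
        assert ppm_error(1500.0, 1500.0) == 0.0

    def test_signed_magnitude(self):
        assert ppm_error(1339.503, 1339.476) == pytest.approx(20.2, abs=0.1)

    def test_printed_value_consistency(self):
        assert abs(ppm_error(1485.533, theoretical_mz("H3N4F1"))) < 2

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(-1.0, 1500.0)


def _oracle_enumerate(mz, tol_ppm, bounds: CompositionBounds, biosynthetic=True):
    """Exhaustive nested-loop enumeration using independent arithmetic."""
    out = set()
    (h0, h1), (n0, n1) = bounds.hex, bounds.hexnac
    (f0, f1), (e0, e1), (l0, l1) = bounds.fuc, bounds.eneuac, bounds.lneuac
    for h in range(h0, h1 + 1):
        for n in range(n0, n1 + 1):
            for f in range(f0, f1 + 1):
                for e in range(e0, e1 + 1):
                    for l in range(l0, l1 + 1):
                        if h + n + f + e + l < 1:
                            continue
                        if biosynthetic:
                            if n < 2 or (e + l) > max(n - 2, 0) or f > n:
                                continue
                        theo = _oracle_mz(h, n, f, e, l)
                        if abs((mz - theo) / theo) * 1e6 <= tol_ppm:
                            out.add((h, n, f, e, l))
    return out


class TestEnumeration:
    def test_printed_peak_contains_expected(self):
        assert GlycanComposition(3, 4) in enumerate_compositions(1339.476, 20)

    def test_below_glycan_mass_empty(self):
        assert enumerate_compositions(100.0, 20) == set()

    def test_matches_bruteforce_oracle_on_probe(self):
        got = {
            (c.hex, c.hexnac, c.fuc, c.eneuac, c.lneuac)
            for c in enumerate_compositions(2174.771, 20)
        }
        assert got == _oracle_enumerate(2174.771, 20, CompositionBounds())

    def test_matches_bruteforce_oracle_random_probes(self):
        rng = np.random.default_rng(42)
        bounds = CompositionBounds(hex=(0, 6), hexnac=(2, 6), fuc=(0, 3),
                                   eneuac=(0, 2), lneuac=(0, 2))
        for mz in rng.uniform(900, 3500, size=25):
            got = {
                (c.hex, c.hexnac, c.fuc, c.eneuac, c.lneuac)
                for c in enumerate_compositions(float(mz), 50, bounds=bounds)
            }
            assert got == _oracle_enumerate(float(mz), 50, bounds)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            enumerate_compositions(-5.0, 20)
        with pytest.raises(ValueError):
            enumerate_compositions(1500.0, 0.0)

    def test_rank_prefers_smaller_ppm_then_fewer_residues(self):
        comps = [GlycanComposition(5, 4), GlycanComposition(3, 4)]
        mz = theoretical_mz("H3N4") + 0.001
        assert rank_candidates(mz, comps)[0] == GlycanComposition(3, 4)


def _sympy_pattern_oracle(formula: dict, n_peaks: int) -> np.ndarray:
    """Aggregated isotopologue abundances via symbolic polynomial expansion."""
    import sympy

    from glycotraits.chem import _element_abundances

    x = sympy.symbols("x")
    poly = sympy.Integer(1)
    for element, count in formula.items():
        abundances = _element_abundances(element)
        elem_poly = sum(
            sympy.Float(a, 30) * x**k for k, a in enumerate(abundances)
        )
        poly *= elem_poly**count
    coeffs = sympy.Poly(sympy.expand(poly), x).all_coeffs()[::-1]
    dist = np.array([float(c) for c in coeffs[:n_peaks]], dtype=float)
    if dist.size < n_peaks:
        dist = np.pad(dist, (0, n_peaks - dist.size))
    return dist / dist.sum()


class TestIsotopePattern:
    def test_normalized_and_nonnegative(self):
        for text in ("H3N4", "H5N2", "H7N6F3E1"):
            pattern = isotope_pattern(text, 6)
            assert pattern.sum() == pytest.approx(1.0, abs=1e-9)
            assert (pattern >= 0).all()

    def test_monoisotopic_peak_dominates_small_glycan(self):
        pattern = isotope_pattern("H3N4", 4)
        assert pattern[0] == pytest.approx(pattern.max())

    def test_doubling_composition_raises_a1_fraction(self):
        small = isotope_pattern("H3N4", 4)
        big = isotope_pattern("H6N8", 4)
        assert big[1] / big[0] > small[1] / small[0]

    def test_matches_symbolic_expansion_oracle(self):
        comp = GlycanComposition(hex=1)  # C6H12O6 + Na
        expected = _sympy_pattern_oracle(comp.formula(sodiated=True), 5)
        assert isotope_pattern(comp, 5) == pytest.approx(expected, rel=1e-9)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            isotope_pattern("H3N4", 1)


class TestInterpretLosses:
    def test_fucose_loss_flagged(self):
        matches = interpret_losses(1809.504, [1663.420], 0.1)
        assert (1663.420, "Fuc") in matches

    def test_empty_fragments(self):
        assert interpret_losses(1809.504, [], 0.1) == []

    def test_ethyl_ester_sialic_loss(self):
        precursor = theoretical_mz("H5N4E1")
        fragment = precursor - residue_mass("ENeuAc")
        assert (fragment, "ENeuAc") in interpret_losses(precursor, [fragment], 0.05)

    def test_isotope_spacing_is_carbon13_delta(self):
        assert ISOTOPE_SPACING == pytest.approx(1.00335, abs=1e-5)
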