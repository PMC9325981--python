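"""Formula arithmetic, parsing, and the [M-H]- assignment search."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leachdom.chem import (
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    AssignmentConfig,
    MolecularFormula,
    Peak,
    assign_formulas,
    blank_correct,
    ion_mass,
    monoisotopic_mass,
)
from leachdom.dom_metrics import SampleFormulaTable

from conftest import make_table


@pytest.mark.parametrize(
    "formula, expected",
    [
        ("CH0", 12.0),            # bare carbon: the mass scale's anchor
        ("C8H6O4", 166.02661),
        ("C20H26O4", 330.18311),
    ],
)
def test_monoisotopic_mass(formula, expected):
    f = MolecularFormula.parse(formula)
    assert monoisotopic_mass(f) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize(
    "formula, expected",
    [
        ("C8H6O4", 165.01933),
        ("CH2", 13.00838),
    ],
)
def test_ion_mass(formula, expected):
    assert ion_mass(MolecularFormula.parse(formula)) == pytest.approx(expected, abs=1e-5)


def test_ion_mass_requires_hydrogen():
    with pytest.raises(ValueError, match="deprotonat"):
        ion_mass(MolecularFormula(c=6, h=0))


def test_ion_mass_rejects_other_modes():
    with pytest.raises(ValueError, match="mode"):
        ion_mass(MolecularFormula.parse("C8H6O4"), mode="positive")


def test_ion_mass_is_neutral_minus_proton():
    for f in (MolecularFormula(10, 14, 0, 2), MolecularFormula(5, 9, 1, 3, 1)):
        assert monoisotopic_mass(f) - ion_mass(f) == pytest.approx(PROTON_MASS, abs=1e-12)


@given(
    c=st.integers(1, 60),
    h=st.integers(0, 120),
    n=st.integers(0, 4),
    o=st.integers(0, 40),
    s=st.integers(0, 2),
)
@settings(max_examples=200, deadline=None)
def test_parse_format_roundtrip(c, h, n, o, s):
    f = MolecularFormula(c, h, n, o, s)
    assert MolecularFormula.parse(str(f)) == f


@pytest.mark.parametrize("bad", ["", "H2O", "C8H6O4X", "8CH6", "Fe2O3"])
def test_parse_rejects_invalid(bad):
    with pytest.raises(ValueError):
        MolecularFormula.parse(bad)


def test_parse_tolerates_underscores():
    assert MolecularFormula.parse("C_20_H_26_O_4_") == MolecularFormula(20, 26, 0, 4)


def test_formula_requires_carbon():
    with pytest.raises(ValueError):
        MolecularFormula(c=0, h=4)


def test_dbe():
    assert MolecularFormula.parse("C8H6O4").dbe == 6.0   # aromatic diacid
    assert MolecularFormula.parse("CH4").dbe == 0.0


class TestAssignment:
    def test_known_ion_masses_recover_their_formulas(self):
        res = assign_formulas([Peak(mz=165.01933), Peak(mz=329.17583)])
        assert str(res[0].best.formula) == "C8H6O4"
        assert str(res[1].best.formula) == "C20H26O4"
        for pa in res:
            assert abs(pa.best.mass_error_ppm) <= 0.5
            assert pa.candidates[0].is_best

    def test_arbitrary_mass_unassigned_at_vanishing_tolerance(self):
        res = assign_formulas([Peak(mz=150.0)], AssignmentConfig(tolerance_ppm=1e-4))
        assert res[0].best is None
        assert res[0].candidates == ()

    def test_peak_outside_window_unassigned(self):
        res = assign_formulas([Peak(mz=80.0), Peak(mz=1500.0)])
        assert all(pa.best is None for pa in res)

    def test_empty_peak_list(self):
        assert assign_formulas([]) == []

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            AssignmentConfig(tolerance_ppm=0.0)

    def test_deterministic_and_idempotent(self):
        peaks = [Peak(mz=m) for m in (165.01933, 329.17583, 201.11345, 444.2)]
        first = assign_formulas(peaks)
        second = assign_formulas(peaks)
        assert first == second

    def test_candidates_ranked_by_abs_ppm_error(self):
        res = assign_formulas([Peak(mz=400.1)], AssignmentConfig(tolerance_ppm=5.0))
        errors = [abs(c.mass_error_ppm) for c in res[0].candidates]
        assert errors == sorted(errors)

    def test_even_electron_parity_filter(self):
        # a radical composition (odd h + n) must never appear as a candidate
        res = assign_formulas([Peak(mz=300.05)], AssignmentConfig(tolerance_ppm=10.0))
        assert res[0].candidates
        for cand in res[0].candidates:
            f = cand.formula
            assert (f.h + f.n) % 2 == 0

    def test_table1_roundtrip_all_recovered(self, additives):
        formulas = sorted({a.formula for a in additives}, key=str)
        t0 = time.time()
        res = assign_formulas([Peak(mz=ion_mass(f)) for f in formulas])
        elapsed = time.time() - t0
        for f, pa in zip(formulas, res):
            assert f in {c.formula for c in pa.candidates}, f"{f} not recovered"
        assert elapsed < 10.0


def _brute_force_candidates(mz, config):
    """Independent oracle: unpruned nested loops over the element bounds."""
    m = MONOISOTOPIC_MASS
    found = []
    tol_da = mz * config.tolerance_ppm * 1e-6
    for c in range(config.c_bounds[0], config.c_bounds[1] + 1):
        if c * m["C"] > mz + PROTON_MASS + tol_da:
            break
        for n in range(config.n_bounds[0], config.n_bounds[1] + 1):
            for s in range(config.s_bounds[0], config.s_bounds[1] + 1):
                for o in range(config.o_bounds[0], config.o_bounds[1] + 1):
                    base = c * m["C"] + n * m["N"] + s * m["S"] + o * m["O"]
                    if base > mz + PROTON_MASS + tol_da:
                        break
                    for h in range(config.h_bounds[0], config.h_bounds[1] + 1):
                        neutral = base + h * m["H"]
                        ion = neutral - PROTON_MASS
                        if ion > mz + tol_da:
                            break
                        if abs(ion - mz) > tol_da:
                            continue
                        f = MolecularFormula(c, h, n, s=s, o=o)
                        if config.passes_filters(f):
                            found.append(f)
    return set(found)


@pytest.mark.parametrize("mz", [165.01933, 201.11345, 288.9, 299.99])
def test_search_matches_brute_force_below_300(mz):
    config = AssignmentConfig(tolerance_ppm=5.0)
    res = assign_formulas([Peak(mz=mz)], config)
    fast = {c.formula for c in res[0].candidates}
    assert fast == _brute_force_candidates(mz, config)


class TestBlankCorrect:
    def test_removes_blank_formulas_and_renormalises(self):
        sample = make_table("s", {"C5H10O2": 0.5, "C6H12O3": 0.5})
        blank = make_table("blank", {"C6H12O3": 1.0})
        out = blank_correct(sample, blank)
        assert [str(f) for f in out.formulas] == ["C5H10O2"]
        assert out.weights.sum() == pytest.approx(1.0)

    def test_empty_blank_is_identity(self):
        sample = make_table("s", {"C5H10O2": 2.0})
        blank = SampleFormulaTable("blank", ())
        out = blank_correct(sample, blank)
        assert out.formula_set == sample.formula_set
        assert out.weights[0] == pytest.approx(1.0)

    def test_partial_overlap(self):
        sample = make_table("s", {"C5H10O2": 1.0, "C6H12O3": 1.0, "C7H14O4": 1.0})
        blank = make_table("blank", {"C5H10O2": 1.0, "C6H12O3": 1.0})
        out = blank_correct(sample, blank)
        assert [str(f) for f in out.formulas] == ["C7H14O4"]
        assert out.weights[0] == pytest.approx(1.0)
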