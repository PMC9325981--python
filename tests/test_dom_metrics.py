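"""Functional diversity, lability fractions, unique-formula and additive logic."""

import numpy as np
import pytest

from leachdom.chem import MolecularFormula
from leachdom.dom_metrics import (
    SampleFormulaTable,
    UniqueFormulaResult,
    crossref_additives,
    functional_diversity,
    lability_summary,
    summarize_sample,
    summary_frame,
    unique_formulas,
)

from conftest import make_table


def brute_force_fd(carbons, weights):
    """O(n^2) ordered-pair Rao sum, the oracle for the sorted fast path."""
    total = 0.0
    for ci, pi in zip(carbons, weights):
        for cj, pj in zip(carbons, weights):
            total += pi * pj * abs(ci - cj)
    return total


class TestFunctionalDiversity:
    def test_singleton_is_zero(self):
        assert functional_diversity(make_table("s", {"C5H10O2": 3.0})) == 0.0
        assert functional_diversity(SampleFormulaTable("empty", ())) == 0.0

    def test_two_formulas_equal_weight(self):
        t = make_table("s", {"C5H6O2": 1.0, "C7H8O2": 1.0})
        assert functional_diversity(t) == pytest.approx(1.0)

    def test_three_formulas_equal_weight(self):
        t = make_table("s", {"C4H6O2": 1.0, "C5H8O2": 1.0, "C6H10O2": 1.0})
        assert functional_diversity(t) == pytest.approx(8.0 / 9.0)

    def test_matches_brute_force_on_random_tables(self, rng):
        for n in (2, 7, 40, 300):
            carbons = rng.integers(1, 60, n)
            weights = rng.random(n)
            formulas = []
            seen = set()
            for i, c in enumerate(carbons):
                f = MolecularFormula(int(c), 2 * int(c), o=i % 40)  # unique via o
                while f in seen:
                    f = MolecularFormula(f.c, f.h, o=f.o + 1)
                seen.add(f)
                formulas.append(f)
            t = SampleFormulaTable("s", tuple(formulas), tuple(weights))
            p = weights / weights.sum()
            assert functional_diversity(t) == pytest.approx(
                brute_force_fd([f.c for f in formulas], p), abs=1e-10
            )

    def test_invariant_to_ordering_and_rescaling(self, rng):
        spec = {"C4H6O2": 1.0, "C9H12O3": 2.5, "C20H22O4": 0.5}
        t1 = make_table("s", spec)
        t2 = make_table("s", dict(reversed(list(spec.items()))))
        t3 = make_table("s", {k: 7.0 * v for k, v in spec.items()})
        assert functional_diversity(t1) == pytest.approx(functional_diversity(t2))
        assert functional_diversity(t1) == pytest.approx(functional_diversity(t3))

    def test_bounded_by_carbon_span(self, rng):
        carbons = rng.integers(10, 31, 50)
        formulas = tuple(MolecularFormula(int(c), 2 * int(c), o=i + 1)
                         for i, c in enumerate(carbons))
        t = SampleFormulaTable("s", formulas)
        assert functional_diversity(t, weighted=False) <= carbons.max() - carbons.min()

    def test_uniform_weights_when_intensities_absent(self):
        t = SampleFormulaTable(
            "s", (MolecularFormula(4, 6), MolecularFormula(8, 10, o=2)))
        assert functional_diversity(t) == pytest.approx(2.0)  # 2 * 0.5 * 0.5 * 4


class TestLability:
    def test_additive_formulas_all_below_threshold(self, additives):
        t = SampleFormulaTable("t1", tuple(dict.fromkeys(a.formula for a in additives)))
        count_frac, intensity_frac = lability_summary(t)
        assert count_frac == 0.0
        assert intensity_frac == 0.0

    def test_boundary_ratio_counts_as_high(self):
        t = make_table("s", {"C2H3O1": 1.0})  # H:C exactly 1.5
        assert lability_summary(t) == (1.0, 1.0)

    def test_count_and_intensity_fractions_differ(self):
        t = make_table("s", {"CH4": 0.2, "C6H6": 0.8})
        count_frac, intensity_frac = lability_summary(t)
        assert count_frac == pytest.approx(0.5)
        assert intensity_frac == pytest.approx(0.2)

    def test_empty_table(self):
        assert lability_summary(SampleFormulaTable("s", ())) == (0.0, 0.0)

    def test_monotone_nonincreasing_in_threshold(self, rng):
        formulas = tuple(
            MolecularFormula(10, int(h), o=i)
            for i, h in enumerate(rng.integers(2, 26, 30))
        )
        t = SampleFormulaTable("s", formulas, tuple(rng.random(30)))
        prev = (1.1, 1.1)
        for thr in (0.5, 1.0, 1.5, 2.0, 2.5):
            cur = lability_summary(t, thr)
            assert cur[0] <= prev[0] and cur[1] <= prev[1]
            prev = cur


class TestUniqueFormulas:
    def test_set_difference_and_percentage(self):
        target = make_table("t", {"C5H10O2": 1, "C6H12O3": 1, "C7H14O4": 1})
        ref = make_table("r", {"C6H12O3": 1, "C7H14O4": 1, "C8H16O5": 1})
        res = unique_formulas(target, [ref])
        assert [str(f) for f in res.table.formulas] == ["C5H10O2"]
        assert res.percent_unique == pytest.approx(100.0 / 3.0)

    def test_self_reference_empty(self):
        t = make_table("t", {"C5H10O2": 1})
        res = unique_formulas(t, [t])
        assert res.n_unique == 0
        assert res.percent_unique == 0.0

    def test_no_references_all_unique(self):
        t = make_table("t", {"C5H10O2": 1, "C6H12O3": 1})
        res = unique_formulas(t, [])
        assert res.n_unique == t.n_formulas
        assert res.percent_unique == 100.0

    def test_reported_unique_count_rounds_to_whole_percent(self):
        # 296 unique of 855 assigned formulas: 34.6%, i.e. 35% to the nearest percent
        res = UniqueFormulaResult(table=SampleFormulaTable("t", ()), n_target=855, n_unique=296)
        assert res.percent_unique == pytest.approx(34.62, abs=0.01)
        assert round(res.percent_unique) == 35


class TestCrossref:
    def test_match_carries_name_and_application(self, additives):
        uniques = make_table("u", {"C8H6O4": 1.0})
        matches = crossref_additives(uniques, additives)
        assert len(matches) == 1
        assert matches[0].putative_name == "isophthalic acid"
        assert matches[0].application == "Lubricant/adhesive"

    def test_non_additive_formula_unmatched(self, additives):
        uniques = make_table("u", {"C30H40O10": 1.0})
        assert crossref_additives(uniques, additives) == []

    def test_relative_abundance_uses_full_sample(self, additives):
        full = make_table("full", {"C8H6O4": 1.0, "C30H40O10": 1.0})
        uniques = make_table("u", {"C8H6O4": 1.0})
        matches = crossref_additives(uniques, additives, full=full)
        assert matches[0].relative_abundance_pct == pytest.approx(50.0)

    def test_shared_formula_reported_twice(self, additives):
        # two additive records share C10H14O2; both are candidate identities
        uniques = make_table("u", {"C10H14O2": 1.0})
        matches = crossref_additives(uniques, additives)
        assert len(matches) == 2
        assert {m.putative_name for m in matches} == {
            "2-tert-butylhydroquinone", "4-tert-butylpyrocatechol"}


def test_summary_frame_roundtrip():
    tables = [
        make_table("a", {"C2H3O1": 1.0, "C6H6": 1.0}),
        make_table("b", {"C10H20O2": 2.0}),
    ]
    frame = summary_frame(tables)
    assert list(frame["sample_id"]) == ["a", "b"]
    assert frame.loc[0, "n_formulas"] == 2
    assert frame.loc[0, "frac_high_lability_count"] == pytest.approx(0.5)
    assert frame.loc[1, "fd"] == 0.0


def test_duplicate_formulas_rejected():
    f = MolecularFormula(5, 10, o=2)
    with pytest.raises(ValueError, match="duplicate"):
        SampleFormulaTable("s", (f, f))


def test_weights_normalised(rng):
    raw = rng.random(20) * 100
    formulas = tuple(MolecularFormula(int(c), 2, o=i)
                     for i, c in enumerate(rng.integers(1, 50, 20)))
    t = SampleFormulaTable("s", formulas, tuple(raw))
    assert t.weights.sum() == pytest.approx(1.0, abs=1e-12)
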