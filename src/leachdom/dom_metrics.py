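"""DOM composition statistics: functional diversity, lability, unique formulas.

A sample of dissolved organic matter is represented as the set of molecular
formulas assigned to its mass spectrum with intensity weights.  On top of
that substrate this module computes

* Rao quadratic-entropy functional diversity (FD) over the carbon-atom
  count — the abundance-weighted expected pairwise difference in carbon
  number, a proxy for diversity in molecule size;
* the lability dichotomy of a van Krevelen diagram (H:C >= 1.5 classed as
  high lability index), as count and intensity fractions;
* unique-formula set operations between a target sample (e.g. plastic
  leachate) and a panel of reference samples (lake DOM); and
* cross-referencing of unique formulas against a packaged table of known
  plastic additives and breakdown products.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import MolecularFormula

__all__ = [
    "SampleFormulaTable",
    "DomSummary",
    "AdditiveRecord",
    "AdditiveMatch",
    "UniqueFormulaResult",
    "functional_diversity",
    "lability_summary",
    "unique_formulas",
    "crossref_additives",
    "blank_correct",
    "load_additive_reference",
    "summarize_sample",
    "summary_frame",
]


@dataclass(frozen=True)
class SampleFormulaTable:
    """Per-sample set of molecular formulas with intensity weights.

    Formulas must be unique within a sample.  ``weights`` are the
    normalised intensities p_i (summing to 1); when all raw intensities are
    zero or missing, uniform weights are used.
    """

    sample_id: str
    formulas: tuple[MolecularFormula, ...]
    intensities: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.intensities and len(self.intensities) != len(self.formulas):
            raise ValueError("intensities must match formulas in length")
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be non-negative")
        if len(set(self.formulas)) != len(self.formulas):
            raise ValueError(f"duplicate formulas in sample {self.sample_id!r}")

    @property
    def n_formulas(self) -> int:
        return len(self.formulas)

    @property
    def weights(self) -> np.ndarray:
        """Normalised intensities p_i; uniform when intensities are absent/zero."""
        n = self.n_formulas
        if n == 0:
            return np.empty(0)
        raw = np.asarray(self.intensities, dtype=float) if self.intensities else np.zeros(n)
        total = raw.sum()
        if total > 0:
            return raw / total
        return np.full(n, 1.0 / n)

    @property
    def formula_set(self) -> frozenset[MolecularFormula]:
        return frozenset(self.formulas)

    def subset(self, keep: Iterable[MolecularFormula], sample_id: str | None = None) -> "SampleFormulaTable":
        keep = set(keep)
        pairs = [
            (f, self.intensities[i] if self.intensities else 1.0)
            for i, f in enumerate(self.formulas)
            if f in keep
        ]
        return SampleFormulaTable(
            sample_id=sample_id if sample_id is not None else self.sample_id,
            formulas=tuple(f for f, _ in pairs),
            intensities=tuple(w for _, w in pairs),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: formula string, raw intensity, weight and derived columns."""
        return pd.DataFrame(
            {
                "formula": [str(f) for f in self.formulas],
                "intensity": list(self.intensities) if self.intensities else [np.nan] * self.n_formulas,
                "weight": self.weights,
                "mass": [f.mass for f in self.formulas],
                "hc": [f.hc for f in self.formulas],
                "oc": [f.oc for f in self.formulas],
                "dbe": [f.dbe for f in self.formulas],
            }
        )

    @classmethod
    def from_pairs(cls, sample_id: str, pairs: Iterable[tuple[MolecularFormula, float]]) -> "SampleFormulaTable":
        pairs = list(pairs)
        return cls(
            sample_id=sample_id,
            formulas=tuple(f for f, _ in pairs),
            intensities=tuple(w for _, w in pairs),
        )


def functional_diversity(table: SampleFormulaTable, weighted: bool = True) -> float:
    """Rao quadratic entropy over carbon counts: FD = sum_ij p_i p_j |C_i - C_j|.

    The sum runs over ordered pairs (each unordered pair counted twice,
    i = j contributing zero).  ``weighted=False`` uses uniform weights
    regardless of intensities.  Empty and singleton tables give 0.

    Computed in O(n log n) via the sorted cumulative-weight identity
    E|X - Y| = 2 * sum_k F_k (1 - F_k) (c_(k+1) - c_(k)).
    """
    n = table.n_formulas
    if n <= 1:
        return 0.0
    carbons = np.array([f.c for f in table.formulas], dtype=float)
    p = table.weights if weighted else np.full(n, 1.0 / n)
    order = np.argsort(carbons, kind="stable")
    c_sorted = carbons[order]
    cum = np.cumsum(p[order])[:-1]
    gaps = np.diff(c_sorted)
    return float(2.0 * np.sum(cum * (1.0 - cum) * gaps))


def lability_summary(table: SampleFormulaTable, threshold: float = 1.5) -> tuple[float, float]:
    """Fractions of formulas (by count and by intensity) with H:C >= threshold.

    The boundary H:C exactly equal to the threshold counts as high lability.
    Empty tables give (0, 0).
    """
    n = table.n_formulas
    if n == 0:
        return 0.0, 0.0
    high = np.array([f.hc >= threshold for f in table.formulas])
    return float(high.mean()), float(table.weights[high].sum())


@dataclass(frozen=True)
class UniqueFormulaResult:
    """Formulas of a target sample absent from every reference sample."""

    table: SampleFormulaTable
    n_target: int
    n_unique: int

    @property
    def percent_unique(self) -> float:
        return 100.0 * self.n_unique / self.n_target if self.n_target else 0.0


def unique_formulas(
    target: SampleFormulaTable, references: Sequence[SampleFormulaTable]
) -> UniqueFormulaResult:
    """Subset of ``target`` whose formulas occur in none of the references.

    With an empty reference list the whole target is unique (100%).
    """
    seen: set[MolecularFormula] = set()
    for ref in references:
        seen.update(ref.formulas)
    keep = [f for f in target.formulas if f not in seen]
    return UniqueFormulaResult(
        table=target.subset(keep),
        n_target=target.n_formulas,
        n_unique=len(keep),
    )


@dataclass(frozen=True)
class AdditiveRecord:
    """A known plastic additive or breakdown product with its formula."""

    formula: MolecularFormula
    putative_name: str
    application: str
    printed_abundance_pct: float | None = None


@dataclass(frozen=True)
class AdditiveMatch:
    formula: MolecularFormula
    putative_name: str
    application: str
    relative_abundance_pct: float


def load_additive_reference() -> list[AdditiveRecord]:
    """The packaged reference table of plastic additives (13 CHO formulas).

    Two rows legitimately share C10H14O2: exact-formula matching cannot
    separate isomers, so both are reported as candidate identities.
    """
    path = resources.files("leachdom").joinpath("data/plastic_additives.csv")
    records = []
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            records.append(
                AdditiveRecord(
                    formula=MolecularFormula.parse(row["formula"]),
                    putative_name=row["putative_name"],
                    application=row["application"],
                    printed_abundance_pct=float(row["printed_abundance_pct"]),
                )
            )
    return records


def crossref_additives(
    uniques: SampleFormulaTable,
    reference: Sequence[AdditiveRecord],
    full: SampleFormulaTable | None = None,
) -> list[AdditiveMatch]:
    """Match unique formulas against the additive reference by exact identity.

    Relative abundance is the formula's intensity share of the FULL sample
    (all assigned formulas, not just the unique subset), as a percentage;
    pass the pre-subset table as ``full``.  Without it, the unique subset
    itself is the normalisation basis.
    """
    basis = full if full is not None else uniques
    weight_of = dict(zip(basis.formulas, basis.weights))
    unique_set = uniques.formula_set
    matches = []
    for record in reference:
        if record.formula in unique_set:
            matches.append(
                AdditiveMatch(
                    formula=record.formula,
                    putative_name=record.putative_name,
                    application=record.application,
                    relative_abundance_pct=100.0 * float(weight_of.get(record.formula, 0.0)),
                )
            )
    return matches


def blank_correct(sample: SampleFormulaTable, blank: SampleFormulaTable) -> SampleFormulaTable:
    """Drop formulas seen in the procedural blank; renormalise what remains.

    Removal is on formula identity, not intensity subtraction: any formula
    present in the blank at all is treated as a contaminant.
    """
    blank_set = blank.formula_set
    keep = [f for f in sample.formulas if f not in blank_set]
    return sample.subset(keep)


@dataclass(frozen=True)
class DomSummary:
    """Headline DOM statistics for one sample."""

    sample_id: str
    fd: float
    n_formulas: int
    frac_high_lability_count: float
    frac_high_lability_intensity: float


def summarize_sample(
    table: SampleFormulaTable, threshold: float = 1.5, weighted_fd: bool = True
) -> DomSummary:
    count_frac, intensity_frac = lability_summary(table, threshold)
    return DomSummary(
        sample_id=table.sample_id,
        fd=functional_diversity(table, weighted=weighted_fd),
        n_formulas=table.n_formulas,
        frac_high_lability_count=count_frac,
        frac_high_lability_intensity=intensity_frac,
    )


def summary_frame(tables: Sequence[SampleFormulaTable], **kwargs) -> pd.DataFrame:
    """One DomSummary row per sample, ready for CSV export."""
    rows = [summarize_sample(t, **kwargs).__dict__ for t in tables]
    return pd.DataFrame(rows)
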