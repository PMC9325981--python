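"""Molecular-formula arithmetic and assignment of formulas to negative-mode peak lists.

Ultrahigh-resolution mass spectrometry of dissolved organic matter (DOM)
resolves peak masses precisely enough that an elemental composition (an
isotope-free molecular formula over C, H, N, O and S) can be assigned to
each peak by exhaustive search within a small mass tolerance.  This module
provides the formula data model (exact monoisotopic masses, H:C and O:C
ratios, double-bond equivalents), the [M-H]- ion-mass arithmetic used in
negative-mode electrospray ionisation, and the assignment search itself
with the standard chemical-plausibility filters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "Peak",
    "FormulaAssignment",
    "PeakAssignment",
    "AssignmentConfig",
    "monoisotopic_mass",
    "ion_mass",
    "assign_formulas",
    "blank_correct",
]

#: Monoisotopic masses of the CHNOS alphabet, Da (CODATA/IUPAC values).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Mass of the proton removed on deprotonation, Da.
PROTON_MASS: float = 1.007276466621

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_ELEMENT_ORDER = ("C", "H", "N", "O", "S")  # Hill order for CHNOS


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """An isotope-free molecular formula over the CHNOS alphabet.

    Parameters
    ----------
    c, h, n, o, s
        Non-negative atom counts; at least one carbon is required.
    """

    c: int
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"atom count {name}={v!r} must be a non-negative integer")
        if self.c < 1:
            raise ValueError("a molecular formula requires at least one carbon atom")

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return monoisotopic_mass(self)

    @property
    def hc(self) -> float:
        """H:C atom ratio (the lability-index axis of a van Krevelen diagram)."""
        return self.h / self.c

    @property
    def oc(self) -> float:
        """O:C atom ratio."""
        return self.o / self.c

    @property
    def dbe(self) -> float:
        """Double-bond equivalents, c - h/2 + n/2 + 1."""
        return self.c - self.h / 2 + self.n / 2 + 1

    @property
    def heteroatoms(self) -> int:
        return self.n + self.s

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a formula string such as ``"C8H6O4"`` (underscores tolerated)."""
        cleaned = text.replace("_", "").strip()
        counts = {e: 0 for e in _ELEMENT_ORDER}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(cleaned):
            if match.start() != pos or not match.group(0):
                break
            element, digits = match.group(1), match.group(2)
            if element not in counts:
                raise ValueError(f"unsupported element {element!r} in {text!r}")
            counts[element] += int(digits) if digits else 1
            pos = match.end()
        if pos != len(cleaned) or pos == 0:
            raise ValueError(f"cannot parse molecular formula {text!r}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"], o=counts["O"], s=counts["S"])

    def __str__(self) -> str:
        parts = []
        for element in _ELEMENT_ORDER:
            count = getattr(self, element.lower())
            if count == 0:
                continue
            parts.append(element if count == 1 else f"{element}{count}")
        return "".join(parts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass (Da) as the sum of atom-count x element masses."""
    m = MONOISOTOPIC_MASS
    return (
        formula.c * m["C"]
        + formula.h * m["H"]
        + formula.n * m["N"]
        + formula.o * m["O"]
        + formula.s * m["S"]
    )


def ion_mass(formula: MolecularFormula, mode: str = "negative") -> float:
    """m/z of the singly charged [M-H]- ion (the only mode in scope).

    Raises
    ------
    ValueError
        If ``mode`` is not negative-mode deprotonation, or the formula has
        no hydrogen to remove.
    """
    if mode not in ("negative", "[M-H]-"):
        raise ValueError(f"unsupported ionisation mode {mode!r}; only negative-mode [M-H]- is supported")
    if formula.h < 1:
        raise ValueError(f"{formula} has no hydrogen and cannot be deprotonated")
    return monoisotopic_mass(formula) - PROTON_MASS


@dataclass(frozen=True)
class Peak:
    """A calibrated mass peak: measured m/z (Da, singly charged) and intensity."""

    mz: float
    intensity: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class FormulaAssignment:
    """One candidate formula for a peak with its signed mass error."""

    peak: Peak
    formula: MolecularFormula
    mass_error_ppm: float
    is_best: bool = False


@dataclass(frozen=True)
class PeakAssignment:
    """All in-tolerance candidates for one peak, ranked by |mass error|.

    An empty ``candidates`` tuple means the peak is unassigned.
    """

    peak: Peak
    candidates: tuple[FormulaAssignment, ...] = ()

    @property
    def best(self) -> FormulaAssignment | None:
        return self.candidates[0] if self.candidates else None


@dataclass(frozen=True)
class AssignmentConfig:
    """Element bounds, tolerance and plausibility filters for the assignment search.

    Defaults: C 1-60, H 1-120, N 0-4, O 0-40, S 0-2; 0.5 ppm tolerance;
    analytical window 150-1000 m/z; 0 <= H:C <= 2.5; 0 <= O:C <= 1.2;
    DBE >= 0; and the even-electron [M-H]- parity rule (h + n even in the
    closed-shell neutral, so the deprotonated anion is even-electron).
    """

    c_bounds: tuple[int, int] = (1, 60)
    h_bounds: tuple[int, int] = (1, 120)
    n_bounds: tuple[int, int] = (0, 4)
    o_bounds: tuple[int, int] = (0, 40)
    s_bounds: tuple[int, int] = (0, 2)
    tolerance_ppm: float = 0.5
    mz_window: tuple[float, float] = (150.0, 1000.0)
    hc_max: float = 2.5
    oc_max: float = 1.2
    require_even_electron: bool = True

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        for name in ("c_bounds", "h_bounds", "n_bounds", "o_bounds", "s_bounds", "mz_window"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (got {lo} > {hi})")

    def passes_filters(self, f: MolecularFormula) -> bool:
        """Chemical-plausibility filters applied to a candidate neutral formula."""
        if not (0.0 <= f.hc <= self.hc_max and 0.0 <= f.oc <= self.oc_max):
            return False
        if f.dbe < 0:
            return False
        if self.require_even_electron and (f.h + f.n) % 2 == 1:
            return False
        return True


# Candidate tables are expensive to enumerate, cheap to reuse; cache per config.
_CANDIDATE_CACHE: dict[AssignmentConfig, tuple[np.ndarray, np.ndarray]] = {}


def _candidate_table(config: AssignmentConfig) -> tuple[np.ndarray, np.ndarray]:
    """All plausible neutral formulas in the window, as (ion_mass_sorted, atoms).

    ``atoms`` is an (n, 5) int array of (c, h, n, o, s) sorted by [M-H]- mass.
    """
    cached = _CANDIDATE_CACHE.get(config)
    if cached is not None:
        return cached

    m = MONOISOTOPIC_MASS
    c_lo, c_hi = config.c_bounds
    h_lo, h_hi = max(1, config.h_bounds[0]), config.h_bounds[1]
    lo_mass = config.mz_window[0] + PROTON_MASS - 1.0
    hi_mass = config.mz_window[1] + PROTON_MASS + 1.0

    blocks: list[np.ndarray] = []
    c_arr = np.arange(c_lo, c_hi + 1)
    h_arr = np.arange(h_lo, h_hi + 1)
    cg, hg = np.meshgrid(c_arr, h_arr, indexing="ij")
    cg, hg = cg.ravel(), hg.ravel()
    base_ok = (hg <= config.hc_max * cg) & (cg - hg / 2 + 1 >= -2.5)  # n can add up to n_hi/2 to DBE
    for n_cnt in range(config.n_bounds[0], config.n_bounds[1] + 1):
        for s_cnt in range(config.s_bounds[0], config.s_bounds[1] + 1):
            for o_cnt in range(config.o_bounds[0], config.o_bounds[1] + 1):
                hetero_mass = n_cnt * m["N"] + o_cnt * m["O"] + s_cnt * m["S"]
                mass = cg * m["C"] + hg * m["H"] + hetero_mass
                ok = base_ok & (mass >= lo_mass) & (mass <= hi_mass)
                ok &= o_cnt <= config.oc_max * cg
                ok &= cg - hg / 2 + n_cnt / 2 + 1 >= 0
                if config.require_even_electron:
                    ok &= (hg + n_cnt) % 2 == 0
                if not ok.any():
                    continue
                cc, hh = cg[ok], hg[ok]
                block = np.empty((cc.size, 6))
                block[:, 0] = cc * m["C"] + hh * m["H"] + hetero_mass - PROTON_MASS
                block[:, 1] = cc
                block[:, 2] = hh
                block[:, 3] = n_cnt
                block[:, 4] = o_cnt
                block[:, 5] = s_cnt
                blocks.append(block)
    if blocks:
        table = np.concatenate(blocks)
        order = np.argsort(table[:, 0], kind="stable")
        table = table[order]
        ion_masses = table[:, 0].copy()
        atoms = table[:, 1:].astype(np.int64)
    else:  # pragma: no cover - degenerate bounds
        ion_masses = np.empty(0)
        atoms = np.empty((0, 5), dtype=np.int64)
    _CANDIDATE_CACHE[config] = (ion_masses, atoms)
    return ion_masses, atoms


def _rank_key(a: FormulaAssignment) -> tuple:
    # |ppm error| first; ties broken by fewer heteroatoms, then lower DBE,
    # then the canonical string so that the ordering is fully deterministic.
    f = a.formula
    return (abs(a.mass_error_ppm), f.heteroatoms, f.dbe, str(f))


def assign_formulas(
    peaks: Sequence[Peak],
    config: AssignmentConfig | None = None,
) -> list[PeakAssignment]:
    """Assign candidate CHNOS formulas to [M-H]- peaks by exhaustive search.

    Every candidate within ``config.tolerance_ppm`` of the measured m/z that
    passes the plausibility filters is returned, ranked by absolute ppm
    error; the best candidate is flagged.  Peaks outside the analytical
    window or with no surviving candidate come back unassigned.  The search
    is deterministic: identical peaks and config give identical output.
    """
    config = config or AssignmentConfig()
    if len(peaks) == 0:
        return []
    ion_masses, atoms = _candidate_table(config)
    results: list[PeakAssignment] = []
    lo_win, hi_win = config.mz_window
    for peak in peaks:
        if not (lo_win <= peak.mz <= hi_win):
            results.append(PeakAssignment(peak=peak))
            continue
        tol_da = peak.mz * config.tolerance_ppm * 1e-6
        lo = np.searchsorted(ion_masses, peak.mz - tol_da, side="left")
        hi = np.searchsorted(ion_masses, peak.mz + tol_da, side="right")
        candidates = []
        for i in range(lo, hi):
            c, h, n, o, s = atoms[i]
            formula = MolecularFormula(int(c), int(h), int(n), int(o), int(s))
            err_ppm = (peak.mz - ion_masses[i]) / ion_masses[i] * 1e6
            if abs(err_ppm) <= config.tolerance_ppm:
                candidates.append(FormulaAssignment(peak=peak, formula=formula, mass_error_ppm=err_ppm))
        candidates.sort(key=_rank_key)
        if candidates:
            candidates[0] = replace(candidates[0], is_best=True)
        results.append(PeakAssignment(peak=peak, candidates=tuple(candidates)))
    return results


def blank_correct(sample, blank):
    """Remove formulas present in the procedural blank from a sample table.

    Correction is on canonical formula identity (a formula seen in the blank
    is removed outright, not intensity-subtracted); surviving intensities are
    renormalised.  Both tables must come from the same assignment config.
    """
    from .dom_metrics import blank_correct as _impl  # table type lives with the DOM metrics

    return _impl(sample, blank)
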