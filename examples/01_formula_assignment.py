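"""Assign molecular formulas to a small negative-mode peak list.

Builds three peaks — two at the exact [M-H]- masses of known plastic
additives (isophthalic acid, dicyclohexyl phthalate) and one at an
arbitrary mass — and runs the exhaustive CHNOS search at 0.5 ppm.
"""

from leachdom import AssignmentConfig, MolecularFormula, Peak, assign_formulas, ion_mass

peaks = [
    Peak(mz=ion_mass(MolecularFormula.parse("C8H6O4")), intensity=120.0),
    Peak(mz=ion_mass(MolecularFormula.parse("C20H26O4")), intensity=80.0),
    Peak(mz=412.345678, intensity=5.0),
]

for pa in assign_formulas(peaks, AssignmentConfig(tolerance_ppm=0.5)):
    best = pa.best
    if best is None:
        print(f"m/z {pa.peak.mz:10.5f}  -> unassigned (no plausible CHNOS formula in 0.5 ppm)")
    else:
        f = best.formula
        print(
            f"m/z {pa.peak.mz:10.5f}  -> {f}  "
            f"(error {best.mass_error_ppm:+.3f} ppm, H:C {f.hc:.2f}, DBE {f.dbe:.0f}, "
            f"{len(pa.candidates)} candidate(s))"
        )

# The two exact masses come back as their generating formulas with ~0 ppm
# error; the arbitrary mass finds no chemically plausible composition.
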