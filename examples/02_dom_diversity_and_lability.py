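"""DOM composition metrics on a synthetic leachate / lake contrast.

Generates a small formula universe (a leachate sample with the additive
formulas injected, plus lake DOM samples), then computes functional
diversity (FD, the intensity-weighted expected carbon-number difference
between molecules), the H:C >= 1.5 lability fractions, the leachate's
unique formulas and their matches in the plastic-additive reference.
"""

import numpy as np

from leachdom import crossref_additives, load_additive_reference, unique_formulas
from leachdom.dom_metrics import functional_diversity, lability_summary
from leachdom.synthetic import StudyDesign, make_formula_universe, make_lake_covariates

rng = np.random.default_rng(42)
design = StudyDesign()
covariates = make_lake_covariates(design, rng)
universe = make_formula_universe(design, rng, covariates=covariates,
                                 n_lake_formulas=(600, 900))

leachate = universe.tables["leachate"]
count_frac, intensity_frac = lability_summary(leachate)
print(f"Leachate: {leachate.n_formulas} formulas, FD {functional_diversity(leachate):.2f}")
print(f"  high-lability (H:C >= 1.5): {100 * count_frac:.1f}% of formulas, "
      f"{100 * intensity_frac:.1f}% of intensity")

for lake in list(universe.lake_ids)[:3]:
    t = universe.tables[lake]
    cf, _ = lability_summary(t)
    print(f"Lake {lake}: {t.n_formulas} formulas, FD {functional_diversity(t):.2f}, "
          f"high-lability {100 * cf:.1f}%")

unique = unique_formulas(leachate, [universe.tables[l] for l in universe.lake_ids])
print(f"\nUnique to leachate: {unique.n_unique} of {unique.n_target} "
      f"({unique.percent_unique:.1f}%)")

matches = crossref_additives(unique.table, load_additive_reference(), full=leachate)
print(f"Known plastic additives among the unique formulas: {len(matches)}")
for m in matches[:4]:
    print(f"  {str(m.formula):10s} {m.putative_name:40s} {m.relative_abundance_pct:.2f}%")

# Leachate DOM is less size-diverse (lower FD) but far more labile than
# lake DOM, and its unique formulas include known plastic additives.
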