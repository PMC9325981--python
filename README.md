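# leachdom

Plastics shed dissolved organic matter (DOM) as they degrade, and that
leachate is chemically unlike the natural DOM of lakes: fewer, more
uniform molecules, but a much larger share of compounds labile enough for
bacteria to use. `leachdom` is a Python library for the full analysis
chain behind that question — from ultrahigh-resolution mass spectra and
raw bottle-incubation measurements to mixed-effects treatment inference
and taxon-level association statistics — built for limnologists and
microbial ecologists who want each step reusable, testable and offline.

## What it computes

**Molecular-formula assignment** (`leachdom.chem`). Negative-mode
FT-ICR-MS peaks are matched to isotope-free CHNOS formulas by exhaustive
search within a ppm tolerance, filtered by chemical plausibility
(0 ≤ H:C ≤ 2.5, 0 ≤ O:C ≤ 1.2, DBE ≥ 0, even-electron [M−H]⁻ parity) and
ranked by mass error. Procedural blanks are removed on formula identity.

**DOM composition statistics** (`leachdom.dom_metrics`). Functional
diversity as Rao quadratic entropy over carbon number,
FD = Σᵢⱼ pᵢ pⱼ |Cᵢ − Cⱼ|, with normalised peak intensities as weights;
the van Krevelen lability dichotomy (H:C ≥ 1.5) as count and intensity
fractions; unique-formula set operations and cross-referencing against a
packaged table of 13 known plastic additives and breakdown products.

**Bacterial metabolism** (`leachdom.metabolism`). Bacterial protein
production (BPP) from ³H-leucine scintillation counts (CPM → DPM via a
counting standard, 2.22×10¹² DPM Ci⁻¹, 1.55 kg C per mol leucine);
respiration from oxygen-optode % air-saturation series via the
García–Gordon solubility refit and a respiratory quotient of 1; growth
efficiency BGE = BPP/(BPP + respiration); carbon budgets and leachate
dosing volumes.

**Treatment inference** (`leachdom.mixed_model`). Log-scale linear mixed
models with lake random intercepts, fitted by a profiled (RE)ML
likelihood; collinearity screening (|r| > 0.90), AIC backwards
elimination (drop when retention does not lower AIC by more than 2),
estimated marginal means, fold changes and ±1 SD interaction probes with
Wald *t* intervals.

**ASV association** (`leachdom.asv_assoc`). Shannon diversity,
low-abundance filtering (< 100 total reads), median-of-ratios size
factors, per-ASV negative-binomial GLMs (log link, size-factor offset,
method-of-moments dispersion) against a metabolic fold-change covariate,
with Benjamini–Hochberg correction.

**Synthetic study data** (`leachdom.synthetic`). Every input above can be
generated with known ground truth at the scale of the motivating design —
29 lakes × 2 treatments, 3 production bottles and 1 respiration vial per
treatment, DOM for 22 lakes, 16S for 20, respiration for 18 — by
inverting the corresponding analysis chain, so round-trip recovery is
testable without any external data.

## Worked example

`examples/` holds one short script per capability. The end-to-end run
(`python examples/06_full_pipeline.py`) generates a synthetic bundle with
a planted 2.29× production effect and a 1.72× growth-efficiency effect,
then analyses it from the raw peak lists and counts upward:

```
leachdom pipeline summary
=========================
Leachate formulas assigned: 854
Unique to leachate: 299 (35.0%)
Known plastic additives matched: 13
Leachate FD (intensity-weighted): 3.86
High-lability fraction: 18.6% of formulas, 82.2% of intensity
BPP fold change (plastic/control): 2.24 [2.05, 2.46]
BGE fold change (plastic/control): 1.80 [1.63, 1.98]
ASVs: 150 total, 133 after filtering
ASVs positively associated with the BPP fold change: 15
```

Reading this: of the 855 leachate formulas planted by the generator, 854
survive assignment and blank correction; 35% occur in no lake sample, and
all 13 packaged additive formulas are found among them. The leachate's
functional diversity (3.86) is far below the lake range, while molecules
with H:C ≥ 1.5 make up 18.6% of its formulas but carry 82% of its signal
— the labile-leachate fingerprint. Downstream, the mixed models recover
the planted treatment folds within simulation error, and the ASV stage
concentrates its discoveries in the genera given planted slopes.

The same stages are exposed as a CLI for shell use:

```sh
leachdom generate --outdir bundle --seed 7
leachdom run --bundle bundle --outdir results --seed 7
```

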