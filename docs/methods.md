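# Methods

This note documents the models and numerical choices behind `leachdom`,
module by module, including the defaults, why they were chosen, and what
the synthetic-data generator does and does not emulate.

## Formula assignment (`chem`)

A measured negative-mode peak at m/z *m* is matched against the neutral
formulas C_c H_h N_n O_o S_s whose [M−H]⁻ ion mass (neutral monoisotopic
mass minus 1.0072765 Da) lies within the ppm tolerance of *m*. The search
is exhaustive over the element bounds (defaults C 1–60, H 1–120, N 0–4,
O 0–40, S 0–2), implemented by enumerating all plausible candidates in
the analytical window once per configuration into a sorted mass table and
binary-searching each peak; a test verifies that this returns exactly the
candidate set of an unpruned nested loop below 300 Da.

Plausibility filters: 0 ≤ H:C ≤ 2.5 and 0 ≤ O:C ≤ 1.2 (the populated
region of a van Krevelen diagram), double-bond equivalents
DBE = c − h/2 + n/2 + 1 ≥ 0, and the even-electron parity rule — a
closed-shell CHNOS neutral has h + n even (the nitrogen rule), so that
deprotonation yields an even-electron anion. Candidates are ranked by
absolute ppm error, with ties broken by fewer heteroatoms, then lower
DBE, then the canonical formula string, making the output fully
deterministic.

Defaults that are choices rather than physics: the 0.5 ppm tolerance is
typical of a well-calibrated 15 T FT-ICR instrument; the analytical
window defaults to 150–1000 m/z (a 150–2000 Da window is a one-line
config change); ions are assumed singly charged, standard for ESI⁻ DOM.
Phosphorus is excluded from the default alphabet because every formula
the package ships (the additive reference) is CHO; the bounds are
configurable where richer chemistry is expected. Blank correction
removes formulas by identity rather than subtracting intensities: a
compound seen in a procedural blank cannot be distinguished from
contamination at any intensity.

## DOM metrics (`dom_metrics`)

Functional diversity is the Rao quadratic entropy of the carbon-number
trait: FD = Σᵢ Σⱼ pᵢ pⱼ |Cᵢ − Cⱼ| over ordered pairs (i = j contributes
zero; each unordered pair counts twice — conventions differ and this one
is stated explicitly). Weights pᵢ are normalised peak intensities by
default, with a uniform-weight option, since trait-diversity indices of
this family are abundance-weighted and intensity is the only abundance
proxy a mass spectrum offers. The computation uses the sorted
cumulative-weight identity E|X − Y| = 2 Σₖ Fₖ(1 − Fₖ)(c₍ₖ₊₁₎ − c₍ₖ₎),
O(n log n), verified against the O(n²) pair sum to 1e-10.

The lability classification is the standard van Krevelen dichotomy:
H:C ≥ 1.5 (boundary inclusive) marks a formula as having a high lability
index. Both the count fraction and the intensity fraction are reported
because they answer different questions (how many kinds of labile
molecules vs how much labile signal). The intensity fraction is computed
over assigned, blank-corrected formulas — the only normalisation basis
that is well-defined after assignment.

Unique-formula analysis is a set difference on canonical formula
identity, and additive cross-referencing matches exactly on formula; two
reference rows legitimately share C10H14O2 and both are reported, since
formulas cannot resolve isomers. Matched abundances are expressed
relative to the full sample, not the unique subset.

## Metabolism (`metabolism`)

BPP: net CPM = live − killed − blank (clamped at zero with a warning;
field noise can push it negative), divided by the counting efficiency
(standard CPM / standard DPM) to give DPM, converted through
2.22×10¹² DPM Ci⁻¹ and the lot's specific activity (Ci mmol⁻¹) to moles
of leucine, then to carbon at 1.55 kg C per mol leucine — the standard
conversion without isotope dilution, appropriate when the added leucine
(17 nM scale) is treated as saturating. All constants are explicit
`ScintillationSet` fields; defaults are 1 h incubations of 1.5 mL.

Oxygen: optode series are % air saturation at 1 s cadence. The reading
used is the median of the last 10 values inside the latest "stable"
window, where stable means a trailing 10-point SD ≤ 0.1 % sat — the
threshold is an operational definition of "steady state" and is a config
value; if no window qualifies the median of the final readings is used
and flagged. Saturation converts to mg L⁻¹ via the García–Gordon refit
of the Benson–Krause solubility data (valid 0–40 °C, 0–40 PSU), scaled
linearly by pressure/1013.25. Respiration converts O2 drawdown to carbon
with a respiratory quotient of 1 (configurable); O2 production in a dark
incubation is clamped to zero with a warning.

BGE = BPP/(BPP + respiration), undefined (NaN) when both are zero. In
the tidy-table driver, BPP per lake × treatment is the mean of the three
replicate bottles and respiration comes from the single start/end vial
pair per treatment, mirroring the design's replication. The carbon
budget divides the cumulative biomass-carbon increase by BGE; the dosing
helper solves v·DOC = target·(V + v) so dilution by the added volume is
accounted for.

## Mixed models (`mixed_model`)

Responses are strictly positive and right-skewed, so models are fitted
to ln(response) with a lake random intercept; treatment contrasts
back-transform to fold changes. Covariates are z-scored before fitting,
which makes "±1 SD" probing exact and effect sizes comparable; the
standardisation statistics are stored on the fit and reused across
refits during elimination.

Fitting maximises the profiled (RE)ML likelihood in the variance ratio
λ = σ²_lake/σ²_resid: for fixed λ the GLS fixed effects and residual
variance are closed-form (per-group (I + λJ)⁻¹ = I − λ/(1 + λnᵢ)·J), so
only a scalar profile is optimised (bounded search on ln λ, with λ = 0
checked explicitly). This is deterministic, fast, and well behaved
exactly where free optimisation of the full likelihood struggles:
boundary variances and near-saturated fixed designs such as 16 fixed
effects on 36 observations. The test suite verifies agreement with
statsmodels MixedLM to 1e-6 on well-conditioned problems.

Model selection is single-term backwards deletion: under ML
(AIC = −2ℓ + 2k, k counting fixed effects plus both variances), every
droppable term is removed in turn and the removal with the lowest AIC is
accepted when it raises the AIC by at most 2 — i.e. a term is kept only
if retaining it lowers the AIC by more than 2. Marginality is respected
(a main effect is droppable only when no retained interaction contains
it) and the treatment main effect, being the design variable, is never
eliminable. Ties resolve to the lexicographically first term name. The
selected model is refit by REML for reporting.

Marginal means are computed at covariate means (z = 0), and at z = ∓1
when probing an interaction; fold change is exp of the treatment
contrast and equals the ratio of back-transformed means exactly.
Intervals are Wald *t* intervals with between-within residual degrees of
freedom, df = n − p − (g − 1): with only 18 lakes in the growth-
efficiency design, normal intervals measurably under-cover (~93% in
simulation), while the between-within t correction restores ~94–95%
coverage and remains closed-form — a deliberate middle ground short of
Satterthwaite/Kenward–Roger machinery. Collinearity screening drops the
lower-priority member of any covariate pair with |r| strictly > 0.90;
"biological relevance" is operationalised as a user-suppliable priority
order defaulting to FD > DOC > TN > temperature > pH > latitude >
Shannon.

## ASV association (`asv_assoc`)

Shannon diversity is computed in nats on unrarefied counts (rarefaction
discards data; the log base is a config choice). ASVs with fewer than
100 total reads across samples are removed before association (boundary
retained; a per-sample variant is available). Size factors are
median-of-ratios over ASVs present in every sample, with an optional
pseudocount for sparse tables.

The association model is a deliberately plain per-ASV negative-binomial
GLM: log link, offset = log size factor, design = intercept + covariate,
NB2 dispersion per ASV by method of moments around an initial Poisson
fit (floored at 1e-8), Wald tests, slopes reported in log2 units.
Dispersion shrinkage across ASVs, outlier filtering and independent
filtering are intentionally not reproduced — the transparent estimator
costs some power relative to shrinkage-based tools, so absolute
discovery counts are not comparable with them, but its type-I behaviour
is calibrated (4–7% at α = 0.05 under a Poisson null in the acceptance
suite). The covariate is the per-lake fold change of the metabolic rate
(plastic/control), log2-transformed for symmetry. BH adjustment is the
step-up q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j with missing p-values passed through
and excluded from m.

## Synthetic data (`synthetic`)

The generator's defaults are the study conditions the package is built
around: 29 lakes, 2 treatments, 3 production bottles and 1 respiration
vial per treatment, DOM spectra in 22 lakes, 16S in 20, respiration in
18; covariates uniform over the observed field ranges (DOC
0.55–7.97 mg L⁻¹, pH 5.81–6.95, temperature 9.4–20.6 °C, FD 6.12–6.96,
latitude 59.1–70.3 °N, Shannon 3.46–6.38 nats). TN has no published
range and defaults to 0.1–0.9 mg L⁻¹, realistic for boreal lakes.
Planted effects default to the headline values: a 2.29× production fold
(with a 0.35 log-SD of between-lake heterogeneity, without which the
per-lake fold covariate of the ASV stage would be pure noise), a 1.72×
growth-efficiency fold moderated by FD at −0.335 per SD, lake random
intercepts of 0.4 and bottle residuals of 0.25 on the log scale.

Each generator inverts its consuming module. Formula sets are drawn from
the exhaustively enumerated CHO universe with exact high-lability count
fractions (leachate 18.6%, lakes 10.3–12.5%) and the intensity share of
the labile group rescaled to its target (82.2% for leachate); the 13
additive formulas are always injected into the leachate and withheld
from every lake, and a shared subset sized by the overlap fraction
(default 0.65, hence 35% unique) is placed in all lakes. Leachate draws
are weighted toward mid-teens carbon numbers and lake draws toward a
wider distribution centred at C₂₅, reproducing the low-FD leachate /
high-FD lake contrast qualitatively. Peak m/z values are exact ion
masses with 0.05 ppm Gaussian error (well inside the 0.5 ppm tolerance);
30 blank contaminants are spiked into every raw peak list. Scintillation
counts are produced by running the leucine arithmetic backwards plus
Poisson counting noise; oxygen series as an equilibration transient
decaying onto the solubility-model plateau with 0.02 % sat noise. With
noise disabled every chain is exact, and the tests require < 2% rate
recovery through the full CPM/O2 path.

These defaults are a calibration, not a validation: pipeline output on
synthetic data matching the headline numbers shows the machinery is
self-consistent, not that the field values are reproduced. What the
generator does not emulate: mass-spectral noise physics (peak shoulders,
dynamic-range compression, isotopologues), spatial structure among lake
covariates, phylogenetic correlation among ASVs, and taxon-specific
substrate preferences. The default ASV scale (300 ASVs × 20 samples) is
reduced from the ~2100 of a real survey for desk runtime; the full scale
is one argument away.

## Problem sizes in the shipped checks

The test and acceptance runs use: FD oracle equivalence to n = 2000;
BH oracle to m = 1000; coverage of the treatment-effect intervals over
1000 simulated experiments per response design; NB type-I calibration
over 500 ASVs × 20 Poisson-null tables and slope recovery over 50
planted tables of 100 ASVs; elimination behaviour over 60 simulated
datasets per scenario; and one full study-scale bundle (855 leachate +
22 × 3700–7100 lake formulas, all incubations, 300 ASVs) run end to end.
These sizes keep a complete run to a few minutes on one core while
leaving every statistical check at or above the scale of the motivating
design.

## Known limitations

Assignment resolves formulas, not structures, and close heteroatom
candidates can displace the true composition at high mass — the
generator's peak lists occasionally lose one or two formulas to such
collisions, visible as 853–855 assigned leachate formulas. The mixed
model supports a single random intercept only (no random slopes or
crossed designs). The NB association's moment dispersion is noisy for
low-count ASVs, which is the main reason shrinkage estimators exist; the
abundance filter mitigates but does not remove this. Wald t intervals
are approximate for variance parameters near the boundary.
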