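"""Synthetic study-data generator with known ground truth.

Emulates every input the analysis consumes, at the scale of the field
campaign the pipeline is built around: 29 lakes sampled once, a plastic
and a control treatment per lake, three replicate production bottles and
one respiration vial per treatment, DOM spectra for 22 lakes, 16S data
for 20 and respiration for 18.  Each generator is the inverse of the
module that consumes its output — scintillation counts are produced from
known true production rates through the same leucine arithmetic run
backwards, optode series from known respiration through the solubility
model, mass peak lists from known formula sets through exact ion masses —
so round-trip recovery at zero noise is exact by construction and every
downstream statistic has a known target.

All randomness flows from a single ``numpy`` Generator; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import AssignmentConfig, MolecularFormula, ion_mass, _candidate_table
from .dom_metrics import SampleFormulaTable, load_additive_reference
from .asv_assoc import AsvCountTable
from .metabolism import (
    C_MOLAR_MASS,
    DPM_PER_CURIE,
    O2_MOLAR_MASS,
    o2_saturation_concentration,
)

__all__ = [
    "StudyDesign",
    "FormulaBundle",
    "IncubationBundle",
    "make_lake_covariates",
    "make_formula_universe",
    "make_incubation_data",
    "make_response_data",
    "make_asv_table",
    "generate_bundle",
]

_NAMED_GENERA = ("Acinetobacter", "Exiguobacterium", "Brevundimonas", "Hymenobacter", "Deinococcus")


@dataclass(frozen=True)
class StudyDesign:
    """The study layout and the planted effect/noise parameters.

    Covariate ranges are the observed ranges of the field campaign; the
    planted treatment folds default to the headline effects (2.29x on
    production, 1.72x on growth efficiency, the latter moderated by DOM
    functional diversity).
    """

    n_lakes: int = 29
    lakes_with_dom: int = 22
    lakes_with_16s: int = 20
    lakes_with_respiration: int = 18
    bpp_replicates: int = 3
    bge_replicates: int = 1

    doc_range: tuple[float, float] = (0.55, 7.97)        # mg C L-1
    tn_range: tuple[float, float] = (0.1, 0.9)           # mg N L-1
    temperature_range: tuple[float, float] = (9.4, 20.6) # deg C
    ph_range: tuple[float, float] = (5.81, 6.95)
    latitude_range: tuple[float, float] = (59.1, 70.3)   # deg N
    fd_range: tuple[float, float] = (6.12, 6.96)
    shannon_range: tuple[float, float] = (3.46, 6.38)    # nats

    baseline_bpp: float = 0.078       # ug C L-1 h-1, control mean
    baseline_bge: float = 0.081       # fraction, control mean
    treatment_fold_bpp: float = 2.29
    bpp_fold_sd: float = 0.35          # between-lake SD of the log BPP fold
    treatment_fold_bge: float = 1.72
    bge_fd_interaction: float = -0.335  # log-scale slope of the treatment effect per SD of FD
    lake_sd: float = 0.40             # random-intercept SD on the log scale
    resid_sd: float = 0.25            # residual SD on the log scale
    incubation_hours: float = 72.0

    def __post_init__(self) -> None:
        for name in ("lakes_with_dom", "lakes_with_16s", "lakes_with_respiration"):
            if getattr(self, name) > self.n_lakes:
                raise ValueError(f"{name} exceeds n_lakes")
        for name in ("doc_range", "tn_range", "temperature_range", "ph_range",
                     "latitude_range", "fd_range", "shannon_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")

    @property
    def lake_ids(self) -> tuple[str, ...]:
        return tuple(f"L{i:02d}" for i in range(1, self.n_lakes + 1))


def make_lake_covariates(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Lake covariates drawn uniformly over the study ranges + availability masks."""
    n = design.n_lakes
    df = pd.DataFrame(
        {
            "lake": design.lake_ids,
            "doc": rng.uniform(*design.doc_range, n),
            "tn": rng.uniform(*design.tn_range, n),
            "temperature": rng.uniform(*design.temperature_range, n),
            "ph": rng.uniform(*design.ph_range, n),
            "latitude": rng.uniform(*design.latitude_range, n),
            "fd": rng.uniform(*design.fd_range, n),
            "shannon": rng.uniform(*design.shannon_range, n),
        }
    ).set_index("lake")
    for col, count in (
        ("has_dom", design.lakes_with_dom),
        ("has_16s", design.lakes_with_16s),
        ("has_respiration", design.lakes_with_respiration),
    ):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=count, replace=False)] = True
        df[col] = mask
    return df


# ---------------------------------------------------------------------------
# DOM formula universe


@dataclass(frozen=True)
class FormulaBundle:
    """Ground-truth formula tables and the peak lists derived from them."""

    tables: dict          # sample_id -> SampleFormulaTable (contaminant-free truth)
    peaks: dict           # sample_id -> DataFrame(mz, intensity), incl. 'blank'
    blank_formulas: tuple # contaminants present in every raw peak list
    lake_ids: tuple


def _scale_high_intensities(
    high: np.ndarray, intensities: np.ndarray, target_fraction: float
) -> np.ndarray:
    """Rescale the high-lability group so its intensity share hits the target."""
    hi_sum = intensities[high].sum()
    lo_sum = intensities[~high].sum()
    if hi_sum == 0 or lo_sum == 0 or not (0 < target_fraction < 1):
        return intensities
    f = target_fraction * lo_sum / ((1 - target_fraction) * hi_sum)
    out = intensities.copy()
    out[high] *= f
    return out


def make_formula_universe(
    design: StudyDesign,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
    n_leachate_formulas: int = 855,
    n_lake_formulas: tuple[int, int] = (3700, 7100),
    overlap_fraction: float = 0.65,
    leachate_lability: float = 0.186,
    leachate_intensity_lability: float = 0.822,
    lake_lability: tuple[float, float] = (0.103, 0.125),
    lake_intensity_lability: tuple[float, float] = (0.054, 0.106),
    n_blank: int = 30,
    ppm_sd: float = 0.05,
    config: AssignmentConfig | None = None,
) -> FormulaBundle:
    """Random CHO formula sets for leachate, lakes and a procedural blank.

    The plastic-additive reference formulas are always injected into the
    leachate (and kept out of every lake, so they stay unique); the
    high-lability count fraction and the leachate/lake overlap are exact
    by construction.  Peak m/z values are exact [M-H]- masses perturbed by
    Gaussian ppm error; blank contaminants are spiked into every raw peak
    list so that blank correction is exercised downstream.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if not (0.0 <= leachate_lability <= 1.0):
        raise ValueError("leachate_lability must lie in [0, 1]")
    config = config or AssignmentConfig()
    cho = AssignmentConfig(
        n_bounds=(0, 0), s_bounds=(0, 0),
        c_bounds=config.c_bounds, h_bounds=config.h_bounds, o_bounds=config.o_bounds,
        tolerance_ppm=config.tolerance_ppm, mz_window=config.mz_window,
    )
    _, atoms = _candidate_table(cho)
    pool = [MolecularFormula(int(c), int(h), int(n), int(o), int(s)) for c, h, n, o, s in atoms]
    additives = []
    for record in load_additive_reference():
        if record.formula not in additives:
            additives.append(record.formula)
    additive_set = set(additives)
    pool = [f for f in pool if f not in additive_set]
    hc = np.array([f.hc for f in pool])
    carbon = np.array([f.c for f in pool], dtype=float)
    high_idx = np.nonzero(hc >= 1.5)[0]
    low_idx = np.nonzero(hc < 1.5)[0]

    def sample_set(n_total: int, frac_high: float, exclude: set, carbon_center: float | None = None):
        n_high = int(round(frac_high * n_total))
        n_low = n_total - n_high
        chosen: list[MolecularFormula] = []
        for idx_pool, n_want in ((high_idx, n_high), (low_idx, n_low)):
            avail = np.array([i for i in idx_pool if pool[i] not in exclude])
            if n_want > avail.size:
                raise ValueError("formula pool too small for the requested set")
            if carbon_center is not None:
                w = np.exp(-0.5 * ((carbon[avail] - carbon_center) / 4.0) ** 2) + 1e-9
                w /= w.sum()
            else:
                w = None
            take = rng.choice(avail, size=n_want, replace=False, p=w)
            chosen.extend(pool[i] for i in take)
        return chosen

    # procedural blank contaminants: never overlap anything real
    blank_formulas = sample_set(n_blank, 0.2, exclude=set())
    used: set[MolecularFormula] = set(blank_formulas)

    # leachate: additives + controlled lability fraction, narrow carbon spread
    n_extra = n_leachate_formulas - len(additives)
    n_high_target = int(round(leachate_lability * n_leachate_formulas))
    extra = sample_set(n_extra, n_high_target / n_extra, exclude=used, carbon_center=14.0)
    leachate_formulas = list(additives) + extra
    used.update(leachate_formulas)

    # shared (non-unique) leachate subset injected into every lake
    non_additive = [f for f in leachate_formulas if f not in additive_set]
    n_shared = int(round(overlap_fraction * n_leachate_formulas))
    if n_shared > len(non_additive):
        raise ValueError("overlap_fraction too high: additives must stay unique to the leachate")
    shared = [non_additive[i] for i in rng.choice(len(non_additive), size=n_shared, replace=False)]
    shared_high = sum(f.hc >= 1.5 for f in shared)

    if covariates is None:
        covariates = make_lake_covariates(design, rng)
    lake_ids = tuple(covariates.index[covariates["has_dom"]])

    # lakes may share formulas with each other but never with blank
    # contaminants or with anything in the leachate outside the shared set
    lake_avail_high = np.array([i for i in high_idx if pool[i] not in used])
    lake_avail_low = np.array([i for i in low_idx if pool[i] not in used])
    # natural lake DOM spans a wider carbon-number range than leachate but is
    # still centred in the CRAM-like mid-mass region
    lake_weights = {}
    for key, avail in (("high", lake_avail_high), ("low", lake_avail_low)):
        w = np.exp(-0.5 * ((carbon[avail] - 25.0) / 8.0) ** 2) + 1e-9
        lake_weights[key] = w / w.sum()

    def table_with_intensities(sample_id, formulas, intensity_target):
        intensities = rng.lognormal(mean=0.0, sigma=1.0, size=len(formulas))
        high = np.array([f.hc >= 1.5 for f in formulas])
        intensities = _scale_high_intensities(high, intensities, intensity_target)
        return SampleFormulaTable(sample_id=sample_id, formulas=tuple(formulas),
                                  intensities=tuple(intensities))

    tables: dict[str, SampleFormulaTable] = {}
    tables["leachate"] = table_with_intensities("leachate", leachate_formulas,
                                                leachate_intensity_lability)
    for lake in lake_ids:
        n_total = int(rng.integers(n_lake_formulas[0], n_lake_formulas[1] + 1))
        frac = rng.uniform(*lake_lability)
        n_high = int(round(frac * n_total))
        own_high = max(0, n_high - shared_high)
        own_low = max(0, (n_total - n_high) - (len(shared) - shared_high))
        own: list[MolecularFormula] = []
        for key, avail, n_want in (("high", lake_avail_high, own_high),
                                   ("low", lake_avail_low, own_low)):
            take = rng.choice(avail, size=n_want, replace=False, p=lake_weights[key])
            own.extend(pool[i] for i in take)
        formulas = shared + own
        tables[lake] = table_with_intensities(
            lake, formulas, rng.uniform(*lake_intensity_lability)
        )

    peaks: dict[str, pd.DataFrame] = {}
    blank_intensity = rng.lognormal(mean=0.0, sigma=0.5, size=len(blank_formulas))

    def peak_frame(formulas, intensities):
        mz = np.array([ion_mass(f) for f in formulas])
        mz = mz * (1.0 + rng.normal(0.0, ppm_sd, size=mz.size) * 1e-6)
        frame = pd.DataFrame({"mz": mz, "intensity": intensities})
        return frame.sort_values("mz", ignore_index=True)

    peaks["blank"] = peak_frame(blank_formulas, blank_intensity)
    for sample_id, table in tables.items():
        formulas = list(table.formulas) + list(blank_formulas)
        intensities = np.concatenate([np.asarray(table.intensities), blank_intensity])
        peaks[sample_id] = peak_frame(formulas, intensities)

    return FormulaBundle(
        tables=tables, peaks=peaks, blank_formulas=tuple(blank_formulas), lake_ids=lake_ids
    )


# ---------------------------------------------------------------------------
# Incubations


@dataclass(frozen=True)
class IncubationBundle:
    """Raw incubation tables plus the true rates they were generated from."""

    scintillation: pd.DataFrame
    oxygen_meta: pd.DataFrame
    oxygen_series: pd.DataFrame
    truth: pd.DataFrame    # lake x treatment true bpp / respiration / bge

    # instrument constants used for the inversion (shared with the truth)
    counting_efficiency: float = 0.85
    standard_dpm: float = 1.0e5
    leucine_specific_activity: float = 60.0  # Ci mmol-1


def _true_cell_rates(
    design: StudyDesign, rng: np.random.Generator, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Planted per-lake true rates for both treatments.

    Control production is log-normal around the baseline with a lake
    random effect; the plastic arm multiplies it by the planted fold.  The
    BGE fold is moderated by the lake's (z-scored) DOM functional
    diversity through ``design.bge_fd_interaction``.
    """
    z_fd = (covariates["fd"] - covariates["fd"].mean()) / covariates["fd"].std(ddof=1)
    rows = []
    for lake in design.lake_ids:
        u = rng.normal(0.0, design.lake_sd)
        bpp_control = design.baseline_bpp * np.exp(u)
        bpp_plastic = bpp_control * design.treatment_fold_bpp * np.exp(
            rng.normal(0.0, design.bpp_fold_sd)
        )
        log_bge_effect = np.log(design.treatment_fold_bge) + design.bge_fd_interaction * z_fd[lake]
        bge_control = min(0.6, design.baseline_bge * np.exp(rng.normal(0.0, 0.25)))
        bge_plastic = min(0.6, bge_control * np.exp(log_bge_effect))
        for treatment, bpp, bge in (
            ("control", bpp_control, bge_control),
            ("plastic", bpp_plastic, bge_plastic),
        ):
            respiration = bpp * (1.0 - bge) / bge
            rows.append({"lake": lake, "treatment": treatment, "bpp": bpp,
                         "respiration": respiration, "bge": bge})
    return pd.DataFrame(rows)


def make_incubation_data(
    design: StudyDesign,
    rng: np.random.Generator,
    covariates: pd.DataFrame | None = None,
    true_rates: pd.DataFrame | None = None,
    noise: bool = True,
    n_readings: int = 240,
) -> IncubationBundle:
    """Scintillation counts and optode series inverted from true rates.

    Counts: the leucine arithmetic run backwards (carbon -> mol leucine ->
    DPM -> CPM via the counting efficiency) plus Poisson counting noise.
    Oxygen: % saturation start/end values from the solubility model, each
    series an equilibration transient decaying onto a plateau with small
    optode noise.  With ``noise=False`` both chains are exact and the
    consuming module recovers the true rates to machine precision (modulo
    CPM rounding, which is disabled in that case).
    """
    if covariates is None:
        covariates = make_lake_covariates(design, rng)
    if true_rates is None:
        true_rates = _true_cell_rates(design, rng, covariates)
    eff, standard_dpm, sa = 0.85, 1.0e5, 60.0
    vol_l, hours = 0.0015, 1.0
    cpm_killed, cpm_blank = 30.0, 20.0

    scint_rows = []
    o2_meta_rows = []
    o2_series_frames = []
    truth = true_rates.set_index(["lake", "treatment"])

    for (lake, treatment), row in truth.iterrows():
        has_resp = bool(covariates.loc[lake, "has_respiration"])
        for rep in range(1, design.bpp_replicates + 1):
            bpp = row["bpp"] * (np.exp(rng.normal(0.0, design.resid_sd)) if noise else 1.0)
            ug_c = bpp * vol_l * hours
            mol_leu = ug_c * 1e-9 / 1.55
            net_cpm = mol_leu * 1000.0 * sa * DPM_PER_CURIE * eff
            live = net_cpm + cpm_killed + cpm_blank
            if noise:
                live = float(rng.poisson(live))
            scint_rows.append({
                "bottle_id": f"{lake}-{treatment}-b{rep}",
                "lake": lake, "treatment": treatment, "replicate": rep,
                "cpm_live": live, "cpm_killed": cpm_killed, "cpm_blank": cpm_blank,
                "cpm_standard": eff * standard_dpm, "standard_dpm": standard_dpm,
                "leucine_specific_activity": sa,
                "incubation_hours": hours, "sample_volume_l": vol_l,
            })
        if not has_resp:
            continue
        temp = float(covariates.loc[lake, "temperature"])
        sat = o2_saturation_concentration(temp)
        start_pct = 100.0
        delta_mg = row["respiration"] * design.incubation_hours * O2_MOLAR_MASS / C_MOLAR_MASS / 1000.0
        end_pct = (start_pct / 100.0 * sat - delta_mg) / sat * 100.0
        for phase, pct in (("start", start_pct), ("end", end_pct)):
            vial = f"{lake}-{treatment}-o2-{phase}"
            t = np.arange(n_readings, dtype=float)
            series = np.full(n_readings, pct)
            if noise:
                series = pct + 2.0 * np.exp(-t / 30.0) + rng.normal(0.0, 0.02, n_readings)
            o2_meta_rows.append({
                "vial_id": vial, "lake": lake, "treatment": treatment, "phase": phase,
                "temperature_c": temp, "salinity_psu": 0.0, "pressure_hpa": 1013.25,
                "duration_h": design.incubation_hours,
            })
            o2_series_frames.append(pd.DataFrame({
                "vial_id": vial, "t_seconds": t.astype(int), "pct_saturation": series,
            }))

    return IncubationBundle(
        scintillation=pd.DataFrame(scint_rows),
        oxygen_meta=pd.DataFrame(o2_meta_rows),
        oxygen_series=(
            pd.concat(o2_series_frames, ignore_index=True)
            if o2_series_frames else pd.DataFrame(columns=["vial_id", "t_seconds", "pct_saturation"])
        ),
        truth=true_rates,
        counting_efficiency=eff,
        standard_dpm=standard_dpm,
        leucine_specific_activity=sa,
    )


# ---------------------------------------------------------------------------
# Mixed-model responses


def make_response_data(
    design: StudyDesign,
    rng: np.random.Generator,
    response: str = "bpp",
    covariates: pd.DataFrame | None = None,
    main_effects: dict | None = None,
    interactions: dict | None = None,
    lake_sd: float | None = None,
    resid_sd: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Bottle-level log-normal responses drawn from the mixed model itself.

    log y = log(baseline) + b_t * treat + sum_k m_k z_k
            + sum_k g_k treat * z_k + u_lake + eps,
    with z the population-z-scored covariates.  Defaults plant the headline
    treatment folds; the BGE scenario includes the FD x treatment
    interaction.  Returns the tidy frame and the ground-truth parameters.
    """
    if response not in ("bpp", "bge"):
        raise ValueError("response must be 'bpp' or 'bge'")
    if covariates is None:
        covariates = make_lake_covariates(design, rng)
    if response == "bpp":
        lakes = list(design.lake_ids)
        n_rep = design.bpp_replicates
        baseline, fold = design.baseline_bpp, design.treatment_fold_bpp
        interactions = {} if interactions is None else dict(interactions)
    else:
        lakes = list(covariates.index[covariates["has_respiration"]])
        n_rep = design.bge_replicates
        baseline, fold = design.baseline_bge, design.treatment_fold_bge
        interactions = (
            {"fd": design.bge_fd_interaction} if interactions is None else dict(interactions)
        )
    main_effects = {} if main_effects is None else dict(main_effects)
    lake_sd = design.lake_sd if lake_sd is None else lake_sd
    resid_sd = design.resid_sd if resid_sd is None else resid_sd

    cov_names = sorted(set(main_effects) | set(interactions))
    z = {}
    for name in cov_names:
        vals = covariates.loc[lakes, name].to_numpy(dtype=float)
        z[name] = (vals - vals.mean()) / vals.std(ddof=1)

    b_t = float(np.log(fold))
    rows = []
    for li, lake in enumerate(lakes):
        u = rng.normal(0.0, lake_sd)
        for treatment, treat in (("control", 0.0), ("plastic", 1.0)):
            for rep in range(1, n_rep + 1):
                log_y = np.log(baseline) + b_t * treat + u + rng.normal(0.0, resid_sd)
                for name in cov_names:
                    log_y += main_effects.get(name, 0.0) * z[name][li]
                    log_y += interactions.get(name, 0.0) * treat * z[name][li]
                row = {"lake_id": lake, "treatment": treatment, "replicate": rep,
                       "response": float(np.exp(log_y))}
                for name in covariates.columns:
                    if not name.startswith("has_"):
                        row[name] = float(covariates.loc[lake, name])
                rows.append(row)
    truth = {"log_treatment_effect": b_t, "fold": fold,
             "main_effects": main_effects, "interactions": interactions,
             "lake_sd": lake_sd, "resid_sd": resid_sd}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# ASV tables


def make_asv_table(
    design: StudyDesign,
    rng: np.random.Generator,
    n_asvs: int = 300,
    samples: Sequence[str] | None = None,
    covariate: pd.Series | None = None,
    planted_fraction: float = 0.1,
    planted_slope_log2: float = 1.5,
    dispersion: float = 0.2,
    library_factor_range: tuple[float, float] = (0.5, 2.0),
) -> tuple[AsvCountTable, pd.Series, tuple[str, ...]]:
    """Negative-binomial ASV counts with planted covariate slopes.

    Baseline abundances are log-normal, library sizes vary by the given
    factor range, and a ``planted_fraction`` of ASVs respond to the
    per-sample covariate with slope ``planted_slope_log2`` (log2 units per
    covariate unit).  Returns (table, covariate, planted ASV ids).
    Planted ASVs are labelled with the leachate-responsive genera so the
    demo report reads like the field study; the rest draw generic labels.
    """
    if samples is None:
        samples = [f"L{i:02d}" for i in range(1, design.lakes_with_16s + 1)]
    samples = list(samples)
    n_samples = len(samples)
    if covariate is None:
        covariate = pd.Series(rng.normal(1.0, 0.5, n_samples), index=samples, name="covariate")
    x = covariate.loc[samples].to_numpy(dtype=float)

    n_planted = int(round(planted_fraction * n_asvs))
    planted = rng.choice(n_asvs, size=n_planted, replace=False)
    slopes = np.zeros(n_asvs)
    slopes[planted] = planted_slope_log2

    base = rng.lognormal(mean=3.0, sigma=1.2, size=n_asvs)
    lib = np.exp(rng.uniform(np.log(library_factor_range[0]), np.log(library_factor_range[1]),
                             n_samples))
    mu = base[:, None] * lib[None, :] * np.exp2(slopes[:, None] * x[None, :])
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    asv_ids = [f"ASV{i + 1:04d}" for i in range(n_asvs)]
    genera = []
    responsive = set(planted.tolist())
    for i in range(n_asvs):
        if i in responsive:
            genera.append(_NAMED_GENERA[3 + (i % 2)])  # Hymenobacter / Deinococcus
        else:
            genera.append(
                _NAMED_GENERA[i % 3] if rng.random() < 0.3 else f"Genus{i + 1:04d}"
            )
    table = AsvCountTable(
        counts=pd.DataFrame(counts, index=asv_ids, columns=samples),
        taxonomy=pd.Series(genera, index=asv_ids, name="genus"),
    )
    return table, covariate, tuple(asv_ids[i] for i in planted)


# ---------------------------------------------------------------------------
# Bundle writer


def generate_bundle(
    design: StudyDesign,
    outdir: str | Path,
    seed: int = 0,
    n_lake_formulas: tuple[int, int] = (3700, 7100),
    n_asvs: int = 300,
) -> dict:
    """Write the full synthetic input bundle (peak lists, incubation CSVs,
    covariates, ASV tables and a ground-truth JSON) into ``outdir``.

    Returns a manifest of the files written and the planted truth.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    covariates = make_lake_covariates(design, rng)

    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    universe = make_formula_universe(design, rng, covariates=covariates,
                                     n_lake_formulas=n_lake_formulas)
    for sample_id, frame in universe.peaks.items():
        frame.to_csv(peaks_dir / f"{sample_id}.csv", index=False)

    incubation = make_incubation_data(design, rng, covariates=covariates)
    incubation.scintillation.to_csv(outdir / "scintillation.csv", index=False)
    incubation.oxygen_meta.to_csv(outdir / "oxygen_meta.csv", index=False)
    incubation.oxygen_series.to_csv(outdir / "oxygen_series.csv", index=False)
    incubation.truth.to_csv(outdir / "true_rates.csv", index=False)

    covariates.reset_index().to_csv(outdir / "lake_covariates.csv", index=False)

    lakes_16s = list(covariates.index[covariates["has_16s"]])
    bpp_fold = incubation.truth.pivot(index="lake", columns="treatment", values="bpp")
    covariate = pd.Series(
        np.log2(bpp_fold.loc[lakes_16s, "plastic"] / bpp_fold.loc[lakes_16s, "control"]),
        index=lakes_16s, name="log2_bpp_fold",
    )
    table, covariate, planted = make_asv_table(
        design, rng, n_asvs=n_asvs, samples=lakes_16s, covariate=covariate
    )
    table.to_tsv(outdir / "asv_counts.tsv", outdir / "asv_taxonomy.tsv")

    truth = {
        "seed": seed,
        "treatment_fold_bpp": design.treatment_fold_bpp,
        "treatment_fold_bge": design.treatment_fold_bge,
        "bge_fd_interaction": design.bge_fd_interaction,
        "n_leachate_formulas": universe.tables["leachate"].n_formulas,
        "planted_asvs": list(planted),
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=2)
    return truth
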