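"""Bacterial metabolism from raw incubation measurements.

Converts the two raw measurement streams of a dark bottle incubation into
rates of bacterial carbon metabolism:

* scintillation counts from [3H]-leucine incorporation -> bacterial
  protein production (BPP, ug C L-1 h-1), via DPM conversion, counting
  efficiency from a standard of known activity, and a leucine-to-carbon
  factor;
* oxygen-optode time series (% air saturation) before and after the
  incubation -> respiration (ug C L-1 h-1), via an air-saturation
  solubility model (Garcia & Gordon refit of the Benson-Krause data)
  with linear pressure scaling and a respiratory quotient.

Bacterial growth efficiency (BGE) is BPP / (BPP + respiration); the carbon
budget divides an observed biomass-carbon increase by BGE to estimate the
total carbon a community must have processed.  Leachate dosing volumes for
a target added carbon concentration are computed accounting for dilution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScintillationSet",
    "OxygenSeries",
    "BacterialRates",
    "bpp_from_counts",
    "o2_saturation_concentration",
    "o2_concentration",
    "respiration_rate",
    "growth_efficiency",
    "carbon_processed",
    "spike_volume",
    "bottle_bpp",
    "rates_from_frames",
]

DPM_PER_CURIE = 2.22e12
O2_MOLAR_MASS = 31.9988   # g mol-1
C_MOLAR_MASS = 12.011     # g mol-1
STANDARD_PRESSURE_HPA = 1013.25


@dataclass(frozen=True)
class ScintillationSet:
    """One bottle's scintillation counts and the constants to convert them.

    ``leucine_specific_activity`` is in Ci mmol-1; ``leucine_to_carbon`` in
    kg C per mol leucine (default 1.55, the standard conversion without
    isotope dilution).
    """

    cpm_live: float
    cpm_killed: float
    cpm_blank: float
    cpm_standard: float
    standard_dpm: float
    leucine_specific_activity: float
    incubation_hours: float = 1.0
    sample_volume_l: float = 0.0015
    leucine_to_carbon: float = 1.55

    def __post_init__(self) -> None:
        if min(self.cpm_live, self.cpm_killed, self.cpm_blank, self.cpm_standard) < 0:
            raise ValueError("CPM values must be non-negative")
        if self.sample_volume_l <= 0 or self.incubation_hours <= 0:
            raise ValueError("sample volume and incubation time must be positive")
        eff = self.counting_efficiency
        if not (0 < eff <= 1):
            raise ValueError(f"counting efficiency {eff:.3f} outside (0, 1]")

    @property
    def counting_efficiency(self) -> float:
        if self.standard_dpm <= 0:
            raise ValueError("standard DPM must be positive")
        return self.cpm_standard / self.standard_dpm


def bpp_from_counts(s: ScintillationSet) -> float:
    """Bacterial protein production (ug C L-1 h-1) from scintillation counts.

    Chain: net CPM (live minus killed minus blank, clamped at zero) ->
    DPM via counting efficiency -> mol leucine via the specific activity
    (2.22e12 DPM Ci-1) -> carbon via the leucine-to-carbon factor, per
    litre per hour.
    """
    net_cpm = s.cpm_live - s.cpm_killed - s.cpm_blank
    if net_cpm < 0:
        warnings.warn(
            f"net CPM {net_cpm:.1f} < 0 (live below killed + blank); clamped to zero",
            stacklevel=2,
        )
        net_cpm = 0.0
    dpm = net_cpm / s.counting_efficiency
    mol_leucine = dpm / DPM_PER_CURIE / s.leucine_specific_activity / 1000.0  # Ci -> mmol -> mol
    ug_c = mol_leucine * s.leucine_to_carbon * 1e9  # kg -> ug
    return ug_c / (s.sample_volume_l * s.incubation_hours)


# Garcia & Gordon (1992) refit of the Benson-Krause oxygen solubility data,
# combined-fit coefficients; yields equilibrium O2 in mL(STP) L-1 as a
# function of temperature (deg C) and salinity (PSU).
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_GG_B = (-0.00624523, -0.00737614, -0.0103410, -0.00817083)
_GG_C0 = -4.88682e-7
_ML_PER_MG_O2 = 1.42905  # mg O2 per mL(STP)


def o2_saturation_concentration(
    temperature_c: float, salinity_psu: float = 0.0, pressure_hpa: float = STANDARD_PRESSURE_HPA
) -> float:
    """Equilibrium (100% air saturation) dissolved O2 in mg L-1.

    Valid for 0-40 degC and 0-40 PSU; pressure scales the solubility
    linearly relative to 1013.25 hPa.
    """
    if not (0.0 <= temperature_c <= 40.0):
        raise ValueError("temperature outside the 0-40 degC validity range")
    if not (0.0 <= salinity_psu <= 40.0):
        raise ValueError("salinity outside the 0-40 PSU validity range")
    ts = np.log((298.15 - temperature_c) / (273.15 + temperature_c))
    a0, a1, a2, a3, a4, a5 = _GG_A
    b0, b1, b2, b3 = _GG_B
    ln_c = (
        a0 + a1 * ts + a2 * ts**2 + a3 * ts**3 + a4 * ts**4 + a5 * ts**5
        + salinity_psu * (b0 + b1 * ts + b2 * ts**2 + b3 * ts**3)
        + _GG_C0 * salinity_psu**2
    )
    ml_per_l = float(np.exp(ln_c))
    return ml_per_l * _ML_PER_MG_O2 * pressure_hpa / STANDARD_PRESSURE_HPA


@dataclass(frozen=True)
class OxygenSeries:
    """An optode time series (% air saturation at 1 s cadence) for one vial."""

    readings: tuple[float, ...]
    temperature_c: float
    salinity_psu: float = 0.0
    pressure_hpa: float = STANDARD_PRESSURE_HPA
    vial_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.readings, dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 150):
            raise ValueError("% air saturation readings outside [0, 150]")


def _stable_tail_median(
    readings: np.ndarray, window: int = 10, sd_threshold: float = 0.1
) -> tuple[float, bool]:
    """Median of the last `window` stable readings; flag True on fallback.

    A reading index is stable when the trailing `window`-point standard
    deviation up to it is <= `sd_threshold` (% saturation).  If no stable
    window exists, the plain median of the final `window` readings is used.
    """
    n = readings.size
    if n < window:
        raise ValueError(f"need at least {window} readings, got {n}")
    # rolling SD over trailing windows, vectorised via cumulative sums
    c1 = np.cumsum(np.insert(readings, 0, 0.0))
    c2 = np.cumsum(np.insert(readings**2, 0, 0.0))
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = np.maximum(s2 / window - (s1 / window) ** 2, 0.0)
    stable = np.sqrt(var) <= sd_threshold  # stable[i] -> window ending at i+window-1
    if not stable.any():
        return float(np.median(readings[-window:])), True
    last = int(np.nonzero(stable)[0][-1]) + window  # exclusive end of last stable window
    return float(np.median(readings[last - window : last])), False


def o2_concentration(
    series: OxygenSeries, window: int = 10, sd_threshold: float = 0.1
) -> float:
    """Dissolved O2 (mg L-1) from the stable tail of an optode series.

    Takes the median of the last `window` readings inside the latest stable
    window (rolling SD <= `sd_threshold` % sat) and converts % saturation
    to concentration at the recorded temperature, salinity and pressure.
    Falls back, with a warning, to the median of the final readings when
    the series never stabilises.
    """
    readings = np.asarray(series.readings, dtype=float)
    pct, fallback = _stable_tail_median(readings, window=window, sd_threshold=sd_threshold)
    if fallback:
        warnings.warn(
            f"vial {series.vial_id!r}: no stable window (SD <= {sd_threshold}); "
            "using median of the final readings",
            stacklevel=2,
        )
    sat = o2_saturation_concentration(series.temperature_c, series.salinity_psu, series.pressure_hpa)
    return pct / 100.0 * sat


def respiration_rate(
    start: OxygenSeries,
    end: OxygenSeries,
    duration_h: float,
    rq: float = 1.0,
    **o2_kwargs,
) -> float:
    """Respiration (ug C L-1 h-1) from O2 drawdown between two optode series.

    Oxygen consumption is converted to carbon assuming ``rq`` mol CO2 per
    mol O2 (default 1).  O2 production (concentration increase) is clamped
    to zero with a warning — a dark incubation should only consume oxygen.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    delta_mg = o2_concentration(start, **o2_kwargs) - o2_concentration(end, **o2_kwargs)
    if delta_mg < 0:
        warnings.warn(
            f"O2 increased by {-delta_mg:.3f} mg L-1 over the incubation; respiration clamped to 0",
            stacklevel=2,
        )
        delta_mg = 0.0
    mg_o2_per_h = delta_mg / duration_h
    return mg_o2_per_h / O2_MOLAR_MASS * rq * C_MOLAR_MASS * 1000.0  # mg -> ug


def growth_efficiency(bpp: float, respiration: float) -> float:
    """BGE = BPP / (BPP + respiration); NaN when both rates are zero."""
    if bpp < 0 or respiration < 0:
        raise ValueError("rates must be non-negative")
    total = bpp + respiration
    if total == 0:
        return float("nan")
    return bpp / total


def carbon_processed(delta_bpp_total: float, bge: float) -> float:
    """Total carbon (ug C L-1) processed to sustain a biomass-carbon increase.

    ``delta_bpp_total`` is the cumulative BPP increase over the incubation;
    dividing by the growth efficiency gives the gross carbon demand.
    """
    if not (0 < bge <= 1):
        raise ValueError(f"BGE must be in (0, 1], got {bge}")
    return delta_bpp_total / bge


def spike_volume(
    target_added_conc: float, leachate_doc: float, incubation_volume_l: float
) -> float:
    """Leachate volume (L) adding ``target_added_conc`` mg C L-1 to a bottle.

    Solves v * DOC = target * (V + v), i.e. the added-carbon concentration
    in the final (diluted) mixture equals the target.
    """
    if target_added_conc < 0 or incubation_volume_l <= 0:
        raise ValueError("target concentration must be >= 0 and volume positive")
    if target_added_conc == 0:
        return 0.0
    if leachate_doc <= target_added_conc:
        raise ValueError(
            f"leachate DOC {leachate_doc} mg C L-1 cannot reach an added "
            f"concentration of {target_added_conc} mg C L-1 in the mixture"
        )
    return incubation_volume_l * target_added_conc / (leachate_doc - target_added_conc)


@dataclass(frozen=True)
class BacterialRates:
    """BPP, respiration and BGE for one lake x treatment cell."""

    lake_id: str
    treatment: str
    bpp: float
    respiration: float

    @property
    def bge(self) -> float:
        return growth_efficiency(self.bpp, self.respiration)


def bottle_bpp(scint: pd.DataFrame, leucine_to_carbon: float = 1.55) -> pd.DataFrame:
    """Per-bottle BPP (ug C L-1 h-1) from a tidy scintillation table.

    Keeps replicate structure (one row per bottle) for mixed-model use;
    ``rates_from_frames`` averages these per lake x treatment.
    """
    rows = []
    for row in scint.itertuples():
        s = ScintillationSet(
            cpm_live=row.cpm_live,
            cpm_killed=row.cpm_killed,
            cpm_blank=row.cpm_blank,
            cpm_standard=row.cpm_standard,
            standard_dpm=row.standard_dpm,
            leucine_specific_activity=row.leucine_specific_activity,
            incubation_hours=getattr(row, "incubation_hours", 1.0),
            sample_volume_l=getattr(row, "sample_volume_l", 0.0015),
            leucine_to_carbon=leucine_to_carbon,
        )
        rows.append({
            "lake": str(row.lake), "treatment": str(row.treatment),
            "replicate": getattr(row, "replicate", 0), "bpp": bpp_from_counts(s),
        })
    return pd.DataFrame(rows)


def rates_from_frames(
    scint: pd.DataFrame,
    oxygen_meta: pd.DataFrame,
    oxygen_series: pd.DataFrame,
    rq: float = 1.0,
    leucine_to_carbon: float = 1.55,
    sd_threshold: float = 0.1,
) -> pd.DataFrame:
    """Tidy BacterialRates per lake x treatment from raw measurement tables.

    ``scint``: one row per scintillation bottle with columns lake, treatment,
    cpm_live, cpm_killed, cpm_blank, cpm_standard, standard_dpm,
    leucine_specific_activity and optionally incubation_hours /
    sample_volume_l.  BPP per cell is the mean over replicate bottles.

    ``oxygen_meta``: one row per vial with columns vial_id, lake, treatment,
    phase ('start' or 'end'), temperature_c, salinity_psu, pressure_hpa and
    duration_h (on end rows).  ``oxygen_series``: long format with columns
    vial_id, t_seconds, pct_saturation.  One start/end pair per cell is
    expected (single respiration vial per treatment); with replicate end
    vials their rates are averaged.
    """
    records: dict[tuple[str, str], dict] = {}

    for (lake, treatment), grp in scint.groupby(["lake", "treatment"], sort=True):
        bpps = []
        for row in grp.itertuples():
            s = ScintillationSet(
                cpm_live=row.cpm_live,
                cpm_killed=row.cpm_killed,
                cpm_blank=row.cpm_blank,
                cpm_standard=row.cpm_standard,
                standard_dpm=row.standard_dpm,
                leucine_specific_activity=row.leucine_specific_activity,
                incubation_hours=getattr(row, "incubation_hours", 1.0),
                sample_volume_l=getattr(row, "sample_volume_l", 0.0015),
                leucine_to_carbon=leucine_to_carbon,
            )
            bpps.append(bpp_from_counts(s))
        records[(str(lake), str(treatment))] = {"bpp": float(np.mean(bpps))}

    series_by_vial = {
        vial: np.asarray(grp.sort_values("t_seconds")["pct_saturation"], dtype=float)
        for vial, grp in oxygen_series.groupby("vial_id")
    }

    def _series(row) -> OxygenSeries:
        return OxygenSeries(
            readings=tuple(series_by_vial[row.vial_id]),
            temperature_c=row.temperature_c,
            salinity_psu=getattr(row, "salinity_psu", 0.0),
            pressure_hpa=getattr(row, "pressure_hpa", STANDARD_PRESSURE_HPA),
            vial_id=str(row.vial_id),
        )

    for (lake, treatment), grp in oxygen_meta.groupby(["lake", "treatment"], sort=True):
        starts = [r for r in grp.itertuples() if r.phase == "start"]
        ends = [r for r in grp.itertuples() if r.phase == "end"]
        if not starts or not ends:
            continue
        start_series = _series(starts[0])
        rates = [
            respiration_rate(start_series, _series(e), duration_h=e.duration_h, rq=rq,
                             sd_threshold=sd_threshold)
            for e in ends
        ]
        cell = records.setdefault((str(lake), str(treatment)), {})
        cell["respiration"] = float(np.mean(rates))

    rows = []
    for (lake, treatment), cell in sorted(records.items()):
        bpp = cell.get("bpp", np.nan)
        resp = cell.get("respiration", np.nan)
        bge = bpp / (bpp + resp) if np.isfinite(bpp) and np.isfinite(resp) and bpp + resp > 0 else np.nan
        rows.append({"lake": lake, "treatment": treatment, "bpp": bpp, "respiration": resp, "bge": bge})
    return pd.DataFrame(rows)
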