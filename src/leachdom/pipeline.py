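"""End-to-end orchestration: raw input bundle -> consolidated report.

Runs the stages in dependency order — formula assignment and DOM metrics,
incubation metabolism, mixed-effects treatment inference, ASV association
— on whatever inputs are present in the bundle directory, skipping (with a
logged warning) stages whose inputs are missing.  All numeric outputs are
deterministic for a given bundle; the seed in the config is recorded in
the report for provenance of generated bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem, dom_metrics, metabolism, mixed_model, asv_assoc

logger = logging.getLogger("leachdom")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, stage toggles and module options for a pipeline run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    run_dom: bool = True
    run_metabolism: bool = True
    run_lmm: bool = True
    run_asv: bool = True

    tolerance_ppm: float = 0.5
    mz_window: tuple = (150.0, 1000.0)
    fd_weighted: bool = True
    lability_threshold: float = 1.5
    rq: float = 1.0
    leucine_to_carbon: float = 1.55
    stability_sd: float = 0.1
    min_reads: int = 100
    covariate_priority: tuple = mixed_model.DEFAULT_PRIORITY

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle)
        for key in ("mz_window", "covariate_priority"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _table_from_assignments(sample_id: str, assignments) -> dom_metrics.SampleFormulaTable:
    """Best-candidate formulas of a peak list, merged by formula identity."""
    merged: dict = {}
    for pa in assignments:
        best = pa.best
        if best is None:
            continue
        merged[best.formula] = merged.get(best.formula, 0.0) + pa.peak.intensity
    return dom_metrics.SampleFormulaTable.from_pairs(sample_id, sorted(merged.items(), key=lambda kv: str(kv[0])))


def _dom_stage(config: RunConfig, input_dir: Path, outdir: Path, report: dict) -> None:
    peaks_dir = input_dir / "peaks"
    if not peaks_dir.is_dir():
        logger.warning("DOM stage skipped: no peaks/ directory in %s", input_dir)
        return
    assign_config = chem.AssignmentConfig(
        tolerance_ppm=config.tolerance_ppm, mz_window=tuple(config.mz_window)
    )
    tables: dict[str, dom_metrics.SampleFormulaTable] = {}
    for path in sorted(peaks_dir.glob("*.csv")):
        sample_id = path.stem
        frame = pd.read_csv(path)
        peaks = [
            chem.Peak(mz=row.mz, intensity=row.intensity, sample_id=sample_id)
            for row in frame.itertuples()
        ]
        tables[sample_id] = _table_from_assignments(sample_id, chem.assign_formulas(peaks, assign_config))
        logger.info("assigned %s: %d formulas", sample_id, tables[sample_id].n_formulas)

    blank = tables.pop("blank", None)
    if blank is not None:
        tables = {sid: dom_metrics.blank_correct(t, blank) for sid, t in tables.items()}

    summaries = dom_metrics.summary_frame(
        list(tables.values()), threshold=config.lability_threshold, weighted_fd=config.fd_weighted
    )
    summaries.to_csv(outdir / "dom_summary.csv", index=False)
    report["dom"] = {
        "n_samples": len(tables),
        "summaries": summaries.set_index("sample_id").to_dict("index"),
    }

    leachate = tables.get("leachate")
    if leachate is not None:
        lake_tables = [t for sid, t in tables.items() if sid != "leachate"]
        unique = dom_metrics.unique_formulas(leachate, lake_tables)
        unique.table.to_frame().to_csv(outdir / "leachate_unique_formulas.csv", index=False)
        matches = dom_metrics.crossref_additives(
            unique.table, dom_metrics.load_additive_reference(), full=leachate
        )
        pd.DataFrame([m.__dict__ for m in matches]).to_csv(outdir / "additive_matches.csv", index=False)
        report["dom"]["leachate"] = {
            "n_formulas": leachate.n_formulas,
            "n_unique": unique.n_unique,
            "percent_unique": unique.percent_unique,
            "n_additive_matches": len(matches),
        }


def _metabolism_stage(config: RunConfig, input_dir: Path, outdir: Path, report: dict):
    scint_path = input_dir / "scintillation.csv"
    if not scint_path.is_file():
        logger.warning("metabolism stage skipped: %s missing", scint_path)
        return None, None
    scint = pd.read_csv(scint_path)
    oxygen_meta = pd.read_csv(input_dir / "oxygen_meta.csv")
    oxygen_series = pd.read_csv(input_dir / "oxygen_series.csv")
    rates = metabolism.rates_from_frames(
        scint, oxygen_meta, oxygen_series,
        rq=config.rq, leucine_to_carbon=config.leucine_to_carbon,
        sd_threshold=config.stability_sd,
    )
    bottles = metabolism.bottle_bpp(scint, leucine_to_carbon=config.leucine_to_carbon)
    rates.to_csv(outdir / "bacterial_rates.csv", index=False)
    bottles.to_csv(outdir / "bottle_bpp.csv", index=False)
    report["metabolism"] = {
        "n_cells": len(rates),
        "mean_bpp_control": float(rates.loc[rates.treatment == "control", "bpp"].mean()),
        "mean_bpp_plastic": float(rates.loc[rates.treatment == "plastic", "bpp"].mean()),
        "mean_bge_control": float(rates.loc[rates.treatment == "control", "bge"].mean()),
        "mean_bge_plastic": float(rates.loc[rates.treatment == "plastic", "bge"].mean()),
    }
    return rates, bottles


def _effect_dict(e: mixed_model.EffectSummary) -> dict:
    return {
        "moderator": e.moderator, "level_sd": e.level_sd,
        "control_mean": e.control_mean, "control_ci": list(e.control_ci),
        "plastic_mean": e.plastic_mean, "plastic_ci": list(e.plastic_ci),
        "fold_change": e.fold_change, "fold_ci": list(e.fold_ci),
    }


def _lmm_stage(config: RunConfig, covariates: pd.DataFrame, rates, bottles, outdir: Path, report: dict):
    cov_cols = [c for c in ("fd", "doc", "tn", "temperature", "ph", "latitude", "shannon")
                if c in covariates.columns]
    results = {}
    for response, frame in (("bpp", bottles), ("bge", rates)):
        if frame is None:
            continue
        if response == "bge":
            frame = frame.dropna(subset=["bge"]).rename(columns={"bge": "value"})
            frame = frame[frame["value"] > 0]
            data = frame[["lake", "treatment", "value"]].rename(
                columns={"lake": "lake_id", "value": "response"})
        else:
            data = frame.rename(columns={"lake": "lake_id", "bpp": "response"})
            data = data[data["response"] > 0]
        data = data.merge(covariates.reset_index(), left_on="lake_id", right_on="lake", how="inner")
        data = data.dropna(subset=cov_cols)
        if data["lake_id"].nunique() < 3:
            logger.warning("LMM for %s skipped: too few lakes with complete data", response)
            continue
        retained, dropped = mixed_model.collinearity_screen(
            data, cov_cols, priority=config.covariate_priority)
        terms = ["treatment"] + retained + [f"treatment:{c}" for c in retained]
        elimination = mixed_model.backward_eliminate(data, terms)
        fit = elimination.final
        effects = mixed_model.marginal_effects(fit)
        probes = {}
        for term in fit.terms:
            if ":" in term:
                moderator = [p for p in term.split(":") if p != "treatment"][0]
                probes[moderator] = [
                    _effect_dict(e) for e in mixed_model.marginal_effects(fit, moderator=moderator)
                ]
        results[response] = {
            "collinearity_dropped": [list(map(str, d[:2])) + [float(d[2])] for d in dropped],
            "selected_terms": list(fit.terms),
            "estimates": {k: float(v) for k, v in fit.params.items()},
            "aic_trace": [
                {k: v for k, v in step.items() if k != "candidates"} for step in elimination.trace
            ],
            "effects": [_effect_dict(e) for e in effects],
            "interaction_probes": probes,
            "n_lakes": fit.n_groups,
            "n_obs": fit.n_obs,
        }
    with open(outdir / "model_report.json", "w", encoding="utf-8") as handle:
        json.dump(results, handle, indent=2, default=float)
    report["lmm"] = {
        resp: {
            "fold_change": res["effects"][0]["fold_change"],
            "fold_ci": res["effects"][0]["fold_ci"],
            "selected_terms": res["selected_terms"],
        }
        for resp, res in results.items()
    }
    return results


def _asv_stage(config: RunConfig, input_dir: Path, rates, outdir: Path, report: dict):
    counts_path = input_dir / "asv_counts.tsv"
    if not counts_path.is_file():
        logger.warning("ASV stage skipped: %s missing", counts_path)
        return
    table = asv_assoc.AsvCountTable.from_tsv(counts_path, input_dir / "asv_taxonomy.tsv")
    shannon = asv_assoc.shannon_per_sample(table)
    shannon.to_csv(outdir / "shannon.csv")
    filtered = asv_assoc.filter_low_abundance(table, min_reads=config.min_reads)
    report["asv"] = {
        "n_asvs": table.n_asvs,
        "n_after_filter": filtered.n_asvs,
        "shannon_range": [float(shannon.min()), float(shannon.max())],
    }
    if rates is None:
        logger.warning("ASV association skipped: no metabolic rates available")
        return
    folds = rates.pivot(index="lake", columns="treatment", values="bpp")
    folds = folds.dropna()
    common = [s for s in filtered.counts.columns if s in folds.index]
    if len(common) < 3:
        logger.warning("ASV association skipped: too few samples with rate data")
        return
    sub = asv_assoc.AsvCountTable(
        counts=filtered.counts[common], taxonomy=filtered.taxonomy)
    covariate = np.log2(folds.loc[common, "plastic"] / folds.loc[common, "control"])
    assoc = asv_assoc.nb_association(sub, covariate)
    assoc = assoc.sort_values("padj")
    assoc.to_csv(outdir / "asv_associations.csv")
    significant = assoc[(assoc["padj"] < 0.05) & (assoc["log2_fold_change"] > 0)]
    report["asv"]["n_positive_significant"] = int(len(significant))
    report["asv"]["top_genera"] = significant["genus"].head(5).tolist()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages and write the consolidated report.

    Raises on a stage failure (partial outputs are retained); missing
    inputs merely skip the dependent stage.
    """
    input_dir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "input_dir": str(input_dir)}

    covariates = None
    cov_path = input_dir / "lake_covariates.csv"
    if cov_path.is_file():
        covariates = pd.read_csv(cov_path).set_index("lake")

    if config.run_dom:
        _dom_stage(config, input_dir, outdir, report)
    rates = bottles = None
    if config.run_metabolism:
        rates, bottles = _metabolism_stage(config, input_dir, outdir, report)
    if config.run_lmm:
        if covariates is None or bottles is None:
            logger.warning("LMM stage skipped: missing covariates or rates")
        else:
            _lmm_stage(config, covariates, rates, bottles, outdir, report)
    if config.run_asv:
        _asv_stage(config, input_dir, rates, outdir, report)

    with open(outdir / "report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, default=float)
    _write_summary(report, outdir / "summary.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = ["leachdom pipeline summary", "=" * 25]
    dom = report.get("dom", {})
    if "leachate" in dom:
        le = dom["leachate"]
        lines += [
            f"Leachate formulas assigned: {le['n_formulas']}",
            f"Unique to leachate: {le['n_unique']} ({le['percent_unique']:.1f}%)",
            f"Known plastic additives matched: {le['n_additive_matches']}",
        ]
        summary = dom.get("summaries", {}).get("leachate")
        if summary:
            lines += [
                f"Leachate FD (intensity-weighted): {summary['fd']:.2f}",
                f"High-lability fraction: {100 * summary['frac_high_lability_count']:.1f}% of formulas, "
                f"{100 * summary['frac_high_lability_intensity']:.1f}% of intensity",
            ]
    lmm = report.get("lmm", {})
    for resp, res in lmm.items():
        lo, hi = res["fold_ci"]
        lines.append(
            f"{resp.upper()} fold change (plastic/control): "
            f"{res['fold_change']:.2f} [{lo:.2f}, {hi:.2f}]"
        )
    asv = report.get("asv", {})
    if asv:
        lines.append(f"ASVs: {asv.get('n_asvs')} total, {asv.get('n_after_filter')} after filtering")
        if "n_positive_significant" in asv:
            lines.append(
                f"ASVs positively associated with the BPP fold change: {asv['n_positive_significant']}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
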