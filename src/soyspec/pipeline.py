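"""Configuration-driven orchestration of the full study workflow:
split -> preprocess -> PLS calibration with LOO factor selection ->
diagnostics -> external validation -> report, and the SIMCA
classification study with its stratified per-class split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from soyspec import assess, regression, simca as simca_mod
from soyspec.errors import ConfigError, DataError
from soyspec.preprocess import regression_recipe, simca_recipe
from soyspec.spectra_io import (
    ReferenceTable, SpectraSet, assign_splits,
)


@dataclass
class TraitConfig:
    """Per-trait modeling choices: spectral region and factor ceiling."""

    lo_nm: float
    hi_nm: float
    max_factors: int

    def __post_init__(self):
        if self.lo_nm >= self.hi_nm:
            raise ConfigError(f"region lo {self.lo_nm} >= hi {self.hi_nm}")
        if self.max_factors < 1:
            raise ConfigError("max_factors must be >= 1")


#: Published per-trait spectral regions and factor counts: protein
#: 2294-1876 nm / 4 factors; amino acids 2307-1978 nm / 4-6; fat and fatty
#: acids 1859-1680 nm / 5-6; moisture 1825-1440 nm / 6.
TRAIT_DEFAULTS: dict[str, TraitConfig] = {
    "threonine": TraitConfig(1978.0, 2307.0, 6),
    "cysteine": TraitConfig(1978.0, 2307.0, 4),
    "methionine": TraitConfig(1978.0, 2307.0, 4),
    "lysine": TraitConfig(1978.0, 2307.0, 5),
    "tryptophan": TraitConfig(1978.0, 2307.0, 4),
    "total_protein": TraitConfig(1876.0, 2294.0, 4),
    "palmitic": TraitConfig(1680.0, 1859.0, 5),
    "stearic": TraitConfig(1680.0, 1859.0, 6),
    "oleic": TraitConfig(1680.0, 1859.0, 5),
    "linoleic": TraitConfig(1680.0, 1859.0, 5),
    "linolenic": TraitConfig(1680.0, 1859.0, 5),
    "fat": TraitConfig(1680.0, 1859.0, 6),
    "moisture": TraitConfig(1440.0, 1825.0, 6),
}


@dataclass
class RunConfig:
    """Study-level settings for both workflows."""

    traits: dict[str, TraitConfig] = field(
        default_factory=lambda: dict(TRAIT_DEFAULTS))
    split_fraction: float = 0.8
    seed: int = 0
    savgol_window: int = 21
    savgol_polyorder: int = 3
    exclude_outliers: bool = False
    min_samples: int = 10
    simca_alpha: float = 1e-4
    simca_variance_target: float = 98.0
    simca_k: int | None = 3
    output_dir: str | None = None

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ConfigError("split_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        traits = raw.pop("traits", None)
        cfg = cls(**raw) if traits is None else cls(
            traits={k: TraitConfig(**v) for k, v in traits.items()}, **raw)
        return cfg


def run_regression_study(
    config: RunConfig,
    spectra: SpectraSet,
    refs: ReferenceTable,
    traits: list[str] | None = None,
) -> dict:
    """Calibrate and validate a PLS model for each configured trait.

    For each trait: replicate-aware 80/20 split, recipe fit on
    calibration scans, sample-level LOO-CV factor selection capped at the
    configured maximum, optional leverage/residual exclusion with one
    refit, final fit, external validation. Returns
    ``{"reports": DataFrame, "models": {trait: PLSModel},
    "cv": {trait: CVResult}, "predictions": DataFrame, "log": dict}`` and,
    when ``config.output_dir`` is set, writes reports/predictions CSV,
    model bundles, and a JSON run log there.
    """
    trait_list = traits if traits is not None else list(config.traits)
    reports, models, cvs, pred_rows = [], {}, {}, []
    log = {"seed": config.seed, "split_fraction": config.split_fraction,
           "traits": {}, "exclude_outliers": config.exclude_outliers}
    for trait in trait_list:
        if trait not in config.traits:
            raise ConfigError(
                f"no trait configuration for {trait!r}; known traits: "
                f"{sorted(config.traits)}"
            )
        tcfg = config.traits[trait]
        n_avail = len(refs.samples_with(trait))
        if n_avail < config.min_samples:
            raise DataError(
                f"trait {trait!r}: {n_avail} samples < floor {config.min_samples}"
            )
        split = assign_splits(spectra, refs, trait,
                              config.split_fraction, config.seed)
        recipe = regression_recipe(tcfg.lo_nm, tcfg.hi_nm,
                                   config.savgol_window,
                                   config.savgol_polyorder)
        cal_ids = sorted(split.calibration_ids)
        model, cv = regression.train_pls(
            spectra, refs, trait, recipe, tcfg.max_factors,
            calibration_ids=cal_ids,
        )
        excluded = []
        if config.exclude_outliers:
            cal_scans = spectra.subset_samples(model.calibration_ids)
            y_scan = refs.trait_values(trait).loc[
                cal_scans.scan_meta["sample_id"]].to_numpy()
            diag = regression.diagnostics(
                model, y_scan, scan_ids=cal_scans.scan_meta["sample_id"])
            excluded = list(diag.flagged_ids)
            if excluded:
                keep = [s for s in cal_ids if s not in set(excluded)]
                recipe = regression_recipe(tcfg.lo_nm, tcfg.hi_nm,
                                           config.savgol_window,
                                           config.savgol_polyorder)
                model, cv = regression.train_pls(
                    spectra, refs, trait, recipe, tcfg.max_factors,
                    calibration_ids=keep,
                )
        val_ids = [s for s in sorted(split.validation_ids)]
        val_set = spectra.subset_samples(val_ids)
        pred = regression.predict(model, val_set, per_sample=True)
        truth = refs.trait_values(trait).loc[pred.index]
        cal_refs = refs.trait_values(trait).loc[model.calibration_ids]
        report = assess.build_validation_report(
            trait=trait,
            n_factors=model.n_factors,
            rmsecv_value=float(cv.rmsecv_by_factor[cv.chosen_factors - 1]),
            r_cv_value=float(cv.r_cv_by_factor[cv.chosen_factors - 1]),
            cal_refs=cal_refs.to_numpy(),
            val_refs=truth.to_numpy(),
            val_predictions=pred.to_numpy(),
        )
        reports.append(report.to_row())
        models[trait] = model
        cvs[trait] = cv
        for sid, yhat, yref in zip(pred.index, pred.to_numpy(), truth):
            pred_rows.append({"trait": trait, "sample_id": sid,
                              "reference": yref, "predicted": yhat})
        log["traits"][trait] = {
            "n_calibration": len(model.calibration_ids),
            "n_validation": len(val_ids),
            "chosen_factors": int(model.n_factors),
            "capped_folds": int(cv.capped_folds),
            "excluded": excluded,
        }
    result = {
        "reports": pd.DataFrame(reports),
        "models": models,
        "cv": cvs,
        "predictions": pd.DataFrame(pred_rows),
        "log": log,
    }
    if config.output_dir:
        _write_regression_outputs(config, result)
    return result


def _write_regression_outputs(config: RunConfig, result: dict) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["reports"].to_csv(out / "validation_reports.csv", index=False)
    result["predictions"].to_csv(out / "validation_predictions.csv",
                                 index=False)
    for trait, model in result["models"].items():
        model.save(out / f"pls_{trait}.json")
    with open(out / "run_log.json", "w") as fh:
        json.dump(result["log"], fh, indent=2)


def stratified_class_split(spectra: SpectraSet, fraction: float, seed: int
                           ) -> tuple[list[str], list[str]]:
    """Per-class 80/20 split over labeled samples (replicates grouped)."""
    meta = spectra.scan_meta
    labeled = meta[meta["class_label"].notna()]
    rng = np.random.default_rng(seed)
    cal, val = [], []
    for lab in dict.fromkeys(labeled["class_label"]):
        ids = sorted(dict.fromkeys(
            labeled.loc[labeled["class_label"] == lab, "sample_id"]))
        perm = rng.permutation(len(ids))
        n_cal = int(round(fraction * len(ids)))
        n_cal = min(max(n_cal, 1), len(ids) - 1)
        cal.extend(ids[i] for i in perm[:n_cal])
        val.extend(ids[i] for i in perm[n_cal:])
    return cal, val


def run_classification_study(config: RunConfig, spectra: SpectraSet) -> dict:
    """SIMCA study on the labeled samples.

    Stratified per-class 80/20 split, SIMCA fit on calibration scans,
    classification of the hold-out, interclass distances, discriminating
    power, and confusion metrics. Returns a dict with the model, per-scan
    decisions DataFrame, ICD matrix, DP trace, and summary; writes CSV/JSON
    when ``config.output_dir`` is set.
    """
    meta = spectra.scan_meta
    labels_present = [l for l in dict.fromkeys(meta["class_label"]) if l]
    if len(labels_present) < 2:
        raise DataError(f"need two labeled classes, found {labels_present}")
    cal_ids, val_ids = stratified_class_split(
        spectra, config.split_fraction, config.seed)
    cal = spectra.subset_samples(cal_ids)
    val = spectra.subset_samples(val_ids)
    recipe = simca_recipe()
    model = simca_mod.fit_simca(
        cal, recipe, k_per_class=config.simca_k, alpha=config.simca_alpha,
        variance_target=config.simca_variance_target,
    )
    decisions = simca_mod.classify(model, val)
    truth = val.scan_meta["class_label"].tolist()
    metrics = simca_mod.confusion_metrics(decisions, truth)
    class_labels = model.class_labels()
    icd = {}
    for i, a in enumerate(class_labels):
        for b in class_labels[i + 1:]:
            icd[f"{a}|{b}"] = simca_mod.interclass_distance(model, cal, a, b)
    dp = simca_mod.discriminating_power(
        model, cal, class_labels[0], class_labels[1])
    wl = model.recipe.apply(cal).grid.values
    decision_df = pd.DataFrame({
        "sample_id": val.scan_meta["sample_id"],
        "replicate_id": val.scan_meta["replicate_id"],
        "truth": truth,
        "assigned": [d.assigned for d in decisions],
        **{f"distance_{lab}": [d.distance[lab] for d in decisions]
           for lab in class_labels},
    })
    summary = {
        "n_calibration_samples": len(cal_ids),
        "n_validation_samples": len(val_ids),
        "k_per_class": {lab: model.classes[lab].k for lab in class_labels},
        "interclass_distance": icd,
        "metrics": metrics,
        "dp_argmax_nm": float(wl[int(np.argmax(dp))]),
        "seed": config.seed,
    }
    result = {"model": model, "decisions": decision_df,
              "discriminating_power": pd.Series(dp, index=wl),
              "summary": summary}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        decision_df.to_csv(out / "simca_decisions.csv", index=False)
        model.save(out / "simca_model.json")
        with open(out / "simca_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return result
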