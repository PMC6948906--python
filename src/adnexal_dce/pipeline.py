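"""End-to-end study driver: generate, fit, describe, summarise, evaluate.

``run_study`` reproduces the complete analysis on a synthetic cohort (or on
externally supplied curves): AIF calibration against measured arterial
curves, extended Tofts fitting per lesion, semi-quantitative descriptor
extraction, three-group comparisons and ROC diagnostics.  Outputs are plain
CSV tables (a group-comparison table and a diagnostic-performance table in
the layout of the study's summary tables), per-lesion intermediates, and a
JSON manifest recording the seed, configuration hash and package versions,
so every cell of the result tables can be recomputed from persisted files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from adnexal_dce._version import __version__ as _pkg_version
from adnexal_dce.aif import (
    blood_to_plasma,
    calibrate_to_measured,
    population_blood_curve,
    weinmann_aif,
)
from adnexal_dce.diagnostics import compare_groups, roc_with_cutoff
from adnexal_dce.pk_model import (
    DEFAULT_FIT_SETTINGS,
    FitSettings,
    fit_curve,
    signal_to_enhancement,
)
from adnexal_dce.aif import ConcentrationCurve
from adnexal_dce.protocol import AcquisitionProtocol
from adnexal_dce.semiquant import compute_descriptors
from adnexal_dce.synthetic_cohort import CohortSpec, generate_cohort

__all__ = ["RunConfig", "run_study", "EVALUATED_PARAMETERS"]

logger = logging.getLogger(__name__)

#: Parameters evaluated in the group-comparison and diagnostic tables.
EVALUATED_PARAMETERS = (
    "age", "ktrans", "kep", "ve", "vp", "ttp",
    "si_max", "si_peak", "si_rel", "wir", "wor", "iauc60",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one study run.

    The cohort seed is always overridden by ``seed`` so a single flag
    controls every source of randomness.
    """

    protocol: AcquisitionProtocol = AcquisitionProtocol()
    cohort: CohortSpec = CohortSpec()
    fit: FitSettings = DEFAULT_FIT_SETTINGS
    hct: float = 0.45
    aif_constants_file: str | None = None
    outdir: str = "results/study"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON; unspecified fields keep defaults."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "protocol" in raw:
            kwargs["protocol"] = AcquisitionProtocol(**raw["protocol"])
        if "cohort" in raw:
            cohort = dict(raw["cohort"])
            if "class_params" in cohort:
                cohort["class_params"] = {
                    cls: {k: tuple(v) for k, v in params.items()}
                    for cls, params in cohort["class_params"].items()
                }
            kwargs["cohort"] = CohortSpec(**cohort)
        if "fit" in raw:
            fit = dict(raw["fit"])
            for key in ("ktrans_bounds", "kep_bounds", "vp_bounds", "x0",
                        "delay_grid"):
                if key in fit:
                    fit[key] = tuple(fit[key])
            kwargs["fit"] = FitSettings(**fit)
        for key in ("hct", "aif_constants_file", "outdir", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable hash of the full configuration."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def fit_cohort_lesions(dataset, fit_settings: FitSettings = DEFAULT_FIT_SETTINGS,
                       calibrate: bool = True) -> pd.DataFrame:
    """Calibrate the AIF and fit + describe every lesion of a cohort.

    Returns one row per lesion holding pathology, ground truth, fitted
    kinetic parameters and semi-quantitative descriptors.
    """
    protocol = dataset.protocol
    times = protocol.times()
    population = weinmann_aif(dose=protocol.dose_mmol_per_kg,
                              onset_time=protocol.injection_time_s,
                              hct=dataset.aif.hct)
    if calibrate and dataset.arterial_curves:
        aif = calibrate_to_measured(population, dataset.arterial_curves)
    else:
        aif = population
    cp = blood_to_plasma(population_blood_curve(aif, times), aif.hct)

    rows = []
    for record in dataset.records:
        curve = record.curve
        enh = signal_to_enhancement(curve.signal, curve.n_baseline_frames)
        ct = ConcentrationCurve(times=times, values=enh, compartment="tissue")
        pk = fit_curve(ct, cp, settings=fit_settings,
                       frame_interval=protocol.frame_interval_s)
        sq = compute_descriptors(curve)
        row = {
            "lesion_id": record.lesion_id,
            "patient_id": record.patient_id,
            "pathology": record.pathology,
            "age": record.age,
            "ktrans": pk.ktrans, "kep": pk.kep, "ve": pk.ve, "vp": pk.vp,
            "delta": pk.delta, "sse": pk.sse, "r2": pk.r2,
            "fit_status": pk.status,
            "true_ktrans": record.truth.ktrans,
            "true_kep": record.truth.kep,
            "true_vp": record.truth.vp,
            "true_delta": record.truth.delta,
        }
        row.update(sq.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["aif_scale"] = aif.scale
    df.attrs["aif_onset"] = aif.onset_time
    return df


def group_comparison_table(lesions: pd.DataFrame,
                           parameters=EVALUATED_PARAMETERS) -> pd.DataFrame:
    """Per-parameter three-group summary (means, SDs, significance tests).

    Columns for a class absent from the cohort are omitted.
    """
    counts = lesions["pathology"].value_counts()
    rows = []
    for param in parameters:
        gc = compare_groups(lesions[param].to_numpy(),
                            lesions["pathology"].to_numpy(), parameter=param)
        row = {
            "parameter": param,
            "mean_benign": gc.mean_benign, "sd_benign": gc.sd_benign,
            "mean_borderline": gc.mean_borderline,
            "sd_borderline": gc.sd_borderline,
            "mean_malignant": gc.mean_malignant, "sd_malignant": gc.sd_malignant,
            "p_anova": gc.p_anova,
            "p_benign_vs_malignant": gc.p_benign_vs_malignant,
            "p_benign_vs_borderline_malignant":
                gc.p_benign_vs_borderline_malignant,
            "test_benign_vs_malignant": gc.test_benign_vs_malignant,
            "test_benign_vs_borderline_malignant":
                gc.test_benign_vs_borderline_malignant,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    for cls in ("benign", "borderline", "malignant"):
        if counts.get(cls, 0) == 0:
            table = table.drop(columns=[f"mean_{cls}", f"sd_{cls}"])
    return table


def diagnostic_table(lesions: pd.DataFrame,
                     parameters=EVALUATED_PARAMETERS) -> pd.DataFrame:
    """Per-parameter ROC diagnostics for benign vs borderline/malignant."""
    positive = lesions["pathology"].isin(["borderline", "malignant"]).to_numpy()
    rows = []
    for param in parameters:
        dp = roc_with_cutoff(lesions[param].to_numpy(), positive,
                             parameter=param)
        rows.append({
            "parameter": param, "auc": dp.auc, "p_auc": dp.p_auc,
            "cutoff": dp.cutoff, "accuracy": dp.accuracy,
            "sensitivity": dp.sensitivity, "specificity": dp.specificity,
            "npv": dp.npv, "ppv": dp.ppv,
            "tp": dp.tp, "fp": dp.fp, "tn": dp.tn, "fn": dp.fn,
        })
    return pd.DataFrame(rows)


def roc_points_table(lesions: pd.DataFrame,
                     parameters=EVALUATED_PARAMETERS) -> pd.DataFrame:
    """Full ROC curves (one point per candidate threshold) for plotting."""
    positive = lesions["pathology"].isin(["borderline", "malignant"]).to_numpy()
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    frames = []
    for param in parameters:
        values = lesions[param].to_numpy()
        uniq = np.unique(values)
        cuts = np.concatenate(([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                               [uniq[-1] + 1.0]))
        sens = [(values > c)[positive].sum() / n_pos for c in cuts]
        spec = [(~(values > c))[~positive].sum() / n_neg for c in cuts]
        frames.append(pd.DataFrame({
            "parameter": param, "cutoff": cuts,
            "sensitivity": sens, "specificity": spec,
        }))
    return pd.concat(frames, ignore_index=True)


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and persist all outputs under the outdir.

    Returns a dict with the output paths and the in-memory tables.  On a
    partial failure a ``status.json`` naming the failed stage is written
    next to whatever outputs were produced, and the exception propagates.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status = {"stage": "init", "ok": False}

    def checkpoint(stage: str) -> None:
        status["stage"] = stage
        (outdir / "status.json").write_text(json.dumps(status))

    try:
        checkpoint("generate")
        spec = replace(config.cohort, seed=config.seed)
        dataset = generate_cohort(spec, protocol=config.protocol)
        dataset.manifest().to_csv(outdir / "cohort_manifest.csv", index=False)
        dataset.curves_frame().to_csv(outdir / "curves.csv", index=False)
        dataset.arterial_frame().to_csv(outdir / "arterial_curves.csv",
                                        index=False)

        checkpoint("fit")
        lesions = fit_cohort_lesions(dataset, fit_settings=config.fit)
        lesions.to_csv(outdir / "lesions.csv", index=False)

        checkpoint("evaluate")
        table3 = group_comparison_table(lesions)
        table4 = diagnostic_table(lesions)
        roc_points = roc_points_table(lesions)
        table3.to_csv(outdir / "group_comparison.csv", index=False)
        table4.to_csv(outdir / "diagnostic_performance.csv", index=False)
        roc_points.to_csv(outdir / "roc_points.csv", index=False)

        checkpoint("manifest")
        import scipy

        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "package_version": _pkg_version,
            "numpy_version": np.__version__,
            "scipy_version": scipy.__version__,
            "pandas_version": pd.__version__,
            "n_lesions": len(dataset.records),
            "n_patients": dataset.manifest()["patient_id"].nunique(),
            "signal_gain": dataset.gain,
            "aif_scale": lesions.attrs["aif_scale"],
            "aif_onset_s": lesions.attrs["aif_onset"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        status["ok"] = True
        checkpoint("done")
    except Exception:
        (outdir / "status.json").write_text(json.dumps(status))
        logger.exception("study failed at stage %s", status["stage"])
        raise

    return {
        "outdir": outdir,
        "lesions": lesions,
        "group_comparison": table3,
        "diagnostic_performance": table4,
        "manifest": manifest,
    }
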