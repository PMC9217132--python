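"""End-to-end orchestration: simulate -> fit -> z-score -> associate -> mediate.

The pipeline operates on tidy tables throughout.  Given (or after generating)
regional spectra, SUVR maps and group labels, it fits the regional model per
subject x ROI, computes band powers from the empirical spectra, z-scores
parameters and band powers against the control cohort, runs the four
parameter and four band-power association models, the regional group t-maps,
and the five canonical mediation decompositions, and writes CSV outputs plus
a machine-readable JSON summary carrying every seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, SyntheticCohort, generate_cohort, suvr_summary
from .fitting import FitConfig, fit_subject
from .forward import FrequencyGrid
from .io import (
    BAND_SCHEMA,
    PARAMS_SCHEMA,
    SPECTRA_SCHEMA,
    SUVR_SCHEMA,
    config_hash,
    write_table,
)
from .mediation import run_hypotheses
from .spectral import BANDS, RegionalSpectrum, band_power_db
from .stats import association_model, regional_group_map, zscore_vs_controls

__all__ = ["PipelineConfig", "run_pipeline", "band_power_table", "fit_cohort", "build_analysis_table"]

log = logging.getLogger(__name__)

PARAM_MEASURES = ("tau_e_ms", "tau_i_ms", "g_ee", "g_ii")
BAND_MEASURES = ("broadband", "delta_theta", "alpha", "beta")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one full pipeline run."""

    out_dir: Path = Path("results")
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    variance: str = "homogeneous"
    mediation_estimator: str = "ols_product"
    mediation_ci: str = "sobel"
    n_boot: int = 500
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "fit" in kwargs:
            kwargs["fit"] = FitConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["fit"].items()
            })
        if "out_dir" in kwargs:
            kwargs["out_dir"] = Path(kwargs["out_dir"])
        return cls(**kwargs)


def band_power_table(spectra: pd.DataFrame) -> pd.DataFrame:
    """Per subject x ROI mean dB power in each canonical band (wide columns)."""
    f = spectra.frequency_hz.to_numpy()
    out = spectra[["subject_id", "roi"]].drop_duplicates().reset_index(drop=True)
    agg = {}
    for name, band in BANDS.items():
        mask = (f >= band.lo_hz) & (f <= band.hi_hz)
        sub = spectra[mask]
        agg[name] = sub.groupby(["subject_id", "roi"], sort=False).psd_db.mean()
    wide = pd.DataFrame(agg).reset_index()
    return out.merge(wide, on=["subject_id", "roi"], validate="1:1")


def fit_cohort(spectra: pd.DataFrame, config: FitConfig) -> pd.DataFrame:
    """Fit every subject x ROI spectrum; returns the long parameter table."""
    frames = []
    for i, (sid, sub) in enumerate(spectra.groupby("subject_id", sort=True)):
        specs = [
            RegionalSpectrum(
                FrequencyGrid(g.frequency_hz.to_numpy()),
                g.psd_db.to_numpy(),
                subject_id=sid,
                roi=roi,
            )
            for roi, g in sub.groupby("roi", sort=True)
        ]
        cfg = dataclasses.replace(config, seed=config.seed + i)
        frames.append(fit_subject(specs, cfg))
        log.info("fitted subject %s (%d ROIs)", sid, len(specs))
    return pd.concat(frames, ignore_index=True)


def build_analysis_table(
    params: pd.DataFrame, bands: pd.DataFrame, suvr: pd.DataFrame, groups: pd.DataFrame
) -> pd.DataFrame:
    """Merge parameters, band powers and SUVR; add control-referenced z-scores."""
    df = params.merge(bands, on=["subject_id", "roi"], validate="1:1")
    df = df.merge(suvr[["subject_id", "roi", "tau_suvr", "ab_suvr"]],
                  on=["subject_id", "roi"], validate="1:1")
    if "group" not in df.columns:
        df = df.merge(groups, on="subject_id", validate="m:1")
    for measure in (*PARAM_MEASURES, *BAND_MEASURES):
        df[f"{measure}_z"] = zscore_vs_controls(df, measure)
    return df


def run_pipeline(
    config: PipelineConfig, cohort: SyntheticCohort | None = None
) -> dict:
    """Execute the full pipeline; returns (and writes) the summary dict."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config_hash(config),
        "seed": config.seed,
    }

    try:
        if cohort is None:
            cohort = generate_cohort(
                dataclasses.replace(config.cohort, seed=config.seed)
            )
    except Exception as exc:
        raise RuntimeError(f"simulate stage failed: {exc}") from exc
    write_table(cohort.spectra, out / "spectra.csv", SPECTRA_SCHEMA, meta)
    write_table(cohort.true_params, out / "true_params.csv", PARAMS_SCHEMA, meta)
    write_table(cohort.suvr, out / "suvr.csv", SUVR_SCHEMA, meta)

    try:
        fit_config = dataclasses.replace(config.fit, seed=config.seed)
        params = fit_cohort(cohort.spectra, fit_config)
    except Exception as exc:
        raise RuntimeError(f"fit stage failed: {exc}") from exc
    write_table(params, out / "fitted_params.csv", PARAMS_SCHEMA, meta)

    try:
        bands = band_power_table(cohort.spectra)
        groups = cohort.true_params[["subject_id", "group"]].drop_duplicates()
        table = build_analysis_table(params, bands, cohort.suvr, groups)
    except Exception as exc:
        raise RuntimeError(f"z-score stage failed: {exc}") from exc

    long_bands = bands.melt(
        id_vars=["subject_id", "roi"], var_name="band", value_name="power_db"
    )
    write_table(long_bands, out / "band_power.csv", BAND_SCHEMA, meta)
    table.to_csv(out / "analysis_table.csv", index=False)

    summary: dict = {
        "seed": config.seed,
        "config_hash": meta["config_hash"],
        "n_controls": int((groups.group == "control").sum()),
        "n_patients": int((groups.group == "patient").sum()),
        "n_rois": int(table.roi.nunique()),
        "suvr_means": suvr_summary(cohort),
        "mean_fit_pearson_r": float(params.pearson_r.mean()),
        "n_retried_fits": int(params.retried.sum()),
        "fit_failures": params.attrs.get("failures", {}),
    }

    try:
        assoc_rows = []
        associations = {}
        for measure in (*PARAM_MEASURES, *BAND_MEASURES):
            res = association_model(table, f"{measure}_z", variance=config.variance)
            associations[measure] = {
                pred: {k: float(res[pred][k]) for k in ("estimate", "se", "t", "p")}
                for pred in res.table.index
            }
            for pred in res.table.index:
                assoc_rows.append({"measure": measure, "predictor": pred,
                                   **{k: float(res[pred][k]) for k in ("estimate", "se", "t", "p")}})
        summary["associations"] = associations
        pd.DataFrame(assoc_rows).to_csv(out / "associations.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"association stage failed: {exc}") from exc

    try:
        tmap_frames = []
        group_diffs = {}
        for measure in PARAM_MEASURES:
            tmap = regional_group_map(table, f"{measure}_z")
            tmap["measure"] = measure
            tmap_frames.append(tmap.reset_index())
            patients = table[table.group == "patient"]
            group_diffs[measure] = {
                "patient_mean_z": float(patients[f"{measure}_z"].mean()),
                "n_significant_rois": int(tmap.significant.sum()),
            }
        summary["patient_shifts"] = group_diffs
        pd.concat(tmap_frames, ignore_index=True).to_csv(out / "regional_tmaps.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"regional-map stage failed: {exc}") from exc

    try:
        med = run_hypotheses(
            table,
            estimator=config.mediation_estimator,
            ci_method=config.mediation_ci,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        med.to_csv(out / "mediation.csv", index=False)
        summary["mediation"] = med.to_dict(orient="records")
    except Exception as exc:
        raise RuntimeError(f"mediation stage failed: {exc}") from exc

    if config.make_plots:
        try:
            _plot_report(cohort, table, out)
        except Exception as exc:  # plotting must never sink a completed analysis
            log.warning("report plots failed: %s", exc)

    summary["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def _plot_report(cohort: SyntheticCohort, table: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    spectra = cohort.spectra.merge(
        cohort.true_params[["subject_id", "group"]].drop_duplicates(), on="subject_id"
    )
    for group, sub in spectra.groupby("group"):
        mean = sub.groupby("frequency_hz").psd_db.mean()
        axes[0].plot(mean.index, mean.values, label=group)
    axes[0].set_xlabel("frequency (Hz)")
    axes[0].set_ylabel("power (dB)")
    axes[0].legend()
    axes[0].set_title("group-average regional spectra")

    patients = table[table.group == "patient"]
    axes[1].scatter(patients.tau_suvr, patients.tau_e_ms_z, s=4, alpha=0.4)
    axes[1].set_xlabel("tau SUVR")
    axes[1].set_ylabel("tau_e z-score")
    axes[1].set_title("excitatory time-constant vs tau uptake")
    fig.tight_layout()
    fig.savefig(out / "report.png", dpi=110)
    plt.close(fig)
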