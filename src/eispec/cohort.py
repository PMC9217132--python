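"""Synthetic study cohorts with known ground truth.

Generates a control group and a patient group of per-subject, per-ROI model
parameters (Gaussian dispersion around group means, truncated to the fitting
bounds), the corresponding regional dB spectra (closed-form model plus
additive dB noise), and regional tau / amyloid-beta SUVR maps whose spatial
variation is linearly coupled to the time-constant z-scores.  Everything is
reproducible from (config, seed), so each downstream stage — fitting,
z-scoring, association models, mediation — can be validated against the
generating truth.

Default group means and shifts follow the reported cohort-level pattern in
Alzheimer's disease: longer excitatory and inhibitory time-constants, higher
excitatory gain and lower inhibitory gain in patients, with tau tracer uptake
coupled to the excitatory time-constant and amyloid-beta uptake to the
inhibitory one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .forward import FrequencyGrid, _psd_db_fast

__all__ = ["CohortConfig", "SyntheticCohort", "dk68_rois", "generate_cohort", "suvr_summary"]

_PARAMS = ("tau_e_ms", "tau_i_ms", "g_ee", "g_ii")


def dk68_rois() -> list[str]:
    """The 68 Desikan--Killiany cortical ROI names (lh_/rh_ prefixed)."""
    text = resources.files("eispec.data").joinpath("dk68_rois.txt").read_text()
    return text.split()


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    Group means and patient shifts are in the units of each parameter
    (milliseconds for time-constants, dimensionless for gains).  Per-parameter
    dispersion is split into a subject-level random effect (shared across a
    subject's ROIs, creating the repeated-measures correlation the mixed
    models are built for) and an independent ROI-level part.

    SUVR maps are ``base + slope * z + noise`` where ``z`` is the parameter's
    z-score against the control cohort at that ROI; ``coupling_tau_taue``
    links tau uptake to the excitatory time-constant, ``coupling_ab_taui``
    links amyloid-beta uptake to the inhibitory one, and the cross slopes
    default to zero.
    """

    n_controls: int = 35
    n_patients: int = 20
    roi_list: tuple[str, ...] | None = None
    control_means: dict = field(
        default_factory=lambda: {"tau_e_ms": 11.8, "tau_i_ms": 15.4, "g_ee": 1.7, "g_ii": 3.7}
    )
    patient_shifts: dict = field(
        default_factory=lambda: {"tau_e_ms": 4.0, "tau_i_ms": 1.0, "g_ee": 0.3, "g_ii": -0.4}
    )
    subject_sds: dict = field(
        default_factory=lambda: {"tau_e_ms": 1.0, "tau_i_ms": 1.0, "g_ee": 0.25, "g_ii": 0.25}
    )
    roi_sds: dict = field(
        default_factory=lambda: {"tau_e_ms": 1.0, "tau_i_ms": 1.0, "g_ee": 0.25, "g_ii": 0.25}
    )
    tau_bounds_ms: tuple[float, float] = (5.0, 30.0)
    gain_bounds: tuple[float, float] = (0.1, 10.0)
    tau_suvr_base: float = 1.64
    ab_suvr_base: float = 1.99
    coupling_tau_taue: float = 0.10
    coupling_ab_taui: float = 0.10
    coupling_tau_taui: float = 0.0
    coupling_ab_taue: float = 0.0
    suvr_noise_sd: float = 0.15
    # Matches the Welch noise floor of the package's default simulation
    # protocol (600 s records, 2 s Hann windows, 50% overlap):
    # sigma_dB = (10/ln 10)/sqrt(K_eff) with K_eff ~ 599/1.06 => ~0.18 dB.
    spectral_noise_db: float = 0.2
    grid_step_hz: float = 0.5
    roi_random_effects: bool = False
    roi_effect_sds: dict = field(
        default_factory=lambda: {"tau_e_ms": 0.5, "tau_i_ms": 0.5, "g_ee": 0.1, "g_ii": 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("both groups need at least 2 subjects")
        for d in (self.subject_sds, self.roi_sds):
            if any(v <= 0 for v in d.values()):
                raise ValueError("dispersion SDs must be positive")
        if self.suvr_noise_sd <= 0 or self.spectral_noise_db < 0:
            raise ValueError("noise scales must be positive")
        for name in _PARAMS:
            lo, hi = self.tau_bounds_ms if name.startswith("tau") else self.gain_bounds
            sd = np.hypot(self.subject_sds[name], self.roi_sds[name])
            for mean in (
                self.control_means[name],
                self.control_means[name] + self.patient_shifts[name],
            ):
                if mean < lo - 3 * sd or mean > hi + 3 * sd:
                    raise ValueError(
                        f"{name} group mean {mean} lies more than 3 SD outside [{lo}, {hi}]"
                    )

    @property
    def rois(self) -> list[str]:
        return list(self.roi_list) if self.roi_list is not None else dk68_rois()


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated tables plus the config they came from.

    ``true_params``: subject_id, group, roi, tau_e_ms, tau_i_ms, g_ee, g_ii.
    ``spectra``: long table subject_id, roi, frequency_hz, psd_db.
    ``suvr``: subject_id, group, roi, tau_suvr, ab_suvr.
    """

    true_params: pd.DataFrame
    spectra: pd.DataFrame
    suvr: pd.DataFrame
    config: CohortConfig


def _bounds_of(config: CohortConfig, name: str) -> tuple[float, float]:
    return config.tau_bounds_ms if name.startswith("tau") else config.gain_bounds


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw a complete synthetic cohort; deterministic for a fixed config seed."""
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed)
    rois = config.rois
    n_roi = len(rois)
    subjects = [(f"C{i:03d}", "control") for i in range(config.n_controls)] + [
        (f"P{i:03d}", "patient") for i in range(config.n_patients)
    ]

    # optional smooth ROI-level random effects shared by everyone
    roi_effects = {
        name: (
            rng.normal(0.0, config.roi_effect_sds[name], n_roi)
            if config.roi_random_effects
            else np.zeros(n_roi)
        )
        for name in _PARAMS
    }

    rows = {name: [] for name in _PARAMS}
    ids, groups, roi_col = [], [], []
    for sid, group in subjects:
        shift = config.patient_shifts if group == "patient" else dict.fromkeys(_PARAMS, 0.0)
        for name in _PARAMS:
            mean = config.control_means[name] + shift[name]
            subj_eff = rng.normal(0.0, config.subject_sds[name])
            vals = mean + subj_eff + roi_effects[name] + rng.normal(
                0.0, config.roi_sds[name], n_roi
            )
            lo, hi = _bounds_of(config, name)
            rows[name].append(np.clip(vals, lo, hi))
        ids += [sid] * n_roi
        groups += [group] * n_roi
        roi_col += rois

    params = pd.DataFrame(
        {"subject_id": ids, "group": groups, "roi": roi_col}
        | {name: np.concatenate(rows[name]) for name in _PARAMS}
    )

    # spectra: closed-form model + iid dB noise (vectorized over subject x ROI)
    grid = FrequencyGrid.default(step=config.grid_step_hz)
    nbin = len(grid)
    db = _psd_db_fast(
        params.tau_e_ms.to_numpy()[:, None],
        params.tau_i_ms.to_numpy()[:, None],
        params.g_ee.to_numpy()[:, None],
        params.g_ii.to_numpy()[:, None],
        1.0,
        grid.omega,
    )
    db = db + rng.normal(0.0, config.spectral_noise_db, db.shape)
    spectra = pd.DataFrame(
        {
            "subject_id": np.repeat(params.subject_id.to_numpy(), nbin),
            "roi": np.repeat(params.roi.to_numpy(), nbin),
            "frequency_hz": np.tile(grid.frequencies, len(params)),
            "psd_db": db.ravel(),
        }
    )

    # SUVR maps coupled to time-constant z-scores (vs the control cohort per ROI)
    ctrl = params[params.group == "control"]
    z = {}
    for name in ("tau_e_ms", "tau_i_ms"):
        stats = ctrl.groupby("roi")[name].agg(["mean", "std"])
        z[name] = (
            params[name].to_numpy()
            - stats["mean"].reindex(params.roi).to_numpy()
        ) / stats["std"].reindex(params.roi).to_numpy()
    n = len(params)
    tau_suvr = (
        config.tau_suvr_base
        + config.coupling_tau_taue * z["tau_e_ms"]
        + config.coupling_tau_taui * z["tau_i_ms"]
        + rng.normal(0.0, config.suvr_noise_sd, n)
    )
    ab_suvr = (
        config.ab_suvr_base
        + config.coupling_ab_taui * z["tau_i_ms"]
        + config.coupling_ab_taue * z["tau_e_ms"]
        + rng.normal(0.0, config.suvr_noise_sd, n)
    )
    suvr = params[["subject_id", "group", "roi"]].copy()
    suvr["tau_suvr"] = tau_suvr
    suvr["ab_suvr"] = ab_suvr

    return SyntheticCohort(params, spectra, suvr, config)


def suvr_summary(cohort: SyntheticCohort) -> dict[str, float]:
    """Cohort-wide mean tau and amyloid-beta SUVR (covariate-fixing points)."""
    if len(cohort.suvr) == 0:
        raise ValueError("empty cohort")
    return {
        "tau_suvr_mean": float(cohort.suvr.tau_suvr.mean()),
        "ab_suvr_mean": float(cohort.suvr.ab_suvr.mean()),
    }
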