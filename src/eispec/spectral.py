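"""Empirical power spectra in dB and canonical frequency-band summaries.

Spectra are estimated with Welch's method (Hann windows, 50% overlap by
default), converted to dB as ``10*log10(power)``, and restricted to the
1--35 Hz analysis range.  Band powers are arithmetic means of the dB values
over the band's bins, matching how dB-scale spectra are usually compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, welch

from .forward import ANALYSIS_BAND, FrequencyGrid, NMMParameters, local_transfer

__all__ = [
    "BandDefinition",
    "BANDS",
    "RegionalSpectrum",
    "compute_psd_db",
    "band_power_db",
    "welch_expectation_db",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band requires lo_hz < hi_hz")


#: The canonical analysis bands: delta-theta, alpha, beta and broadband.
BANDS: dict[str, BandDefinition] = {
    "delta_theta": BandDefinition("delta_theta", 2.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 35.0),
    "broadband": BandDefinition("broadband", 1.0, 35.0),
}


@dataclass(frozen=True)
class RegionalSpectrum:
    """Power spectrum in dB for one subject x ROI."""

    grid: FrequencyGrid
    psd_db: np.ndarray
    subject_id: str = ""
    roi: str = ""

    def __post_init__(self) -> None:
        psd = np.asarray(self.psd_db, dtype=float)
        if len(psd) != len(self.grid):
            raise ValueError("psd_db and grid lengths differ")
        if not np.all(np.isfinite(psd)):
            raise ValueError("psd_db contains non-finite values")
        object.__setattr__(self, "psd_db", psd)


def compute_psd_db(
    trace: np.ndarray,
    sample_rate: float,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    fmin: float = ANALYSIS_BAND[0],
    fmax: float = ANALYSIS_BAND[1],
    subject_id: str = "",
    roi: str = "",
) -> RegionalSpectrum:
    """Welch-averaged power spectrum of a sampled signal, in dB.

    Hann windows of ``window_s`` seconds with fractional overlap
    ``overlap_frac``; the returned grid is restricted to [fmin, fmax] Hz.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    nperseg = int(round(window_s * sample_rate))
    if len(trace) < 2 * nperseg:
        raise ValueError(
            f"trace of {len(trace)} samples is shorter than two windows ({2 * nperseg})"
        )
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    freqs, pxx = welch(
        trace,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
    )
    mask = (freqs >= fmin) & (freqs <= fmax)
    return RegionalSpectrum(
        FrequencyGrid(freqs[mask]), 10.0 * np.log10(pxx[mask]), subject_id, roi
    )


def band_power_db(spec: RegionalSpectrum, band: BandDefinition | str) -> float:
    """Mean dB power over the band's bins (inclusive edges)."""
    if isinstance(band, str):
        band = BANDS[band]
    f = spec.grid.frequencies
    mask = (f >= band.lo_hz) & (f <= band.hi_hz)
    if not np.any(mask):
        raise ValueError(f"band {band.name} [{band.lo_hz}, {band.hi_hz}] Hz has no grid bins")
    return float(np.mean(spec.psd_db[mask]))


def welch_expectation_db(
    params: NMMParameters,
    grid: FrequencyGrid,
    sample_rate: float,
    window_s: float = 2.0,
    noise_mode: str = "common",
    fine_step_hz: float = 0.02,
    fmax_hz: float = 300.0,
) -> np.ndarray:
    """Expected value of the Welch dB spectrum under the closed-form model.

    The Welch estimator is unbiased for the true PSD convolved with the
    window's power response, not for the PSD itself; near weakly damped
    resonances the difference (spectral leakage) is substantial.  This
    computes ``E[P_welch(f)]`` by convolving the model's two-sided linear PSD
    with the squared magnitude of the Hann window transform, which is the
    correct reference when validating stochastic simulations.
    """
    nperseg = int(round(window_s * sample_rate))
    w = get_window("hann", nperseg)
    nfft = 1 << 18
    W = np.fft.fftshift(np.fft.fft(w, nfft))
    f_w = np.fft.fftshift(np.fft.fftfreq(nfft, 1.0 / sample_rate))
    power_response = np.abs(W) ** 2 / (sample_rate * np.sum(w**2))

    f_fine = np.arange(fine_step_hz, fmax_hz, fine_step_hz)
    h_e, h_i = local_transfer(params, FrequencyGrid(f_fine))
    if noise_mode == "common":
        s = np.abs(h_e + h_i) ** 2
    elif noise_mode == "independent":
        s = np.abs(h_e) ** 2 + np.abs(h_i) ** 2
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    s = params.noise_sd**2 * s
    f_two = np.concatenate([-f_fine[::-1], f_fine])
    s_two = np.concatenate([s[::-1], s])

    out = np.empty(len(grid))
    for j, f0 in enumerate(grid.frequencies):
        kernel = np.interp(f0 - f_two, f_w, power_response)
        out[j] = 2.0 * np.trapezoid(s_two * kernel, f_two)  # one-sided
    return 10.0 * np.log10(out)
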