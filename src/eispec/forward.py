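"""Linearized excitatory/inhibitory neural mass model of a single cortical region.

The regional signal is modelled as the sum of an excitatory population signal
``x_e(t)`` and an inhibitory population signal ``x_i(t)``.  Each population
integrates recurrent input through a gamma-shaped ensemble impulse response
with time-constant ``tau`` and postsynaptic gain ``g``, and both are driven by
Gaussian white noise:

    dx_e/dt = -(f_e/tau_e) * (g_ee * x_e - g_ei * f_i * x_i) + p(t)
    dx_i/dt = -(f_i/tau_i) * (g_ii * x_i + g_ei * f_e * x_e) + p(t)

(``*`` denotes convolution; ``f_e``, ``f_i`` are unit-area gamma kernels).
Because the system is linear, the stationary power spectral density has a
closed form in terms of the two transfer functions ``H_e``, ``H_i`` obtained
by solving a 2x2 complex linear system per frequency.  A stochastic
time-domain twin (Euler--Maruyama integration of the state-space realization)
is provided as a brute-force cross-check of the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NMMParameters",
    "FrequencyGrid",
    "ModelSpectrum",
    "TimeDomainRealization",
    "NumericalDegeneracyError",
    "InstabilityError",
    "gamma_transfer",
    "local_transfer",
    "model_psd_db",
    "state_matrices",
    "is_stable",
    "simulate_time_domain",
]

#: Frequency range (Hz) over which spectra are modelled and compared.
ANALYSIS_BAND = (1.0, 35.0)


class NumericalDegeneracyError(ValueError):
    """The 2x2 frequency-domain system is numerically singular at a frequency."""


class InstabilityError(RuntimeError):
    """The time-domain integration diverged (state magnitude exceeded 1e12)."""


@dataclass(frozen=True)
class NMMParameters:
    """Free and fixed parameters of the regional E/I model.

    Time-constants are stored in seconds; use :meth:`from_ms` / the ``*_ms``
    properties at interfaces, where milliseconds are the conventional unit.

    Parameters
    ----------
    tau_e, tau_i
        Excitatory / inhibitory time-constants (seconds).  Larger values mean
        slower dissipation of local activity and lower-frequency spectra.
    g_ee, g_ii
        Excitatory / inhibitory neural gains (dimensionless).
    g_ei
        Cross-population gain, fixed to 1 by convention and excluded from
        fitting by default.
    noise_sd
        Standard deviation of the white-noise drive.  On a dB scale this is a
        pure additive offset, so it is unidentifiable under correlation-based
        costs and fixed to 1 during fitting.
    """

    tau_e: float
    tau_i: float
    g_ee: float
    g_ii: float
    g_ei: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_e > 0 and self.tau_i > 0):
            raise ValueError("time-constants must be positive")
        if self.g_ee < 0 or self.g_ii < 0 or self.g_ei < 0:
            raise ValueError("neural gains must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_ms(
        cls,
        tau_e_ms: float,
        tau_i_ms: float,
        g_ee: float,
        g_ii: float,
        g_ei: float = 1.0,
        noise_sd: float = 1.0,
    ) -> "NMMParameters":
        return cls(tau_e_ms * 1e-3, tau_i_ms * 1e-3, g_ee, g_ii, g_ei, noise_sd)

    @property
    def tau_e_ms(self) -> float:
        return self.tau_e * 1e3

    @property
    def tau_i_ms(self) -> float:
        return self.tau_i * 1e3

    def to_dict(self) -> dict:
        """Serializable mapping with time-constants in milliseconds."""
        return {
            "tau_e_ms": self.tau_e_ms,
            "tau_i_ms": self.tau_i_ms,
            "g_ee": self.g_ee,
            "g_ii": self.g_ii,
            "g_ei": self.g_ei,
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NMMParameters":
        return cls.from_ms(
            d["tau_e_ms"],
            d["tau_i_ms"],
            d["g_ee"],
            d["g_ii"],
            d.get("g_ei", 1.0),
            d.get("noise_sd", 1.0),
        )

    def with_(self, **kwargs) -> "NMMParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies (Hz) at which spectra live."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if not np.all(f > 0):
            raise ValueError("all grid frequencies must be positive")
        if not np.all(np.diff(f) > 0):
            raise ValueError("grid frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def default(cls, lo: float = 1.0, hi: float = 35.0, step: float = 0.5) -> "FrequencyGrid":
        n = int(round((hi - lo) / step))
        return cls(lo + step * np.arange(n + 1))

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class ModelSpectrum:
    """Closed-form model PSD on a grid, in dB (10*log10 of linear power)."""

    grid: FrequencyGrid
    psd_db: np.ndarray
    transfer_e: np.ndarray | None = None
    transfer_i: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.psd_db) != len(self.grid):
            raise ValueError("psd_db and grid lengths differ")
        if not np.all(np.isfinite(self.psd_db)):
            raise ValueError("psd_db contains non-finite values")


@dataclass(frozen=True)
class TimeDomainRealization:
    """One stochastic realization of the regional model."""

    sample_rate: float
    duration: float
    x_e: np.ndarray
    x_i: np.ndarray
    seed: int

    @property
    def signal(self) -> np.ndarray:
        """The regional population signal, x_e + x_i."""
        return self.x_e + self.x_i


def gamma_transfer(tau: float, grid: FrequencyGrid) -> np.ndarray:
    """Fourier transform of the unit-area gamma kernel f(t) = (t/tau^2) e^(-t/tau).

    Returns ``F(omega) = 1 / (1 + j*omega*tau)^2`` at each grid frequency.
    The kernel has unit area, so ``F -> 1`` as ``f -> 0``, and ``|F|`` decays
    monotonically with frequency.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    return 1.0 / (1.0 + 1j * grid.omega * tau) ** 2


def local_transfer(
    params: NMMParameters, grid: FrequencyGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-domain solution (H_e, H_i) of the coupled E/I equations.

    With ``F_e``, ``F_i`` the gamma transfer functions, solves per frequency

        (jw + (F_e/tau_e) g_ee) X_e - (F_e/tau_e) g_ei F_i X_i = 1
        (F_i/tau_i) g_ei F_e X_e + (jw + (F_i/tau_i) g_ii) X_i = 1

    i.e. the transfer from a unit (shared) noise input to each population.
    """
    w = 1j * grid.omega
    fe = gamma_transfer(params.tau_e, grid)
    fi = gamma_transfer(params.tau_i, grid)
    a11 = w + (fe / params.tau_e) * params.g_ee
    a12 = -(fe / params.tau_e) * params.g_ei * fi
    a21 = (fi / params.tau_i) * params.g_ei * fe
    a22 = w + (fi / params.tau_i) * params.g_ii

    det = a11 * a22 - a12 * a21
    scale = np.maximum(np.abs(a11 * a22), np.abs(a12 * a21))
    bad = np.abs(det) <= 1e-12 * scale
    if np.any(bad):
        f_bad = grid.frequencies[bad][0]
        raise NumericalDegeneracyError(
            f"transfer system is singular at {f_bad:g} Hz for parameters {params.to_dict()}"
        )
    h_e = (a22 - a12) / det
    h_i = (a11 - a21) / det
    return h_e, h_i


def _psd_db_fast(
    tau_e_ms: float,
    tau_i_ms: float,
    g_ee: float,
    g_ii: float,
    g_ei: float,
    omega: np.ndarray,
    noise_mode: str = "common",
) -> np.ndarray:
    """Unvalidated closed-form dB spectrum for optimizer inner loops.

    Identical math to :func:`model_psd_db` with noise_sd = 1; skips the
    dataclass plumbing (which dominates runtime at ~70 bins per call).
    Returns NaNs instead of raising on degenerate input.
    """
    te, ti = tau_e_ms * 1e-3, tau_i_ms * 1e-3
    jw = 1j * omega
    fe = 1.0 / (1.0 + jw * te) ** 2
    fi = 1.0 / (1.0 + jw * ti) ** 2
    ae = fe / te
    ai = fi / ti
    a11 = jw + ae * g_ee
    a12 = -ae * g_ei * fi
    a21 = ai * g_ei * fe
    a22 = jw + ai * g_ii
    det = a11 * a22 - a12 * a21
    with np.errstate(divide="ignore", invalid="ignore"):
        h_e = (a22 - a12) / det
        h_i = (a11 - a21) / det
        if noise_mode == "common":
            lin = np.abs(h_e + h_i) ** 2
        else:
            lin = np.abs(h_e) ** 2 + np.abs(h_i) ** 2
        return 10.0 * np.log10(lin)


def model_psd_db(
    params: NMMParameters,
    grid: FrequencyGrid | None = None,
    noise_mode: str = "common",
) -> ModelSpectrum:
    """Closed-form power spectral density of the regional signal, in dB.

    Under ``noise_mode='common'`` (default) both populations share one noise
    realization and the regional signal is the coherent sum, giving linear
    power ``noise_sd^2 |H_e + H_i|^2``.  Under ``'independent'`` the drives
    are uncorrelated and the powers add: ``noise_sd^2 (|H_e|^2 + |H_i|^2)``.
    """
    if grid is None:
        grid = FrequencyGrid.default()
    if params.noise_sd == 0:
        raise ValueError("noise_sd must be positive for a dB spectrum")
    h_e, h_i = local_transfer(params, grid)
    if noise_mode == "common":
        lin = np.abs(h_e + h_i) ** 2
    elif noise_mode == "independent":
        lin = np.abs(h_e) ** 2 + np.abs(h_i) ** 2
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    lin = params.noise_sd**2 * lin
    return ModelSpectrum(grid, 10.0 * np.log10(lin), transfer_e=h_e, transfer_i=h_i)


# ---------------------------------------------------------------------------
# time-domain twin
# ---------------------------------------------------------------------------

# State vector: [x_e, x_i, y_e, y_e', y_i, y_i', w_e, w_e', w_i, w_i'] where
# y_e = f_e * (g_ee x_e - g_ei w_i), y_i = f_i * (g_ii x_i + g_ei w_e),
# w_e = f_e * x_e, w_i = f_i * x_i.  Each gamma convolution y = f * u is
# realized as the 2nd-order filter tau^2 y'' + 2 tau y' + y = u.
_NSTATE = 10


def state_matrices(
    params: NMMParameters, noise_mode: str = "common"
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time state-space (A, B) of the full E/I system.

    B has one column when both populations share the noise drive, two when
    the drives are independent.
    """
    te, ti = params.tau_e, params.tau_i
    gee, gii, gei = params.g_ee, params.g_ii, params.g_ei
    A = np.zeros((_NSTATE, _NSTATE))
    # dx_e = -y_e/tau_e + p ; dx_i = -y_i/tau_i + p
    A[0, 2] = -1.0 / te
    A[1, 4] = -1.0 / ti
    # y_e filter: input u_e = g_ee x_e - g_ei w_i
    A[2, 3] = 1.0
    A[3, 0] = gee / te**2
    A[3, 8] = -gei / te**2
    A[3, 2] = -1.0 / te**2
    A[3, 3] = -2.0 / te
    # y_i filter: input u_i = g_ii x_i + g_ei w_e
    A[4, 5] = 1.0
    A[5, 1] = gii / ti**2
    A[5, 6] = gei / ti**2
    A[5, 4] = -1.0 / ti**2
    A[5, 5] = -2.0 / ti
    # w_e = f_e * x_e
    A[6, 7] = 1.0
    A[7, 0] = 1.0 / te**2
    A[7, 6] = -1.0 / te**2
    A[7, 7] = -2.0 / te
    # w_i = f_i * x_i
    A[8, 9] = 1.0
    A[9, 1] = 1.0 / ti**2
    A[9, 8] = -1.0 / ti**2
    A[9, 9] = -2.0 / ti

    if noise_mode == "common":
        B = np.zeros((_NSTATE, 1))
        B[0, 0] = 1.0
        B[1, 0] = 1.0
    elif noise_mode == "independent":
        B = np.zeros((_NSTATE, 2))
        B[0, 0] = 1.0
        B[1, 1] = 1.0
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    return A, B


def is_stable(params: NMMParameters) -> bool:
    """Whether the linear system is asymptotically stable.

    A stationary power spectrum only exists for stable parameterizations;
    the closed form remains a well-defined function of frequency either way.
    """
    A, _ = state_matrices(params)
    return bool(np.max(np.linalg.eigvals(A).real) < 0)


def _step_loop(Ad, Bn, noise, x0, n):  # pragma: no cover - numba kernel
    x = x0.copy()
    out_e = np.empty(n)
    out_i = np.empty(n)
    for k in range(n):
        x = Ad @ x + Bn @ noise[k]
        out_e[k] = x[0]
        out_i[k] = x[1]
        if abs(x[0]) > 1e12 or abs(x[1]) > 1e12:
            return out_e, out_i, k
    return out_e, out_i, -1


try:  # JIT-compile the inner loop; the pure-Python fallback is only for safety
    from numba import njit

    _step_loop = njit(cache=False)(_step_loop)
except ImportError:  # pragma: no cover
    pass


def _discretize(
    A: np.ndarray, B: np.ndarray, noise_sd: float, dt: float, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """One-step transition matrix and noise square root for the linear SDE.

    ``exact`` uses the matrix-exponential (Van Loan) discretization, which is
    distribution-exact and stable whenever the continuous system is.  The
    gamma-loop system has weakly damped oscillatory modes for which forward
    Euler is numerically unstable even at small steps, so ``euler`` is kept
    only for reference.
    """
    if method == "euler":
        Phi = np.eye(_NSTATE) + dt * A
        # p_k ~ N(0, sd^2/dt) per step => additive term sqrt(dt)*sd*B*xi
        return Phi, np.sqrt(dt) * noise_sd * B
    if method != "exact":
        raise ValueError(f"unknown discretization {method!r}")
    from scipy.linalg import expm

    Qc = noise_sd**2 * (B @ B.T)
    n = _NSTATE
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = -A
    M[:n, n:] = Qc
    M[n:, n:] = A.T
    E = expm(M * dt)
    Phi = E[n:, n:].T
    Q = Phi @ E[:n, n:]
    Q = 0.5 * (Q + Q.T)
    # symmetric square root (Q can be numerically rank-deficient)
    vals, vecs = np.linalg.eigh(Q)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return Phi, L


def simulate_time_domain(
    params: NMMParameters,
    sample_rate: float,
    duration: float,
    seed: int,
    noise_mode: str = "common",
    initial_state: np.ndarray | None = None,
    discretization: str = "exact",
) -> TimeDomainRealization:
    """Stochastic integration of the E/I system driven by white noise.

    The drive p(t) has flat (two-sided) spectral density ``noise_sd^2``, so
    the Welch spectrum of ``x_e + x_i`` matches the closed-form PSD up to the
    one-sided factor of two.  Requires an asymptotically stable parameter set
    (raises :class:`InstabilityError` otherwise).  Reproducible per seed.
    """
    if sample_rate < 200:
        raise ValueError("sample_rate must be at least 200 Hz")
    if duration < 10:
        raise ValueError("duration must be at least 10 s")
    dt = 1.0 / sample_rate
    n = int(round(sample_rate * duration))
    A, B = state_matrices(params, noise_mode)
    Phi, L = _discretize(A, B, params.noise_sd, dt, discretization)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, L.shape[1]))
    x0 = np.zeros(_NSTATE) if initial_state is None else np.asarray(initial_state, float)
    if x0.shape != (_NSTATE,):
        raise ValueError(f"initial_state must have shape ({_NSTATE},)")

    x_e, x_i, blew_up = _step_loop(
        np.ascontiguousarray(Phi), np.ascontiguousarray(L), noise, x0, n
    )
    if blew_up >= 0:
        raise InstabilityError(
            f"integration diverged at t={blew_up * dt:.3f} s; "
            "the parameter set is linearly unstable (no stationary spectrum)"
        )
    return TimeDomainRealization(sample_rate, duration, x_e, x_i, seed)
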