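"""Balloon-Windkessel hemodynamic forward model and resting-band filtering.

Regional excitatory firing rates drive a vasodilatory signal s; blood
inflow f follows s, with venous volume v and deoxyhemoglobin content q
relaxing on the transit time tau.  The BOLD signal is the usual
volume-weighted sum of extra- and intravascular terms.  Integration is
explicit Euler on log(f), log(v), log(q), which keeps the physiological
states positive by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._kernels import balloon_euler
from .params import HemodynamicParameters

__all__ = ["BoldTimeseries", "bold_from_rates", "bandpass",
           "balloon_steady_state"]


@dataclass
class BoldTimeseries:
    """Region x time BOLD matrix sampled at ``sampling_interval`` seconds.

    ``band`` is None for broadband signals or an (low, high) Hz pair after
    band-pass filtering.
    """

    values: np.ndarray
    sampling_interval: float
    band: tuple[float, float] | None = None
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")
        if self.values.shape[1] < 2:
            raise ValueError("BOLD needs at least 2 time points")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.band is not None and not self.band[0] < self.band[1]:
            raise ValueError("band must satisfy low < high")
        if not self.region_labels:
            self.region_labels = [f"R{i}" for i in range(self.values.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def discard(self, seconds: float) -> "BoldTimeseries":
        k = int(round(seconds / self.sampling_interval))
        return BoldTimeseries(self.values[:, k:], self.sampling_interval,
                              self.band, self.region_labels)

    def to_file(self, path, delimiter: str = "\t") -> None:
        t = np.arange(self.n_samples) * self.sampling_interval
        data = np.column_stack([t, self.values.T])
        header = delimiter.join(["time_s"] + self.region_labels)
        np.savetxt(path, data, delimiter=delimiter, header=header, comments="")

    @classmethod
    def from_file(cls, path, delimiter: str = "\t") -> "BoldTimeseries":
        with open(path) as fh:
            labels = fh.readline().strip().split(delimiter)[1:]
        data = np.loadtxt(path, delimiter=delimiter, skiprows=1, ndmin=2)
        t = data[:, 0]
        tr = float(np.median(np.diff(t)))
        return cls(data[:, 1:].T, tr, None, labels)


def balloon_steady_state(rate: float, params: HemodynamicParameters) -> dict:
    """Algebraic steady state of the hemodynamic ODEs for a constant rate.

    Setting all derivatives to zero gives s* = 0,
    f* = 1 + (c1 r + c0)/gamma_h, v* = f*^alpha and
    q* = E(f*) v* / rho with E(f) = 1 - (1 - rho)^(1/f).
    """
    drive = params.drive_slope * rate + params.drive_offset
    f = 1.0 + drive / params.gamma_h
    if f <= 0:
        raise ValueError("steady-state flow is non-positive for this drive")
    v = f ** params.alpha
    E = 1.0 - (1.0 - params.rho_h) ** (1.0 / f)
    q = E * v / params.rho_h * f / v ** (1.0 / params.alpha)
    bold = params.V0 * (params.k1 * (1 - q) + params.k2 * (1 - q / v)
                        + params.k3 * (1 - v))
    return {"s": 0.0, "f": f, "v": v, "q": q, "bold": bold}


def bold_from_rates(rates_E: np.ndarray, params: HemodynamicParameters,
                    dt: float = 1.0, out_interval: float = 2.0,
                    region_labels: list[str] | None = None
                    ) -> BoldTimeseries:
    """Transform excitatory rate trajectories into a BOLD time series.

    Parameters
    ----------
    rates_E : ndarray, shape (n_regions, n_samples)
        Nonnegative firing rates (Hz) sampled every ``dt`` ms.
    dt : float
        Sampling interval of the rates in ms (the hemodynamic ODEs are
        integrated on this grid).
    out_interval : float
        Output repetition time in seconds; BOLD is averaged within each
        TR window (trailing partial window dropped).
    """
    rates_E = np.atleast_2d(np.asarray(rates_E, dtype=float))
    if np.any(rates_E < 0):
        raise ValueError("rates must be nonnegative")
    dt_s = dt / 1000.0
    if out_interval < dt_s:
        raise ValueError("out_interval must be at least the rate sampling dt")
    drive = params.drive_slope * rates_E + params.drive_offset
    status, bad_region, bad_step, B = balloon_euler(
        np.ascontiguousarray(drive), dt_s, params.kappa, params.gamma_h,
        params.tau_h, params.alpha, params.rho_h, params.V0,
        params.k1, params.k2, params.k3)
    if status != 0:
        raise FloatingPointError(
            f"hemodynamic state blew up in region {bad_region} "
            f"at step {bad_step}")
    rec = int(round(out_interval / dt_s))
    n_out = B.shape[1] // rec
    if n_out < 2:
        raise ValueError("rates too short for the requested out_interval")
    B = B[:, :n_out * rec].reshape(B.shape[0], n_out, rec).mean(axis=2)
    return BoldTimeseries(B, out_interval, None, region_labels or [])


def bandpass(x: BoldTimeseries, low: float = 0.01, high: float = 0.1,
             order: int = 2) -> BoldTimeseries:
    """Zero-phase Butterworth band-pass into the resting-state band.

    ``order`` is the design order of the second-order-section filter
    before the forward-backward (filtfilt) application.
    """
    nyq = 0.5 / x.sampling_interval
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq:.4g} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 /
                        x.sampling_interval, output="sos")
    # forward-backward padding requirement
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.n_samples <= padlen:
        raise ValueError(
            f"signal of {x.n_samples} samples is shorter than the filter "
            f"warm-up ({padlen} samples)")
    vals = signal.sosfiltfilt(sos, x.values, axis=1)
    return BoldTimeseries(vals, x.sampling_interval, (low, high),
                          x.region_labels)


def bandpass_response(freqs, sampling_interval: float, low: float = 0.01,
                      high: float = 0.1, order: int = 2) -> np.ndarray:
    """Amplitude response of the zero-phase filter at the given frequencies."""
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=1.0 / sampling_interval, output="sos")
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs)
                           * sampling_interval)
    return np.abs(h) ** 2  # applied forward and backward


def load_bold_directory(path, delimiter: str = "\t") -> list[BoldTimeseries]:
    """Load every delimited BOLD file in a directory (sorted by name)."""
    import os

    files = sorted(f for f in os.listdir(path)
                   if f.endswith((".tsv", ".txt", ".csv")))
    if not files:
        raise FileNotFoundError(f"no BOLD files found in {path}")
    out = []
    for f in files:
        delim = "," if f.endswith(".csv") else delimiter
        out.append(BoldTimeseries.from_file(os.path.join(path, f), delim))
    return out
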