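"""Frequency-domain bandpass filtering and its degrees-of-freedom ledger.

A discrete series of duration ``t_max`` sampled at TR has positive
frequencies ``k / t_max`` up to the Nyquist rate ``1 / (2 TR)`` — that bin
count *is* the data's spectral degrees of freedom.  A bandpass keeps only
the bins inside the band, so 5 min at TR = 1 s (150 bins) filtered to
0.01-0.2 Hz keeps 57 and to 0.01-0.1 Hz keeps 27.

Band-edge convention: a bin is retained when ``f_lo <= f < f_hi``
(lower-inclusive, upper-exclusive), which reproduces the 57/27 counts
above; a closed upper edge would give 58/28.  As the one exception, when
``f_hi`` reaches Nyquist the Nyquist bin is retained, so a full-band filter
passes everything.

Filtering can be applied as a brick-wall FFT filter (to data and model
identically) or *inside* the GLM as sine/cosine regressors at the stop-band
bins — the two routes give identical residuals, but only the in-GLM route
makes the DOF cost explicit in the model's column count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regressors import Regressor

__all__ = ["BandSpec", "bandpass_dof", "fft_bandpass", "spectral_regressors"]


@dataclass
class BandSpec:
    """A bandpass specification tied to an acquisition geometry."""

    f_lo: float
    f_hi: float
    tr_s: float
    t_max_s: float

    def __post_init__(self) -> None:
        if self.f_lo < 0 or not self.f_lo < self.f_hi:
            raise ValueError("need 0 <= f_lo < f_hi")
        if not self.tr_s > 0 or not self.t_max_s > 0:
            raise ValueError("tr_s and t_max_s must be positive")
        if self.f_hi > self.nyquist_hz + 1e-12:
            raise ValueError(
                f"f_hi={self.f_hi} Hz exceeds the Nyquist frequency "
                f"{self.nyquist_hz} Hz at TR={self.tr_s} s")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    @property
    def delta_f_hz(self) -> float:
        return 1.0 / self.t_max_s

    @property
    def n_timepoints(self) -> int:
        return int(round(self.t_max_s / self.tr_s))

    def retained_bins(self) -> np.ndarray:
        """Indices k (1-based frequency bins) whose frequency lies in the band."""
        n_total = self.n_timepoints // 2
        k = np.arange(1, n_total + 1)
        f = k * self.delta_f_hz
        keep = (f >= self.f_lo - 1e-12) & (f < self.f_hi - 1e-12)
        if self.f_hi >= self.nyquist_hz - 1e-12:  # band reaches Nyquist: keep it
            keep |= np.isclose(f, self.nyquist_hz)
            keep &= f >= self.f_lo - 1e-12
        return k[keep]


def bandpass_dof(spec: BandSpec) -> tuple[int, int]:
    """Spectral degrees of freedom before and after a bandpass.

    Returns ``(n_total_bins, n_retained_bins)``: positive-frequency bins up
    to Nyquist (``floor(t_max / 2 TR)``) and the count inside the band.
    """
    n_total = spec.n_timepoints // 2
    return n_total, int(spec.retained_bins().size)


def fft_bandpass(series: np.ndarray, spec: BandSpec, keep_dc: bool = True) -> np.ndarray:
    """Ideal (brick-wall) bandpass: zero every Fourier bin outside the band.

    Works on a (t,) series or a (t, n_voxels) stack.  ``keep_dc`` controls
    whether the mean survives; the conjugate-symmetric negative band is
    handled implicitly by the real FFT.
    """
    y = np.asarray(series, dtype=float)
    n = y.shape[0]
    if n != spec.n_timepoints:
        raise ValueError(
            f"series length {n} does not match spec ({spec.n_timepoints} timepoints)")
    spec_f = np.fft.rfft(y, axis=0)
    keep = np.zeros(spec_f.shape[0], dtype=bool)
    keep[spec.retained_bins()] = True
    if keep_dc:
        keep[0] = True
    spec_f[~keep] = 0.0
    return np.fft.irfft(spec_f, n=n, axis=0)


def spectral_regressors(n_timepoints: int, spec: BandSpec) -> list[Regressor]:
    """Unit-norm sine/cosine columns at every stop-band frequency bin.

    Adding these to the noise model (role ``filter``) removes exactly the
    frequencies a brick-wall bandpass would, while keeping the DOF cost
    visible as added columns.  DC is excluded — the constant detrend column
    owns the baseline.  For even lengths the Nyquist bin contributes only a
    cosine (its sine vanishes on the sample grid).
    """
    if n_timepoints != spec.n_timepoints:
        raise ValueError("n_timepoints does not match spec")
    n = n_timepoints
    n_total = n // 2
    stop = np.setdiff1d(np.arange(1, n_total + 1), spec.retained_bins())
    t = np.arange(n)
    regs: list[Regressor] = []
    for k in stop:
        cos = np.cos(2.0 * np.pi * k * t / n)
        cos /= np.linalg.norm(cos)
        regs.append(Regressor(f"filt_cos_{k:03d}", cos, dt=spec.tr_s, role="filter"))
        if 2 * k != n:  # Nyquist sine is identically zero on the grid
            sin = np.sin(2.0 * np.pi * k * t / n)
            sin /= np.linalg.norm(sin)
            regs.append(Regressor(f"filt_sin_{k:03d}", sin, dt=spec.tr_s, role="filter"))
    return regs
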