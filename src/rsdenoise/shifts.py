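"""Temporal-shift optimisation of nuisance regressors, with honest inference.

Physiological regressors (end-tidal CO2, heart rate) lag the BOLD signal
they drive, so the regressor is slid over a grid of candidate shifts and
the shift maximising |Pearson r| kept.  Trying m shifts is m correlation
tests: the maximal r must clear a Šidák-corrected threshold
``alpha_sidak = 1 - (1 - alpha)^(1/m)`` rather than the single-test one,
and the chosen shift should be validated by recomputing it on independent
halves of the data before it is trusted.

Sign convention: a positive shift *delays* the regressor (the value used at
time t is the source at t - s), so a BOLD response lagging CO2 by 6 s shows
up as an optimal shift of +6 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import critical_r
from .regressors import Regressor

__all__ = [
    "ShiftGrid",
    "ShiftSearchResult",
    "sidak",
    "resample_linear",
    "shifted_variants",
    "optimise_shift",
    "split_half_validate",
    "group_shift_reliability",
]


@dataclass
class ShiftGrid:
    """Uniform grid of candidate temporal shifts, in seconds."""

    t_min_s: float
    t_max_s: float
    step_s: float

    def __post_init__(self) -> None:
        if not self.step_s > 0:
            raise ValueError("step_s must be positive")
        if self.t_min_s > self.t_max_s:
            raise ValueError("t_min_s must not exceed t_max_s")

    @property
    def m_variants(self) -> int:
        return int(round((self.t_max_s - self.t_min_s) / self.step_s)) + 1

    @property
    def shifts_s(self) -> np.ndarray:
        return self.t_min_s + self.step_s * np.arange(self.m_variants)


@dataclass
class ShiftSearchResult:
    """Outcome of a shift search: the r-vs-shift curve and its verdict."""

    shifts_s: np.ndarray
    r_values: np.ndarray
    best_shift_s: float
    best_r: float
    alpha: float
    alpha_sidak: float
    r_threshold_sidak: float
    significant: bool
    r_threshold_uncorrected: float = float("nan")


def sidak(alpha: float, m: int) -> float:
    """Šidák-corrected per-test threshold for m tests: ``1 - (1 - alpha)^(1/m)``.

    For 61 shifted variants at family-wise alpha 0.05 this is 8.4e-4 (and
    1.6e-4 at alpha 0.01).  Conservative when the tests are positively
    dependent, as shifted variants of one regressor are.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def resample_linear(series: np.ndarray, dt_in: float, dt_out: float) -> np.ndarray:
    """Linearly interpolate a series onto a new uniform grid and demean it.

    The output grid spans the same interval ``[0, (n-1) dt_in]`` starting at
    the same origin.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("series must be a 1-D vector with >= 2 samples")
    if not dt_in > 0 or not dt_out > 0:
        raise ValueError("sampling intervals must be positive")
    t_in = np.arange(y.size) * dt_in
    n_out = int(np.floor(t_in[-1] / dt_out + 1e-9)) + 1
    if n_out < 1:
        raise ValueError("output grid is empty")
    t_out = np.arange(n_out) * dt_out
    out = np.interp(t_out, t_in, y)
    return out - out.mean()


def shifted_variants(series: np.ndarray, dt: float, grid: ShiftGrid,
                     n_out: int, out_dt: float, t_start_s: float = 0.0,
                     name: str = "regressor") -> list[Regressor]:
    """Build one regressor per candidate shift, zero-filling uncovered points.

    The source is demeaned first, so zero-fill equals mean-fill.  Variant s
    takes the source value at ``t - s`` (linear interpolation between source
    samples); output times are ``t_start_s + j * out_dt`` for j < n_out.
    ``t_start_s`` allows building variants for a later window of the scan
    (used by split-half validation).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("series must be a 1-D vector with >= 2 samples")
    duration = (y.size - 1) * dt
    if grid.step_s > duration:
        raise ValueError("shift grid step exceeds the series duration")
    y = y - y.mean()
    t_src = np.arange(y.size) * dt
    t_out = t_start_s + np.arange(n_out) * out_dt
    variants = []
    for s in grid.shifts_s:
        tq = t_out - s
        vals = np.interp(tq, t_src, y, left=0.0, right=0.0)
        variants.append(Regressor(f"{name}_shift{s:+.2f}s", vals, dt=out_dt,
                                  role="nuisance", shift_s=float(s)))
    return variants


def _pearson_stack(y: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Pearson r of y against each column of cols; zero-variance columns -> 0."""
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    cc = cols - cols.mean(axis=0)
    sc = np.sqrt(np.sum(cc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ cc) / (sy * sc)
    return np.where(sc == 0, 0.0, r)


def optimise_shift(y: np.ndarray, variants: list[Regressor], alpha: float = 0.05,
                   tails: str = "two", positive_only: bool = False) -> ShiftSearchResult:
    """Pick the shift with maximal |r| and judge it at the Šidák threshold.

    ``m`` is the number of variants; the corrected alpha is converted to a
    correlation-magnitude threshold at the series' sample count.  Ties in
    |r| break toward the smallest |shift|.  ``positive_only`` restricts the
    search to positive correlations (physiologically signed regressors).
    """
    y = np.asarray(y, dtype=float)
    if not variants:
        raise ValueError("need at least one shifted variant")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance time-series: correlation undefined")
    n = y.size
    cols = np.column_stack([v.values for v in variants])
    if cols.shape[0] != n:
        raise ValueError("variants and y must have the same length")
    r = _pearson_stack(y, cols)
    shifts = np.array([v.shift_s for v in variants])
    score = r if positive_only else np.abs(r)
    best_score = score.max()
    # ties toward the smallest absolute shift
    tied = np.flatnonzero(np.isclose(score, best_score, rtol=0, atol=1e-12))
    best_i = tied[np.argmin(np.abs(shifts[tied]))]
    m = len(variants)
    a_sidak = sidak(alpha, m)
    thr_sidak = critical_r(n, a_sidak, tails)
    thr_plain = critical_r(n, alpha, tails)
    best_r = float(r[best_i])
    return ShiftSearchResult(
        shifts_s=shifts,
        r_values=r,
        best_shift_s=float(shifts[best_i]),
        best_r=best_r,
        alpha=alpha,
        alpha_sidak=a_sidak,
        r_threshold_sidak=thr_sidak,
        significant=bool(abs(best_r) >= thr_sidak if not positive_only
                         else best_r >= thr_sidak),
        r_threshold_uncorrected=thr_plain,
    )


def split_half_validate(y: np.ndarray, source: np.ndarray, source_dt: float,
                        grid: ShiftGrid, alpha: float = 0.05,
                        out_dt: float | None = None, tails: str = "two"):
    """Optimal shift estimated independently on the two halves of the data.

    ``y`` is the full series sampled at ``out_dt`` (defaults to
    ``source_dt``); the source regressor covers the same window.  Returns
    ``(result_first_half, result_second_half)`` — agreement of their
    ``best_shift_s`` within a grid step is the validation criterion.
    """
    y = np.asarray(y, dtype=float)
    if out_dt is None:
        out_dt = source_dt
    n = y.size
    n_half = n // 2
    if n_half < 20:
        raise ValueError("each half must contain at least 20 samples")
    halves = []
    for h, (lo, n_h) in enumerate([(0, n_half), (n_half, n - n_half)]):
        variants = shifted_variants(source, source_dt, grid, n_h, out_dt,
                                    t_start_s=lo * out_dt)
        halves.append(optimise_shift(y[lo:lo + n_h], variants, alpha, tails))
    return halves[0], halves[1]


def group_shift_reliability(pairs) -> tuple[float, float]:
    """Across-subject Pearson correlation of first- vs second-half shifts.

    ``pairs`` is a sequence of (shift_first_half, shift_second_half).
    Degenerate (constant) inputs raise, since the correlation is undefined.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (shift, shift) pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant shifts across subjects: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
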