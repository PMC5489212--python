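"""Ordinary least-squares fitting of the noise model and its fit statistics.

The model is ``Y = X b + e`` with Y the BOLD time-series (one column per
voxel) and X a role-partitioned design matrix.  The figure of merit for a
noise model is the *partial* R² of the nuisance columns — the variance they
explain beyond the detrending (and filter) columns — together with its
F test.  Closed-form critical values for R² and for Pearson correlations
are provided so maps can be thresholded at a stated alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .regressors import CollinearityError, DesignMatrix

__all__ = [
    "BoldImage",
    "FitResult",
    "ols_fit",
    "partial_r2",
    "f_test_r2",
    "critical_r",
    "critical_r2",
]


@dataclass
class BoldImage:
    """A 4-D BOLD dataset: ``data[x, y, z, t]``, TR in seconds, 3-D mask."""

    data: np.ndarray
    tr_s: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] < 2:
            raise ValueError("data must be 4-D (x, y, z, t) with t >= 2")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match the spatial dimensions")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    def timeseries(self) -> np.ndarray:
        """In-mask voxel time-series as an (n_timepoints, n_voxels) array."""
        return self.data[self.mask].T

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an (n_voxels,) per-voxel statistic back into a 3-D map."""
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out

    def mean_timeseries(self) -> np.ndarray:
        return self.timeseries().mean(axis=1)

    @classmethod
    def from_nifti(cls, path, mask_path=None) -> "BoldImage":
        import nibabel as nib

        img = nib.load(str(path))
        tr = float(img.header.get_zooms()[3])
        mask = None
        if mask_path is not None:
            mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
        return cls(np.asanyarray(img.dataobj, dtype=float), tr_s=tr, mask=mask)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.data.astype(np.float32), np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, self.tr_s))
        nib.save(img, str(path))


@dataclass
class FitResult:
    """Per-voxel OLS results and the ingredients of the noise-model R².

    ``r2_noise`` is the hierarchical R² of the nuisance columns over the
    detrend/filter-only model, NaN for voxels with no variance left after
    detrending (``zero_variance`` marks them).  ``dof_error`` is
    ``n_timepoints - n_columns`` of the model actually fitted.
    """

    beta: np.ndarray
    residuals: np.ndarray
    r2_noise: np.ndarray
    f_stat: np.ndarray
    p_value: np.ndarray
    dof_model: int
    dof_error: int
    sse_full: np.ndarray = field(repr=False, default=None)
    sse_reduced: np.ndarray = field(repr=False, default=None)
    zero_variance: np.ndarray = field(repr=False, default=None)
    column_names: list = field(default_factory=list)
    total_variance: np.ndarray = field(repr=False, default=None)


def noise_r2(sse_full, sse_red, total_var):
    """Noise-model R² from the two SSEs, handling degenerate voxels.

    Voxels with no variance at all (``total_var ~ 0``) are undefined: NaN,
    flagged.  Voxels fully explained by the detrend/filter columns alone
    (``sse_red ~ 0`` but real variance) get R² = 0 — the nuisance columns
    add nothing beyond the trend.
    """
    sse_full = np.asarray(sse_full, dtype=float)
    sse_red = np.asarray(sse_red, dtype=float)
    total_var = np.asarray(total_var, dtype=float)
    eps = np.finfo(float).eps
    zero_var = total_var <= max(float(total_var.max(initial=0.0)), 1.0) * 100 * eps
    trend_only = (sse_red <= total_var * 1e-12 + eps) & ~zero_var
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - sse_full / sse_red
    r2 = np.where(trend_only, 0.0, r2)
    r2 = np.where(zero_var, np.nan, np.clip(r2, 0.0, 1.0))
    return r2, zero_var


def _as_stack(y) -> tuple[np.ndarray, bool]:
    """Return (Y as (t, nvox), was_1d)."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return y[:, None], True
    if y.ndim == 2:
        return y, False
    raise ValueError("y must be 1-D, 2-D (t, n_voxels), or a BoldImage")


def ols_fit(y, design: DesignMatrix) -> FitResult:
    """Fit ``Y = X b + e`` by ordinary least squares, per voxel.

    Parameters
    ----------
    y : 1-D array, (t, n_voxels) array, or BoldImage
        Observations.  For a BoldImage only in-mask voxels are fitted.
    design : DesignMatrix
        Full-rank design; its role partition determines which columns count
        toward the noise-model R².

    Returns
    -------
    FitResult
        ``beta`` has shape (n_columns,) for 1-D input, else
        (n_columns, n_voxels); residuals (t,) or (t, n_voxels).
    """
    if isinstance(y, BoldImage):
        return ols_fit(y.timeseries(), design)
    Y, was_1d = _as_stack(y)
    x = design.matrix
    if Y.shape[0] != x.shape[0]:
        raise ValueError(
            f"length mismatch: y has {Y.shape[0]} timepoints, design has {x.shape[0]}")
    if design.rank < design.n_columns:
        raise CollinearityError("design is rank deficient")

    q, r = np.linalg.qr(x)
    beta = np.linalg.solve(r, q.T @ Y)
    resid = Y - x @ beta
    sse_full = np.sum(resid**2, axis=0)

    nuis = design.indices_of("nuisance")
    other = np.setdiff1d(np.arange(design.n_columns), nuis)
    if other.size:
        xr = x[:, other]
        qr_, rr_ = np.linalg.qr(xr)
        resid_red = Y - xr @ np.linalg.solve(rr_, qr_.T @ Y)
        sse_red = np.sum(resid_red**2, axis=0)
    else:
        sse_red = np.sum(Y**2, axis=0)

    n = Y.shape[0]
    dof_model = int(nuis.size)
    dof_error = int(n - design.n_columns)
    total_var = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    r2, zero_var = noise_r2(sse_full, sse_red, total_var)
    f, p = f_test_r2(r2, max(dof_model, 1), max(dof_error, 1))
    if dof_model == 0:
        f = np.zeros_like(r2)
        p = np.ones_like(r2)
        r2 = np.zeros_like(r2)

    if was_1d:
        beta, resid = beta[:, 0], resid[:, 0]
        r2, f, p = r2[0], np.asarray(f)[0], np.asarray(p)[0]
        sse_full, sse_red, zero_var = sse_full[0], sse_red[0], zero_var[0]
        total_var = total_var[0]
    return FitResult(
        beta=beta,
        residuals=resid,
        r2_noise=r2,
        f_stat=f,
        p_value=p,
        dof_model=dof_model,
        dof_error=dof_error,
        sse_full=sse_full,
        sse_reduced=sse_red,
        zero_variance=zero_var,
        column_names=list(design.names),
        total_variance=total_var,
    )


def partial_r2(fit: FitResult, design: DesignMatrix) -> np.ndarray:
    """Noise-model R²: variance explained by nuisance columns beyond the rest.

    ``1 - SSE(full) / SSE(detrend+filter only)``; voxels flagged
    ``zero_variance`` (no variance after detrending) are returned as NaN.
    """
    if design.indices_of("nuisance").size == 0:
        return np.zeros_like(np.asarray(fit.sse_full, dtype=float))
    if fit.total_variance is not None:
        r2, _ = noise_r2(fit.sse_full, fit.sse_reduced, fit.total_variance)
        return r2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - fit.sse_full / fit.sse_reduced
    return np.where(fit.zero_variance, np.nan, np.clip(r2, 0.0, 1.0))


def f_test_r2(r2, k_test: int, dof_error: int):
    """F statistic and upper-tail p for a (partial) R² on k_test columns.

    ``F = (r2 / k_test) / ((1 - r2) / dof_error)``.  ``r2 == 1`` maps to
    ``F = inf, p = 0``.
    """
    if k_test < 1 or dof_error < 1:
        raise ValueError("k_test and dof_error must be >= 1")
    r2 = np.asarray(r2, dtype=float)
    if np.nanmin(r2, initial=0) < 0 or np.nanmax(r2, initial=0) > 1:
        raise ValueError("r2 must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        f = (r2 / k_test) / ((1.0 - r2) / dof_error)
    p = stats.f.sf(f, k_test, dof_error)
    p = np.where(r2 >= 1.0, 0.0, p)
    if f.ndim == 0:
        return float(f), float(p)
    return f, p


def critical_r(n_samples: int, alpha: float, tails: str = "two") -> float:
    """Pearson-correlation magnitude whose p-value equals ``alpha``.

    Uses the exact t transform ``t = r sqrt(n-2) / sqrt(1-r²)`` with
    ``n - 2`` degrees of freedom; ``tails`` is ``"two"`` (default, negative
    correlations count) or ``"one"``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    tail_p = alpha / 2 if tails == "two" else alpha
    t = stats.t.ppf(1.0 - tail_p, n_samples - 2)
    return float(t / np.sqrt(t**2 + n_samples - 2))


def critical_r2(n_timepoints: int, k_test: int, k_other: int, alpha: float) -> float:
    """Critical partial R² at significance ``alpha``.

    Inverts :func:`f_test_r2` at the upper-``alpha`` F quantile with
    ``dof_error = n_timepoints - k_test - k_other``.  With the typical
    8 nuisance regressors, quadratic detrending (3 columns) and 160 volumes
    this gives 0.097 at alpha 0.05.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    dof_error = n_timepoints - k_test - k_other
    if dof_error < 1:
        raise ValueError(
            f"impossible degrees of freedom: n={n_timepoints}, "
            f"k_test={k_test}, k_other={k_other}")
    f_crit = stats.f.ppf(1.0 - alpha, k_test, dof_error)
    return float(k_test * f_crit / (k_test * f_crit + dof_error))
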