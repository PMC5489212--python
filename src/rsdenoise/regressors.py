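"""Construction and assembly of nuisance-regression design matrices.

A noise model for resting-state BOLD data is an ordered collection of
columns: *nuisance* regressors (motion parameters, convolved physiological
traces), *detrend* columns (orthogonal polynomials absorbing baseline and
slow drift), and optional *filter* columns (sines/cosines implementing a
bandpass inside the GLM).  This module builds those columns, convolves raw
physiological traces with response kernels, and assembles them into a
rank-checked design matrix with collinearity diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Regressor",
    "ResponseKernel",
    "DesignMatrix",
    "CollinearityError",
    "legendre_detrend",
    "convolve_response",
    "assemble_design",
    "collinearity_report",
    "canonical_hrf",
    "cardiac_response_function",
]

ROLES = ("nuisance", "detrend", "filter")


class CollinearityError(ValueError):
    """Raised when a design matrix is rank deficient."""


@dataclass
class Regressor:
    """One named column of the noise model.

    Parameters
    ----------
    name : str
        Label, e.g. ``"petco2"`` or ``"trans_x"``.
    values : ndarray
        Sampled values, arbitrary units.
    dt : float
        Sampling interval in seconds.
    role : {"nuisance", "detrend", "filter"}
        Which partition of the design the column belongs to.  Only
        ``nuisance`` columns count toward the noise-model R².
    shift_s : float
        Temporal shift applied during construction (positive = regressor
        delayed), 0 if none.
    kernel_name : str
        Name of the convolution kernel used, empty if none.
    """

    name: str
    values: np.ndarray
    dt: float
    role: str = "nuisance"
    shift_s: float = 0.0
    kernel_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError(f"regressor {self.name!r}: need a 1-D vector with >= 2 samples")
        if not self.dt > 0:
            raise ValueError(f"regressor {self.name!r}: dt must be positive, got {self.dt}")
        if self.role not in ROLES:
            raise ValueError(f"regressor {self.name!r}: unknown role {self.role!r}")
        if self.role == "detrend" and self.shift_s != 0.0:
            raise ValueError(f"detrend regressor {self.name!r} cannot carry a temporal shift")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ResponseKernel:
    """A finite-support convolution kernel sampled at interval ``dt``."""

    name: str
    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.dt > 0:
            raise ValueError("kernel dt must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0 or not np.all(np.isfinite(self.samples)):
            raise ValueError("kernel samples must be a finite 1-D vector")


@dataclass
class DesignMatrix:
    """Ordered, role-partitioned collection of regressors (the GLM's X)."""

    regressors: list[Regressor]
    n_timepoints: int
    rank: int
    condition_number: float

    @property
    def matrix(self) -> np.ndarray:
        """(n_timepoints, n_columns) array, columns in input order."""
        return np.column_stack([r.values for r in self.regressors])

    @property
    def dt(self) -> float:
        return self.regressors[0].dt

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regressors]

    @property
    def roles(self) -> list[str]:
        return [r.role for r in self.regressors]

    def indices_of(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.regressors) if r.role == role], dtype=int)

    def columns_of(self, role: str) -> np.ndarray:
        idx = self.indices_of(role)
        return self.matrix[:, idx] if idx.size else np.empty((self.n_timepoints, 0))

    @property
    def n_columns(self) -> int:
        return len(self.regressors)

    def n_of(self, role: str) -> int:
        return sum(r.role == role for r in self.regressors)

    def with_replaced(self, index: int, regressor: Regressor) -> "DesignMatrix":
        """Return a new design with column ``index`` swapped out (re-checked)."""
        regs = list(self.regressors)
        regs[index] = regressor
        return assemble_design(regs)


def legendre_detrend(n_timepoints: int, order: int, dt: float = 1.0) -> list[Regressor]:
    """Orthogonal polynomial detrending columns (constant, linear, ...).

    Columns are mutually orthogonal in the discrete inner product on the
    ``n_timepoints`` sample grid (a Gram-Schmidt of ``1, t, t^2, ...``),
    so every non-constant column is exactly demeaned and the constant
    column alone carries the baseline.

    Parameters
    ----------
    n_timepoints : int
        Number of samples; must be at least ``order + 2``.
    order : int
        Highest polynomial degree; ``order=2`` removes baseline, linear and
        quadratic trends.

    Returns
    -------
    list of Regressor
        ``order + 1`` columns with role ``detrend``, unit-norm except the
        constant column which is all ones.
    """
    if order < 0:
        raise ValueError(f"polynomial order must be >= 0, got {order}")
    if n_timepoints < order + 2:
        raise ValueError(
            f"need at least order+2={order + 2} timepoints for order-{order} detrending, "
            f"got {n_timepoints}"
        )
    t = np.linspace(-1.0, 1.0, n_timepoints)
    vander = np.vander(t, order + 1, increasing=True)
    # QR gives the discrete Gram-Schmidt orthogonalisation of {1, t, ..., t^order}
    q, _ = np.linalg.qr(vander)
    # fix sign so the leading coefficient is positive, and scale the constant to 1
    cols = []
    names = {0: "poly_const", 1: "poly_linear", 2: "poly_quadratic"}
    for k in range(order + 1):
        col = q[:, k]
        if col[-1] < 0:
            col = -col
        if k == 0:
            col = np.ones(n_timepoints)
        cols.append(Regressor(names.get(k, f"poly_{k}"), col, dt=dt, role="detrend"))
    return cols


def _double_gamma(t: np.ndarray, peak: float, under: float, disp1: float, disp2: float,
                  ratio: float) -> np.ndarray:
    from scipy.stats import gamma as gamma_dist

    h = gamma_dist.pdf(t, peak / disp1, scale=disp1) - gamma_dist.pdf(
        t, under / disp2, scale=disp2) / ratio
    return h


def canonical_hrf(dt: float, duration_s: float = 32.0) -> ResponseKernel:
    """Canonical double-gamma haemodynamic response function.

    Peak at 6 s, undershoot at 16 s, undershoot ratio 1/6 (the standard
    SPM-style parameterisation), normalised to unit sum so convolution
    preserves the scale of slow inputs.
    """
    t = np.arange(0.0, duration_s + dt / 2, dt)
    h = _double_gamma(t, peak=6.0, under=16.0, disp1=1.0, disp2=1.0, ratio=6.0)
    h /= h.sum()
    return ResponseKernel("hrf", h, dt)


def cardiac_response_function(dt: float, duration_s: float = 32.0) -> ResponseKernel:
    """Cardiac response function for heart-rate regressors.

    The empirical kernel of Chang, Cunningham & Glover (2009):
    ``0.6 t^2.7 exp(-t/1.6) - 16/sqrt(18 pi) exp(-(t-12)^2/18)``,
    an early positive lobe followed by a ~12 s undershoot.  Normalised to
    unit maximum (the kernel integrates to roughly zero, so unit-sum
    normalisation is not meaningful here).
    """
    t = np.arange(0.0, duration_s + dt / 2, dt)
    h = 0.6 * t**2.7 * np.exp(-t / 1.6) - 16.0 / np.sqrt(18.0 * np.pi) * np.exp(
        -((t - 12.0) ** 2) / 18.0)
    h /= np.abs(h).max()
    return ResponseKernel("crf", h, dt)


def convolve_response(trace: np.ndarray, trace_dt: float, kernel: ResponseKernel,
                      out_dt: float, out_n: int) -> Regressor:
    """Convolve a physiological trace with a response kernel and resample.

    The kernel is resampled to the trace's sampling interval (linear
    interpolation), the discrete linear convolution is taken, the result is
    linearly resampled onto the output grid ``0, out_dt, ..., (out_n-1)*out_dt``
    and demeaned.  Role of the returned regressor is ``nuisance``.

    The trace is extended backwards with its initial value before
    convolving (the physiological state is assumed steady before
    recording), so a constant trace maps to a constant — hence to zero
    after demeaning — rather than to a kernel-onset ramp.

    Raises
    ------
    ValueError
        If the kernel outlasts the trace, or the trace does not cover the
        requested output window.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    k = kernel.samples
    if abs(kernel.dt - trace_dt) > 1e-12:
        t_k = np.arange(k.size) * kernel.dt
        t_new = np.arange(0.0, t_k[-1] + trace_dt / 2, trace_dt)
        k = np.interp(t_new, t_k, k) * (trace_dt / kernel.dt)  # preserve integral
    if k.size > trace.size:
        raise ValueError(
            f"kernel ({k.size} samples at dt={trace_dt}) is longer than the trace "
            f"({trace.size} samples)")
    padded = np.r_[np.full(k.size - 1, trace[0]), trace]
    conv = np.convolve(padded, k, mode="valid")
    t_conv = np.arange(conv.size) * trace_dt
    t_out = np.arange(out_n) * out_dt
    if t_out[-1] > t_conv[-1] + 1e-9:
        raise ValueError(
            f"trace covers {t_conv[-1]:.2f} s but {t_out[-1]:.2f} s requested")
    out = np.interp(t_out, t_conv, conv)
    out = out - out.mean()
    return Regressor("convolved", out, dt=out_dt, kernel_name=kernel.name)


def assemble_design(*groups) -> DesignMatrix:
    """Concatenate regressor groups into a full-rank design matrix.

    Accepts any number of lists of :class:`Regressor` (or a single flat
    list).  All regressors must share length and sampling interval.  Rank
    and condition number come from the SVD of the column-normalised matrix;
    rank-deficient input raises :class:`CollinearityError` naming the
    offending columns.
    """
    regs: list[Regressor] = []
    for g in groups:
        if isinstance(g, Regressor):
            regs.append(g)
        else:
            regs.extend(g)
    if not regs:
        raise ValueError("no regressors supplied")
    n = len(regs[0])
    dt = regs[0].dt
    for r in regs:
        if len(r) != n:
            raise ValueError(
                f"mixed lengths: {r.name!r} has {len(r)} samples, expected {n}")
        if abs(r.dt - dt) > 1e-9:
            raise ValueError(f"mixed sampling intervals: {r.name!r} has dt={r.dt}, expected {dt}")
    x = np.column_stack([r.values for r in regs])
    # normalise columns so the condition number reflects shape, not units
    norms = np.linalg.norm(x, axis=0)
    if np.any(norms == 0):
        dead = [regs[i].name for i in np.flatnonzero(norms == 0)]
        raise CollinearityError(f"all-zero columns: {dead}")
    s = np.linalg.svd(x / norms, compute_uv=False)
    tol = s[0] * max(x.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank < x.shape[1]:
        # name columns that are (numerically) linear combinations of earlier ones
        dep = []
        for j in range(1, x.shape[1]):
            sub = x[:, : j + 1] / norms[: j + 1]
            if np.linalg.matrix_rank(sub) <= np.linalg.matrix_rank(x[:, :j] / norms[:j]):
                dep.append(regs[j].name)
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {x.shape[1]} columns); "
            f"dependent columns: {dep}")
    cond = float(s[0] / s[-1])
    return DesignMatrix(regs, n_timepoints=n, rank=rank, condition_number=cond)


def collinearity_report(design: DesignMatrix) -> dict:
    """Variance-inflation factors and pairwise correlations of a design.

    ``VIF_j = 1 / (1 - R2_j)`` where ``R2_j`` comes from regressing column j
    on all remaining columns.  Constant (zero-variance) columns get VIF
    ``nan`` — collinearity with the intercept is not meaningful.

    Returns
    -------
    dict with keys ``vif`` (name -> float), ``correlations`` (symmetric
    DataFrame-like ndarray with ``names``), and ``condition_number``.
    """
    x = design.matrix
    n_cols = x.shape[1]
    if design.rank < n_cols:
        raise CollinearityError("design is rank deficient")
    vif = {}
    for j in range(n_cols):
        yj = x[:, j]
        if np.ptp(yj) == 0:
            vif[design.names[j]] = float("nan")
            continue
        others = np.delete(x, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst
        vif[design.names[j]] = float(1.0 / (1.0 - r2)) if r2 < 1 else float("inf")
    centred = x - x.mean(axis=0)
    sd = centred.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centred / np.where(sd == 0, np.nan, sd)).T @ (
            centred / np.where(sd == 0, np.nan, sd)) / x.shape[0]
    return {
        "vif": vif,
        "correlations": corr,
        "names": design.names,
        "condition_number": design.condition_number,
    }


def demean(regressor: Regressor) -> Regressor:
    """Return a copy with the temporal mean removed."""
    return replace(regressor, values=regressor.values - regressor.values.mean())
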