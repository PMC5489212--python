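"""End-to-end denoising: model assembly, shift optimisation, pre-whitened
fit, and subtraction of the noise fit in original space.

The orchestration follows the recommended recipe: detrend inside the model
(orthogonal polynomials), filter inside the model if filtering is wanted at
all, optimise a single temporal shift per physiological regressor only when
it is Šidák-significant *and* split-half validated, fit with pre-whitening,
and report every choice (DOF ledger, Durbin-Watson summary, shift
decisions) alongside the cleaned data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import filtering, prewhiten, regressors as regmod, shifts as shiftmod
from .glm import BoldImage, critical_r2, ols_fit
from .regressors import DesignMatrix, Regressor, assemble_design, legendre_detrend

__all__ = ["DenoiseConfig", "denoise"]


@dataclass
class DenoiseConfig:
    """Everything a denoising run needs, serialisable for the report.

    ``whiten`` is ``"ar"`` (iterative AR(p), default), ``"arma11"`` (REML
    grid) or ``"none"`` (plain OLS, inference invalid — provided for
    comparison only).  ``filter_mode`` mirrors the three legitimate options:
    ``off``, ``in_glm`` (filter columns inside the model), ``pre_both``
    (identical brick-wall filter on data and regressors before fitting) or
    ``post`` (filter the cleaned output).  ``shift_grids`` maps regressor
    names to :class:`~rsdenoise.shifts.ShiftGrid`s; a shift is applied only
    if significant after Šidák correction and (by default) split-half
    validated within ``validation_tol_steps`` grid steps.
    """

    detrend_order: int = 2
    whiten: str = "ar"
    ar_order: int = 1
    max_iter: int = 10
    tol: float = 1e-4
    filter_mode: str = "off"
    band: filtering.BandSpec | None = None
    shift_grids: dict = field(default_factory=dict)
    shift_dt_s: float = 0.2
    alpha: float = 0.05
    tails: str = "two"
    require_validation: bool = True
    validation_tol_steps: float = 1.0
    drop_nonsignificant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.whiten not in ("ar", "arma11", "none"):
            raise ValueError(f"unknown whitening mode {self.whiten!r}")
        if self.filter_mode not in ("off", "in_glm", "pre_both", "post"):
            raise ValueError(f"unknown filter mode {self.filter_mode!r}")
        if self.filter_mode != "off" and self.band is None:
            raise ValueError("filter_mode requires a BandSpec")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.band is not None:
            d["band"] = dataclasses.asdict(self.band)
        d["shift_grids"] = {
            k: dataclasses.asdict(g) for k, g in self.shift_grids.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiseConfig":
        d = dict(d)
        if d.get("band"):
            d["band"] = filtering.BandSpec(**d["band"])
        d["shift_grids"] = {
            k: shiftmod.ShiftGrid(**g) for k, g in d.get("shift_grids", {}).items()}
        return cls(**d)


def _optimise_one_shift(name: str, reg: Regressor, mean_ts: np.ndarray,
                        tr_s: float, grid: shiftmod.ShiftGrid,
                        config: DenoiseConfig) -> tuple[Regressor, dict]:
    """Shift-optimise one regressor against the mask-mean series; gate on
    significance and split-half validation."""
    n = mean_ts.size
    fine = shiftmod.resample_linear(reg.values, reg.dt, config.shift_dt_s)
    variants = shiftmod.shifted_variants(fine, config.shift_dt_s, grid, n, tr_s,
                                         name=name)
    res = shiftmod.optimise_shift(mean_ts, variants, config.alpha, config.tails)
    first, second = shiftmod.split_half_validate(
        mean_ts, fine, config.shift_dt_s, grid, config.alpha,
        out_dt=tr_s, tails=config.tails)
    agree = abs(first.best_shift_s - second.best_shift_s) <= (
        config.validation_tol_steps * grid.step_s + 1e-9)
    validated = bool(agree)
    apply = bool(res.significant and (validated or not config.require_validation))
    decision = {
        "regressor": name,
        "grid": dataclasses.asdict(grid),
        "m_variants": grid.m_variants,
        "best_shift_s": res.best_shift_s,
        "best_r": res.best_r,
        "alpha": res.alpha,
        "alpha_sidak": res.alpha_sidak,
        "r_threshold_sidak": res.r_threshold_sidak,
        "significant": bool(res.significant),
        "split_half_shifts_s": [first.best_shift_s, second.best_shift_s],
        "validated": validated,
        "shift_applied": apply,
        "r_vs_shift": {"shifts_s": res.shifts_s.tolist(),
                       "r": res.r_values.tolist()},
    }
    if apply:
        single = shiftmod.ShiftGrid(res.best_shift_s, res.best_shift_s, grid.step_s)
        shifted = shiftmod.shifted_variants(fine, config.shift_dt_s, single, n,
                                            tr_s, name=name)[0]
        return shifted, decision
    return reg, decision


def denoise(image: BoldImage, nuisance: list[Regressor], config: DenoiseConfig):
    """Run the full nuisance-regression pipeline on a BOLD image.

    Returns ``(cleaned, r2_map, p_map, report)``: a :class:`BoldImage` whose
    in-mask voxels equal the original minus the fitted noise, detrend and
    filter components (out-of-mask voxels pass through untouched), 3-D R²
    and p maps of the noise model, and a report dict with the DOF ledger,
    Durbin-Watson summary and every shift decision.
    """
    n = image.n_timepoints
    tr = image.tr_s
    Y = image.timeseries()

    warnings_log: list[str] = []
    nuisance = [regmod.demean(r) for r in nuisance]

    # optional single-shift optimisation per configured regressor
    shift_decisions = []
    mean_ts = Y.mean(axis=1)
    named = {r.name: i for i, r in enumerate(nuisance)}
    for name, grid in config.shift_grids.items():
        if name not in named:
            raise ValueError(f"shift grid given for unknown regressor {name!r}")
        i = named[name]
        new_reg, decision = _optimise_one_shift(name, nuisance[i], mean_ts, tr,
                                                grid, config)
        shift_decisions.append(decision)
        if decision["shift_applied"]:
            nuisance[i] = new_reg
        elif decision["significant"] and not decision["validated"]:
            warnings_log.append(
                f"{name}: optimal shift {decision['best_shift_s']:+.2f} s failed "
                f"split-half validation; regressor left unshifted")
        if not decision["significant"]:
            if config.drop_nonsignificant:
                warnings_log.append(f"{name}: not Šidák-significant; dropped")
            else:
                warnings_log.append(
                    f"{name}: best correlation not significant after Šidák "
                    f"correction; retained unshifted (set drop_nonsignificant "
                    f"to remove)")
    if config.drop_nonsignificant:
        dropped = {d["regressor"] for d in shift_decisions if not d["significant"]}
        nuisance = [r for r in nuisance if r.name not in dropped]

    detrend = legendre_detrend(n, config.detrend_order, dt=tr)
    filter_regs: list[Regressor] = []
    if config.filter_mode == "in_glm":
        filter_regs = filtering.spectral_regressors(n, config.band)
    if config.filter_mode == "pre_both":
        Y = filtering.fft_bandpass(Y, config.band, keep_dc=True)
        nuisance = [
            dataclasses.replace(
                r, values=filtering.fft_bandpass(r.values, config.band, keep_dc=False))
            for r in nuisance
        ]
        warnings_log.append(
            "filter_mode=pre_both pre-colours the data; whitened-fit inference "
            "is no longer exact and the spectral DOF ledger applies")

    design = assemble_design(nuisance, detrend, filter_regs)

    if config.whiten == "ar":
        wf = prewhiten.prewhitened_fit(Y, design, config.ar_order,
                                       config.max_iter, config.tol)
        fit, beta, dropped_pts = wf.fit, wf.beta_original_space, config.ar_order
    elif config.whiten == "arma11":
        wf = prewhiten.arma11_whitened_fit(Y, design)
        fit, beta, dropped_pts = wf.fit, wf.beta_original_space, 0
    else:
        fit = ols_fit(Y, design)
        beta, dropped_pts, wf = fit.beta, 0, None

    x = design.matrix
    beta = np.atleast_2d(beta)            # (k, nvox)
    parts = {}
    for role in ("nuisance", "detrend", "filter"):
        idx = design.indices_of(role)
        parts[role] = x[:, idx] @ beta[idx] if idx.size else 0.0
    cleaned_vox = Y - parts["nuisance"] - parts["detrend"] - parts["filter"]
    if config.filter_mode == "post":
        cleaned_vox = filtering.fft_bandpass(cleaned_vox, config.band, keep_dc=False)

    cleaned_data = image.data.copy()
    cleaned_data[image.mask] = cleaned_vox.T
    cleaned = BoldImage(cleaned_data, tr_s=tr, mask=image.mask)

    r2_thr = critical_r2(n - dropped_pts, max(design.n_of("nuisance"), 1),
                         design.n_columns - design.n_of("nuisance"), config.alpha)
    r2 = np.asarray(fit.r2_noise, dtype=float)
    r2_map = image.unflatten(np.nan_to_num(r2, nan=0.0))
    p_map = image.unflatten(np.nan_to_num(np.asarray(fit.p_value, float), nan=1.0),
                            fill=1.0)

    if wf is not None:
        dwv = np.atleast_1d(wf.durbin_watson)
        _, verdicts = prewhiten.durbin_watson(
            np.atleast_2d(fit.residuals.T).T if fit.residuals.ndim == 1 else fit.residuals,
            config.alpha)
        verdicts = np.atleast_1d(verdicts)
        dw_summary = {
            "median_dw": float(np.median(dwv)),
            "frac_positive_autocorr": float(np.mean(verdicts == "positive-autocorrelation")),
            "frac_negative_autocorr": float(np.mean(verdicts == "negative-autocorrelation")),
            "frac_pass": float(np.mean(verdicts == "pass")),
        }
        n_nonconverged = (0 if wf.converged_voxels is None
                          else int((~wf.converged_voxels).sum()))
        converged = bool(wf.converged)
    else:
        dw_summary = None
        n_nonconverged = 0
        converged = True

    report = {
        "config": config.to_dict(),
        "dof_ledger": {
            "n_timepoints": n,
            "n_dropped_prewhitening": dropped_pts,
            "n_nuisance_columns": design.n_of("nuisance"),
            "n_detrend_columns": design.n_of("detrend"),
            "n_filter_columns": design.n_of("filter"),
            "dof_error": fit.dof_error,
        },
        "whitening": {
            "model": config.whiten,
            "order": config.ar_order if config.whiten == "ar" else None,
            "converged": converged,
            "n_nonconverged_voxels": n_nonconverged,
        },
        "durbin_watson": dw_summary,
        "shift_decisions": shift_decisions,
        "r2_threshold": r2_thr,
        "alpha": config.alpha,
        "frac_voxels_significant": float(np.nanmean(r2 > r2_thr)),
        "warnings": warnings_log,
    }
    return cleaned, r2_map, p_map, report
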