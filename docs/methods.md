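# Methods

## The model

The noise model is an ordinary GLM, `Y = Xβ + e`, where `Y` holds the
BOLD time-series of each in-mask voxel and `X` is partitioned by role:

- **nuisance** columns — the noise model proper: motion parameters read
  from confound files, and physiological traces (end-tidal CO2, beat-to-
  beat heart rate) convolved with a response kernel and resampled to TR.
  All nuisance columns are demeaned on construction, so the baseline is
  carried by the detrend constant alone.
- **detrend** columns — orthogonal polynomials (discrete Gram–Schmidt of
  `1, t, t², …`, equivalent to Legendre polynomials on the sample grid).
  Orthogonal polynomials rather than raw powers purely for conditioning;
  the default order is 2 (baseline + linear + quadratic drift).
- **filter** columns — optional unit-norm sines/cosines at every
  stop-band frequency bin, implementing a bandpass inside the model.

The figure of merit for a noise model is the *partial* R² of the nuisance
columns beyond the detrend/filter columns, `R² = 1 − SSE(full)/SSE(reduced)`,
with its F test on `(k_nuisance, n − k_total)` degrees of freedom. The
matching closed-form thresholds are exposed directly: `critical_r2(160, 8,
3, 0.05) = 0.097`, and for Pearson correlations `critical_r(160, 0.05) =
0.16` via the t transform `t = r√(n−2)/√(1−r²)`.

## Pre-whitening

Because the GLM residual in nuisance regression *is* the intrinsic brain
signal, it is strongly autocorrelated and naive OLS p-values are invalid.
The default fit is the Cochrane–Orcutt iteration:

1. OLS in original space, extract residuals;
2. fit AR(p) coefficients γ to the residuals by lagged least squares
   (conditional MLE; Yule–Walker differs negligibly at n ≥ 100);
3. quasi-difference data and design (`Y′_t = Y_t − Σ γᵢ Y_{t−i}`, same
   for every column of X) dropping the first p points, and refit;
4. repeat until max |Δγ| < 1e-4 (default) or 10 iterations; non-converged
   voxels are returned flagged, never silently.

Coefficients are estimated **per voxel** (vectorised over voxels in
chunks); β is unchanged by quasi-differencing, so the same vector serves
for inference (transformed space) and for subtracting the noise fit from
the raw data (original space). The error DOF ledger is decremented by the
p dropped points. Stationarity of γ̂ is enforced by shrinking toward zero
with a flag when a characteristic root reaches the unit circle.

An ARMA(1,1) option (`arma11_whitened_fit`) selects the AR coefficient a
and MA coefficient λ per voxel by restricted maximum likelihood over a
grid, using the exact ARMA autocorrelation (`ρ₁ = (1+aλ)(a+λ)/(1+2aλ+λ²)`,
`ρ_k = a ρ_{k−1}`), Toeplitz Cholesky whitening, and GLS at the selected
pair. λ = 0 nests AR(1). A grid-recovery simulation (n = 500, 200
replicates) places the selected pair within one grid step of truth in
over 95% of replicates.

Whiteness is verified with the Durbin–Watson statistic
`dw = Σ(e_t − e_{t−1})²/Σe_t²` (2 = white). Verdicts use the normal
approximation `ρ̂₁ ~ N(0, 1/n)` with `ρ̂₁ = 1 − dw/2` rather than
Durbin–Watson bound tables, which is accurate at fMRI series lengths
(n ≥ 100); a value significant one-sided but not two-sided is reported
`inconclusive`, echoing the classical inconclusive band.

## Temporal filtering and degrees of freedom

A scan of duration `t_max` at repetition time TR has positive-frequency
bins at `k / t_max` up to Nyquist `1/(2·TR)` — `floor(t_max / 2 TR)` of
them, which is the series' spectral DOF. `bandpass_dof` counts the bins a
bandpass retains using a lower-inclusive, upper-exclusive convention
(`f_lo ≤ f < f_hi`; the Nyquist bin is kept when `f_hi` reaches Nyquist so
a full-band filter is a no-op). This convention reproduces the canonical
counts 150 → 57 (0.01–0.2 Hz) and 150 → 27 (0.01–0.1 Hz) for 5 min at
TR = 1 s; a closed upper edge would give 58/28. Both the complex bin count
and the real-coefficient count (2 per bin, 1 for Nyquist) are derivable
from the returned values.

Three legitimate placements of a filter are supported (`filter_mode`):
`post` (after fitting), `pre_both` (brick-wall FFT filter applied
identically to data and model — note this pre-colours the data, so
whitened inference afterwards is approximate), and `in_glm` (stop-band
sines/cosines as model columns). The in-GLM route is the recommended one:
its residuals equal the pre-filter route's to 1e-8 on any input, but the
DOF cost appears explicitly as added columns. DC is never a filter
column; the detrend constant owns it.

The false-positive consequence of filtering with an unadjusted threshold
is quantified by `fpr_filtered_experiment`: both members of independent
white-noise pairs are identically filtered and |r| compared with the
unfiltered critical value. A recalibrated threshold using the surviving
spectral DOF (a band keeping `n_b` bins behaves like a Pearson null on
`2 n_b + 1` samples) restores the nominal rate, demonstrating the
inflation is purely a threshold artefact.

## Temporal-shift optimisation

Physiological regressors lag the BOLD responses they drive, so
`shifted_variants` builds one regressor per candidate shift on a uniform
grid (default −4 … +12 s in 0.2 s steps, 81 variants; the asymmetry
reflects the expected positive physiological delay). The source trace is
linearly interpolated to a 0.2 s working resolution, demeaned, and
zero-filled where a shift runs off the recorded window (zero = mean after
demeaning). Sign convention: a positive shift *delays* the regressor —
the value used at time t is the source at t − s.

`optimise_shift` picks the maximal |r| (ties break toward the smallest
|shift|; an option restricts to positive r for physiologically signed
regressors) and judges it against the Šidák-corrected threshold
`α_sidak = 1 − (1 − α)^{1/m}` with m the number of variants, converted to
an r threshold at the series' sample count (zero-filled points are not
excluded from n — a conservative simplification). Šidák assumes
independent tests; shifted variants are positively dependent, so the
correction is conservative, which the FPR simulations confirm
(corrected rate ≤ α).

Selection bias is real and large: `fpr_shift_experiment` slides one
member of each white-noise pair over every integer lag in ±S and records
the maximal |r| (Pearson on the overlapping segments, both the "2S
shifted variants" and "2S+1 tests" counts reported). At ±10 TR on 900
point pairs the FPR at the single-test threshold is ≈ 67% — more than
ten-fold the nominal 5% — and the signed maxima are bimodal.

A shift is only trusted when it replicates: `split_half_validate` reruns
the grid search independently on the two halves of the scan, and the
pipeline applies a shift only when it is Šidák-significant *and* the two
half-estimates agree within a configurable number of grid steps (default
1). `group_shift_reliability` correlates first- versus second-half shifts
across subjects for cohort-level validation.

## Surrogate null models

Two nulls benchmark a noise model's fit against chance. Phase
randomisation keeps every Fourier amplitude and draws uniform phases
(DC untouched so the mean is preserved; for even lengths the Nyquist bin
gets a random sign), yielding regressors with the original's exact
frequency content. Subject rotation gives subject i the nuisance columns
of subject i+1 (wrap-around); detrend/filter columns remain the subject's
own. Neither null is orthogonalised against the true regressors — chance
resemblance is part of the null being modelled, so empirical null rates
can sit slightly above α when the true regressors genuinely drive the
data.

Note a subtlety the tests document: a surrogate's correlation *with its
own original* has fatter tails than the Pearson null (the shared
amplitude spectrum lowers the effective DOF); against an independent
series the nominal 5% rate holds exactly.

## The synthetic-data generator

`synth_physio` emulates an end-tidal CO2 trace in mmHg: resting mode is a
Gaussian random walk brick-wall lowpassed below 0.05 Hz, scaled to a 2
mmHg SD around a 40 mmHg baseline; breath-hold mode adds six 20 s
hold-driven transients (default 8 mmHg) spread evenly across the scan,
smoothed to a physiological rise/fall. It does **not** emulate
breath-by-breath sampling, measurement dropouts, or inter-subject
response-shape variability.

`synth_bold_dataset` builds each voxel as
`100 + Σ wⱼ·regⱼ(t − lagⱼ) + AR(1) intrinsic + white noise`, with weights
N(weight_mean, weight_scale²) for a configurable active fraction, AR
coefficient 0.3 at TR = 2 s by default (a plausible BOLD value; always
logged), intrinsic marginal SD 1.0 and white SD 0.5. The default
weight_mean for recovery demonstrations is positive, mirroring the
near-universally positive CO2 reactivity of grey matter — necessary for
the mask-mean series to carry the lag information the optimiser uses.
Everything regenerates bit-exactly from the seed.

A green recovery test therefore establishes that the estimators are
correct *in this stated world* — linear response, stationary AR(1)
intrinsic signal, spatially independent noise. It does not establish
robustness to motion artefacts, spatially correlated noise, non-neural
drifts beyond quadratic, or mis-specified response kernels.

## Numerical choices

- Response kernels are not printed in the source literature for the
  traces they smooth, so the defaults are the field's canonical forms:
  SPM-style double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6,
  unit-sum) for CO2, and the Chang–Glover cardiac response function
  `0.6 t^2.7 e^{−t/1.6} − (16/√(18π)) e^{−(t−12)²/18}` (unit peak) for
  heart rate. Both are user-overridable `ResponseKernel`s.
- Convolution extends the trace backwards with its initial value
  (steady pre-scan physiology), so constant traces map to constants and
  there is no kernel-onset ramp.
- Quasi-differencing drops the first p points rather than applying an
  exact stationary first-block transform; the DOF ledger reflects it.
- Voxels with zero raw variance are flagged and reported NaN; voxels
  whose variance is fully absorbed by detrend/filter columns get
  noise-model R² = 0 (the nuisance columns add nothing).
- The cleaned series is `data − noise fit − detrend fit (− filter fit)`
  computed with the whitened-fit β on the original-space design, so
  cleaned + fits reconstruct the input exactly. With a GLS β the
  per-voxel variance reduction against the detrended original is not a
  mathematical identity (it is for OLS); at realistic SNR it holds
  everywhere, and the test suite checks it on the seeded dataset.
- Shift ties in |r| break toward the smallest absolute shift
  (parsimony). Correlation significance is two-tailed by default
  (negative maxima are meaningful); `tails` is explicit everywhere.
- Whitening convergence: tol 1e-4 on max |Δγ|, max 10 iterations.

## Known limitations

- No voxelwise lag *mapping* (RIPTiDe-style): the primitives operate on
  the mask-mean series or a supplied series; per-voxel best-shift maps
  can be assembled from `shifted_variants` + vectorised correlation.
- No motion-parameter estimation, RETROICOR phase regressors, or
  CompCor/ANATICOR component extraction — regressors are consumed, not
  computed from images.
- REML is limited to the ARMA(1,1) grid; no spatial regularisation of
  autocorrelation fields, no ARIMA/long-memory models.
- `pre_both` filtering followed by pre-whitening is supported but
  approximate by construction (the filter pre-colours the data); the
  report warns when this combination is used.
- No spatial modelling, smoothing, cluster inference or group statistics
  beyond across-subject shift reliability.
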