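"""Null noise models: phase-randomised regressors and subject rotation.

A noise model should explain no more variance than chance when its
regressors are unrelated to the data.  Two null constructions provide that
benchmark: surrogates that keep each regressor's amplitude spectrum but
scramble its phases, and wholesale borrowing of another subject's
regressors.  Neither is orthogonalised against the true regressors — by
chance a surrogate can resemble the original, which is part of the null
being simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .regressors import DesignMatrix, Regressor, assemble_design

__all__ = ["SurrogateSpec", "phase_randomise", "rotate_subject_models"]


@dataclass
class SurrogateSpec:
    """How to build null regressors; ``seed`` fixes the output exactly."""

    method: str  # "phase_randomise" | "subject_rotate"
    seed: int
    n_surrogates: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("phase_randomise", "subject_rotate"):
            raise ValueError(f"unknown surrogate method {self.method!r}")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")


def phase_randomise(series: np.ndarray, rng_seed) -> np.ndarray:
    """Surrogate with the original's amplitude spectrum and random phases.

    DC is untouched (the surrogate keeps the original mean) and, for even
    lengths, the Nyquist bin keeps a real value with a random sign, so the
    output is exactly real and bin-for-bin amplitude-identical to the input.
    ``rng_seed`` may be an int or a ``numpy.random.Generator``.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("series must be 1-D with at least 4 samples")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = y.size
    spec = np.fft.rfft(y)
    amp = np.abs(spec)
    n_bins = spec.size
    phases = np.zeros(n_bins)
    hi = n_bins - 1 if n % 2 == 0 else n_bins  # even length: last bin is Nyquist
    phases[1:hi] = rng.uniform(0.0, 2.0 * np.pi, hi - 1)
    new = amp * np.exp(1j * phases)
    new[0] = spec[0]  # DC: keep the mean exactly
    if n % 2 == 0:
        new[-1] = amp[-1] * rng.choice([-1.0, 1.0])  # Nyquist phase in {0, pi}
    return np.fft.irfft(new, n=n)


def rotate_subject_models(models: list[DesignMatrix]) -> list[DesignMatrix]:
    """Give each subject the *next* subject's nuisance regressors.

    Subject i receives subject (i+1 mod N)'s nuisance columns; detrend and
    filter columns stay the subject's own (they are deterministic functions
    of that subject's scan geometry, not measurements).  All models must
    share length and column structure.
    """
    if len(models) < 2:
        raise ValueError("subject rotation needs at least 2 subjects")
    n_list = {m.n_timepoints for m in models}
    if len(n_list) != 1:
        raise ValueError("all subjects must share the same number of timepoints")
    structure = {tuple(m.roles) for m in models}
    if len(structure) != 1:
        raise ValueError("all subjects must share the same column structure")
    rotated = []
    for i, own in enumerate(models):
        donor = models[(i + 1) % len(models)]
        regs = [
            donor.regressors[j] if r.role == "nuisance" else r
            for j, r in enumerate(own.regressors)
        ]
        rotated.append(assemble_design(regs))
    return rotated
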