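"""Readers and writers for the text formats regressors arrive in.

Supported inputs: AFNI-style ``.1D`` whitespace-delimited columns (no
header, ``#`` comments), BIDS-confounds-style TSV (header row, one row per
volume), and two-column ``time_s value`` physiological traces at arbitrary
sampling rate.  Designs are written as TSV with a ``#roles:`` annotation
line so a design can round-trip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regressors import DesignMatrix, Regressor, assemble_design

__all__ = [
    "read_1d",
    "read_confounds_tsv",
    "read_physio",
    "regressors_from_table",
    "write_design_tsv",
    "read_design_tsv",
]


def read_1d(path) -> np.ndarray:
    """Read an AFNI ``.1D`` file: whitespace-delimited columns, ``#`` comments."""
    arr = np.loadtxt(str(path), comments="#", ndmin=2)
    return arr


def read_confounds_tsv(path, columns: list[str] | None = None) -> pd.DataFrame:
    """Read a BIDS-confounds-style TSV (header row, one row per volume)."""
    df = pd.read_csv(str(path), sep="\t")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"confounds file lacks columns: {missing}")
        df = df[columns]
    return df


def read_physio(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a two-column ``time_s value`` trace; returns (times, values, dt).

    The time column must be uniformly sampled (to 1e-6 s); dt is inferred.
    """
    arr = np.loadtxt(str(path), comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError("physiological trace needs two columns: time_s value")
    t, v = arr[:, 0], arr[:, 1]
    dts = np.diff(t)
    if dts.size == 0 or np.ptp(dts) > 1e-6:
        raise ValueError("time column must be uniformly sampled")
    return t, v, float(dts.mean())


def regressors_from_table(values: np.ndarray | pd.DataFrame, tr_s: float,
                          names: list[str] | None = None,
                          demean: bool = True) -> list[Regressor]:
    """Turn columns of a confounds table into nuisance regressors at TR."""
    if isinstance(values, pd.DataFrame):
        names = names or list(values.columns)
        values = values.to_numpy(dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < values.shape[1] and values.shape[0] <= 6:
        values = values.T  # tolerate row-oriented input
    if names is None:
        names = [f"confound_{j}" for j in range(values.shape[1])]
    regs = []
    for j, name in enumerate(names):
        col = values[:, j]
        if demean:
            col = col - col.mean()
        regs.append(Regressor(str(name), col, dt=tr_s, role="nuisance"))
    return regs


def write_design_tsv(design: DesignMatrix, path) -> None:
    """Write a design as TSV with a ``#roles:`` annotation line."""
    with open(str(path), "w") as fh:
        fh.write("#roles:\t" + "\t".join(design.roles) + "\n")
        fh.write("#shift_s:\t" + "\t".join(f"{r.shift_s:g}" for r in design.regressors) + "\n")
        fh.write(f"#dt_s:\t{design.dt:g}\n")
        fh.write("\t".join(design.names) + "\n")
        np.savetxt(fh, design.matrix, delimiter="\t", fmt="%.10g")


def read_design_tsv(path) -> DesignMatrix:
    """Round-trip reader for :func:`write_design_tsv` output."""
    roles = shifts = None
    dt = 1.0
    with open(str(path)) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#roles:"):
            roles = line.rstrip("\n").split("\t")[1:]
        elif line.startswith("#shift_s:"):
            shifts = [float(v) for v in line.rstrip("\n").split("\t")[1:]]
        elif line.startswith("#dt_s:"):
            dt = float(line.rstrip("\n").split("\t")[1])
        else:
            body_start = i
            break
    names = lines[body_start].rstrip("\n").split("\t")
    data = np.loadtxt(lines[body_start + 1:], delimiter="\t", ndmin=2)
    if roles is None:
        roles = ["nuisance"] * len(names)
    if shifts is None:
        shifts = [0.0] * len(names)
    regs = [
        Regressor(n, data[:, j], dt=dt, role=roles[j], shift_s=shifts[j])
        for j, n in enumerate(names)
    ]
    return assemble_design(regs)
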