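"""PLUMED-dialect text file I/O: HILLS, COLVAR and FES tables.

All three formats are whitespace-separated tables with ``#!``-prefixed
header lines; the first header names the columns
(``#! FIELDS time cv sigma_cv height biasf`` for HILLS).  Round trips are
exact to the printed precision (17 significant digits, i.e. lossless for
float64).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .sampling import BiasState, FESGrid, GridSpec, Hill

__all__ = ["write_hills", "read_hills", "write_colvar", "read_colvar",
           "write_fes", "read_fes"]


class PlumedParseError(ValueError):
    pass


def _parse_table(path) -> tuple[list[str], np.ndarray]:
    fields: list[str] = []
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                toks = line[2:].split()
                if toks and toks[0] == "FIELDS":
                    fields = toks[1:]
                continue
            if line.startswith("#"):
                continue
            try:
                vals = [float(t) for t in line.split()]
            except ValueError as exc:
                raise PlumedParseError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise PlumedParseError(
                    f"{path}:{lineno}: ragged row ({len(vals)} columns, expected {ncol})")
            rows.append(vals)
    data = np.array(rows) if rows else np.empty((0, len(fields)))
    return fields, data


def write_hills(state: BiasState, path) -> None:
    """Write the hill log: time, centre(s), sigma(s), height, biasfactor."""
    dim = state.dim
    cv_names = [f"cv{i+1}" for i in range(dim)]
    cols = (["time"] + cv_names + [f"sigma_{n}" for n in cv_names]
            + ["height", "biasf"])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for h in state.hills:
            row = [h.time, *h.centre, *h.sigma, h.height, state.gamma]
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_hills(path, grid: GridSpec, gamma: Optional[float] = None) -> BiasState:
    """Rebuild a :class:`BiasState` from a HILLS file.

    If an explicit ``gamma`` disagrees with the file's ``biasf`` column a
    warning is issued and the explicit value wins.
    """
    fields, data = _parse_table(path)
    ncv = max(1, sum(1 for f in fields if f.startswith("cv"))) if fields else 1
    file_gamma = None
    if len(data):
        if fields and "biasf" in fields:
            file_gamma = float(data[0][fields.index("biasf")])
        else:
            file_gamma = float(data[0][-1])
    if gamma is not None and file_gamma is not None and abs(gamma - file_gamma) > 1e-9:
        warnings.warn(
            f"explicit gamma {gamma} overrides HILLS biasfactor {file_gamma}",
            stacklevel=2)
    state = BiasState(grid, gamma if gamma is not None else (file_gamma or 1.0))
    for row in data:
        t = row[0]
        centre = tuple(row[1:1 + ncv])
        sigma = tuple(row[1 + ncv:1 + 2 * ncv])
        height = row[1 + 2 * ncv]
        state.add_hill(Hill(time=t, centre=centre, sigma=sigma, height=height))
    return state


def write_colvar(path, times, values, names: Optional[list[str]] = None) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(times) > 1:
        values = values.T
    names = names or [f"cv{i+1}" for i in range(values.shape[1])]
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(names) + "\n")
        for t, row in zip(times, values):
            fh.write(f"{t:.17g} " + " ".join(f"{v:.17g}" for v in row) + "\n")


def read_colvar(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (times, values, cv names)."""
    fields, data = _parse_table(path)
    if data.size == 0:
        return np.empty(0), np.empty((0, 0)), fields[1:] if fields else []
    return data[:, 0], data[:, 1:], (fields[1:] if fields else
                                     [f"cv{i+1}" for i in range(data.shape[1] - 1)])


def write_fes(path, fes: FESGrid) -> None:
    if fes.F.ndim != 1:
        raise NotImplementedError("FES file I/O is 1-D")
    with open(path, "w") as fh:
        fh.write("#! FIELDS cv free" + (" sem" if fes.sem is not None else "") + "\n")
        fh.write(f"#! SET method {fes.method}\n")
        for i, (x, f) in enumerate(zip(fes.grid, fes.F)):
            row = f"{x:.17g} {f:.17g}"
            if fes.sem is not None:
                row += f" {fes.sem[i]:.17g}"
            fh.write(row + "\n")


def read_fes(path) -> FESGrid:
    method = "bias_inversion"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#! SET method"):
                method = line.split()[-1]
    fields, data = _parse_table(path)
    sem = data[:, 2] if data.shape[1] > 2 else None
    return FESGrid(grid=data[:, 0], F=data[:, 1], method=method, sem=sem)
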