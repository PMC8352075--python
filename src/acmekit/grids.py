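"""Uniform cell-centred grids and densities.

Cells are half-open boxes ``[m*dx, (m+1)*dx)^d`` with centres at
``(m + 1/2)*dx``; densities are stored as cell averages, one array per
discrete state, so that ``mass = sum(values) * dx**d``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Grid", "GridDensity", "project_density", "marginal", "moments",
           "density_to_frame", "save_density_csv", "save_density_hdf5", "load_density_hdf5"]


@dataclass(frozen=True)
class Grid:
    """Tensor-product uniform grid over ``[0, n*dx]`` per axis."""

    dx: float
    shape: tuple[int, ...]
    axis_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if not self.axis_names:
            object.__setattr__(self, "axis_names", tuple(f"x{i}" for i in range(self.d)))

    @classmethod
    def from_species(cls, species) -> "Grid":
        dxs = {round(sp.dx, 15) for sp in species}
        if len(dxs) != 1:
            raise ValueError(f"species must share a cell width, got {sorted(dxs)}")
        return cls(dx=species[0].dx, shape=tuple(sp.n_cells for sp in species),
                   axis_names=tuple(sp.name for sp in species))

    @property
    def d(self) -> int:
        return len(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell_volume(self) -> float:
        return self.dx ** self.d

    @property
    def domain_max(self) -> tuple[float, ...]:
        return tuple(n * self.dx for n in self.shape)

    def centers(self, axis: int = 0) -> np.ndarray:
        return (np.arange(self.shape[axis]) + 0.5) * self.dx

    def coords(self) -> tuple[np.ndarray, ...]:
        """Full per-axis coordinate meshes (ij indexing)."""
        return tuple(np.meshgrid(*[self.centers(a) for a in range(self.d)], indexing="ij"))


@dataclass
class GridDensity:
    """Per-discrete-state cell-average densities on a shared grid."""

    grid: Grid
    labels: tuple[str, ...]
    values: np.ndarray  # shape (n_states, *grid.shape)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.labels),) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @classmethod
    def zeros(cls, grid: Grid, labels: Sequence[str]) -> "GridDensity":
        return cls(grid, tuple(labels), np.zeros((len(labels),) + grid.shape))

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def state(self, label: str) -> np.ndarray:
        return self.values[self.index(label)]

    def mass(self, label: str | None = None) -> float | dict[str, float]:
        v = self.grid.cell_volume
        if label is not None:
            return float(self.state(label).sum() * v)
        return {lbl: float(self.values[i].sum() * v) for i, lbl in enumerate(self.labels)}

    def total_mass(self) -> float:
        return float(self.values.sum() * self.grid.cell_volume)

    def copy(self) -> "GridDensity":
        return GridDensity(self.grid, self.labels, self.values.copy())

    def scaled(self, c: float) -> "GridDensity":
        return GridDensity(self.grid, self.labels, c * self.values)

    def __add__(self, other: "GridDensity") -> "GridDensity":
        if other.labels != self.labels or other.grid.shape != self.grid.shape:
            raise ValueError("densities are not compatible")
        return GridDensity(self.grid, self.labels, self.values + other.values)


def project_density(
    f: Callable | dict[str, Callable],
    grid: Grid,
    labels: Sequence[str] = ("p",),
    normalize: bool = False,
) -> GridDensity:
    """Project density function(s) onto cell averages via the midpoint rule.

    ``f`` is either one function of the coordinate meshes (placed in the first
    state, others zero) or a mapping ``label -> function``.  With
    ``normalize=True`` the result is rescaled to unit total mass.
    """
    coords = grid.coords()
    out = GridDensity.zeros(grid, labels)

    def eval_one(fn, label):
        vals = np.asarray(fn(*coords) if grid.d > 1 else fn(coords[0]), dtype=float)
        vals = np.broadcast_to(vals, grid.shape)
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            centre = tuple(float(coords[a][tuple(bad)]) for a in range(grid.d))
            raise ValueError(f"non-finite density for state {label!r} at cell {tuple(bad)} (centre {centre})")
        return vals

    if isinstance(f, dict):
        for lbl, fn in f.items():
            out.values[out.index(lbl)] = eval_one(fn, lbl)
    else:
        out.values[0] = eval_one(f, labels[0])

    if normalize:
        m = out.total_mass()
        if m <= 0:
            raise ValueError("cannot normalise a density with non-positive mass")
        out.values /= m
    return out


def marginal(p: GridDensity, axis: int = 0, states: Iterable[str] | None = None) -> pd.DataFrame:
    """One-dimensional marginal: sum over discrete states, integrate out the
    other continuum axes.  Total mass is preserved exactly."""
    if states is None:
        sel = p.values
    else:
        idx = [p.index(s) for s in states]
        sel = p.values[idx]
    summed = sel.sum(axis=0)
    other = tuple(a for a in range(p.grid.d) if a != axis)
    dens = summed.sum(axis=other) * p.grid.dx ** len(other) if other else summed
    return pd.DataFrame({p.grid.axis_names[axis]: p.grid.centers(axis), "density": dens})


def moments(p: GridDensity, order: int, axis: int = 0) -> dict[str, float]:
    """Per-state raw moments of the coordinate along ``axis``.

    Order 0 is the state mass; order 1 is ``sum x_m p dx^d``, etc.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    v = p.grid.cell_volume
    if order == 0:
        return {lbl: float(p.values[i].sum() * v) for i, lbl in enumerate(p.labels)}
    x = p.grid.centers(axis).reshape([-1 if a == axis else 1 for a in range(p.grid.d)])
    w = x ** order
    return {lbl: float((p.values[i] * w).sum() * v) for i, lbl in enumerate(p.labels)}


# ---------------------------------------------------------------------------
# export

def density_to_frame(p: GridDensity) -> pd.DataFrame:
    """Tidy table: one row per (state, cell), coordinate columns then value."""
    coords = p.grid.coords()
    rows = []
    for i, lbl in enumerate(p.labels):
        df = pd.DataFrame({name: c.ravel() for name, c in zip(p.grid.axis_names, coords)})
        df.insert(0, "state", lbl)
        df["value"] = p.values[i].ravel()
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def save_density_csv(p: GridDensity, path) -> None:
    density_to_frame(p).to_csv(path, index=False)


def save_density_hdf5(p: GridDensity, path, mode: str = "w") -> None:
    import h5py

    with h5py.File(path, mode) as h5:
        g = h5.require_group("grid")
        g.attrs["dx"] = p.grid.dx
        g.attrs["shape"] = p.grid.shape
        g.attrs["axis_names"] = [n.encode() for n in p.grid.axis_names]
        st = h5.require_group("states")
        for i, lbl in enumerate(p.labels):
            if lbl in st:
                del st[lbl]
            st.create_dataset(lbl, data=p.values[i])


def load_density_hdf5(path) -> GridDensity:
    import h5py

    with h5py.File(path, "r") as h5:
        g = h5["grid"]
        grid = Grid(dx=float(g.attrs["dx"]), shape=tuple(int(n) for n in g.attrs["shape"]),
                    axis_names=tuple(n.decode() if isinstance(n, bytes) else str(n)
                                     for n in g.attrs["axis_names"]))
        labels = tuple(h5["states"].keys())
        values = np.stack([h5["states"][lbl][...] for lbl in labels])
    return GridDensity(grid, labels, values)
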