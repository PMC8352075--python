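"""Truncated discrete chemical master equation (benchmarking reference).

The CME generator is assembled over a finite box of molecule counts in
finite-state-projection style: reactions that would leave the box are simply
dropped, so interior generator columns sum to zero exactly.  The stationary
law is the normalised null vector of the generator.  A lumping helper turns a
count distribution into a cell-average density comparable with the continuum
solver output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .grids import Grid

__all__ = ["TruncatedCME", "build_generator", "cme_steady_state", "lump_to_grid"]


@dataclass
class TruncatedCME:
    """Sparse generator of a truncated continuous-time Markov chain.

    ``bounds[i]`` is the number of retained count values of species ``i``
    (counts ``0 .. bounds[i]-1``); states are enumerated in C order.
    """

    bounds: tuple[int, ...]
    generator: sp.csr_matrix  # Q[dest, src]

    @property
    def n_states(self) -> int:
        return int(np.prod(self.bounds))

    def unravel(self, flat: np.ndarray) -> tuple[np.ndarray, ...]:
        return np.unravel_index(flat, self.bounds)


def build_generator(reactions: Sequence[tuple[Sequence[int], Callable]],
                    bounds: Sequence[int]) -> TruncatedCME:
    """Assemble the truncated CME generator.

    ``reactions`` is a list of ``(displacement, propensity)`` pairs, the
    propensity a function of the count meshgrids (one array argument per
    species).  Column convention: ``Q[dest, src]`` holds the propensity of
    ``src -> dest``; diagonals are negative column sums.
    """
    bounds = tuple(int(b) for b in bounds)
    if any(b <= 0 for b in bounds):
        raise ValueError("bounds must be positive")
    counts = np.indices(bounds)
    flat_src = np.arange(int(np.prod(bounds)))
    src_multi = np.unravel_index(flat_src, bounds)
    rows, cols, vals = [], [], []
    diag = np.zeros(flat_src.size)
    for disp, prop in reactions:
        disp = tuple(int(c) for c in disp)
        if len(disp) != len(bounds):
            raise ValueError(f"displacement {disp} incompatible with bounds {bounds}")
        rates = np.asarray(prop(*counts), dtype=float).reshape(-1)
        dest_multi = [src_multi[a] + disp[a] for a in range(len(bounds))]
        ok = np.ones(flat_src.size, dtype=bool)
        for a in range(len(bounds)):
            ok &= (dest_multi[a] >= 0) & (dest_multi[a] < bounds[a])
        ok &= rates > 0
        dest = np.ravel_multi_index([m[ok] for m in dest_multi], bounds)
        rows.append(dest)
        cols.append(flat_src[ok])
        vals.append(rates[ok])
        np.add.at(diag, flat_src[ok], -rates[ok])
    rows.append(flat_src)
    cols.append(flat_src)
    vals.append(diag)
    Q = sp.csr_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                      shape=(flat_src.size, flat_src.size))
    return TruncatedCME(bounds=bounds, generator=Q)


def cme_steady_state(cme: TruncatedCME) -> np.ndarray:
    """Stationary distribution: normalised null vector of the generator.

    Requires a unique closed communicating class; otherwise raises listing the
    closed classes found.  Entries are non-negative to solver precision.
    """
    Q = cme.generator
    n = Q.shape[0]
    if n == 1:
        return np.array([1.0])
    adj = sp.csr_matrix((np.ones_like(Q.tocoo().data),
                         (Q.tocoo().row, Q.tocoo().col)), shape=Q.shape)
    adj.setdiag(0)
    adj.eliminate_zeros()
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = _closed_classes(adj, n_comp, labels)
    if len(closed) > 1:
        raise ValueError(f"reducible chain: {len(closed)} closed classes "
                         f"(component ids {sorted(closed)[:10]})")
    M = Q.tolil()
    M[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    pi = spla.spsolve(M.tocsc(), b)
    if np.any(pi < -1e-9):
        raise ArithmeticError("steady-state solve produced significantly negative entries")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _closed_classes(adj: sp.csr_matrix, n_comp: int, labels: np.ndarray) -> set[int]:
    coo = adj.tocoo()
    open_comp = set()
    for src, dest in zip(coo.col, coo.row):
        if labels[src] != labels[dest]:
            open_comp.add(labels[src])
    return set(range(n_comp)) - open_comp


def lump_to_grid(dist: np.ndarray, grid: Grid, omega: float, axis: int = 0) -> pd.DataFrame:
    """Lump a 1-D count distribution onto continuum cells.

    The lump size ``dx * omega`` must be a whole number of molecules; each
    block of that many consecutive counts is summed and divided by ``dx``,
    yielding a cell-average density on the grid (mass is preserved exactly).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 1:
        raise ValueError("lump_to_grid expects a one-dimensional count distribution")
    lump_f = grid.dx * omega
    lump = int(round(lump_f))
    if lump < 1 or abs(lump_f - lump) > 1e-9:
        raise ValueError(f"dx*omega = {lump_f} is not a positive integer lump size")
    n_cells = grid.shape[axis]
    padded = np.zeros(n_cells * lump)
    padded[: min(dist.size, padded.size)] = dist[: padded.size]
    if dist.size > padded.size and dist[padded.size:].sum() > 1e-12:
        raise ValueError("count distribution extends beyond the grid domain")
    dens = padded.reshape(n_cells, lump).sum(axis=1) / grid.dx
    return pd.DataFrame({grid.axis_names[axis]: grid.centers(axis), "density": dens})
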