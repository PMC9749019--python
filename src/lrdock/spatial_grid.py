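"""Regular-grid (cell list) spatial partition for cutoff neighbor queries.

The ligand is gridded once in its local frame; receptor atoms are mapped into
that frame for queries, so rigid ligand moves never trigger a rebuild. The
cutoff comparison is a strict ``<`` so the grid path and any brute-force
distance filter agree on the exact pair set.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


class RegularGrid:
    """Cell list over a fixed snapshot of atom positions.

    Every indexed atom lies in exactly one cell; the union of the cell lists
    is the full index set. ``last_query_cells`` records how many cells the
    most recent query touched (used by the cost-bound property test).
    """

    def __init__(self, positions: np.ndarray, cell_size: float):
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        if positions.shape[0] < 1:
            raise ValidationError("grid needs at least one atom")
        if not np.all(np.isfinite(positions)):
            raise ValidationError("non-finite coordinates")
        if cell_size <= 0:
            raise ValidationError("cell_size must be positive")
        self.positions = positions.copy()
        self.cell_size = float(cell_size)
        lo = positions.min(axis=0)
        hi = positions.max(axis=0)
        # pad the box by one cell on every side
        self.origin = lo - cell_size
        self.dims = np.maximum(
            np.ceil((hi - self.origin) / cell_size).astype(int) + 1, 1)
        idx = np.floor((positions - self.origin) / cell_size).astype(int)
        self._cells: dict[tuple[int, int, int], np.ndarray] = {}
        keys = [tuple(k) for k in idx]
        buckets: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            buckets.setdefault(k, []).append(i)
        for k, v in buckets.items():
            self._cells[k] = np.array(v, dtype=int)
        self.last_query_cells = 0

    def __len__(self):
        return self.positions.shape[0]

    def cell_index(self, point) -> tuple[int, int, int]:
        return tuple(np.floor((np.asarray(point, dtype=float) - self.origin)
                              / self.cell_size).astype(int))

    def query_within(self, point, cutoff: float) -> np.ndarray:
        """Indices of atoms with Euclidean distance strictly below ``cutoff``
        from ``point``, ascending."""
        if cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        point = np.asarray(point, dtype=float).reshape(3)
        reach = int(np.ceil(cutoff / self.cell_size))
        center = np.floor((point - self.origin) / self.cell_size).astype(int)
        # clipping is safe: any cell outside the clipped window is at least
        # reach*cell_size >= cutoff away from the point, excluded by strict <
        lo = np.clip(center - reach, 0, self.dims - 1)
        hi = np.clip(center + reach, 0, self.dims - 1)
        candidates = []
        ncells = 0
        for ix in range(lo[0], hi[0] + 1):
            for iy in range(lo[1], hi[1] + 1):
                for iz in range(lo[2], hi[2] + 1):
                    ncells += 1
                    cell = self._cells.get((ix, iy, iz))
                    if cell is not None:
                        candidates.append(cell)
        self.last_query_cells = ncells
        if not candidates:
            return np.empty(0, dtype=int)
        cand = np.concatenate(candidates)
        d2 = np.einsum("ij,ij->i", self.positions[cand] - point,
                       self.positions[cand] - point)
        hits = cand[d2 < cutoff * cutoff]
        return np.sort(hits)


def build_grid(positions: np.ndarray, cell_size: float = 8.0) -> RegularGrid:
    """Build a cell list; default cell size equals the 8 A nonbonded cutoff."""
    return RegularGrid(positions, cell_size)


def query_within(grid: RegularGrid, point, cutoff: float) -> np.ndarray:
    return grid.query_within(point, cutoff)
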