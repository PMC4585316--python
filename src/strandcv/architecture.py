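"""Random two-dimensional cellular architectures of patterned strands.

A strand (default 3000 x 150 um) is tessellated into elongated,
quasi-rectangular cells on a regular node grid (default spacing 5 um) using
a jittered brick-wall layout: horizontal rows of cells whose heights and
lengths fluctuate around the nominal cell dimensions, with row-to-row
staggering of the longitudinal cell boundaries.  Cell types (PCM, LE_SCM,
HE_SCM) are then assigned per cell in predefined proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lr1 import CELL_TYPE_INDEX

__all__ = [
    "StrandGeometry",
    "StrandArchitecture",
    "generate_architecture",
    "assign_cell_types",
]


@dataclass(frozen=True)
class StrandGeometry:
    """Strand dimensions and spatial discretization, in micrometers."""

    length: float = 3000.0
    width: float = 150.0
    node_spacing: float = 5.0

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0 or self.node_spacing <= 0:
            raise ValueError("geometry dimensions must be positive")
        for dim, name in ((self.length, "length"), (self.width, "width")):
            n = dim / self.node_spacing
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"node_spacing must divide {name} into a whole node count"
                )

    @property
    def nx(self) -> int:
        return int(round(self.length / self.node_spacing))

    @property
    def ny(self) -> int:
        return int(round(self.width / self.node_spacing))


@dataclass
class StrandArchitecture:
    """A tessellated strand: per-node cell labels and per-cell types.

    ``cell_id_grid`` has shape (ny, nx), row-major with x increasing in the
    propagation direction.  ``cell_type`` maps cell_id -> type name; before
    :func:`assign_cell_types` every cell is PCM.
    """

    geometry: StrandGeometry
    cell_id_grid: np.ndarray
    cell_type: dict[int, str]
    seed: int
    type_seed: int | None = None
    requested_p_scm: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.cell_type)

    def type_index_grid(self) -> np.ndarray:
        """(ny, nx) uint8 grid of cell-type indices (PCM 0, LE 1, HE 2)."""
        lut = np.zeros(self.cell_id_grid.max() + 1, dtype=np.uint8)
        for cid, tname in self.cell_type.items():
            lut[cid] = CELL_TYPE_INDEX[tname]
        return lut[self.cell_id_grid]

    def type_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in CELL_TYPE_INDEX}
        for tname in self.cell_type.values():
            counts[tname] += 1
        return counts

    def realized_p_scm(self) -> float:
        c = self.type_counts()
        return (c["LE_SCM"] + c["HE_SCM"]) / max(1, self.n_cells)

    def to_files(self, raster_path: str | Path, table_path: str | Path) -> None:
        """Persist as an integer raster (CSV) plus a cell_id -> type table."""
        np.savetxt(raster_path, self.cell_id_grid, fmt="%d", delimiter=",")
        pd.DataFrame(
            {"cell_id": list(self.cell_type), "type": list(self.cell_type.values())}
        ).to_csv(table_path, index=False)


def generate_architecture(
    geometry: StrandGeometry | None = None,
    cell_length_mean: float = 100.0,
    cell_width_mean: float = 15.0,
    jitter: float = 0.3,
    seed: int = 0,
) -> StrandArchitecture:
    """Generate a jittered brick-wall tessellation of the strand.

    Cell lengths and row heights are drawn from normal distributions with
    coefficient of variation ``jitter`` around the nominal dimensions and
    rounded to the node grid; each row starts with a random partial cell so
    that longitudinal boundaries are staggered between rows.  ``jitter=0``
    yields a perfectly regular lattice of identical rectangles.  The result
    is bit-reproducible from (parameters, seed).
    """
    geometry = geometry or StrandGeometry()
    if not 0.0 <= jitter < 1.0:
        raise ValueError("jitter must lie in [0, 1)")
    h = geometry.node_spacing
    if cell_length_mean <= h or cell_width_mean <= h:
        raise ValueError("cell dimensions must exceed the node spacing")
    nx, ny = geometry.nx, geometry.ny
    len_nodes = cell_length_mean / h
    wid_nodes = cell_width_mean / h

    rng = np.random.default_rng(seed)
    grid = np.empty((ny, nx), dtype=np.int32)

    # horizontal row bands
    heights: list[int] = []
    remaining = ny
    while remaining > 0:
        dh = wid_nodes * (1.0 + jitter * rng.standard_normal())
        hh = int(np.clip(round(dh), 1, remaining))
        # avoid a trailing sliver thinner than half a nominal cell
        if 0 < remaining - hh < max(1, round(wid_nodes / 2)):
            hh = remaining
        heights.append(hh)
        remaining -= hh

    next_id = 0
    y0 = 0
    for hh in heights:
        x0 = 0
        first = True
        while x0 < nx:
            if first:
                # random partial first cell staggers boundaries across rows
                # (regular lattice in the jitter-free limit)
                frac = rng.uniform(0.1, 1.0) if jitter > 0 else 1.0
                ln = max(1, int(round(len_nodes * frac)))
                first = False
            else:
                dl = len_nodes * (1.0 + jitter * rng.standard_normal())
                ln = max(2, int(round(dl)))
            ln = min(ln, nx - x0)
            if 0 < nx - (x0 + ln) < 2:  # merge a 1-node sliver at the far end
                ln = nx - x0
            grid[y0 : y0 + hh, x0 : x0 + ln] = next_id
            next_id += 1
            x0 += ln
        y0 += hh

    cell_type = {cid: "PCM" for cid in range(next_id)}
    return StrandArchitecture(geometry, grid, cell_type, seed)


def assign_cell_types(
    arch: StrandArchitecture,
    p_scm: float,
    le_fraction_within_scm: float = 2.0 / 3.0,
    seed: int = 0,
) -> StrandArchitecture:
    """Label each cell SCM with probability ``p_scm``, then LE vs HE.

    Assignment is independent per cell (the biological unit mixed at
    seeding): SCM with probability ``p_scm``, and within SCMs low
    excitability with probability ``le_fraction_within_scm`` (default 2:1
    LE:HE).  Returns a new architecture sharing the cell_id grid.
    """
    if not 0.0 <= p_scm <= 1.0:
        raise ValueError("p_scm must lie in [0, 1]")
    if not 0.0 <= le_fraction_within_scm <= 1.0:
        raise ValueError("le_fraction_within_scm must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cell_type: dict[int, str] = {}
    for cid in arch.cell_type:
        if rng.random() < p_scm:
            cell_type[cid] = (
                "LE_SCM" if rng.random() < le_fraction_within_scm else "HE_SCM"
            )
        else:
            cell_type[cid] = "PCM"
    return StrandArchitecture(
        arch.geometry,
        arch.cell_id_grid,
        cell_type,
        arch.seed,
        type_seed=seed,
        requested_p_scm=p_scm,
    )
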