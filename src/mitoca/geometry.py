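"""3-D lattices of Ca2+ release units (CRUs) and mitochondria.

A ventricular myocyte is discretized as a regular grid of CRUs; mitochondria
form a coarser grid, each mitochondrion serving the contiguous block of CRUs
it tiles.  At full scale the cell holds 21504 (64x28x12) CRUs and 5376
(64x14x6) mitochondria, i.e. a 1x2x2 block of CRUs per mitochondrion.

Linear indices are x-fastest: ``i = x + nx*(y + ny*z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpatialGrid", "build_lattice", "neighbor_list", "GeometryError"]


class GeometryError(ValueError):
    """Raised for inconsistent lattice dimension configurations."""


def _index(x: int, y: int, z: int, dims: tuple[int, int, int]) -> int:
    nx, ny, _ = dims
    return x + nx * (y + ny * z)


@dataclass
class SpatialGrid:
    """CRU and mitochondrion lattices plus their coupling map.

    Attributes
    ----------
    cru_dims, mito_dims
        ``(nx, ny, nz)`` grid shapes.
    mito_to_cru
        For each mitochondrion, the array of CRU indices in its block.
        The blocks partition the CRU set.
    cru_to_mito
        Inverse map, one mitochondrion index per CRU.
    neighbors
        ``(cru_count, 6)`` array of face-adjacent CRU indices, padded
        with -1 at no-flux boundaries.
    """

    cru_dims: tuple[int, int, int]
    mito_dims: tuple[int, int, int]
    mito_to_cru: np.ndarray = field(repr=False)
    cru_to_mito: np.ndarray = field(repr=False)
    neighbors: np.ndarray = field(repr=False)

    @property
    def cru_count(self) -> int:
        nx, ny, nz = self.cru_dims
        return nx * ny * nz

    @property
    def mito_count(self) -> int:
        nx, ny, nz = self.mito_dims
        return nx * ny * nz

    @property
    def block_shape(self) -> tuple[int, int, int]:
        """CRUs per mitochondrion along each axis (1x2x2 at full scale)."""
        return tuple(c // m for c, m in zip(self.cru_dims, self.mito_dims))

    def report(self) -> str:
        """Small text summary for debugging/config echo."""
        bx, by, bz = self.block_shape
        return (
            f"CRU grid {self.cru_dims} ({self.cru_count} CRUs); "
            f"mito grid {self.mito_dims} ({self.mito_count} mitochondria); "
            f"coupling block {bx}x{by}x{bz}"
        )


def build_lattice(
    cru_dims: tuple[int, int, int], mito_dims: tuple[int, int, int]
) -> SpatialGrid:
    """Build CRU and mitochondrion grids and their block coupling map.

    Each mitochondrion is coupled to the contiguous block of CRUs it tiles;
    block shape is derived from the dimension ratios, which must be integral
    along every axis.

    Raises
    ------
    GeometryError
        If any dimension is < 1 or a CRU dimension is not an integer
        multiple of the matching mitochondrion dimension (the offending
        axis is named).
    """
    cru_dims = tuple(int(d) for d in cru_dims)
    mito_dims = tuple(int(d) for d in mito_dims)
    for name, dims in (("CRU", cru_dims), ("mitochondrion", mito_dims)):
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise GeometryError(f"{name} dimensions must be three integers >= 1, got {dims}")
    for axis, (c, m) in enumerate(zip(cru_dims, mito_dims)):
        if c % m != 0:
            raise GeometryError(
                f"CRU dimension {c} not divisible by mitochondrion dimension {m} "
                f"on axis {'xyz'[axis]}"
            )

    nx, ny, nz = cru_dims
    ncru = nx * ny * nz
    block = tuple(c // m for c, m in zip(cru_dims, mito_dims))
    bx, by, bz = block

    cru_to_mito = np.empty(ncru, dtype=np.int64)
    x = np.arange(nx)
    y = np.arange(ny)
    z = np.arange(nz)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    mito_idx = (xx // bx) + mito_dims[0] * ((yy // by) + mito_dims[1] * (zz // bz))
    cru_idx = xx + nx * (yy + ny * zz)
    cru_to_mito[cru_idx.ravel()] = mito_idx.ravel()

    nmito = mito_dims[0] * mito_dims[1] * mito_dims[2]
    order = np.argsort(cru_to_mito, kind="stable")
    mito_to_cru = order.reshape(nmito, bx * by * bz)

    # face adjacency with -1 padding at no-flux boundaries
    neighbors = np.full((ncru, 6), -1, dtype=np.int64)
    flat = cru_idx.ravel()
    for k, (dx, dy, dz) in enumerate(
        [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    ):
        xs, ys, zs = xx + dx, yy + dy, zz + dz
        ok = (
            (xs >= 0) & (xs < nx) & (ys >= 0) & (ys < ny) & (zs >= 0) & (zs < nz)
        ).ravel()
        nb = (np.clip(xs, 0, nx - 1) + nx * (np.clip(ys, 0, ny - 1) + ny * np.clip(zs, 0, nz - 1))).ravel()
        neighbors[flat[ok], k] = nb[ok]

    return SpatialGrid(
        cru_dims=cru_dims,
        mito_dims=mito_dims,
        mito_to_cru=mito_to_cru,
        cru_to_mito=cru_to_mito,
        neighbors=neighbors,
    )


def neighbor_list(grid: SpatialGrid, cru_index: int) -> list[int]:
    """Face-adjacent CRU indices of ``cru_index`` (no self, no duplicates).

    Boundary CRUs have fewer than six neighbors (no-flux boundary).
    """
    if not 0 <= cru_index < grid.cru_count:
        raise IndexError(f"CRU index {cru_index} out of range [0, {grid.cru_count})")
    row = grid.neighbors[cru_index]
    return [int(j) for j in row if j >= 0]
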