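"""Uniform cell-centered 2D grid with no-flux (Neumann) difference operators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid2D:
    """Uniform cell-centered grid: ``nx`` x ``ny`` cells of spacing ``dx`` (µm).

    Fields live at cell centers ``(i + 1/2)*dx``; arrays are indexed
    ``[iy, ix]``.  All difference operators below assume homogeneous
    Neumann (no-flux) outer boundaries.
    """

    nx: int
    ny: int
    dx: float

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8 cells")
        if self.dx <= 0:
            raise ValueError("dx must be > 0")

    @classmethod
    def square(cls, n: int, length: float) -> "Grid2D":
        return cls(nx=n, ny=n, dx=length / n)

    @property
    def lx(self) -> float:
        return self.nx * self.dx

    @property
    def ly(self) -> float:
        return self.ny * self.dx

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.dx * self.dx

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinate arrays (X, Y), each of shape (ny, nx)."""
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dx
        return np.meshgrid(x, y)

    # -- difference operators ------------------------------------------------

    def laplacian(self, field: np.ndarray) -> np.ndarray:
        """5-point Laplacian with no-flux boundaries (ghost = mirror)."""
        f = np.pad(field, 1, mode="edge")
        return (
            f[:-2, 1:-1] + f[2:, 1:-1] + f[1:-1, :-2] + f[1:-1, 2:] - 4.0 * field
        ) / self.dx**2

    def gradient(self, field: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Central-difference gradient (gx, gy), one-sided at boundaries."""
        gy, gx = np.gradient(field, self.dx)
        return gx, gy

    def grad_sq(self, field: np.ndarray) -> np.ndarray:
        gx, gy = self.gradient(field)
        return gx * gx + gy * gy

    def face_diff_x(self, field: np.ndarray) -> np.ndarray:
        """Differences across interior x-faces, shape (ny, nx-1)."""
        return (field[:, 1:] - field[:, :-1]) / self.dx

    def face_diff_y(self, field: np.ndarray) -> np.ndarray:
        """Differences across interior y-faces, shape (ny-1, nx)."""
        return (field[1:, :] - field[:-1, :]) / self.dx

    def boundary_mask(self, side: str | None = None) -> np.ndarray:
        """Boolean mask of the one-cell boundary layer (or one named side)."""
        m = np.zeros(self.shape, dtype=bool)
        if side is None:
            m[0, :] = m[-1, :] = True
            m[:, 0] = m[:, -1] = True
        elif side == "left":
            m[:, 0] = True
        elif side == "right":
            m[:, -1] = True
        elif side == "bottom":
            m[0, :] = True
        elif side == "top":
            m[-1, :] = True
        else:
            raise ValueError(
                f"unknown side {side!r}; expected left/right/bottom/top"
            )
        return m

    def disk_mask(self, center: tuple[float, float], radius: float) -> np.ndarray:
        """Cells whose centers lie inside a disk (µm coordinates)."""
        cx, cy = center
        if not (radius <= cx <= self.lx - radius and radius <= cy <= self.ly - radius):
            raise ValueError("disk must lie inside the domain")
        x, y = self.coords()
        return (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
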