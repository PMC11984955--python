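"""Scalar summaries of spatial fields: area fractions, means, nest counts.

The tumor nest is defined operationally as the set of cells whose
cancer-cell mass fraction exceeds 0.1; the same threshold defines the
fibrotic (CAF-rich) and T-cell-rich zones.  Area fractions are the
thresholded cell count times the cell area over the domain area, with
the indicator evaluated strictly (> threshold) at cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from tmemix.grid import Grid2D
from tmemix.spatial import FieldState

__all__ = ["area_fraction", "field_summary", "label_nests", "ObservableSeries"]

DEFAULT_THRESHOLD = 0.1


@dataclass
class ObservableSeries:
    """Named time series of the standard run observables (all in [0, 1])."""

    times: np.ndarray
    nest_area_frac: np.ndarray
    fibrotic_area_frac: np.ndarray
    tcell_area_frac: np.ndarray
    mean_c: np.ndarray
    mean_t: np.ndarray
    mean_na: np.ndarray
    mean_a: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.times).size
        for name in (
            "nest_area_frac",
            "fibrotic_area_frac",
            "tcell_area_frac",
            "mean_c",
            "mean_t",
            "mean_na",
            "mean_a",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"series {name} length mismatch")
            if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
                raise ValueError(f"series {name} must lie in [0, 1]")
            setattr(self, name, arr)


def area_fraction(
    field: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    grid: Grid2D | None = None,
) -> float:
    """Fraction of the domain where ``field > threshold``.

    On a uniform grid this is simply the thresholded cell count over the
    total cell count (cell areas cancel).
    """
    field = np.asarray(field)
    if field.size == 0:
        raise ValueError("empty field")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if grid is not None and field.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    return float((field > threshold).sum() / field.size)


def field_summary(state: FieldState) -> dict[str, float]:
    """Arithmetic mean mass fraction per species over all grid cells."""
    return state.species_means()


def label_nests(
    phi_c: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> int:
    """Number of 4-connected components of the thresholded cancer field."""
    mask = np.asarray(phi_c) > threshold
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n = ndimage.label(mask, structure=structure)
    return int(n)
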