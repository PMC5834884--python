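"""Shared geometric primitives.

All coordinates are physical nanometres with the origin at the stack
corner, x/y in the imaging plane and z along the milling axis.  Intervals
are half-open ``[min, max)`` and voxel indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NM_PER_UM = 1.0e3
NM3_PER_UM3 = 1.0e9


@dataclass(frozen=True)
class Window3D:
    """Axis-aligned observation window (a FIB/SEM stack volume).

    Parameters
    ----------
    origin : (3,) array-like
        Corner of the window, nm.
    extents : (3,) array-like
        Side lengths (Lx, Ly, Lz), nm; all strictly positive.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    extents: tuple[float, float, float] = (10240.0, 7680.0, 2980.0)

    def __post_init__(self) -> None:
        ext = np.asarray(self.extents, dtype=float)
        if ext.shape != (3,) or not np.all(ext > 0):
            raise ValueError(f"window extents must be 3 positive lengths, got {self.extents}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "extents", tuple(float(v) for v in ext))

    @classmethod
    def from_stack(cls, nx: int = 2048, ny: int = 1536, n_sections: int = 149,
                   pixel_nm: float = 5.0, section_nm: float = 20.0) -> "Window3D":
        """Window of an image stack (defaults: 2048x1536 px at 5 nm/px, 20 nm sections)."""
        return cls((0.0, 0.0, 0.0), (nx * pixel_nm, ny * pixel_nm, n_sections * section_nm))

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return self.lo + np.asarray(self.extents, dtype=float)

    @property
    def volume_nm3(self) -> float:
        return float(np.prod(self.extents))

    @property
    def volume_um3(self) -> float:
        return self.volume_nm3 / NM3_PER_UM3

    @property
    def min_side(self) -> float:
        return float(min(self.extents))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the half-open window."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= self.lo) & (pts < self.hi), axis=1)

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest window face, nm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.minimum(pts - self.lo, self.hi - pts).min(axis=1)


@dataclass
class PointPattern:
    """A finite 3D point pattern observed in a window.

    ``points`` is an (n, 3) float array in nm; every point must lie inside
    the window.
    """

    points: np.ndarray
    window: Window3D
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if pts.size and not np.all(self.window.contains(pts)):
            raise ValueError("all points must lie inside the window")
        self.points = pts
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(pts):
                raise ValueError("labels length must match number of points")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def intensity_per_um3(self) -> float:
        """Empirical intensity, points per μm³."""
        return self.n / self.window.volume_um3


def pairwise_min_distance(points: np.ndarray) -> float:
    """Smallest pairwise Euclidean distance (exhaustive; n ≥ 2)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    from scipy.spatial.distance import pdist

    return float(pdist(pts).min())
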