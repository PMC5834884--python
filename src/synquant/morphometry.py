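"""Morphometry of synaptic apposition surfaces (SAS).

The SAS is the open triangulated surface apposed between the pre- and
post-synaptic densities.  Its size and shape are summarised by three
numbers: surface area (nm²), boundary perimeter (nm) and a dimensionless
curvature defined as one minus the ratio of the projected area of the
surface to its true area.  The curvature is 0 for a perfectly flat SAS
and approaches 1 as the surface closes on itself; a hemisphere scores 0.5.

The projection plane is the least-squares best-fit plane of the mesh
vertices, and the projected area is the area of the *union* of the
projected triangles, so folded surfaces are not double-counted (which
could otherwise push the curvature below zero).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SASMesh",
    "SASFeatures",
    "LogNormalFit",
    "mesh_area",
    "mesh_perimeter",
    "projected_area",
    "sas_curvature",
    "sas_features",
    "fit_lognormal",
    "feature_distributions",
]

_DEGENERATE_REL_TOL = 1e-12


@dataclass
class SASMesh:
    """Open triangulated surface: ``vertices`` (n, 3) nm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh) -> "SASMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))

    def translated(self, offset) -> "SASMesh":
        return SASMesh(self.vertices + np.asarray(offset, dtype=float), self.faces)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


@dataclass
class SASFeatures:
    """Per-synapse SAS morphometry record."""

    area_nm2: float
    perimeter_nm: float
    projected_area_nm2: float
    curvature: float


@dataclass
class LogNormalFit:
    """ML log-normal fit: ``mu``/``sigma`` of log-values, with KS GOF of
    the log-values against the fitted normal."""

    mu: float
    sigma: float
    ks_statistic: float
    ks_pvalue: float
    n: int
    degenerate: bool = False

    @property
    def mean(self) -> float:
        """Arithmetic mean implied by the fit, exp(mu + sigma²/2)."""
        return float(np.exp(self.mu + self.sigma**2 / 2.0))


def _triangle_areas(mesh: SASMesh) -> np.ndarray:
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def mesh_area(mesh: SASMesh) -> float:
    """Total surface area, nm² (sum of triangle areas).

    Raises on degenerate (zero-area) triangles, listing the offenders.
    """
    areas = _triangle_areas(mesh)
    if len(areas) == 0:
        raise ValueError("mesh has no faces")
    tol = _DEGENERATE_REL_TOL * max(areas.max(), 1.0)
    bad = np.flatnonzero(areas <= tol)
    if bad.size:
        raise ValueError(f"degenerate triangles at face indices {bad.tolist()[:20]}")
    return float(areas.sum())


def _boundary_edges(mesh: SASMesh) -> np.ndarray:
    """Edges used by exactly one face (the open boundary)."""
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return key[idx[counts == 1]]


def _count_boundary_loops(boundary: np.ndarray) -> int:
    adj: dict[int, list[int]] = defaultdict(list)
    for a, b in boundary:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    seen: set[int] = set()
    loops = 0
    for start in adj:
        if start in seen:
            continue
        loops += 1
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(u for u in adj[v] if u not in seen)
    return loops


def mesh_perimeter(mesh: SASMesh) -> float:
    """Length of the single open boundary loop, nm.

    Raises if the mesh is closed or has more than one boundary loop.
    """
    boundary = _boundary_edges(mesh)
    if len(boundary) == 0:
        raise ValueError("mesh is closed: no boundary loop to measure")
    loops = _count_boundary_loops(boundary)
    if loops != 1:
        raise ValueError(f"expected exactly one boundary loop, found {loops}")
    v = mesh.vertices
    return float(np.linalg.norm(v[boundary[:, 0]] - v[boundary[:, 1]], axis=1).sum())


def best_fit_plane(mesh: SASMesh) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of the vertices: (centroid, unit normal)."""
    c = mesh.vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(mesh.vertices - c, full_matrices=False)
    return c, vt[2]


def projected_area(mesh: SASMesh, plane_normal: np.ndarray | None = None) -> float:
    """Area of the planar projection onto the best-fit plane, nm².

    Computed as the union of the projected triangles so that folds are
    counted once; always ≤ the true surface area.
    """
    from shapely import union_all
    from shapely.geometry import Polygon

    c, normal = best_fit_plane(mesh)
    if plane_normal is not None:
        normal = np.asarray(plane_normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    uv = (mesh.vertices - c) @ np.stack([e1, e2], axis=1)

    polys = []
    for tri in mesh.faces:
        p = Polygon(uv[tri])
        if p.area > 0:
            polys.append(p if p.is_valid else p.buffer(0))
    if not polys:
        raise ValueError("no non-degenerate projected triangles")
    return float(union_all(polys).area)


def sas_curvature(mesh: SASMesh) -> float:
    """Curvature statistic 1 − projected_area/area, in [0, 1)."""
    area = mesh_area(mesh)
    if area <= 0:
        raise ValueError("mesh area must be positive")
    c = 1.0 - projected_area(mesh) / area
    return float(max(c, 0.0))


def sas_features(mesh: SASMesh) -> SASFeatures:
    """Area, perimeter, projected area and curvature for one SAS."""
    area = mesh_area(mesh)
    proj = projected_area(mesh)
    return SASFeatures(
        area_nm2=area,
        perimeter_nm=mesh_perimeter(mesh),
        projected_area_nm2=proj,
        curvature=float(max(1.0 - proj / area, 0.0)),
    )


def fit_lognormal(values: np.ndarray) -> LogNormalFit:
    """Maximum-likelihood log-normal fit with a KS goodness-of-fit check.

    ``mu``/``sigma`` are the ML mean and SD of log-values; the KS statistic
    compares the log-values with the fitted normal.  A constant sample
    gives ``sigma = 0`` and is flagged degenerate.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    if np.any(x <= 0):
        raise ValueError("all values must be positive for a log-normal fit")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma == 0.0:
        return LogNormalFit(mu, 0.0, np.nan, np.nan, len(x), degenerate=True)
    ks = sps.kstest(logs, "norm", args=(mu, sigma))
    return LogNormalFit(mu, sigma, float(ks.statistic), float(ks.pvalue), len(x))


def feature_distributions(features: pd.DataFrame, bins: str | int = "fd") -> dict:
    """Group × synapse-type summaries and frequency tables of SAS features.

    ``features`` needs columns ``group``, ``type`` (AS/SS) and one or more
    numeric feature columns (e.g. ``area_nm2``).  Returns a dict with a
    ``summary`` table (mean, SEM — SEM is NaN and flagged for singleton
    cells; empty cells are simply absent) and per-feature ``frequency``
    tables binned with the Freedman–Diaconis rule by default.
    """
    required = {"group", "type"}
    if not required.issubset(features.columns):
        raise ValueError(f"features table must have columns {sorted(required)}")
    value_cols = [c for c in features.columns if c not in required
                  and pd.api.types.is_numeric_dtype(features[c])]
    rows = []
    for (grp, typ), sub in features.groupby(["group", "type"], observed=True):
        for col in value_cols:
            vals = sub[col].dropna().to_numpy()
            if len(vals) == 0:
                continue
            sem = float(sps.sem(vals)) if len(vals) > 1 else np.nan
            rows.append({
                "group": grp, "type": typ, "feature": col, "n": len(vals),
                "mean": float(vals.mean()), "sem": sem,
                "sem_defined": len(vals) > 1,
            })
    summary = pd.DataFrame(rows)

    freq: dict[str, pd.DataFrame] = {}
    for col in value_cols:
        vals = features[col].dropna().to_numpy()
        if len(vals) < 2 or np.ptp(vals) == 0:
            continue
        edges = np.histogram_bin_edges(vals, bins=bins)
        frames = []
        for (grp, typ), sub in features.groupby(["group", "type"], observed=True):
            counts, _ = np.histogram(sub[col].dropna(), bins=edges)
            frames.append(pd.DataFrame({
                "group": grp, "type": typ,
                "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
            }))
        freq[col] = pd.concat(frames, ignore_index=True)
    return {"summary": summary, "frequency": freq}
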