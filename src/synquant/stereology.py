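"""Stereology: Cavalieri point counting, shrinkage correction, artifact
discounting and cortical-thickness summaries.

Volume fractions of cortical elements (neurons, glia, blood vessels,
neuropil) are estimated from semithin-section label images by point
counting: a systematic grid whose points each represent a known tissue
area (default 400 μm² per point) is overlaid with a uniform random
offset, and the fraction of hits on each element estimates its volume
fraction.  The neuropil fraction is taken by complement,
``V_neuropil = 100 − (V_neurons + V_glia + V_vessels)``, so the four
fractions close to exactly 100.

Tissue shrinks during EM processing; the area shrinkage factor
``p² = area_after / area_before`` corrects measured quantities.
Post-processing measurements are scaled *up*: a d-dimensional measure is
divided by ``p^d``, i.e. ``corrected = measured / p²^(d/2)``
(equivalently, densities per volume are multiplied by ``p²^(3/2)``).
Fixation-artifact volume is discounted from counting volumes so that
synapse densities are not underestimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import SemithinImage

__all__ = [
    "GridSpec",
    "VolumeFractions",
    "ShrinkageFactor",
    "cavalieri_point_count",
    "neuropil_complement",
    "shrinkage_factor",
    "correct_measurement",
    "discount_artifacts",
    "thickness_summary",
]


@dataclass(frozen=True)
class GridSpec:
    """Systematic point grid: each point represents ``point_area`` μm²."""

    point_area: float = 400.0
    origin_offset: tuple[float, float] | None = None  # μm; random if None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.point_area <= 0:
            raise ValueError("point_area must be positive")


@dataclass(frozen=True)
class VolumeFractions:
    """Percent volume fractions of the four cortical elements (sum = 100)."""

    v_neurons: float
    v_glia: float
    v_vessels: float
    v_neuropil: float
    n_points: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "neurons": self.v_neurons, "glia": self.v_glia,
            "vessels": self.v_vessels, "neuropil": self.v_neuropil,
        }


@dataclass(frozen=True)
class ShrinkageFactor:
    """Area shrinkage ratio p² = area_after / area_before.

    Values ≤ 1 are expected for fixation shrinkage; > 1 (swelling) is
    allowed but flagged.
    """

    p2: float

    def __post_init__(self) -> None:
        if self.p2 <= 0:
            raise ValueError("p2 must be positive")

    @property
    def flagged_swelling(self) -> bool:
        return self.p2 > 1.0

    def linear(self) -> float:
        """Linear shrinkage factor p = sqrt(p²)."""
        return float(np.sqrt(self.p2))


def cavalieri_point_count(image: SemithinImage, grid: GridSpec = GridSpec()) -> VolumeFractions:
    """Volume fractions by Cavalieri point counting on a label image.

    Grid spacing is ``sqrt(point_area)``; the grid origin gets a uniform
    random offset within one spacing (one systematic-random sample) unless
    ``grid.origin_offset`` fixes it.  Per-element fraction = hits/points
    as a percentage; the neuropil is the complement of the other three.
    """
    spacing_px = np.sqrt(grid.point_area) / image.pixel_size_um
    h, w = image.labels.shape
    if spacing_px > h and spacing_px > w:
        raise ValueError("grid spacing exceeds the image: no grid point falls inside")
    if grid.origin_offset is not None:
        off = np.asarray(grid.origin_offset, dtype=float) / image.pixel_size_um
        off = np.mod(off, spacing_px)
    else:
        rng = np.random.default_rng(grid.seed)
        off = rng.random(2) * spacing_px
    rows = np.arange(off[0], h, spacing_px).astype(int)
    cols = np.arange(off[1], w, spacing_px).astype(int)
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("no grid points fall inside the image")
    hits = image.labels[np.ix_(rows, cols)]
    n = hits.size
    pct = {code: 100.0 * float((hits == code).sum()) / n for code in (1, 2, 3)}
    v_np = neuropil_complement(pct[1], pct[2], pct[3])
    return VolumeFractions(pct[1], pct[2], pct[3], v_np, n_points=n)


def neuropil_complement(v_neurons: float, v_glia: float, v_vessels: float) -> float:
    """Neuropil fraction: 100 − (neurons + glia + vessels), percent."""
    for v in (v_neurons, v_glia, v_vessels):
        if v < 0:
            raise ValueError("fractions must be non-negative")
    s = v_neurons + v_glia + v_vessels
    if s > 100:
        raise ValueError(f"element fractions sum to {s} > 100")
    return 100.0 - s


def shrinkage_factor(area_before: float, area_after: float) -> ShrinkageFactor:
    """p² from areas of the same tissue before and after EM processing."""
    if area_before <= 0 or area_after <= 0:
        raise ValueError("areas must be positive")
    return ShrinkageFactor(area_after / area_before)


def correct_measurement(value: float, p2: ShrinkageFactor | float, dimension: int) -> float:
    """Shrinkage-correct a length (d=1), area (d=2) or volume (d=3).

    ``corrected = measured / p²^(d/2)``: post-processing values are scaled
    up by the shrinkage.  A per-volume density is corrected by the inverse
    (multiply by p²^(3/2)); pass ``dimension=-3`` for that case.
    """
    if dimension not in (1, 2, 3, -1, -2, -3):
        raise ValueError("dimension must be ±1, ±2 or ±3")
    f = p2.p2 if isinstance(p2, ShrinkageFactor) else float(p2)
    if f <= 0:
        raise ValueError("p2 must be positive")
    return float(value) / f ** (dimension / 2.0)


def discount_artifacts(frame_volume: float, artifact_volume: float) -> tuple[float, float]:
    """Counting volume after removing fixation-artifact volume (same units).

    Returns ``(corrected_volume, artifact_fraction)``.
    """
    if artifact_volume < 0:
        raise ValueError("artifact volume must be non-negative")
    if artifact_volume >= frame_volume:
        raise ValueError("artifact volume must be smaller than the frame volume")
    return frame_volume - artifact_volume, artifact_volume / frame_volume


def thickness_summary(records: dict[str, np.ndarray], groups: dict[str, str]) -> dict:
    """Cortical-thickness summary from per-case section measurements.

    ``records`` maps case id → (sections, 3) array of thickness
    measurements in mm (three per section); ``groups`` maps case id →
    group name.  Returns per-case means, per-group mean ± SD, and the
    percent reduction of the second group relative to the first (rounded
    to the nearest integer, e.g. 2.66 → 1.74 mm is a 35% reduction).
    """
    if not records:
        raise ValueError("no thickness records")
    missing = set(records) - set(groups)
    if missing:
        raise ValueError(f"cases without group assignment: {sorted(missing)}")
    case_rows = []
    for case_id, m in records.items():
        m = np.asarray(m, dtype=float)
        if m.size == 0 or np.any(m <= 0):
            raise ValueError(f"case {case_id}: thickness measurements must be positive")
        case_rows.append({"case": case_id, "group": groups[case_id],
                          "mean_mm": float(m.mean()), "n_measurements": m.size})
    cases = pd.DataFrame(case_rows)
    group_stats = (
        cases.groupby("group")["mean_mm"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="count")
        .reset_index()
    )
    result = {"cases": cases, "groups": group_stats}
    order = list(dict.fromkeys(groups.values()))
    if len(order) == 2:
        ref = float(group_stats.set_index("group").loc[order[0], "mean"])
        other = float(group_stats.set_index("group").loc[order[1], "mean"])
        result["reduction_pct"] = int(round((ref - other) / ref * 100.0))
    return result
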