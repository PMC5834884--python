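"""File formats: centroid CSV, PLY meshes, TIFF label stacks, YAML
configuration and JSON reports.

Centroid tables are UTF-8 comma-separated CSV with a mandatory header
``stack_id,synapse_id,x_nm,y_nm,z_nm,type`` (type ∈ {AS, SS}), all
coordinates in nm.  JSON reports are pretty-printed with sorted keys so
their hash is stable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

from .geometry import PointPattern, Window3D
from .morphometry import SASMesh
from .synthgen import SemithinImage, StackSample, StudySample

__all__ = [
    "CENTROID_COLUMNS",
    "write_centroids", "read_centroids",
    "write_mesh", "read_mesh", "write_meshes", "read_meshes",
    "write_label_stack", "read_label_stack",
    "write_semithin", "read_semithin",
    "load_config", "write_report", "config_hash",
    "export_study",
]

CENTROID_COLUMNS = ["stack_id", "synapse_id", "x_nm", "y_nm", "z_nm", "type"]


def write_centroids(path, stacks: list[StackSample]) -> pd.DataFrame:
    """Write per-stack synapse centroids to a centroid CSV; returns the table."""
    rows = []
    for st in stacks:
        for i, (p, t) in enumerate(zip(st.pattern.points, st.types)):
            rows.append({
                "stack_id": st.stack_id, "synapse_id": f"{st.stack_id}_syn{i}",
                "x_nm": p[0], "y_nm": p[1], "z_nm": p[2], "type": t,
            })
    df = pd.DataFrame(rows, columns=CENTROID_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_centroids(path) -> pd.DataFrame:
    """Read and validate a centroid CSV.

    Checks the header, the AS/SS labels, and applies a unit heuristic:
    coordinate spans of a few tens of units or less look like μm rather
    than nm and are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in CENTROID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad_type = ~df["type"].isin(["AS", "SS"])
    if bad_type.any():
        lines = (df.index[bad_type] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"{path}: invalid synapse type at line(s) {lines}")
    coords = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        bad = np.flatnonzero(~np.isfinite(coords).all(axis=1)) + 2
        raise ValueError(f"{path}: non-finite coordinates at line(s) {bad.tolist()[:10]}")
    if len(df) > 1 and np.nanmax(np.abs(coords)) < 100.0:
        raise ValueError(
            f"{path}: coordinate magnitudes < 100 look like μm, not nm — "
            "convert to nm before loading"
        )
    return df


def centroids_to_patterns(df: pd.DataFrame, window: Window3D) -> dict[str, PointPattern]:
    """Group a centroid table into one labelled PointPattern per stack."""
    out = {}
    for stack_id, sub in df.groupby("stack_id"):
        pts = sub[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        out[str(stack_id)] = PointPattern(pts, window, labels=sub["type"].to_numpy())
    return out


def write_mesh(path, mesh: SASMesh) -> None:
    """Write one SAS mesh as binary little-endian PLY."""
    mesh.to_trimesh().export(str(path), file_type="ply", encoding="binary")


def read_mesh(path) -> SASMesh:
    m = trimesh.load(str(path), file_type="ply", process=False)
    return SASMesh.from_trimesh(m)


def write_meshes(directory, stack: StackSample) -> list[Path]:
    """One PLY per synapse (mesh translated to its centroid), named by synapse id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (c, m) in enumerate(zip(stack.pattern.points, stack.meshes)):
        p = directory / f"{stack.stack_id}_syn{i}.ply"
        write_mesh(p, m.translated(c))
        paths.append(p)
    return paths


def read_meshes(directory) -> dict[str, SASMesh]:
    return {p.stem: read_mesh(p) for p in sorted(Path(directory).glob("*.ply"))}


def write_label_stack(path, stack: StackSample, voxel_nm=(80.0, 80.0, 80.0)) -> np.ndarray:
    """Voxelise a stack as a uint8 TIFF: 0 background, 1 synapse, 2 artifact.

    Synapse voxels are those whose centre falls inside a synapse extent;
    artifact voxels those inside an artifact ellipsoid.  ``voxel_nm`` is
    (x, y, z) spacing; the array is written z-first (pages are sections).
    """
    w = stack.window
    vox = np.asarray(voxel_nm, dtype=float)
    counts = np.maximum(1, np.floor(np.asarray(w.extents) / vox).astype(int))
    axes = [w.lo[a] + (np.arange(counts[a]) + 0.5) * vox[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    labels = np.zeros(len(pts), dtype=np.uint8)
    for lo, hi in stack.extents():
        inside = np.all((pts >= lo) & (pts <= hi), axis=1)
        labels[inside] = 1
    for e in stack.artifacts:
        labels[e.contains(pts)] = 2
    vol = labels.reshape(counts)  # (x, y, z)
    pages = np.transpose(vol, (2, 1, 0))  # (z, y, x)
    tifffile.imwrite(str(path), pages, photometric="minisblack",
                     metadata={"spacing_nm": list(vox)})
    return pages


def read_label_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_semithin(path, image: SemithinImage) -> None:
    tifffile.imwrite(str(path), image.labels, photometric="minisblack")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({
        "pixel_size_um": image.pixel_size_um,
        "ground_truth": image.ground_truth,
    }, indent=2, sort_keys=True))


def read_semithin(path) -> SemithinImage:
    labels = tifffile.imread(str(path))
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SemithinImage(
        labels=labels.astype(np.uint8),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        ground_truth=meta.get("ground_truth", {}),
    )


def load_config(path) -> dict:
    """Load a YAML study configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, directory) -> Path:
    """Write a study report: one JSON plus a CSV per table.

    The JSON is pretty-printed with sorted keys; DataFrames inside the
    report are also written as individual CSV files named after their
    key path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump_tables(node, prefix=""):
        if isinstance(node, pd.DataFrame):
            node.to_csv(directory / f"{prefix.strip('_')}.csv", index=False)
        elif isinstance(node, dict):
            for k, v in node.items():
                dump_tables(v, f"{prefix}{k}_")

    dump_tables(report)
    out = directory / "report.json"
    out.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return out


def export_study(study: StudySample, directory) -> dict:
    """Write a full synthetic study to disk (centroids, meshes, ground truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    all_stacks = [st for c in study.cases for st in c.stacks]
    write_centroids(directory / "centroids.csv", all_stacks)
    for case in study.cases:
        for st in case.stacks:
            write_meshes(directory / "meshes" / st.stack_id, st)
    truth = {
        "seed": study.params.seed,
        "n_cases_per_group": study.params.n_cases_per_group,
        "cases": {
            c.case_id: {
                "group": c.group,
                "intensity": c.params.intensity,
                "as_fraction": c.params.as_fraction,
                "artifact_fraction": c.params.artifact_fraction,
                "thickness_mean_mm": c.thickness_mean if c.thickness_mm.size else None,
                "stacks": {
                    st.stack_id: {
                        "n_synapses": st.pattern.n,
                        "artifact_volume_nm3": st.artifact_volume_nm3,
                        "seed": st.seed,
                    } for st in c.stacks
                },
            } for c in study.cases
        },
    }
    (directory / "ground_truth.json").write_text(
        json.dumps(_jsonable(truth), indent=2, sort_keys=True))
    return truth
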