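"""On-disk artifacts: scans, tooth-label sidecars, transforms, manifests, results.

Conventions fixed across the package:

* coordinates are millimetres on disk and in memory; angles are degrees in
  user-facing records and radians are never serialized;
* tooth labels use FDI two-digit notation, with 0 reserved for non-tooth
  points (gingiva, cast base) so they can be carried but ignored;
* scans are PLY (ascii or binary_little_endian, double-precision vertices)
  or binary STL, each with a CSV label sidecar ``point_index,tooth_id_FDI``;
* rigid transforms are JSON 4x4 row-major homogeneous matrices in mm.

Readers reject malformed input rather than repairing it.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .errors import ConfigurationError, IntegrityError, ScanParseError
from .registration import RigidTransform

__all__ = [
    "LabeledScan",
    "TIMEPOINTS",
    "GROUPS",
    "SUBGROUPS",
    "read_scan",
    "write_scan",
    "read_transform_json",
    "write_transform_json",
    "read_manifest",
    "write_manifest",
    "read_results",
    "write_results",
]

TIMEPOINTS = ("T1", "T2", "ClinT2")
GROUPS = ("torque", "derotation", "distalization")
SUBGROUPS = ("attachment", "none", "power_ridge")

MANIFEST_COLUMNS = [
    "patient_id", "group", "subgroup", "moved_tooth",
    "planned_Tx", "planned_Ty", "planned_Tz",
    "planned_Rx", "planned_Ry", "planned_Rz",
    "planned_total", "staging_per_aligner", "n_aligners",
    "compliance_hours", "true_efficacy",
]

RESULT_COLUMNS = [
    "patient_id", "group", "subgroup", "moved_tooth", "primary_component",
    "predicted", "achieved", "efficacy_percent",
    "planned_total", "staging_per_aligner", "compliance_hours",
]


@dataclass(frozen=True)
class LabeledScan:
    """A dental-cast point cloud with per-point FDI tooth labels.

    The unit every pipeline stage consumes: one merged 3-D data set per cast
    per timepoint (pre-treatment T1, achieved T2, planned outcome ClinT2).
    """

    points: np.ndarray
    labels: np.ndarray
    patient_id: str = ""
    timepoint: str = "T1"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        lab = np.asarray(self.labels, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 1:
            raise ConfigurationError(f"points must be (N>=1, 3), got {pts.shape}")
        if not np.isfinite(pts).all():
            bad = int(np.argwhere(~np.isfinite(pts).all(axis=1))[0, 0])
            raise ConfigurationError(f"non-finite coordinate at point {bad}")
        if lab.shape != (len(pts),):
            raise IntegrityError(
                f"labels length {lab.shape} does not match {len(pts)} points"
            )
        if self.timepoint not in TIMEPOINTS:
            raise ConfigurationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tooth_ids(self) -> np.ndarray:
        """Sorted distinct FDI labels present (0 excluded)."""
        ids = np.unique(self.labels)
        return ids[ids != 0]

    def tooth_points(self, tooth_id: int) -> np.ndarray:
        pts = self.points[self.labels == tooth_id]
        if len(pts) == 0:
            raise KeyError(f"tooth {tooth_id} not present in scan")
        return pts

    def tooth_centroid(self, tooth_id: int) -> np.ndarray:
        return self.tooth_points(tooth_id).mean(axis=0)

    def with_points(self, points: np.ndarray) -> "LabeledScan":
        return replace(self, points=points)


# ---------------------------------------------------------------------------
# scans

def _write_ply(points: np.ndarray, path, binary: bool) -> None:
    # trimesh's point-cloud export writes float32 vertices; arch coordinates
    # are tens of mm, so doubles are required to honour the 1e-6 mm round-trip
    n = len(points)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        f"ply\nformat {fmt} 1.0\n"
        f"element vertex {n}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(points, dtype="<f8").tobytes())
        else:
            body = "\n".join(
                " ".join(f"{v:.17g}" for v in row) for row in points
            )
            fh.write((body + "\n").encode("ascii"))


def write_scan(scan: LabeledScan, path, label_path, *, binary: bool = True) -> None:
    """Write a scan as PLY (double precision) plus its CSV label sidecar."""
    _write_ply(scan.points, path, binary=binary)
    pd.DataFrame(
        {"point_index": np.arange(len(scan)), "tooth_id_FDI": scan.labels}
    ).to_csv(label_path, index=False)


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Collapse vertices identical within tol, keeping first-occurrence order."""
    key = np.round(points / tol).astype(np.int64)
    _, first = np.unique(key, axis=0, return_index=True)
    return points[np.sort(first)]


def read_scan(path, label_path=None, *, patient_id: str = "",
              timepoint: str = "T1") -> LabeledScan:
    """Read a PLY or STL scan and its label sidecar into a LabeledScan.

    STL vertices are deduplicated within 1e-9 mm before labelling (STL stores
    each vertex once per facet).  Without a sidecar all labels are 0.
    """
    p = str(path)
    kind = "stl" if p.lower().endswith(".stl") else "ply"
    try:
        loaded = trimesh.load(p, file_type=kind, process=False)
    except Exception as exc:  # trimesh raises heterogeneous types
        raise ScanParseError(f"cannot parse {kind.upper()} file {p}: {exc}") from exc
    points = np.asarray(loaded.vertices, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) == 0:
        raise ScanParseError(f"{p}: no vertex records found")
    if not np.isfinite(points).all():
        bad = int(np.argwhere(~np.isfinite(points).all(axis=1))[0, 0])
        raise ScanParseError(f"{p}: non-finite coordinate in vertex record {bad}")
    if kind == "stl":
        points = _dedupe(points)
    if label_path is None:
        labels = np.zeros(len(points), dtype=int)
    else:
        table = pd.read_csv(label_path)
        if "tooth_id_FDI" not in table.columns:
            raise ScanParseError(f"{label_path}: missing tooth_id_FDI column")
        if len(table) != len(points):
            raise IntegrityError(
                f"{label_path}: {len(table)} label rows for {len(points)} points"
            )
        labels = table["tooth_id_FDI"].to_numpy(dtype=int)
        if "point_index" in table.columns:
            order = table["point_index"].to_numpy(dtype=int)
            if not np.array_equal(np.sort(order), np.arange(len(points))):
                raise IntegrityError(f"{label_path}: point_index is not a permutation")
            labels = labels[np.argsort(order, kind="stable")]
    return LabeledScan(points, labels, patient_id=patient_id, timepoint=timepoint)


# ---------------------------------------------------------------------------
# rigid transforms

def write_transform_json(transform: RigidTransform, path) -> None:
    """Serialize as a 4x4 row-major homogeneous matrix (mm)."""
    with open(path, "w") as fh:
        json.dump({"matrix": transform.matrix.tolist(), "units": "mm"}, fh, indent=1)


def read_transform_json(path) -> RigidTransform:
    """Read and validate a rigid transform (orthonormal, det = +1)."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
        M = np.asarray(payload["matrix"], dtype=float)
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ScanParseError(f"{path}: not a transform JSON ({exc})") from exc
    if M.shape != (4, 4):
        raise ScanParseError(f"{path}: matrix must be 4x4, got {M.shape}")
    if not np.allclose(M[3], [0, 0, 0, 1], atol=1e-9):
        raise ScanParseError(f"{path}: last homogeneous row must be (0,0,0,1)")
    R = M[:3, :3]
    if np.abs(R.T @ R - np.eye(3)).max() >= 1e-6:
        raise ScanParseError(f"{path}: rotation block is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ScanParseError(f"{path}: rotation block is a reflection (det < 0)")
    # re-orthonormalize the float round-trip before the strict constructor
    U, _, Vt = np.linalg.svd(R)
    return RigidTransform(U @ Vt, M[:3, 3])


# ---------------------------------------------------------------------------
# manifest and results tables

def write_manifest(manifest: pd.DataFrame, path) -> None:
    _validate_manifest(manifest)
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _validate_manifest(table)
    return table


def _validate_manifest(table: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"manifest is missing columns {missing}")
    bad_group = set(table["group"]) - set(GROUPS)
    if bad_group:
        raise ConfigurationError(f"unknown movement group(s) {sorted(bad_group)}")
    bad_sub = set(table["subgroup"]) - set(SUBGROUPS)
    if bad_sub:
        raise ConfigurationError(f"unknown subgroup(s) {sorted(bad_sub)}")
    hours = table["compliance_hours"].to_numpy(dtype=float)
    if ((hours <= 0) | (hours > 24)).any():
        raise ConfigurationError("compliance_hours must lie in (0, 24]")


def write_results(records, path) -> None:
    """Write EfficacyRecord rows as the results CSV (one analyzed movement each)."""
    rows = [r.to_dict() for r in records]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def read_results(path):
    """Read a results CSV back into EfficacyRecord objects."""
    from .movement import EfficacyRecord  # deferred: movement imports scan_io

    table = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"results table is missing columns {missing}")
    return [EfficacyRecord(**{k: row[k] for k in RESULT_COLUMNS})
            for _, row in table.iterrows()]
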