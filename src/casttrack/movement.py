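"""Per-tooth movement measurement in the patient coordinate system.

The workflow mirrors serial-cast superimposition practice: the untreated
(reference) teeth of the pre-treatment cast T1 define a patient-specific
right-handed frame, the later casts (achieved T2, planned outcome ClinT2) are
superimposed onto T1 using only those reference teeth, and each moved tooth's
residual rigid motion is decomposed into three translations (Tx, Ty, Tz, mm)
and three rotations (Rx, Ry, Rz, degrees) about the frame axes.

Axis semantics (see ArchFrame): x points distally along the arch, z points
occlusally, y completes the right-handed system (bucco-lingual).  Molar
distalization is then a translation on x, incisor torque a rotation about y,
and premolar derotation a rotation about z.  Treatment efficacy is the signed
ratio achieved/planned on the group's primary component, in percent; a tooth
that moved the wrong way yields a negative efficacy and over-correction
exceeds 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import AnchoringError, ConfigurationError, DegeneracyError, UndefinedEfficacyError
from .registration import ICPParams, RigidTransform, icp
from .scan_io import LabeledScan

__all__ = [
    "ArchFrame",
    "MovementComponents",
    "EfficacyRecord",
    "PRIMARY_COMPONENT",
    "build_frame",
    "superimpose_casts",
    "measure_movement",
    "decompose",
    "movement_transform",
    "efficacy",
    "measure_patient",
]

#: the component scored for each movement group
PRIMARY_COMPONENT = {"distalization": "Tx", "torque": "Ry", "derotation": "Rz"}


@dataclass(frozen=True)
class ArchFrame:
    """Patient coordinate system: origin at the moved tooth, axes on the arch.

    x = distal tangent of the arch curve, y = bucco-lingual (torque axis),
    z = occlusal normal of the reference occlusal plane (derotation axis).
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        axes = [np.asarray(a, dtype=float).reshape(3)
                for a in (self.x_axis, self.y_axis, self.z_axis)]
        B = np.column_stack(axes)
        if np.abs(B.T @ B - np.eye(3)).max() >= 1e-9:
            raise ConfigurationError("frame axes must be orthonormal")
        if abs(np.linalg.det(B) - 1.0) >= 1e-9:
            raise ConfigurationError("frame must be right-handed (det = +1)")
        object.__setattr__(self, "origin", o)
        for name, a in zip(("x_axis", "y_axis", "z_axis"), axes):
            object.__setattr__(self, name, a)

    @property
    def basis(self) -> np.ndarray:
        """Columns are (x, y, z) in world coordinates."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])


@dataclass(frozen=True)
class MovementComponents:
    """Six degrees of freedom of one tooth's displacement.

    Translations in mm along the frame axes; rotations in degrees about the
    frame axes (fixed-axes x→y→z composition, right-hand rule).
    """

    Tx: float = 0.0
    Ty: float = 0.0
    Tz: float = 0.0
    Rx: float = 0.0
    Ry: float = 0.0
    Rz: float = 0.0

    def __post_init__(self):
        vals = [self.Tx, self.Ty, self.Tz, self.Rx, self.Ry, self.Rz]
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("movement components must be finite")
        for ang in (self.Rx, self.Ry, self.Rz):
            if abs(ang) > 180.0:
                raise ConfigurationError("rotation components must satisfy |R| <= 180 deg")

    def component(self, name: str) -> float:
        if name not in ("Tx", "Ty", "Tz", "Rx", "Ry", "Rz"):
            raise ConfigurationError(f"unknown component {name!r}")
        return float(getattr(self, name))

    @property
    def translation_mm(self) -> np.ndarray:
        return np.array([self.Tx, self.Ty, self.Tz], dtype=float)

    @property
    def rotation_deg(self) -> np.ndarray:
        return np.array([self.Rx, self.Ry, self.Rz], dtype=float)


@dataclass(frozen=True)
class EfficacyRecord:
    """One analyzed tooth movement: the row type of the cohort tables."""

    patient_id: str
    group: str
    subgroup: str
    moved_tooth: int
    primary_component: str
    predicted: float
    achieved: float
    efficacy_percent: float
    planned_total: float
    staging_per_aligner: float
    compliance_hours: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# frame construction

def build_frame(reference_centroids, moved_tooth_centroid,
                occlusal_hint=(0.0, 0.0, 1.0)) -> ArchFrame:
    """Patient frame from reference-tooth centroids and the moved tooth.

    z is the unit normal of the least-squares plane through the reference
    centroids, signed toward the occlusal side (``occlusal_hint`` breaks the
    plane-normal sign ambiguity; the default assumes the crowns-up cast
    orientation).  x is the tangent of a quadratic arch curve fitted through
    the reference centroids, evaluated nearest the moved tooth and signed
    distally (away from the arch midline).  y = z × x.  The origin is the
    moved tooth's centroid, so translation components read out at the crown.
    """
    C = np.asarray(reference_centroids, dtype=float)
    if C.ndim != 2 or C.shape[1] != 3 or len(C) < 3:
        raise DegeneracyError("need >= 3 reference centroids")
    m = np.asarray(moved_tooth_centroid, dtype=float).reshape(3)
    c0 = C.mean(axis=0)
    U, S, Vt = np.linalg.svd(C - c0)
    if S[1] <= 1e-9 * max(S[0], 1.0):
        raise DegeneracyError("reference centroids are collinear")
    e1, e2, normal = Vt[0], Vt[1], Vt[2]
    hint = np.asarray(occlusal_hint, dtype=float).reshape(3)
    if normal @ hint < 0:
        normal = -normal
    z = normal / np.linalg.norm(normal)

    # quadratic arch curve in the plane coordinates (u along the arch width)
    u = (C - c0) @ e1
    v = (C - c0) @ e2
    a, b, _ = np.polyfit(u, v, 2)
    u_m = (m - c0) @ e1
    tangent = e1 + (2.0 * a * u_m + b) * e2
    tangent -= (tangent @ z) * z  # numerically in-plane
    tangent /= np.linalg.norm(tangent)
    u_apex = -b / (2.0 * a) if abs(a) > 1e-12 else float(np.mean(u))
    if (u_m - u_apex) < 0:
        tangent = -tangent  # distal = away from the midline
    x = tangent
    y = np.cross(z, x)
    return ArchFrame(origin=m, x_axis=x, y_axis=y, z_axis=z)


# ---------------------------------------------------------------------------
# superimposition and measurement

def superimpose_casts(cast_t1: LabeledScan, cast_t2: LabeledScan,
                      reference_ids, moved_ids=(),
                      params: ICPParams | None = None) -> RigidTransform:
    """Transform mapping cast_t2 into cast_t1's frame via the reference teeth.

    ICP restricted to points labelled with ``reference_ids`` (the untreated
    teeth, the corresponding structure shared by all timepoints), initialized
    by centroid alignment.  ``moved_ids`` guards against a clinically moved
    tooth contaminating the anchor.
    """
    ref = set(int(r) for r in reference_ids)
    contaminated = ref & set(int(t) for t in moved_ids)
    if contaminated:
        raise AnchoringError(
            f"moved teeth {sorted(contaminated)} must not serve as reference"
        )
    present = ref & set(cast_t1.tooth_ids) & set(cast_t2.tooth_ids)
    if len(present) < 3:
        raise AnchoringError(
            f"need >= 3 shared reference teeth, only {sorted(present)} usable"
        )
    mask1 = np.isin(cast_t1.labels, sorted(present))
    mask2 = np.isin(cast_t2.labels, sorted(present))
    p1 = cast_t1.points[mask1]
    p2 = cast_t2.points[mask2]
    init = RigidTransform(np.eye(3), p1.mean(axis=0) - p2.mean(axis=0))
    transform, _, _ = icp(p2, p1, init=init, params=params)
    return transform


#: coarse initialization grid for the per-tooth registration: rotations about
#: each frame axis up to the largest clinically plausible movement
_INIT_ANGLES_DEG = (0.0, 10.0, -10.0, 20.0, -20.0, 30.0, -30.0, 40.0, -40.0)


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    u = axis / np.linalg.norm(axis)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def measure_movement(tooth_t1, tooth_t2_in_t1_frame, frame: ArchFrame,
                     params: ICPParams | None = None) -> MovementComponents:
    """Six-DOF movement of one tooth between superimposed timepoints.

    ICP-registers the T1 crown onto its T2 position (both already in the T1
    frame); the recovered rigid motion is decomposed about the frame origin
    (the T1 crown centroid).

    Crowns are compact shapes, so a plain centroid-aligned start can stall in
    a local minimum for the larger clinical rotations (>~20 deg).  The search
    is therefore seeded from a small grid of candidate rotations about the
    frame axes spanning the clinically bounded movement range; each candidate
    gets a short trimmed-ICP run and the lowest-RMS one is polished to
    convergence.  This is a structured local initialization, not a global
    search — movements beyond ~45 deg are outside the measurement envelope.
    """
    t1 = np.asarray(tooth_t1, dtype=float)
    t2 = np.asarray(tooth_t2_in_t1_frame, dtype=float)
    if len(t1) < 10 or len(t2) < 10:
        raise DegeneracyError("need >= 10 points per tooth to measure movement")
    params = params or ICPParams()
    coarse = ICPParams(max_iterations=min(20, params.max_iterations),
                       rel_rms_tol=max(params.rel_rms_tol, 1e-4),
                       trim_fraction=params.trim_fraction,
                       min_points=params.min_points)
    c1 = t1.mean(axis=0)
    c2 = t2.mean(axis=0)
    candidates = [np.eye(3)]
    for axis in (frame.x_axis, frame.y_axis, frame.z_axis):
        for ang in _INIT_ANGLES_DEG[1:]:
            candidates.append(_axis_rotation(axis, ang))
    best = None
    for R0 in candidates:
        init = RigidTransform(R0, c2 - R0 @ c1)
        T, rms, _ = icp(t1, t2, init=init, params=coarse)
        if best is None or rms < best[1]:
            best = (T, rms)
    transform, _, _ = icp(t1, t2, init=best[0], params=params)
    return decompose(transform, frame)


def decompose(transform: RigidTransform, frame: ArchFrame) -> MovementComponents:
    """Express a rigid motion as frame-based translations and Euler angles.

    The rotation re-expressed in the frame basis, R' = BᵀRB, is factored with
    the fixed-axes x→y→z convention, R' = Rz(γ)·Ry(β)·Rx(α); translations are
    the frame-basis components of the frame origin's displacement.  At gimbal
    lock (|Ry| = 90°) Rx is set to 0 by convention and a warning is issued.
    """
    B = frame.basis
    Rp = B.T @ transform.rotation @ B
    s_beta = -Rp[2, 0]
    s_beta = min(1.0, max(-1.0, s_beta))
    beta = np.arcsin(s_beta)
    if abs(abs(beta) - np.pi / 2) < 1e-6:
        warnings.warn("gimbal lock: |Ry| = 90 deg; Rx fixed to 0 by convention")
        alpha = 0.0
        gamma = np.arctan2(-Rp[0, 1], Rp[1, 1])
    else:
        alpha = np.arctan2(Rp[2, 1], Rp[2, 2])
        gamma = np.arctan2(Rp[1, 0], Rp[0, 0])
    disp = transform.apply(frame.origin) - frame.origin
    t = B.T @ disp
    return MovementComponents(
        Tx=float(t[0]), Ty=float(t[1]), Tz=float(t[2]),
        Rx=float(np.degrees(alpha)),
        Ry=float(np.degrees(beta)),
        Rz=float(np.degrees(gamma)),
    )


def movement_transform(components: MovementComponents, frame: ArchFrame,
                       center=None) -> RigidTransform:
    """The rigid motion realizing given components (inverse of decompose).

    Rotates by (Rx, Ry, Rz) about the frame axes at ``center`` (default: the
    frame origin), then translates along the frame axes.
    """
    c = frame.origin if center is None else np.asarray(center, dtype=float).reshape(3)
    a, b, g = np.radians([components.Rx, components.Ry, components.Rz])

    def _rx(t):
        return np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])

    def _ry(t):
        return np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])

    def _rz(t):
        return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])

    B = frame.basis
    Rp = _rz(g) @ _ry(b) @ _rx(a)
    R = B @ Rp @ B.T
    shift = B @ components.translation_mm
    t = c - R @ c + shift
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# efficacy

def efficacy(achieved: float, predicted: float) -> float:
    """Signed treatment efficacy, percent: 100 × achieved / planned.

    Negative when the tooth moved opposite to the plan; above 100 when it
    overshot.  Undefined for a zero planned movement (the study's inclusion
    thresholds guarantee a substantial plan on the primary component).
    """
    if predicted == 0:
        raise UndefinedEfficacyError("planned movement is zero; efficacy undefined")
    return 100.0 * achieved / predicted


def measure_patient(t1: LabeledScan, t2: LabeledScan, clin_t2: LabeledScan,
                    manifest_row, moved_ids=None,
                    params: ICPParams | None = None,
                    occlusal_hint=(0.0, 0.0, 1.0)) -> EfficacyRecord:
    """Full pipeline for one analyzed movement.

    Superimposes T2 and ClinT2 onto T1 via the untreated reference teeth,
    measures the moved tooth's 6-DOF displacement for both, and scores
    efficacy on the group's primary component.  The planned movement is
    measured from the ClinT2 scan by the identical pipeline (not read from
    the manifest) so systematic measurement bias cancels in the ratio.

    ``manifest_row`` is a mapping with at least patient_id, group, subgroup,
    moved_tooth, planned_total, staging_per_aligner, compliance_hours.
    ``moved_ids`` lists every clinically moved tooth of the patient (both
    hemiarchs); default is just this row's tooth.
    """
    row = dict(manifest_row)
    group = row["group"]
    if group not in PRIMARY_COMPONENT:
        raise ConfigurationError(f"unknown movement group {group!r}")
    tooth = int(row["moved_tooth"])
    moved = set(int(t) for t in (moved_ids if moved_ids is not None else [tooth]))
    if tooth not in moved:
        raise ConfigurationError("moved_ids must include the row's own tooth")
    reference_ids = set(int(t) for t in t1.tooth_ids) - moved
    if len(reference_ids) < 3:
        raise AnchoringError("fewer than 3 untreated teeth available as reference")

    to_t1_t2 = superimpose_casts(t1, t2, reference_ids, moved_ids=moved, params=params)
    to_t1_clin = superimpose_casts(t1, clin_t2, reference_ids, moved_ids=moved, params=params)

    ref_centroids = np.array([t1.tooth_centroid(r) for r in sorted(reference_ids)])
    frame = build_frame(ref_centroids, t1.tooth_centroid(tooth), occlusal_hint)

    tooth_t1 = t1.tooth_points(tooth)
    achieved = measure_movement(
        tooth_t1, to_t1_t2.apply(t2.tooth_points(tooth)), frame, params=params)
    predicted = measure_movement(
        tooth_t1, to_t1_clin.apply(clin_t2.tooth_points(tooth)), frame, params=params)

    comp = PRIMARY_COMPONENT[group]
    ach = achieved.component(comp)
    pred = predicted.component(comp)
    return EfficacyRecord(
        patient_id=str(row["patient_id"]),
        group=group,
        subgroup=str(row["subgroup"]),
        moved_tooth=tooth,
        primary_component=comp,
        predicted=pred,
        achieved=ach,
        efficacy_percent=efficacy(ach, pred),
        planned_total=float(row["planned_total"]),
        staging_per_aligner=float(row["staging_per_aligner"]),
        compliance_hours=float(row["compliance_hours"]),
    )
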