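"""Synthetic dental arches with known ground-truth tooth movements.

Stands in for the study's plaster-cast scans: an upper arch of labelled crown
point clouds on a parabolic arch curve, one moved tooth per hemiarch
(split-mouth), planned movements realized as exact rigid motions, scanner
noise as isotropic Gaussian jitter (the laser scanner's stated accuracy is
about 20 μm), and per-movement treatment efficacy drawn from a truncated
normal so the cohort admits negative and >100 % outcomes.

Crowns are superellipsoids: incisors flat and faceted (blade-like), premolars
rounded (the shape that makes clinical derotation hard), molars large and
boxy.  Shape realism is secondary — what downstream code consumes is label
correctness and exact rigid-body ground truth.

All randomness flows through explicit integer seeds; nothing touches global
RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .movement import ArchFrame, MovementComponents, build_frame, movement_transform
from .registration import RigidTransform
from .scan_io import GROUPS, MANIFEST_COLUMNS, SUBGROUPS, LabeledScan

__all__ = [
    "ArchSpec",
    "GroundTruthMovement",
    "CohortConfig",
    "generate_arch",
    "apply_movement",
    "add_scan_noise",
    "generate_cohort",
    "study_configs",
    "moved_tooth_for",
    "arch_frame_for_tooth",
]

# crown half-widths (mesiodistal, buccolingual) in mm and superellipsoid
# exponent per tooth class; loosely after standard odontometric tables
_DEFAULT_CROWN_RADII = {
    "incisor_central": (4.2, 2.0),
    "incisor_lateral": (3.2, 1.8),
    "canine": (3.8, 3.4),
    "premolar": (3.4, 4.4),
    "molar": (5.0, 5.4),
}
_CROWN_EXPONENT = {
    "incisor_central": 4.0,  # faceted, blade-like
    "incisor_lateral": 4.0,
    "canine": 2.5,
    "premolar": 2.0,  # round cross-section
    "molar": 3.0,
}

#: staging caps of the aligner protocol, per movement group
STAGING_CAPS = {"derotation": 2.0, "torque": 1.0, "distalization": 0.25}

#: truncation bounds for the per-movement true-efficacy draw
EFFICACY_BOUNDS = (-0.25, 1.25)


def _tooth_class(position: int) -> str:
    # position = 1 at the midline, increasing distally
    return {1: "incisor_central", 2: "incisor_lateral", 3: "canine",
            4: "premolar", 5: "premolar"}.get(min(position, 7), "molar")


@dataclass(frozen=True)
class ArchSpec:
    """Geometry of a synthetic upper dental arch."""

    n_teeth_per_quadrant: int = 7
    arch_width: float = 55.0
    arch_depth: float = 42.0
    crown_height: float = 8.0
    crown_radii: dict = field(default_factory=lambda: dict(_DEFAULT_CROWN_RADII))
    points_per_tooth: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.n_teeth_per_quadrant < 3:
            raise ConfigurationError("n_teeth_per_quadrant must be >= 3")
        if min(self.arch_width, self.arch_depth, self.crown_height) <= 0:
            raise ConfigurationError("arch dimensions must be positive")
        if any(r <= 0 for pair in self.crown_radii.values() for r in pair):
            raise ConfigurationError("crown radii must be positive")
        if self.points_per_tooth < 50:
            raise ConfigurationError("points_per_tooth must be >= 50")


@dataclass(frozen=True)
class GroundTruthMovement:
    """A known rigid tooth movement: the quantity the pipeline must recover."""

    tooth_id: int
    components: MovementComponents
    center: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3))


@dataclass(frozen=True)
class CohortConfig:
    """One simulated subgroup: movement type, auxiliaries, staging, efficacy.

    ``true_efficacy_mean``/``sd`` parameterize the per-movement efficacy draw
    (fractions of the planned movement, truncated to [-0.25, 1.25]);
    ``planned_magnitude_range`` is in degrees (rotations) or mm (distalization).
    """

    count: int
    group: str
    subgroup: str
    planned_magnitude_range: tuple
    staging_per_aligner: float
    true_efficacy_mean: float
    true_efficacy_sd: float
    noise_sigma: float = 0.020
    seed: int = 0

    def __post_init__(self):
        if self.count < 1:
            raise ConfigurationError("count must be >= 1")
        if self.group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.subgroup not in SUBGROUPS:
            raise ConfigurationError(
                f"subgroup must be one of {SUBGROUPS}, got {self.subgroup!r}")
        lo, hi = self.planned_magnitude_range
        if not (0 < lo <= hi):
            raise ConfigurationError("planned_magnitude_range must be 0 < lo <= hi")
        cap = STAGING_CAPS[self.group]
        if not (0 < self.staging_per_aligner <= cap):
            raise ConfigurationError(
                f"staging for {self.group} must lie in (0, {cap}] per aligner")
        if self.true_efficacy_sd < 0:
            raise ConfigurationError("true_efficacy_sd must be >= 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# arch generation

def _superellipsoid_points(rng, n, rx, ry, rz, p):
    """Sample n points on the superellipsoid |x/rx|^p + |y/ry|^p + |z/rz|^p = 1."""
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    radii = np.array([rx, ry, rz])
    s = (np.abs(d / radii) ** p).sum(axis=1) ** (-1.0 / p)
    return d * s[:, None]


def _arch_positions(spec: ArchSpec):
    """Tooth FDI labels, centers and arch tangents along a parabola.

    The arch curve runs in the z=0 plane, apex (incisal midline) toward +y,
    molars toward -y; +z is occlusal.  Quadrant 1 (patient right) at x < 0.
    """
    n = spec.n_teeth_per_quadrant
    half = spec.arch_width / 2.0
    a = spec.arch_depth / half**2  # y = depth - a x^2
    teeth = []
    # parameter u in [-1, 1]: -1 = right distal molar, +1 = left distal molar
    for i in range(2 * n):
        u = -1.0 + (2 * i + 1) / (2.0 * n)
        x = half * u
        y = spec.arch_depth - a * x**2
        position = n - i if i < n else i - n + 1  # distance from midline
        quadrant = 1 if i < n else 2
        fdi = 10 * quadrant + position
        tangent = np.array([1.0, -2.0 * a * x, 0.0])
        tangent /= np.linalg.norm(tangent)
        teeth.append((fdi, np.array([x, y, spec.crown_height / 2.0]), tangent,
                      _tooth_class(position)))
    return teeth


def generate_arch(spec: ArchSpec) -> LabeledScan:
    """Generate a labelled upper-arch point cloud (2 quadrants of crowns).

    Deterministic for a given spec (including its seed); teeth are emitted in
    FDI order along the arch, each crown oriented with its mesiodistal axis
    along the local arch tangent.
    """
    rng = np.random.default_rng(spec.seed)
    all_points, all_labels = [], []
    for fdi, center, tangent, cls in _arch_positions(spec):
        rx, ry = spec.crown_radii.get(cls, _DEFAULT_CROWN_RADII[cls])
        p = _CROWN_EXPONENT[cls]
        local = _superellipsoid_points(rng, spec.points_per_tooth,
                                       rx, ry, spec.crown_height / 2.0, p)
        # rotate the local mesiodistal (x) axis onto the arch tangent
        z = np.array([0.0, 0.0, 1.0])
        ybl = np.cross(z, tangent)
        basis = np.column_stack([tangent, ybl, z])
        all_points.append(local @ basis.T + center)
        all_labels.append(np.full(spec.points_per_tooth, fdi, dtype=int))
    return LabeledScan(np.vstack(all_points), np.concatenate(all_labels))


def apply_movement(scan: LabeledScan, movement: GroundTruthMovement,
                   frame: ArchFrame) -> LabeledScan:
    """Rigidly move one tooth; all other points stay bit-identical.

    The motion rotates by (Rx, Ry, Rz) about the frame axes at the movement's
    center, then translates along the frame axes — the exact inverse of what
    the measurement pipeline decomposes.
    """
    mask = scan.labels == movement.tooth_id
    if not mask.any():
        raise KeyError(f"tooth {movement.tooth_id} not present in scan")
    c = movement.components
    if all(v == 0.0 for v in (c.Tx, c.Ty, c.Tz, c.Rx, c.Ry, c.Rz)):
        return scan  # exact identity: keep untouched points bit-identical
    T = movement_transform(movement.components, frame, center=movement.center)
    points = scan.points.copy()
    points[mask] = T.apply(points[mask])
    return scan.with_points(points)


def add_scan_noise(scan: LabeledScan, sigma: float, seed: int) -> LabeledScan:
    """Isotropic zero-mean Gaussian jitter per point (scanner accuracy)."""
    if sigma < 0:
        raise ConfigurationError("noise sigma must be >= 0")
    if sigma == 0:
        return scan
    rng = np.random.default_rng(seed)
    return scan.with_points(scan.points + rng.normal(0.0, sigma, scan.points.shape))


# ---------------------------------------------------------------------------
# cohort generation

#: moved tooth per group and hemiarch (FDI): central incisor for torque,
#: first premolar for derotation, first molar for distalization
_MOVED_POSITION = {"torque": 1, "derotation": 4, "distalization": 6}


def moved_tooth_for(group: str, quadrant: int) -> int:
    return 10 * quadrant + _MOVED_POSITION[group]


def arch_frame_for_tooth(scan: LabeledScan, tooth_id: int,
                         exclude=()) -> ArchFrame:
    """Patient frame for one tooth from a labelled scan (reference = the rest)."""
    reference = [t for t in scan.tooth_ids if t != tooth_id and t not in exclude]
    centroids = np.array([scan.tooth_centroid(t) for t in reference])
    return build_frame(centroids, scan.tooth_centroid(tooth_id))


def _planned_components(group: str, magnitude: float) -> MovementComponents:
    comp = {"torque": "Ry", "derotation": "Rz", "distalization": "Tx"}[group]
    return MovementComponents(**{comp: magnitude})


def _scaled(components: MovementComponents, factor: float) -> MovementComponents:
    return MovementComponents(*(factor * v for v in
                                (components.Tx, components.Ty, components.Tz,
                                 components.Rx, components.Ry, components.Rz)))


def _random_pose(rng, max_angle_deg=5.0, max_shift=5.0) -> RigidTransform:
    """A modest random rigid motion emulating independent scanner placement."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, rng.uniform(-max_shift, max_shift, size=3))


def _draw_efficacy(rng, mean, sd):
    if sd == 0:
        return float(np.clip(mean, *EFFICACY_BOUNDS))
    lo, hi = EFFICACY_BOUNDS
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


def generate_cohort(configs, arch_spec: ArchSpec | None = None,
                    scanner_pose_jitter: bool = True):
    """Simulate a split-mouth cohort of patient scan triplets.

    Configs of the same movement group are paired across hemiarchs: the first
    config's movements go on quadrant 1 (patient right), the second's on
    quadrant 2, so each patient carries up to two isolated movements with all
    remaining teeth untouched (the reference structure).  Per movement a true
    efficacy is drawn; ClinT2 applies the full planned movement to T1's
    geometry, T2 the efficacy-scaled one.  Independent scanner noise is added
    to every scan, and (optionally) T2/ClinT2 receive a random global pose.

    Returns (triplets, ground_truths, manifest): ``triplets`` maps patient_id
    to (T1, T2, ClinT2) LabeledScans, ``ground_truths`` maps (patient_id,
    tooth_id) to the planned GroundTruthMovement, and ``manifest`` is a
    DataFrame with one row per movement.
    """
    configs = list(configs)
    if not configs:
        raise ConfigurationError("need at least one CohortConfig")
    base_spec = arch_spec or ArchSpec()
    by_group: dict[str, list[CohortConfig]] = {}
    for cfg in configs:
        by_group.setdefault(cfg.group, []).append(cfg)
    for group, cfgs in by_group.items():
        if len(cfgs) > 2:
            raise ConfigurationError(
                f"at most two subgroups (hemiarchs) per group, got {len(cfgs)} for {group}")

    ss = np.random.SeedSequence([int(c.seed) for c in configs])
    triplets: dict[str, tuple] = {}
    truths: dict[tuple, GroundTruthMovement] = {}
    rows = []
    for group in sorted(by_group):
        cfgs = by_group[group]
        n_patients = max(c.count for c in cfgs)
        for k in range(n_patients):
            pid = f"{group[:4]}{k + 1:03d}"
            child = np.random.default_rng(ss.spawn(1)[0])
            seeds = child.integers(0, 2**31 - 1, size=8)
            spec = ArchSpec(
                n_teeth_per_quadrant=base_spec.n_teeth_per_quadrant,
                arch_width=base_spec.arch_width, arch_depth=base_spec.arch_depth,
                crown_height=base_spec.crown_height,
                crown_radii=base_spec.crown_radii,
                points_per_tooth=base_spec.points_per_tooth, seed=int(seeds[0]))
            base = generate_arch(spec)
            movements = []  # (config, tooth, planned, efficacy)
            for quadrant, cfg in zip((1, 2), cfgs):
                if k >= cfg.count:
                    continue
                tooth = moved_tooth_for(group, quadrant)
                lo, hi = cfg.planned_magnitude_range
                magnitude = float(child.uniform(lo, hi))
                eff = _draw_efficacy(child, cfg.true_efficacy_mean, cfg.true_efficacy_sd)
                movements.append((cfg, tooth, magnitude, eff))
            if not movements:
                continue
            moved_ids = [t for _, t, _, _ in movements]
            clin = base
            achieved = base
            for cfg, tooth, magnitude, eff in movements:
                frame = arch_frame_for_tooth(base, tooth, exclude=moved_ids)
                planned = _planned_components(group, magnitude)
                gt = GroundTruthMovement(tooth, planned, base.tooth_centroid(tooth))
                truths[(pid, tooth)] = gt
                clin = apply_movement(clin, gt, frame)
                achieved = apply_movement(
                    achieved,
                    GroundTruthMovement(tooth, _scaled(planned, eff), gt.center),
                    frame)
                rows.append({
                    "patient_id": pid, "group": group, "subgroup": cfg.subgroup,
                    "moved_tooth": tooth,
                    "planned_Tx": planned.Tx, "planned_Ty": planned.Ty,
                    "planned_Tz": planned.Tz, "planned_Rx": planned.Rx,
                    "planned_Ry": planned.Ry, "planned_Rz": planned.Rz,
                    "planned_total": magnitude,
                    "staging_per_aligner": cfg.staging_per_aligner,
                    "n_aligners": math.ceil(magnitude / cfg.staging_per_aligner),
                    "compliance_hours": 22.0,
                    "true_efficacy": eff,
                })
            sigma = movements[0][0].noise_sigma
            t1 = add_scan_noise(base, sigma, int(seeds[1]))
            t2 = add_scan_noise(achieved, sigma, int(seeds[2]))
            clin_noisy = add_scan_noise(clin, sigma, int(seeds[3]))
            if scanner_pose_jitter:
                pose_rng = np.random.default_rng(int(seeds[4]))
                g2 = _random_pose(pose_rng)
                g3 = _random_pose(pose_rng)
                t2 = t2.with_points(g2.apply(t2.points))
                clin_noisy = clin_noisy.with_points(g3.apply(clin_noisy.points))
            triplets[pid] = (
                LabeledScan(t1.points, t1.labels, patient_id=pid, timepoint="T1"),
                LabeledScan(t2.points, t2.labels, patient_id=pid, timepoint="T2"),
                LabeledScan(clin_noisy.points, clin_noisy.labels,
                            patient_id=pid, timepoint="ClinT2"),
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return triplets, truths, manifest


def study_configs(seed: int = 0, n_per_subgroup: int = 10,
                  noise_sigma: float = 0.020):
    """The six subgroup conditions of the study, as CohortConfigs.

    Planned-magnitude ranges are uniform intervals whose midpoints match the
    study's mean planned movements (derotation 17.8°/20.1°, distalization
    2.7/2.6 mm, torque 16.1°/15.9°) and whose upper ends respect the maxima;
    true-efficacy means and SDs match the observed subgroup accuracies.
    Torque staging is capped at the protocol's 1°/aligner.
    """
    base = dict(count=n_per_subgroup, noise_sigma=noise_sigma)
    entries = [
        ("derotation", "attachment", (10.6, 25.0), 1.1, 0.375, 0.30),
        ("derotation", "none", (10.2, 30.0), 1.2, 0.424, 0.30),
        ("distalization", "attachment", (2.2, 3.2), 0.25, 0.884, 0.20),
        ("distalization", "none", (2.0, 3.2), 0.25, 0.869, 0.20),
        ("torque", "attachment", (10.0, 22.2), 1.0, 0.491, 0.20),
        ("torque", "power_ridge", (10.0, 21.8), 1.0, 0.515, 0.20),
    ]
    return [
        CohortConfig(group=g, subgroup=s, planned_magnitude_range=rng_,
                     staging_per_aligner=st, true_efficacy_mean=m,
                     true_efficacy_sd=sd, seed=seed + i, **base)
        for i, (g, s, rng_, st, m, sd) in enumerate(entries)
    ]
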