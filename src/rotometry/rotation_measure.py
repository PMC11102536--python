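"""Occlusal-plane definition, vector projection, and signed rotation angles.

The prescribed rotation of a tooth is the angle between its T0 landmark
vector and the same vector carried to T1 by the per-tooth best fit, both
projected onto the occlusal plane defined on T0; the achieved rotation is
the T0/T2 analogue.  Both are finally re-signed so the prescribed angle is
non-negative and the achieved angle is expressed relative to the prescribed
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateConfigurationError,
    DegenerateVectorError,
    InvalidInputError,
)
from .mesh_core import LANDMARK_ROLES, Landmark, TriangleMesh, tooth_type_for_fdi
from .registration import (
    AlignmentResult,
    RigidTransform,
    SurfaceIndex,
    global_best_fit,
    three_point_align,
    tooth_best_fit,
    transfer_landmarks,
)

_MIN_PROJECTED_LEN_MM = 1e-9


@dataclass
class OcclusalPlane:
    """Reference plane with unit normal oriented toward the crowns."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            self.normal = self.normal / n
        if not np.isfinite(self.normal).all() or np.linalg.norm(self.normal) == 0:
            raise InvalidInputError("plane normal must be a finite unit vector")


@dataclass
class ToothVector:
    tooth: int
    frame: str
    direction: np.ndarray

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=np.float64)
        if np.linalg.norm(self.direction) == 0:
            raise InvalidInputError(f"tooth {self.tooth}: zero-length landmark vector")


@dataclass
class AngleMeasurement:
    """Per-tooth prescribed (T0->T1) and achieved (T0->T2) angles, degrees."""

    tooth: int
    prescribed: float
    achieved: float
    tooth_type: str = ""
    arch: str = ""
    case_id: str = ""


def occlusal_plane(p1, p2, p3, crown_points=None) -> OcclusalPlane:
    """Plane through three alignment points.

    With ``crown_points`` given (array of crown landmark positions), the
    normal is oriented so their mean lies on the positive side.
    """
    p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1.0)
    if np.linalg.norm(n) < 1e-9 * scale**2:
        raise DegenerateConfigurationError("occlusal plane points are collinear")
    n = n / np.linalg.norm(n)
    if crown_points is not None:
        ref = np.asarray(crown_points, dtype=np.float64).reshape(-1, 3).mean(axis=0)
        if np.dot(ref - p1, n) < 0:
            n = -n
    return OcclusalPlane(origin=p1, normal=n)


def project_vector(v, plane: OcclusalPlane) -> np.ndarray:
    """Remove the normal component of ``v``; error if nothing in-plane remains."""
    v = np.asarray(v, dtype=np.float64)
    if not np.isfinite(v).all():
        raise InvalidInputError("cannot project a non-finite vector")
    proj = v - np.dot(v, plane.normal) * plane.normal
    if np.linalg.norm(proj) < _MIN_PROJECTED_LEN_MM:
        raise DegenerateVectorError(
            "vector is perpendicular to the occlusal plane (no in-plane component)"
        )
    return proj


def signed_rotation_angle(v_ref, v_obs, plane: OcclusalPlane) -> float:
    """Signed angle from ``v_ref`` to ``v_obs`` about the plane normal, degrees.

    Positive is counter-clockwise viewed from the occlusal side; range
    (-180, 180].
    """
    ref = v_ref.direction if isinstance(v_ref, ToothVector) else v_ref
    obs = v_obs.direction if isinstance(v_obs, ToothVector) else v_obs
    u = project_vector(ref, plane)
    w = project_vector(obs, plane)
    angle = np.degrees(
        np.arctan2(np.dot(plane.normal, np.cross(u, w)), np.dot(u, w))
    )
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def landmark_vector(landmarks: list[Landmark], tooth: int, frame: str) -> ToothVector:
    """Vector from the tail landmark to the head landmark of one tooth."""
    tail_role, head_role = LANDMARK_ROLES[tooth_type_for_fdi(tooth)]
    pos = {lm.role: lm.position for lm in landmarks if lm.tooth == tooth}
    if tail_role not in pos or head_role not in pos:
        raise InvalidInputError(
            f"tooth {tooth} lacks its {tail_role}/{head_role} landmark pair"
        )
    return ToothVector(tooth, frame, pos[head_role] - pos[tail_role])


# ---------------------------------------------------------------------------
# Case-level superimposition and measurement
# ---------------------------------------------------------------------------


@dataclass
class RegistrationSettings:
    """Knobs of the global and per-tooth best fits.

    The whole-arch best fit is capped at 50 iterations; the per-tooth fit
    has no published cap and point-to-point ICP converges slowly in
    rotation, so it gets a generous ceiling with an RMS-improvement early
    stop.
    """

    max_iterations: int = 50
    tooth_max_iterations: int = 1000
    tol_mm: float = 1e-7
    tooth_tol_mm: float = 1e-9
    sample_size: int = 5000
    global_trim_fraction: float = 0.0
    tooth_trim_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1 or self.tooth_max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")
        for f in (self.global_trim_fraction, self.tooth_trim_fraction):
            if not 0.0 <= f < 1.0:
                raise InvalidInputError("trim fractions must be in [0, 1)")


@dataclass
class CaseFits:
    """Global and per-tooth alignments of T1 and T2 onto the T0 frame."""

    global_fit: dict  # frame -> AlignmentResult (frame mesh onto T0)
    tooth_fits: dict  # frame -> {fdi -> AlignmentResult (T0 tooth -> frame pose in T0 coords)}
    problems: list = field(default_factory=list)


def fit_case(case, settings: RegistrationSettings | None = None) -> CaseFits:
    """Run the full superimposition for one case.

    For each follow-up frame: 3-point initial alignment onto T0, global best
    fit, then a per-tooth surface best fit of every segmented T0 tooth
    against the aligned follow-up mesh.
    """
    settings = settings or RegistrationSettings()
    t0 = case.meshes["T0"]
    global_fit: dict[str, AlignmentResult] = {}
    tooth_fits: dict[str, dict[int, AlignmentResult]] = {}
    problems: list[tuple] = []
    for frame in ("T1", "T2"):
        moving = case.meshes[frame]
        init = three_point_align(case.init_points(frame), case.init_points("T0"))
        g = global_best_fit(
            moving,
            t0,
            init=init,
            max_iterations=settings.max_iterations,
            tol=settings.tol_mm,
            sample_size=settings.sample_size,
            trim_fraction=settings.global_trim_fraction,
            seed=settings.seed,
        )
        global_fit[frame] = g
        aligned = TriangleMesh(g.transform.apply(moving.vertices), moving.faces)
        surface = SurfaceIndex(aligned)
        fits: dict[int, AlignmentResult] = {}
        for fdi in case.labels.teeth:
            try:
                fits[fdi] = tooth_best_fit(
                    fdi,
                    t0,
                    case.labels,
                    aligned,
                    init=RigidTransform.identity(),
                    max_iterations=settings.tooth_max_iterations,
                    tol=settings.tooth_tol_mm,
                    sample_size=settings.sample_size,
                    trim_fraction=settings.tooth_trim_fraction,
                    seed=settings.seed,
                    surface=surface,
                )
            except Exception as exc:  # quarantine the tooth, keep the case
                problems.append((frame, fdi, repr(exc)))
        tooth_fits[frame] = fits
    return CaseFits(global_fit=global_fit, tooth_fits=tooth_fits, problems=problems)


def measure_case(case, fits: CaseFits) -> tuple[list[AngleMeasurement], list[tuple]]:
    """Per-tooth prescribed and achieved rotation angles for one case.

    Returns ``(measurements, problems)``; teeth with missing fits or
    degenerate vectors are recorded in ``problems`` and skipped.
    """
    p1, p2, p3 = case.init_points("T0")
    plane = occlusal_plane(
        p1, p2, p3, crown_points=[lm.position for lm in case.landmarks_T0]
    )
    measurements: list[AngleMeasurement] = []
    problems = list(fits.problems)
    for fdi in case.labels.teeth:
        try:
            lms = [lm for lm in case.landmarks_T0 if lm.tooth == fdi]
            v0 = landmark_vector(lms, fdi, "T0")
            angles = {}
            for frame in ("T1", "T2"):
                fit = fits.tooth_fits[frame].get(fdi)
                if fit is None:
                    raise InvalidInputError(f"no {frame} fit for tooth {fdi}")
                moved = transfer_landmarks(lms, fit, frame)
                v = landmark_vector(moved, fdi, frame)
                angles[frame] = signed_rotation_angle(v0, v, plane)
            sign = 1.0 if angles["T1"] >= 0 else -1.0
            measurements.append(
                AngleMeasurement(
                    tooth=fdi,
                    prescribed=sign * angles["T1"],
                    achieved=sign * angles["T2"],
                    tooth_type=case.labels.tooth_type[fdi],
                    arch=case.arch,
                    case_id=case.case_id,
                )
            )
        except Exception as exc:
            problems.append(("measure", fdi, repr(exc)))
    return measurements, problems


def measure_arch(case, settings: RegistrationSettings | None = None):
    """Convenience wrapper: ``fit_case`` + ``measure_case``."""
    return measure_case(case, fit_case(case, settings))


def measurements_to_frame(measurements: list[AngleMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": m.case_id,
                "arch": m.arch,
                "fdi": m.tooth,
                "tooth_type": m.tooth_type,
                "prescribed_deg": m.prescribed,
                "achieved_deg": m.achieved,
            }
            for m in measurements
        ]
    )


def measurements_from_frame(df: pd.DataFrame) -> list[AngleMeasurement]:
    return [
        AngleMeasurement(
            tooth=int(r.fdi),
            prescribed=float(r.prescribed_deg),
            achieved=float(r.achieved_deg),
            tooth_type=str(r.tooth_type),
            arch=str(r.arch),
            case_id=str(r.case_id),
        )
        for r in df.itertuples()
    ]
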