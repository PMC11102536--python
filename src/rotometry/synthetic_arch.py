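"""Synthetic dental-arch cases with known ground-truth rotations.

Each case is a T0/T1/T2 mesh triplet sharing one topology: crown templates
are placed along a parabolic arch (T0), every tooth is rotated about the
occlusal-plane normal through its centroid by a prescribed angle (T1) and by
an achieved angle — prescribed times an accuracy factor plus angular noise
(T2) — and both follow-up models then receive an independent whole-arch
rigid pose perturbation and optional vertex jitter mimicking scanner error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from .errors import GenerationError, InvalidInputError
from .mesh_core import (
    TOOTH_TYPES,
    Landmark,
    ToothLabelMap,
    TriangleMesh,
    landmarks_from_json,
    landmarks_to_json,
    load_labels,
    read_stl,
    save_labels,
    write_stl,
)
from .registration import RigidTransform

# Crown bounding dimensions (mesiodistal, buccolingual, height), mm.
_TOOTH_DIMS = {
    "central_incisor": (8.5, 5.2, 10.0),
    "lateral_incisor": (6.6, 4.8, 9.5),
    "canine": (7.6, 6.0, 10.5),
    "first_premolar": (7.0, 9.0, 8.5),
    "second_premolar": (6.8, 9.2, 8.0),
    "first_molar": (10.8, 10.2, 7.5),
    "second_molar": (10.2, 10.0, 7.0),
}

# Prescription distributions per arch and tooth type: (mean, SD) in degrees,
# emulating the magnitudes reported for rotation plans in adult aligner cases.
PRESCRIPTION_DEFAULTS = {
    "mandibular": {
        "central_incisor": (8.79, 5.84),
        "lateral_incisor": (10.77, 9.50),
        "canine": (11.03, 6.94),
        "first_premolar": (11.48, 7.02),
        "second_premolar": (10.18, 11.25),
        "first_molar": (5.55, 2.99),
        "second_molar": (6.12, 3.58),
    },
    "maxillary": {
        "central_incisor": (7.52, 4.05),
        "lateral_incisor": (7.62, 4.84),
        "canine": (8.32, 6.21),
        "first_premolar": (6.92, 3.56),
        "second_premolar": (7.85, 5.84),
        "first_molar": (10.35, 5.50),
        "second_molar": (10.14, 6.88),
    },
}

# Mean achieved/prescribed accuracy factor per arch and tooth type.
ACCURACY_DEFAULTS = {
    "mandibular": {
        "central_incisor": 0.8834,
        "lateral_incisor": 0.8961,
        "canine": 0.7813,
        "first_premolar": 0.7114,
        "second_premolar": 0.7339,
        "first_molar": 0.7468,
        "second_molar": 0.7094,
    },
    "maxillary": {
        "central_incisor": 0.7555,
        "lateral_incisor": 0.7390,
        "canine": 0.7359,
        "first_premolar": 0.7921,
        "second_premolar": 0.8203,
        "first_molar": 0.7839,
        "second_molar": 0.6070,
    },
}


@dataclass
class GeneratorConfig:
    """Everything the arch generator needs; same config + seed => same bytes."""

    seed: int = 0
    arch: str = "mandibular"
    case_id: str = "case-000"
    arch_half_width_mm: float = 27.0
    arch_depth_mm: float = 42.0
    gap_mm: float = 0.8
    prescribed_mean_sd: dict = None  # tooth type -> (mean, sd) degrees
    prescribed_floor_deg: float = 2.0
    accuracy_mean: dict = None  # tooth type -> mean factor
    accuracy_sd: float = 0.3
    accuracy_bounds: tuple = (-0.5, 1.5)
    achieved_noise_sd_deg: float = 1.0
    jitter_sd_mm: float = 0.05
    global_rot_max_deg: float = 5.0
    global_trans_max_mm: float = 5.0

    def __post_init__(self):
        if self.arch not in ("mandibular", "maxillary"):
            raise InvalidInputError(f"unknown arch {self.arch!r}")
        if self.prescribed_mean_sd is None:
            self.prescribed_mean_sd = dict(PRESCRIPTION_DEFAULTS[self.arch])
        if self.accuracy_mean is None:
            self.accuracy_mean = dict(ACCURACY_DEFAULTS[self.arch])
        for t, (m, s) in self.prescribed_mean_sd.items():
            if s < 0:
                raise InvalidInputError(f"negative prescription SD for {t}")
        if self.prescribed_floor_deg < 0 or self.accuracy_sd < 0 or self.jitter_sd_mm < 0:
            raise InvalidInputError("SDs and floor must be non-negative")


@dataclass
class ToothTruth:
    fdi: int
    tooth_type: str
    prescribed_deg: float
    achieved_deg: float
    axis: np.ndarray
    pivot: np.ndarray


@dataclass
class SyntheticGroundTruth:
    teeth: list
    global_T1: RigidTransform
    global_T2: RigidTransform
    jitter_sd_mm: float
    seed: int

    def by_fdi(self) -> dict[int, ToothTruth]:
        return {t.fdi: t for t in self.teeth}


@dataclass
class ArchCase:
    case_id: str
    arch: str
    meshes: dict  # "T0"/"T1"/"T2" -> TriangleMesh
    labels: ToothLabelMap
    landmarks_T0: list
    init_vertex_ids: np.ndarray  # 3 shared-topology vertex ids of the alignment points

    def init_points(self, frame: str) -> np.ndarray:
        """The three alignment points (molar cusps + incisor point) in ``frame``."""
        return self.meshes[frame].vertices[self.init_vertex_ids]


# ---------------------------------------------------------------------------
# Crown templates
# ---------------------------------------------------------------------------


def _superellipsoid_cloud(md, bl, h, n_u=5, n_v=14, p=0.62):
    """Boxy convex crown blank spanning z in [0, h].

    Deliberately coarse: large facets interpolate vertex jitter away, which
    keeps the surface-based best fit well conditioned under scanner noise
    (fine tessellations make the noisy surface jagged and bias the fit).
    """
    a, b, c = md / 2.0, bl / 2.0, h / 2.0
    u = np.linspace(-np.pi / 2, np.pi / 2, n_u + 2)[1:-1]
    v = np.linspace(0.0, 2 * np.pi, n_v, endpoint=False)
    uu, vv = np.meshgrid(u, v, indexing="ij")

    def sgnpow(x, e):
        return np.sign(x) * np.abs(x) ** e

    x = a * sgnpow(np.cos(uu), p) * sgnpow(np.cos(vv), p)
    y = b * sgnpow(np.cos(uu), p) * sgnpow(np.sin(vv), p)
    z = c * sgnpow(np.sin(uu), p) + c
    pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    poles = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, h]])
    return np.vstack([pts, poles])


def _canonicalize(vertices: np.ndarray, faces: np.ndarray):
    """Reorder vertices by first occurrence in the face list.

    Guarantees that writing the mesh as an STL triangle soup and re-welding
    it reproduces the exact same vertex indexing.
    """
    order = []
    seen = np.full(len(vertices), -1, dtype=np.int64)
    for idx in faces.ravel():
        if seen[idx] < 0:
            seen[idx] = len(order)
            order.append(idx)
    order = np.asarray(order, dtype=np.int64)
    if len(order) != len(vertices):
        raise GenerationError("template has vertices unused by any face")
    return vertices[order], seen[faces]


def _hull_mesh(cloud: np.ndarray) -> TriangleMesh:
    hull = ConvexHull(cloud)
    used = hull.vertices
    remap = np.full(len(cloud), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = cloud[used]
    faces = remap[hull.simplices]
    # Enforce outward winding (ConvexHull does not guarantee orientation).
    centroid = verts.mean(axis=0)
    tri = verts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", normals, tri.mean(axis=1) - centroid) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    verts, faces = _canonicalize(verts, faces)
    return TriangleMesh(verts, faces)


def make_tooth_template(tooth_type: str, dims: tuple | None = None):
    """Build a closed crown-like mesh with unambiguous landmark features.

    Returns ``(mesh, features)`` where ``features`` maps feature names to
    template-frame points that are exact mesh vertices.  Template frame:
    +x mesial (canonical left-quadrant convention), +y buccal, +z occlusal;
    the crown base sits at z = 0.

    Features: incisors/canines get incisal-edge corners ``edge+x``/``edge-x``;
    premolars get ``cusp+y``/``cusp-y``; molars get four corner cusps
    ``cusp±x±y`` (of which the disto-vestibular and mesio-lingual pair define
    the measurement vector and the mesio-buccal one serves as an alignment
    fiducial).
    """
    if tooth_type not in TOOTH_TYPES:
        raise InvalidInputError(f"unknown tooth type {tooth_type!r}")
    md, bl, h = dims if dims is not None else _TOOTH_DIMS[tooth_type]
    cloud = _superellipsoid_cloud(md, bl, h)
    feats: dict[str, np.ndarray] = {}
    if tooth_type in ("central_incisor", "lateral_incisor", "canine"):
        # Incisal ridge along the mesiodistal axis, highest at the corners'
        # inner neighbours so the end points stay extremal hull vertices.
        xe = md / 2.0 - 0.4
        ridge_x = np.linspace(-xe, xe, 7)
        ridge_z = h + 1.1 - 0.35 * (ridge_x / xe) ** 2
        ridge = np.column_stack([ridge_x, np.zeros_like(ridge_x), ridge_z])
        cloud = np.vstack([cloud, ridge])
        feats["edge+x"] = ridge[-1]
        feats["edge-x"] = ridge[0]
    elif tooth_type in ("first_premolar", "second_premolar"):
        buccal = np.array([0.0, bl / 2.0 - 1.1, h + 1.7])
        lingual = np.array([0.0, -(bl / 2.0 - 1.3), h + 1.1])
        cloud = np.vstack([cloud, buccal[None], lingual[None]])
        feats["cusp+y"] = buccal
        feats["cusp-y"] = lingual
    else:  # molars: four corner cusps with distinct heights
        cx, cy = md * 0.27, bl * 0.29
        heights = {"cusp+x+y": 1.6, "cusp-x+y": 1.4, "cusp+x-y": 1.2, "cusp-x-y": 1.0}
        for name, dz in heights.items():
            sx = 1.0 if "+x" in name else -1.0
            sy = 1.0 if "+y" in name else -1.0
            p = np.array([sx * cx, sy * cy, h + dz])
            cloud = np.vstack([cloud, p[None]])
            feats[name] = p
    mesh = _hull_mesh(cloud)
    # Features must survive as exact hull vertices.
    for name, p in feats.items():
        d = np.linalg.norm(mesh.vertices - p, axis=1).min()
        if d > 1e-9:
            raise GenerationError(f"{tooth_type} feature {name} lost by hull (d={d:.2g})")
    return mesh, feats


_TEMPLATE_CACHE: dict[str, tuple] = {}


def _template(tooth_type: str):
    if tooth_type not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[tooth_type] = make_tooth_template(tooth_type)
    return _TEMPLATE_CACHE[tooth_type]


def _roles_for_side(tooth_type: str, right_side: bool, feats: dict) -> dict:
    """Resolve anatomical landmark roles to template feature points.

    In the template frame +x points toward world +x after placement; that is
    mesial for left-quadrant teeth and distal for right-quadrant teeth.
    """
    m, d = ("-x", "+x") if right_side else ("+x", "-x")
    if tooth_type in ("central_incisor", "lateral_incisor", "canine"):
        return {"mesial-point": feats[f"edge{m}"], "distal-point": feats[f"edge{d}"]}
    if tooth_type in ("first_premolar", "second_premolar"):
        return {"buccal-cusp": feats["cusp+y"], "lingual-cusp": feats["cusp-y"]}
    return {
        "disto-vestibular-cusp": feats[f"cusp{d}+y"],
        "mesio-lingual-cusp": feats[f"cusp{m}-y"],
    }


# ---------------------------------------------------------------------------
# Arch assembly
# ---------------------------------------------------------------------------

#: Tooth-type digit sequence from the midline outward (FDI last digit 1..7).
_QUADRANT_SEQUENCE = tuple(range(1, 8))


def _arch_fdi_codes(arch: str) -> list[int]:
    """All 14 FDI codes, right quadrant then left, midline outward."""
    right_q, left_q = (4, 3) if arch == "mandibular" else (1, 2)
    return [right_q * 10 + d for d in _QUADRANT_SEQUENCE] + [
        left_q * 10 + d for d in _QUADRANT_SEQUENCE
    ]


def _arch_layout(config: GeneratorConfig):
    """Arc-length positions and local frames for the 14 teeth.

    The arch curve is ``y = depth * (1 - (x / w)^2)`` (anterior at +y); the
    patient's right is world +x < 0?  Convention: right quadrant occupies
    x > 0.  Returns a list of (fdi, tooth_type, position, frame R) where R's
    columns are (along-arch toward +x, buccal, occlusal-up).
    """
    w, depth = config.arch_half_width_mm, config.arch_depth_mm
    if config.gap_mm <= 0:
        raise GenerationError("inter-tooth gap must be positive")
    xs = np.linspace(0.0, 1.6 * w, 4001)
    ys = depth * (1.0 - (xs / w) ** 2)
    seg = np.sqrt(np.diff(xs) ** 2 + np.diff(ys) ** 2)
    s_grid = np.concatenate([[0.0], np.cumsum(seg)])

    def x_at_arclen(s):
        if s > s_grid[-1]:
            raise GenerationError("arch too small for requested teeth")
        return float(np.interp(s, s_grid, xs))

    out = []
    for side_sign, codes in (
        (+1.0, _arch_fdi_codes(config.arch)[:7]),
        (-1.0, _arch_fdi_codes(config.arch)[7:]),
    ):
        s = 0.0
        prev_half = 0.0
        for fdi in codes:
            ttype = TOOTH_TYPES[fdi % 10 - 1]
            md = _TOOTH_DIMS[ttype][0]
            if prev_half == 0.0:
                s = md / 2.0 + config.gap_mm / 2.0
            else:
                s += prev_half + config.gap_mm + md / 2.0
            prev_half = md / 2.0
            x = side_sign * x_at_arclen(s)
            if abs(x) > 1.25 * w:
                raise GenerationError(
                    f"tooth {fdi} falls {abs(x):.1f} mm from midline; arch too small"
                )
            y = depth * (1.0 - (x / w) ** 2)
            dydx = -2.0 * depth * x / w**2
            buccal = np.array([-dydx, 1.0, 0.0])
            buccal /= np.linalg.norm(buccal)
            up = np.array([0.0, 0.0, 1.0])
            along = np.cross(buccal, up)  # unit, points toward +x side
            R = np.column_stack([along, buccal, up])
            out.append((fdi, ttype, np.array([x, y, 0.0]), R, side_sign > 0))
    # Arc-length spacing does not preclude chord overlap on a tight curve:
    # neighbouring crowns must keep their straight-line clearance too.
    ordered = out[6::-1] + out[7:]  # right quadrant reversed, then left
    for (f1, t1, p1, *_), (f2, t2, p2, *_) in zip(ordered, ordered[1:]):
        min_sep = 0.9 * (_TOOTH_DIMS[t1][0] + _TOOTH_DIMS[t2][0]) / 2.0
        if np.linalg.norm(p2 - p1) < min_sep:
            raise GenerationError(
                f"teeth {f1} and {f2} overlap "
                f"({np.linalg.norm(p2 - p1):.1f} mm apart); arch too small"
            )
    return out


def _truncnorm_draw(rng, mean, sd, lower=-np.inf, upper=np.inf):
    if sd == 0:
        return float(np.clip(mean, lower, upper))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


def _random_rigid(rng, rot_max_deg, trans_max_mm) -> RigidTransform:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    angle = np.deg2rad(rng.uniform(0.0, rot_max_deg))
    R = Rotation.from_rotvec(direction * angle).as_matrix()
    t = rng.uniform(-trans_max_mm, trans_max_mm, size=3)
    return RigidTransform(R, t)


def generate_arch(config: GeneratorConfig):
    """Generate one arch case; returns ``(ArchCase, SyntheticGroundTruth)``."""
    rng = np.random.default_rng(config.seed)
    layout = _arch_layout(config)

    verts_parts, faces_parts, assignments = [], [], {}
    tooth_type_map: dict[int, str] = {}
    landmarks: list[Landmark] = []
    feature_vertex_ids: dict[tuple, int] = {}
    offset = 0
    for fdi, ttype, pos, R, right_side in layout:
        tpl_mesh, feats = _template(ttype)
        placed = tpl_mesh.vertices @ R.T + pos
        verts_parts.append(placed)
        faces_parts.append(tpl_mesh.faces + offset)
        assignments[fdi] = np.arange(offset, offset + tpl_mesh.n_vertices)
        tooth_type_map[fdi] = ttype
        for role, p_local in _roles_for_side(ttype, right_side, feats).items():
            landmarks.append(Landmark(fdi, role, R @ p_local + pos, "T0"))
        for name, p_local in feats.items():
            world = R @ p_local + pos
            vid = offset + int(
                np.argmin(np.linalg.norm(tpl_mesh.vertices - p_local, axis=1))
            )
            feature_vertex_ids[(fdi, name)] = vid
        offset += tpl_mesh.n_vertices

    vertices = np.vstack(verts_parts)
    faces = np.vstack(faces_parts)
    t0 = TriangleMesh(vertices, faces)
    labels = ToothLabelMap(assignments, tooth_type_map)

    # Alignment fiducials: mesio-buccal cusps of the right and left first
    # molars plus the mesial incisal point of the right central incisor.
    codes = _arch_fdi_codes(config.arch)
    right_m1, left_m1 = codes[5], codes[12]
    right_ci = codes[0]
    init_ids = np.array(
        [
            feature_vertex_ids[(right_m1, "cusp-x+y")],  # mesio-buccal, right side
            feature_vertex_ids[(left_m1, "cusp+x+y")],  # mesio-buccal, left side
            feature_vertex_ids[(right_ci, "edge-x")],  # mesial edge, right side
        ]
    )

    # Rotation axis: occlusal-plane normal (plane through the three fiducials,
    # oriented toward the crowns).
    p1, p2, p3 = vertices[init_ids]
    normal = np.cross(p2 - p1, p3 - p1)
    normal /= np.linalg.norm(normal)
    lm_mean = np.mean([lm.position for lm in landmarks], axis=0)
    if np.dot(lm_mean - p1, normal) < 0:
        normal = -normal

    teeth_truth: list[ToothTruth] = []
    v1 = vertices.copy()
    v2 = vertices.copy()
    for fdi, ttype, pos, R, right_side in layout:
        mean, sd = config.prescribed_mean_sd[ttype]
        mag = _truncnorm_draw(rng, mean, sd, lower=config.prescribed_floor_deg)
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        prescribed = sign * mag
        factor = _truncnorm_draw(
            rng,
            config.accuracy_mean[ttype],
            config.accuracy_sd,
            *config.accuracy_bounds,
        )
        noise = (
            rng.normal(0.0, config.achieved_noise_sd_deg)
            if config.achieved_noise_sd_deg > 0
            else 0.0
        )
        achieved = prescribed * factor + noise
        idx = assignments[fdi]
        pivot = vertices[idx].mean(axis=0)
        for angle, target in ((prescribed, v1), (achieved, v2)):
            Rot = Rotation.from_rotvec(normal * np.deg2rad(angle)).as_matrix()
            target[idx] = (vertices[idx] - pivot) @ Rot.T + pivot
        teeth_truth.append(
            ToothTruth(fdi, ttype, prescribed, achieved, normal.copy(), pivot)
        )

    g1 = _random_rigid(rng, config.global_rot_max_deg, config.global_trans_max_mm)
    g2 = _random_rigid(rng, config.global_rot_max_deg, config.global_trans_max_mm)
    v1 = g1.apply(v1)
    v2 = g2.apply(v2)
    if config.jitter_sd_mm > 0:
        v1 = v1 + rng.normal(0.0, config.jitter_sd_mm, size=v1.shape)
        v2 = v2 + rng.normal(0.0, config.jitter_sd_mm, size=v2.shape)

    case = ArchCase(
        case_id=config.case_id,
        arch=config.arch,
        meshes={
            "T0": t0,
            "T1": TriangleMesh(v1, faces.copy()),
            "T2": TriangleMesh(v2, faces.copy()),
        },
        labels=labels,
        landmarks_T0=landmarks,
        init_vertex_ids=init_ids,
    )
    truth = SyntheticGroundTruth(
        teeth=teeth_truth,
        global_T1=g1,
        global_T2=g2,
        jitter_sd_mm=config.jitter_sd_mm,
        seed=config.seed,
    )
    return case, truth


# ---------------------------------------------------------------------------
# On-disk case format
# ---------------------------------------------------------------------------


def emit_case(case: ArchCase, truth: SyntheticGroundTruth, directory, mode="binary"):
    """Write STL triplet plus labels / landmarks / truth / case JSON sidecars."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        for frame in ("T0", "T1", "T2"):
            write_stl(case.meshes[frame], directory / f"{frame}.stl", mode=mode)
        save_labels(case.labels, directory / "labels.json")
        (directory / "landmarks_T0.json").write_text(
            json.dumps(landmarks_to_json(case.landmarks_T0))
        )
        (directory / "case.json").write_text(
            json.dumps(
                {
                    "case_id": case.case_id,
                    "arch": case.arch,
                    "init_vertex_ids": case.init_vertex_ids.tolist(),
                }
            )
        )
        (directory / "truth.json").write_text(
            json.dumps(
                {
                    "teeth": [
                        {
                            "fdi": t.fdi,
                            "tooth_type": t.tooth_type,
                            "prescribed_deg": t.prescribed_deg,
                            "achieved_deg": t.achieved_deg,
                            "axis": np.asarray(t.axis).tolist(),
                            "pivot": np.asarray(t.pivot).tolist(),
                        }
                        for t in truth.teeth
                    ],
                    "global_T1": truth.global_T1.to_json_dict(),
                    "global_T2": truth.global_T2.to_json_dict(),
                    "jitter_sd_mm": truth.jitter_sd_mm,
                    "seed": truth.seed,
                }
            )
        )
    except OSError as exc:
        raise OSError(f"cannot write case to {directory}: {exc}") from exc


def load_case(directory):
    """Reload an emitted case; returns ``(ArchCase, SyntheticGroundTruth)``."""
    directory = Path(directory)
    meta = json.loads((directory / "case.json").read_text())
    meshes = {f: read_stl(directory / f"{f}.stl") for f in ("T0", "T1", "T2")}
    labels = load_labels(directory / "labels.json")
    landmarks = landmarks_from_json(
        json.loads((directory / "landmarks_T0.json").read_text())
    )
    case = ArchCase(
        case_id=meta["case_id"],
        arch=meta["arch"],
        meshes=meshes,
        labels=labels,
        landmarks_T0=landmarks,
        init_vertex_ids=np.asarray(meta["init_vertex_ids"], dtype=np.int64),
    )
    td = json.loads((directory / "truth.json").read_text())
    truth = SyntheticGroundTruth(
        teeth=[
            ToothTruth(
                t["fdi"],
                t["tooth_type"],
                t["prescribed_deg"],
                t["achieved_deg"],
                np.asarray(t["axis"]),
                np.asarray(t["pivot"]),
            )
            for t in td["teeth"]
        ],
        global_T1=RigidTransform.from_json_dict(td["global_T1"]),
        global_T2=RigidTransform.from_json_dict(td["global_T2"]),
        jitter_sd_mm=td["jitter_sd_mm"],
        seed=td["seed"],
    )
    return case, truth
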