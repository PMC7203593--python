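"""Rigid-body geometry of lumbar motion segments.

A functional spinal unit (FSU) is modelled as two rigid vertebrae coupled by
an intervertebral disk (a six-degree-of-freedom bushing at the disk centre),
point-to-point ligaments, and two facet contact patches.  A lumbar spine is a
serial chain of such segments above a fixed sacrum.

Coordinate conventions (right-handed, SI units unless noted):

* ``x`` — medio-lateral axis (flexion/extension rotations),
* ``y`` — antero-posterior axis, dorsal positive (lateral-flexion rotations),
* ``z`` — cranio-caudal axis, cranial positive (axial rotations).

Positive rotation about ``x`` tips the cranial vertebra ventrally (flexion).
Body frames coincide with the global frame in the neutral configuration and
have their origin at the body's centre of mass; facet-local landmark
coordinates are in millimetres (forced by the magnitude of the published
surface coefficients), everything else is in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GeometryError",
    "DegenerateLandmarksError",
    "FrameError",
    "Pose",
    "RigidBodyDef",
    "FacetLandmarkSet",
    "FacetFrame",
    "FacetSurfaceDef",
    "LigamentDef",
    "SegmentGeometry",
    "SpineGeometry",
    "LigamentKinematics",
    "fit_facet_surface",
    "ligament_kinematics",
    "LIGAMENT_NAMES",
]

AXES = ("x", "y", "z")

#: Ligaments of the lumbar motion segment: anterior/posterior longitudinal,
#: flaval, intertransverse, capsular (facet capsules), inter- and supraspinous.
LIGAMENT_NAMES = ("ALL", "PLL", "FL", "ITL", "CL", "ISL", "SSL")


class GeometryError(ValueError):
    """Invalid or degenerate geometric input."""


class DegenerateLandmarksError(GeometryError):
    """Facet landmarks do not span the regression design space."""


class FrameError(GeometryError):
    """Landmark sets expressed in different facet-local frames."""


def _vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {a.shape}")
    return a


@dataclass
class Pose:
    """Six-DOF placement of a mobile vertebra relative to its caudal neighbour.

    ``rot`` is a rotation vector in radians (axis scaled by angle) and
    ``trans`` the translation of the disk centre in metres, both expressed in
    the caudal body's frame.  The identity pose is all-zero.
    """

    rot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    trans: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rot = _vec3(self.rot, "rot")
        self.trans = _vec3(self.trans, "trans")
        if np.linalg.norm(self.rot) >= np.pi:
            raise GeometryError("rotation vector magnitude must be < pi")

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix of ``rot``."""
        return Rotation.from_rotvec(self.rot).as_matrix()

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.rot, self.trans])

    @classmethod
    def from_vector(cls, q: np.ndarray) -> "Pose":
        q = np.asarray(q, dtype=float)
        return cls(rot=q[:3].copy(), trans=q[3:6].copy())


def segment_transform(pose: Pose, disk_centre: np.ndarray):
    """Affine map (R, t) taking neutral coordinates of the cranial body to its
    posed coordinates in the caudal frame: ``p -> R (p - d) + d + trans``."""
    R = pose.matrix()
    d = np.asarray(disk_centre, dtype=float)
    t = d + pose.trans - R @ d
    return R, t


@dataclass
class RigidBodyDef:
    """A vertebra: centre of mass (global frame, neutral configuration) and
    named attachment points in the body frame (origin at the com)."""

    name: str
    com: np.ndarray
    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.com = _vec3(self.com, f"{self.name}.com")
        pts = {}
        for label, p in self.points.items():
            if label in pts:
                raise GeometryError(f"duplicate point label {label!r} on body {self.name}")
            pts[label] = _vec3(p, f"{self.name}.points[{label!r}]")
        self.points = pts

    def point_neutral_world(self, label: str) -> np.ndarray:
        """Global-frame position of a named point in the neutral configuration."""
        try:
            return self.com + self.points[label]
        except KeyError:
            raise GeometryError(f"body {self.name!r} has no point {label!r}") from None


@dataclass
class FacetLandmarkSet:
    """Nine digitised landmarks on one articular process, facet-local frame,
    millimetres."""

    points: np.ndarray
    frame_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (9, 3):
            raise GeometryError(
                f"a facet landmark set needs exactly 9 points, got shape {self.points.shape}"
            )


@dataclass
class FacetFrame:
    """Facet-local frame on the caudal body: origin (body frame, metres) and
    row-wise orthonormal axes; local z is the outward surface normal side."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = _vec3(self.origin, "facet frame origin")
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.shape != (3, 3):
            raise GeometryError("facet frame axes must be 3x3")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise GeometryError("facet frame axes must be orthonormal")

    def to_local_mm(self, p_body: np.ndarray) -> np.ndarray:
        return 1000.0 * (self.axes @ (np.asarray(p_body, float) - self.origin))


def _surface_design(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([x**3, y**3, x**2, y**2, np.ones_like(x)])


@dataclass
class FacetSurfaceDef:
    """Mean cubic regression surface of one facet joint plus penalty-contact
    parameters.

    The surface height above the facet-local plane is
    ``f(x, y) = p30 x^3 + p03 y^3 + p20 x^2 + p02 y^2 + p00`` with ``x, y, f``
    in millimetres.  ``probe_points`` are representative contact points on the
    opposing (cranial) articular process, in that body's frame (metres).
    """

    p30: float
    p03: float
    p20: float
    p02: float
    p00: float
    frame: FacetFrame | None = None
    stiffness: float = 12_000.0  # N/m
    damping: float = 4_000.0  # N s/m
    probe_points: np.ndarray | None = None
    fit_rms_sup: float | None = None
    fit_rms_inf: float | None = None

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise GeometryError("facet stiffness must be > 0")
        if self.damping < 0:
            raise GeometryError("facet damping must be >= 0")
        if self.probe_points is not None:
            self.probe_points = np.atleast_2d(np.asarray(self.probe_points, dtype=float))

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.p30, self.p03, self.p20, self.p02, self.p00])

    def height(self, x, y):
        """Surface height f(x, y); inputs and output in millimetres."""
        return (
            self.p30 * np.asarray(x) ** 3
            + self.p03 * np.asarray(y) ** 3
            + self.p20 * np.asarray(x) ** 2
            + self.p02 * np.asarray(y) ** 2
            + self.p00
        )

    def gradient(self, x, y):
        fx = 3 * self.p30 * np.asarray(x) ** 2 + 2 * self.p20 * np.asarray(x)
        fy = 3 * self.p03 * np.asarray(y) ** 2 + 2 * self.p02 * np.asarray(y)
        return fx, fy


def fit_facet_surface(
    landmarks_sup: FacetLandmarkSet,
    landmarks_inf: FacetLandmarkSet,
    *,
    frame: FacetFrame | None = None,
    stiffness: float = 12_000.0,
    damping: float = 4_000.0,
    probe_points: np.ndarray | None = None,
) -> FacetSurfaceDef:
    """Fit the facet contact surface from superior and inferior landmark sets.

    Each nine-point set is fitted by linear least squares with the convex
    cubic basis ``{x^3, y^3, x^2, y^2, 1}``; the contact surface is the
    coefficient-wise mean of the two fits (the "mean regression plane").
    Residual RMS of each individual fit is stored on the result.
    """
    if (
        landmarks_sup.frame_id is not None
        and landmarks_inf.frame_id is not None
        and landmarks_sup.frame_id != landmarks_inf.frame_id
    ):
        raise FrameError(
            f"landmark sets are in different facet-local frames: "
            f"{landmarks_sup.frame_id!r} vs {landmarks_inf.frame_id!r}"
        )

    coeffs, rms = [], []
    for ls in (landmarks_sup, landmarks_inf):
        A = _surface_design(ls.points[:, :2])
        if np.linalg.matrix_rank(A) < 5:
            raise DegenerateLandmarksError(
                "landmarks are degenerate: the cubic design matrix is rank-deficient"
            )
        c, *_ = np.linalg.lstsq(A, ls.points[:, 2], rcond=None)
        r = A @ c - ls.points[:, 2]
        coeffs.append(c)
        rms.append(float(np.sqrt(np.mean(r**2))))
    mean_c = (coeffs[0] + coeffs[1]) / 2.0
    return FacetSurfaceDef(
        p30=float(mean_c[0]),
        p03=float(mean_c[1]),
        p20=float(mean_c[2]),
        p02=float(mean_c[3]),
        p00=float(mean_c[4]),
        frame=frame,
        stiffness=stiffness,
        damping=damping,
        probe_points=probe_points,
        fit_rms_sup=rms[0],
        fit_rms_inf=rms[1],
    )


@dataclass
class LigamentDef:
    """One ligament as a point-to-point cable between two vertebrae.

    ``prestrain`` is the strain (percent) present in the neutral posture;
    negative prestrain means the ligament is slack at neutral.  The rest
    length is derived from the neutral length, ``L0 = L_neutral / (1 +
    prestrain/100)``, so that the neutral-pose strain equals the declared
    prestrain by construction.
    """

    name: str
    side: str  # midline | left | right
    cranial_point: tuple[str, str]  # (body label, point label)
    caudal_point: tuple[str, str]
    prestrain: float = 0.0  # percent
    characteristic: str | None = None  # key into a characteristic set

    def __post_init__(self) -> None:
        if self.side not in ("midline", "left", "right"):
            raise GeometryError(f"ligament side must be midline/left/right, got {self.side!r}")
        if not -20.0 <= self.prestrain <= 20.0:
            raise GeometryError(
                f"{self.name} prestrain {self.prestrain}% outside the physiological [-20, 20]%"
            )
        if self.characteristic is None:
            self.characteristic = self.name

    @property
    def key(self) -> str:
        return self.name if self.side == "midline" else f"{self.name}_{self.side}"


@dataclass
class SegmentGeometry:
    """A functional spinal unit: two vertebrae, disk, ligaments, facets."""

    cranial: RigidBodyDef
    caudal: RigidBodyDef
    disk_centre: np.ndarray
    ligaments: list[LigamentDef] = field(default_factory=list)
    facets: dict[str, FacetSurfaceDef] = field(default_factory=dict)
    csa: float = 1.8e-3  # disk cross-sectional area, m^2

    def __post_init__(self) -> None:
        self.disk_centre = _vec3(self.disk_centre, "disk_centre")
        if self.csa <= 0:
            raise GeometryError(f"csa must be > 0, got {self.csa}")
        zlo, zhi = sorted((self.caudal.com[2], self.cranial.com[2]))
        if not zlo <= self.disk_centre[2] <= zhi:
            raise GeometryError("disk_centre must lie between the two centres of mass along z")
        for lig in self.ligaments:
            self._resolve(lig.cranial_point)
            self._resolve(lig.caudal_point)

    def _resolve(self, ref: tuple[str, str]) -> RigidBodyDef:
        body_label, point_label = ref
        for body in (self.cranial, self.caudal):
            if body.name == body_label:
                body.point_neutral_world(point_label)  # raises if missing
                return body
        raise GeometryError(f"segment has no body named {body_label!r}")

    def body(self, label: str) -> RigidBodyDef:
        if self.cranial.name == label:
            return self.cranial
        if self.caudal.name == label:
            return self.caudal
        raise GeometryError(f"segment has no body named {label!r}")

    def ligament(self, key: str) -> LigamentDef:
        for lig in self.ligaments:
            if lig.key == key or lig.name == key:
                return lig
        raise GeometryError(f"segment has no ligament {key!r}")


@dataclass
class SpineGeometry:
    """A lumbar spine chain: mobile bodies ordered cranial to caudal above a
    fixed sacrum, one segment per adjacent pair, plus muscle cables."""

    bodies: list[RigidBodyDef]
    segments: list[SegmentGeometry]
    muscles: list = field(default_factory=list)  # list[MuscleCableDef]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.bodies) - 1:
            raise GeometryError(
                f"need one segment per adjacent body pair: "
                f"{len(self.bodies)} bodies but {len(self.segments)} segments"
            )

    @property
    def n_mobile(self) -> int:
        return len(self.bodies) - 1

    def segment_index(self, name: str) -> int:
        for i, seg in enumerate(self.segments):
            if f"{seg.cranial.name}-{seg.caudal.name}" == name:
                return i
        raise GeometryError(f"no segment named {name!r}")


@dataclass
class LigamentKinematics:
    length: float  # m
    strain: float  # percent
    line_of_action: np.ndarray  # unit vector of the force on the mobile body
    moment_arm: Mapping[str, float]  # axis -> m, about the disk centre
    attachment_mobile: np.ndarray  # world position of the cranial attachment
    rest_length: float


def ligament_kinematics(
    geom: SegmentGeometry, lig: LigamentDef, pose: Pose
) -> LigamentKinematics:
    """Length, strain, line of action and moment arms of a ligament at a pose.

    The cranial (mobile) body is placed by ``pose`` relative to the fixed
    caudal body.  The line of action is the unit vector of the tensile force
    acting on the mobile body (pointing from its attachment toward the caudal
    attachment).  Moment arms are taken about the disk centre: the torque
    about axis ``a`` per unit tension is ``moment_arm[a]``.
    """
    p_cr_neutral = geom._resolve(lig.cranial_point).point_neutral_world(lig.cranial_point[1])
    p_ca = geom._resolve(lig.caudal_point).point_neutral_world(lig.caudal_point[1])

    L_neutral = float(np.linalg.norm(p_cr_neutral - p_ca))
    if L_neutral <= 0:
        raise GeometryError(f"ligament {lig.key} has zero neutral length")
    L0 = L_neutral / (1.0 + lig.prestrain / 100.0)

    R, t = segment_transform(pose, geom.disk_centre)
    p_cr = R @ p_cr_neutral + t
    delta = p_ca - p_cr
    length = float(np.linalg.norm(delta))
    if length <= 0:
        raise GeometryError(f"ligament {lig.key} collapsed to zero length")
    u = delta / length  # force direction on the mobile body
    strain = 100.0 * (length - L0) / L0

    d_world = geom.disk_centre + pose.trans  # disk centre moves with the joint
    arm = np.cross(p_cr - d_world, u)
    return LigamentKinematics(
        length=length,
        strain=strain,
        line_of_action=u,
        moment_arm={"x": float(arm[0]), "y": float(arm[1]), "z": float(arm[2])},
        attachment_mobile=p_cr,
        rest_length=L0,
    )
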