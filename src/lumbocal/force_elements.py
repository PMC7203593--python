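"""Constitutive laws of the motion-segment force elements.

The intervertebral disk is a nonlinear six-DOF bushing: a quadratic
compression-only axial spring, linear shear springs, and a per-direction
tanh-cubic torque law

    T_spring(phi) = p1 * tanh(phi^3 / p2) + p3 * phi      (phi in radians)

with separate flexion and extension parameter rows (the segment is
asymmetric in the sagittal plane) and a single odd characteristic each for
lateral flexion and axial rotation.  Ligaments follow a softplus
force-strain law

    F_spring(eps) = a * ln(exp((eps + b) / d) + 1) + c    (eps in percent)

which reproduces the nonlinear toe zone with a quasi-linear region of slope
a/d at high strain.  Facet contact is a penalty spring-damper acting along
the local normal of the fitted regression surface.  Muscles are constant
pull, length-independent cables.  All damping terms are linear in the rate
and vanish at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AXES, FacetSurfaceDef, GeometryError, Pose, segment_transform

__all__ = [
    "DiskCharacteristic",
    "LigamentCharacteristic",
    "MuscleCableDef",
    "DiskRotParams",
    "disk_force",
    "disk_torque",
    "ligament_force",
    "ligament_stiffness",
    "facet_force",
    "facet_penetrations",
    "muscle_wrench",
    "idp_from_force",
    "IDP_STRESS_FACTOR",
    "default_characteristics",
]

ROT_DIRECTIONS = ("flexion", "extension", "lateral", "axial")

#: Intradiscal pressure to mean axial stress ratio (Brinckmann-type
#: correlation; comparable reported values range roughly 1.3-1.8).
IDP_STRESS_FACTOR = 1.68


@dataclass(frozen=True)
class DiskRotParams:
    """One row of the disk torque law: T = p1 tanh(phi^3/p2) + p3 phi."""

    p1: float  # Nm
    p2: float  # rad^3
    p3: float  # Nm/rad

    def __post_init__(self) -> None:
        if self.p2 == 0:
            raise ValueError("disk torque parameter p2 must be nonzero")

    def torque(self, phi):
        """Spring torque (Nm) at angle ``phi`` (radians, magnitude convention)."""
        phi = np.asarray(phi, dtype=float)
        return self.p1 * np.tanh(phi**3 / self.p2) + self.p3 * phi


@dataclass
class DiskCharacteristic:
    """Full parameter set of the disk bushing."""

    rot: dict[str, DiskRotParams]
    axial_quad: float = 690_234_060.0  # N/m^2
    axial_lin: float = 659_748.0  # N/m
    shear_stiffness: float = 260_000.0  # N/m; literature placeholder
    d_damp_tra: float = 400_000.0  # N s/m
    d_damp_rot: float = 100.0  # Nm s

    def __post_init__(self) -> None:
        missing = [d for d in ROT_DIRECTIONS if d not in self.rot]
        if missing:
            raise ValueError(f"disk characteristic missing directions: {missing}")
        self.rot = {
            k: (v if isinstance(v, DiskRotParams) else DiskRotParams(*v))
            for k, v in self.rot.items()
        }
        if self.axial_quad < 0 or self.axial_lin < 0:
            raise ValueError("axial polynomial coefficients must be >= 0")

    def torque_x(self, phi_x: float) -> float:
        """Signed restoring-law torque magnitude about x (flexion phi_x > 0)."""
        if phi_x >= 0:
            return float(self.rot["flexion"].torque(phi_x))
        return -float(self.rot["extension"].torque(-phi_x))


def disk_force(char: DiskCharacteristic, r, dr=None) -> np.ndarray:
    """Disk force (N, cranial body, disk frame) at deformation ``r`` (m).

    The axial spring resists compression (``r_z < 0``, cranial body moved
    toward the caudal one) with the quadratic polynomial and transmits no
    spring force in axial tension; shear springs are linear; viscous damping
    is added per axis.
    """
    r = np.asarray(r, dtype=float)
    dr = np.zeros(3) if dr is None else np.asarray(dr, dtype=float)
    F = np.zeros(3)
    F[0] = -char.shear_stiffness * r[0]
    F[1] = -char.shear_stiffness * r[1]
    c = -r[2]  # compression, positive when cranial body approaches caudal
    if c > 0:
        F[2] = char.axial_quad * c**2 + char.axial_lin * c  # pushes cranial body up
    F -= char.d_damp_tra * dr
    return F


def disk_axial_spring_force(char: DiskCharacteristic, r_z: float) -> float:
    """Compressive axial spring force magnitude (N); zero in tension."""
    c = -r_z
    if c <= 0:
        return 0.0
    return char.axial_quad * c**2 + char.axial_lin * c


def disk_torque(char: DiskCharacteristic, phi, dphi=None) -> np.ndarray:
    """Restoring disk torque (Nm, on the cranial body) at rotation ``phi`` (rad).

    About x the flexion row applies for ``phi_x > 0`` and the extension row
    for ``phi_x < 0``; lateral and axial use a single odd characteristic.
    """
    phi = np.asarray(phi, dtype=float)
    dphi = np.zeros(3) if dphi is None else np.asarray(dphi, dtype=float)
    T = np.zeros(3)
    T[0] = -char.torque_x(phi[0])
    lat = char.rot["lateral"]
    axi = char.rot["axial"]
    T[1] = -np.sign(phi[1]) * float(lat.torque(abs(phi[1])))
    T[2] = -np.sign(phi[2]) * float(axi.torque(abs(phi[2])))
    T -= char.d_damp_rot * dphi
    return T


@dataclass
class LigamentCharacteristic:
    """Softplus force-strain parameters; optional separate negative-strain
    branch (used for the supraspinous ligament, which is slack at neutral)."""

    a: float  # N
    b: float  # percent
    c: float  # N
    d: float  # percent
    neg_branch: tuple[float, float, float, float] | None = None
    damping_factor: float = 10.0  # d_damp = damping_factor * F_spring

    def __post_init__(self) -> None:
        if self.d == 0:
            raise ValueError("ligament parameter d must be nonzero")
        if self.neg_branch is not None:
            self.neg_branch = tuple(float(v) for v in self.neg_branch)
            if self.neg_branch[3] == 0:
                raise ValueError("negative-branch parameter d must be nonzero")
            gap = abs(_softplus_force(0.0, self.a, self.b, self.c, self.d)
                      - _softplus_force(0.0, *self.neg_branch))
            if gap >= 0.1:
                raise ValueError(
                    f"negative-strain branch discontinuous at eps=0 (|dF| = {gap:.3g} N)"
                )

    def spring_force(self, eps):
        """Spring force (N) at strain ``eps`` (percent), before clamping."""
        eps = np.asarray(eps, dtype=float)
        pos = _softplus_force(eps, self.a, self.b, self.c, self.d)
        if self.neg_branch is None:
            return pos
        neg = _softplus_force(eps, *self.neg_branch)
        return np.where(eps < 0, neg, pos)

    def slope(self, eps):
        """Analytic dF_spring/deps (N per percent strain)."""
        eps = np.asarray(eps, dtype=float)

        def _slope(e, a, b, c, d):
            return a / (d * (1.0 + np.exp(-(e + b) / d)))

        pos = _slope(eps, self.a, self.b, self.c, self.d)
        if self.neg_branch is None:
            return pos
        return np.where(eps < 0, _slope(eps, *self.neg_branch), pos)


def _softplus_force(eps, a, b, c, d):
    return a * np.logaddexp(0.0, (np.asarray(eps, dtype=float) + b) / d) + c


def ligament_force(char: LigamentCharacteristic, eps, deps=0.0):
    """Total ligament tension (N, >= 0) at strain ``eps`` (percent) and strain
    rate ``deps`` (percent/s).

    Damping is force-proportional, ``damping_factor * F_spring`` applied to
    the strain rate expressed as fraction/s; a cable cannot push, so the
    total is clamped at zero.
    """
    Fs = char.spring_force(eps)
    F = Fs + char.damping_factor * Fs * (np.asarray(deps, dtype=float) / 100.0)
    return np.maximum(F, 0.0)


def ligament_stiffness(char: LigamentCharacteristic, eps):
    """dF/deps of the clamped static force (N per percent)."""
    Fs = char.spring_force(eps)
    return np.where(Fs > 0, char.slope(eps), 0.0)


@dataclass
class MuscleCableDef:
    """Constant-pull wire cable: a length-independent force element anchored
    at a body point, pulling along a fixed global direction."""

    name: str
    attachment: tuple[str, str]  # (body label, point label)
    direction: np.ndarray  # unit vector, global frame
    force: float  # N per cable
    group: str = ""

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"muscle cable {self.name}: |direction| must be 1, got {n:.6g}")
        if self.force < 0:
            raise ValueError(f"muscle cable {self.name}: force must be >= 0")


def facet_penetrations(
    fs: FacetSurfaceDef, pose: Pose, disk_centre, cranial_com, caudal_com, warn=None
):
    """Penetration state of every probe point of one facet at a pose.

    The probe points live on the mobile (cranial) body, the regression
    surface and its local frame on the caudal one; both are stored in body
    frames, hence the two com arguments.  Returns ``(depths_m,
    normals_world, points_world)``: positive depth means the probe point lies
    below the regression surface, measured along the local surface normal at
    the foot point (shallow-slope approximation, depth = vertical gap /
    sqrt(1 + fx^2 + fy^2)).  Probe points landing outside the fitted +-6 mm
    landmark domain are still evaluated; ``warn`` (a callable) is notified
    when that happens.
    """
    if fs.frame is None or fs.probe_points is None:
        raise GeometryError("facet surface needs a local frame and probe points")
    R, t = segment_transform(pose, disk_centre)
    pts_neutral = np.asarray(cranial_com, float) + fs.probe_points
    pts_world = (pts_neutral @ R.T) + t
    origin_world = np.asarray(caudal_com, float) + fs.frame.origin
    local = 1000.0 * ((pts_world - origin_world) @ fs.frame.axes.T)
    x, y, z = local[:, 0], local[:, 1], local[:, 2]
    f = fs.height(x, y)
    fx, fy = fs.gradient(x, y)
    scale = np.sqrt(1.0 + fx**2 + fy**2)
    depths = (f - z) / scale / 1000.0  # m, along the surface normal
    normals_local = np.column_stack([-fx, -fy, np.ones_like(fx)]) / scale[:, None]
    normals_world = normals_local @ fs.frame.axes
    if warn is not None and np.any(np.abs(local[:, :2]) > 6.0):
        warn("facet probe point outside the fitted surface domain; extrapolating")
    return depths, normals_world, pts_world


def facet_force(
    fs: FacetSurfaceDef,
    pose: Pose,
    disk_centre,
    cranial_com,
    caudal_com,
    ref_point=None,
    depth_rates=None,
    stiffness: float | None = None,
    warn=None,
):
    """Contact wrench of one facet on the mobile body.

    For each penetrating probe point a normal force ``stiffness * depth +
    damping * depth_rate`` is applied at the point along the surface normal;
    separated points transmit nothing.  The wrench ``(force, torque)`` is
    accumulated about ``ref_point`` (default: the posed disk centre).
    """
    k = fs.stiffness if stiffness is None else stiffness
    depths, normals, pts = facet_penetrations(
        fs, pose, disk_centre, cranial_com, caudal_com, warn=warn
    )
    if depth_rates is None:
        depth_rates = np.zeros_like(depths)
    mag = np.where(depths > 0, k * depths + fs.damping * depth_rates, 0.0)
    F = (mag[:, None] * normals).sum(axis=0)
    if ref_point is None:
        ref_point = np.asarray(disk_centre, float) + pose.trans
    T = np.cross(pts - ref_point, mag[:, None] * normals).sum(axis=0)
    return F, T


def muscle_wrench(m: MuscleCableDef, attachment_world, ref_point):
    """Wrench ``(force, torque about ref_point)`` of one cable on its body.

    The pull magnitude and direction are pose-independent; only the lever arm
    follows the attachment point.
    """
    F = m.force * m.direction
    T = np.cross(np.asarray(attachment_world, float) - np.asarray(ref_point, float), F)
    return F, T


def idp_from_force(axial_compressive_force: float, csa: float) -> float:
    """Intradiscal pressure (Pa) from the axial compressive disk force (N) and
    the disk cross-sectional area (m^2): ``IDP = 1.68 * F / CSA``."""
    if csa <= 0:
        raise ValueError(f"csa must be > 0, got {csa}")
    if axial_compressive_force < 0:
        raise ValueError("axial force must be a compressive magnitude >= 0")
    return IDP_STRESS_FACTOR * axial_compressive_force / csa


# ---------------------------------------------------------------------------
# Packaged default characteristic set (calibrated L4-L5 values)


def default_characteristics():
    """The packaged default characteristic set as plain Python objects.

    Returns ``(disk, ligaments, facet_stiffness, facet_damping, prestrains)``.
    The full set, including provenance comments, ships as
    ``data/default_characteristics.yaml``; this constructor mirrors it.
    """
    from .io import load_characteristics, packaged_default_path

    model = load_characteristics(packaged_default_path())
    return model
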