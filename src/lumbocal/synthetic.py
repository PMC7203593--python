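"""Synthetic, non-anatomical motion-segment and spine geometries plus
ground-truth-driven experiment tables.

The generator builds mechanically plausible (bilaterally symmetric, convex
facet patches, physiological lever-arm ordering ALL < PLL < FL < ISL < SSL)
but explicitly NON-ANATOMICAL geometries: no published insertion-point
coordinates exist for the modelled specimens, so all coordinates here are
synthetic placeholders.  Driven by a ground-truth characteristic set, the
generator emulates the two experiment shapes — the stepwise-reduction ROM
table and the muscle-loaded intradiscal-pressure table — so that the
calibration and validation machinery can be exercised end to end with no
external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import ROMTable, CalibratedModel
from .force_elements import MuscleCableDef
from .geometry import (
    FacetFrame,
    FacetLandmarkSet,
    LigamentDef,
    RigidBodyDef,
    SegmentGeometry,
    SpineGeometry,
    fit_facet_surface,
)
from .protocols import IDPTable, run_idp_protocol, run_stepwise_forward

__all__ = [
    "SynthConfig",
    "make_synthetic_fsu",
    "make_synthetic_spine",
    "make_facet_landmarks",
    "simulate_eds1",
    "simulate_eds2",
]

log = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Knobs of the synthetic study conditions.

    ``noise_rom_deg`` is the SD of Gaussian noise added to simulated mean
    ROM values; experimental ranges are generated as mean -+
    ``range_halfwidth_frac`` * mean with a 0.1 deg floor.  Geometric scale
    parameters control the segment but stay deliberately non-anatomical.
    """

    seed: int = 0
    noise_rom_deg: float = 0.25
    range_halfwidth_frac: float = 0.15
    idp_sd_frac: float = 0.15
    idp_sd_floor_mpa: float = 0.02
    noise_idp_mpa: float = 0.0
    disk_height: float = 0.04  # vertebral spacing (com to com), m
    insertion_offset: float = 0.010  # |z| of ligament insertions from disk plane, m
    facet_gap_mm: float = 0.3  # neutral clearance of the facet probes
    facet_tilt_deg: float = 30.0  # facet normal tilt from vertical
    csa: float = 1.8e-3  # disk cross-sectional area, m^2
    jitter: float = 0.05  # fractional seeded jitter on insertion offsets

    def __post_init__(self) -> None:
        if self.noise_rom_deg < 0 or self.noise_idp_mpa < 0:
            raise ValueError("noise levels must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# dorsal is +y, cranial is +z, left is +x; offsets in metres
_LIGAMENT_SITES = {
    # name: (x offset, y offset, bilateral?).  Dorsoventral ordering follows
    # anatomy: ALL on the anterior body wall, PLL/FL near the canal, ISL/SSL
    # on the spinous process, CL at the facets, ITL on the transverse
    # processes.
    "ALL": (0.0, -0.026, False),
    "PLL": (0.0, 0.015, False),
    "FL": (0.0, 0.013, False),
    "ISL": (0.0, 0.042, False),
    "SSL": (0.0, 0.058, False),
    "CL": (0.020, 0.028, True),
    "ITL": (0.042, 0.004, True),
}

_DEFAULT_PRESTRAIN = {"ALL": 8.0, "PLL": 10.0, "FL": 10.0, "ITL": 10.0,
                      "CL": 10.0, "ISL": 4.0, "SSL": -6.0}

# convex cubic patch used for the synthetic facet surfaces (mm); the cubic
# y-term is mirrored between sides so left/right are exact sagittal mirrors.
# The curvature is kept gentle so that tangential probe travel (axial
# rotation) does not outrun the tilt of the contact normal — lumbar facets
# are shallowly curved at the articulation zone.
_FACET_COEFFS = {"p30": -0.002, "p03": -0.001, "p20": -0.05, "p02": -0.04, "p00": 47.0}
_FACET_X = 0.021  # lateral offset of the facet contact zone, m
_FACET_Y = 0.028  # dorsal offset, m


def _facet_frame(side: str, tilt_deg: float, centre_world: np.ndarray,
                 caudal_com: np.ndarray) -> FacetFrame:
    """Facet-local frame: local z is the contact normal, tilted medially by
    ``tilt_deg`` so that extension (downward probe motion) and axial
    rotation (tangential probe motion) both engage; local x runs dorsally."""
    alpha = np.radians(tilt_deg)
    sx = -1.0 if side == "left" else 1.0
    e3 = np.array([sx * np.sin(alpha), 0.0, np.cos(alpha)])
    e1 = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e3, e1)
    origin_world = centre_world - (_FACET_COEFFS["p00"] / 1000.0) * e3
    return FacetFrame(origin=origin_world - caudal_com, axes=np.vstack([e1, e2, e3]))


def make_facet_landmarks(side: str, split_mm: float = 0.2) -> tuple[FacetLandmarkSet, FacetLandmarkSet]:
    """Nine-point landmark grids for the two articular processes of one
    facet, sampled exactly on convex cubic patches whose mean is the
    synthetic target surface (superior and inferior offset by ``+-split_mm``
    in the constant term)."""
    c = dict(_FACET_COEFFS)
    if side == "right":
        c["p03"] = -c["p03"]
    g = np.array([-3.0, 0.0, 3.0])
    xx, yy = np.meshgrid(g, g)
    xy = np.column_stack([xx.ravel(), yy.ravel()])

    def surf(p00):
        z = (c["p30"] * xy[:, 0] ** 3 + c["p03"] * xy[:, 1] ** 3
             + c["p20"] * xy[:, 0] ** 2 + c["p02"] * xy[:, 1] ** 2 + p00)
        return np.column_stack([xy, z])

    sup = FacetLandmarkSet(surf(c["p00"] + split_mm), frame_id=f"facet_{side}")
    inf = FacetLandmarkSet(surf(c["p00"] - split_mm), frame_id=f"facet_{side}")
    return sup, inf


def _build_vertebra(name: str, com: np.ndarray, sites: dict, z_sign: float,
                    offset: float) -> RigidBodyDef:
    """One vertebra with ligament insertion points; ``z_sign`` is -1 for a
    cranial body (points reach down toward the disk) and +1 for a caudal
    one."""
    points = {}
    for lig, (x, y, bilateral) in sites.items():
        z = z_sign * offset
        if bilateral:
            points[f"{lig}_left"] = np.array([x, y, z])
            points[f"{lig}_right"] = np.array([-x, y, z])
        else:
            points[lig] = np.array([0.0, y, z])
    return RigidBodyDef(name=name, com=com, points=points)


def make_synthetic_fsu(cfg: SynthConfig | None = None, *,
                       cranial_name: str = "L4", caudal_name: str = "L5",
                       z_offset: float = 0.0) -> SegmentGeometry:
    """A synthetic functional spinal unit, deterministic in ``cfg.seed``.

    Bilaterally symmetric across the sagittal plane; ligament insertion
    sites follow the physiological dorsoventral ordering; facet landmarks
    sample an ellipsoid-like convex patch and the stored surfaces are the
    least-squares fits of those landmark sets.
    """
    cfg = cfg or SynthConfig()
    rng = cfg.rng()
    sites = {}
    for name, (x, y, bilateral) in _LIGAMENT_SITES.items():
        jy = 1.0 + cfg.jitter * (2.0 * rng.random() - 1.0)
        sites[name] = (x, y * jy, bilateral)

    h = cfg.disk_height / 2.0
    d = np.array([0.0, 0.0, z_offset])
    cranial = _build_vertebra(cranial_name, d + [0, 0, h], sites, -1.0, cfg.insertion_offset)
    caudal = _build_vertebra(caudal_name, d + [0, 0, -h], sites, +1.0, cfg.insertion_offset)

    ligaments = []
    for name, (_x, _y, bilateral) in sites.items():
        pre = _DEFAULT_PRESTRAIN[name]
        if bilateral:
            for side in ("left", "right"):
                ligaments.append(LigamentDef(
                    name=name, side=side,
                    cranial_point=(cranial_name, f"{name}_{side}"),
                    caudal_point=(caudal_name, f"{name}_{side}"),
                    prestrain=pre,
                ))
        else:
            ligaments.append(LigamentDef(
                name=name, side="midline",
                cranial_point=(cranial_name, name),
                caudal_point=(caudal_name, name),
                prestrain=pre,
            ))

    facets = {}
    for side in ("left", "right"):
        sx = 1.0 if side == "left" else -1.0
        centre = d + np.array([sx * _FACET_X, _FACET_Y, 0.0])
        frame = _facet_frame(side, cfg.facet_tilt_deg, centre, caudal.com)
        sup, inf = make_facet_landmarks(side)
        # probe points on the cranial body's inferior process, hovering
        # facet_gap_mm above the surface along the contact normal
        e1, e2, e3 = frame.axes
        origin_world = caudal.com + frame.origin
        probes = []
        for px in (-2.0, 0.0, 2.0):
            c = dict(_FACET_COEFFS)
            if side == "right":
                c["p03"] = -c["p03"]
            f = c["p30"] * px**3 + c["p20"] * px**2 + c["p00"]
            p_surf = origin_world + (px * e1 + f * e3) / 1000.0
            probes.append(p_surf + (cfg.facet_gap_mm / 1000.0) * e3 - cranial.com)
        facets[side] = fit_facet_surface(sup, inf, frame=frame,
                                         probe_points=np.array(probes))

    return SegmentGeometry(
        cranial=cranial, caudal=caudal, disk_centre=d,
        ligaments=ligaments, facets=facets, csa=cfg.csa,
    )


# synthetic wire-cable lines of action; explicitly non-anatomical
# placeholders for the five experimental muscle-cable pairs (no directional
# vectors are published).  Each entry: (group, body, x, y, direction)
_MUSCLE_SPEC = [
    ("multifidus_caudal", "L2", 0.014, 0.034, (0.0, 0.20, -1.0)),
    ("iliocostalis_longissimus", "L2", 0.030, 0.030, (0.0, 0.12, -1.0)),
    ("psoas_corpus", "L3", 0.018, -0.020, (0.0, -0.20, -1.0)),
    ("psoas_transversus", "L3", 0.040, 0.004, (0.15, 0.0, -1.0)),
    ("multifidus_cranial", "L2", 0.014, 0.034, (0.0, 0.20, 1.0)),
]

#: Constant pull per cable pair (split equally between the two cables), N.
MUSCLE_PAIR_FORCE = 80.0


def make_synthetic_spine(cfg: SynthConfig | None = None) -> SpineGeometry:
    """A synthetic L2-S1 chain: four stacked copies of the synthetic
    segment above a fixed sacrum, plus the five mirrored muscle-cable
    pairs (40 N per cable)."""
    cfg = cfg or SynthConfig()
    names = ["L2", "L3", "L4", "L5", "sacrum"]
    segments = []
    bodies: list[RigidBodyDef] = []
    for i in range(4):
        z = (1.5 - i) * cfg.disk_height  # disk planes at +1.5h, +0.5h, -0.5h, -1.5h
        seg = make_synthetic_fsu(cfg, cranial_name=names[i], caudal_name=names[i + 1],
                                 z_offset=z)
        segments.append(seg)
        if i == 0:
            bodies.append(seg.cranial)
        else:
            # share one body object between adjacent segments
            seg.cranial = bodies[-1]
            segments[i] = SegmentGeometry(
                cranial=bodies[-1], caudal=seg.caudal, disk_centre=seg.disk_centre,
                ligaments=seg.ligaments, facets=seg.facets, csa=seg.csa,
            )
        bodies.append(segments[i].caudal)

    muscles = []
    for group, body, x, y, direction in _MUSCLE_SPEC:
        for side, sx in (("left", 1.0), ("right", -1.0)):
            dvec = np.array([sx * direction[0], direction[1], direction[2]], float)
            dvec /= np.linalg.norm(dvec)
            label = f"musc_{group}_{side}"
            for b in bodies:
                if b.name == body:
                    b.points[label] = np.array([sx * x, y, 0.0])
            muscles.append(MuscleCableDef(
                name=label, attachment=(body, label), direction=dvec,
                force=MUSCLE_PAIR_FORCE / 2.0, group=group,
            ))
    return SpineGeometry(bodies=bodies, segments=segments, muscles=muscles)


def simulate_eds1(geom: SegmentGeometry, ground_truth: CalibratedModel,
                  cfg: SynthConfig | None = None) -> ROMTable:
    """A stepwise-reduction-shaped ROM table from a ground-truth model.

    Mean ROM is the forward simulation plus seeded Gaussian noise
    (``cfg.noise_rom_deg``); ranges are mean -+ ``range_halfwidth_frac`` *
    mean with a 0.1 deg floor; the 0 Nm neutral rows carry no range.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed + 101)
    table = run_stepwise_forward(ground_truth, geom)
    df = table.df.copy()
    loaded = df["torque_nm"] > 0
    if cfg.noise_rom_deg > 0:
        df.loc[loaded, "rom_mean_deg"] += rng.normal(0.0, cfg.noise_rom_deg, int(loaded.sum()))
    half = np.maximum(0.1, cfg.range_halfwidth_frac * df.loc[loaded, "rom_mean_deg"].abs())
    df.loc[loaded, "rom_min_deg"] = df.loc[loaded, "rom_mean_deg"] - half
    df.loc[loaded, "rom_max_deg"] = df.loc[loaded, "rom_mean_deg"] + half
    return ROMTable(df)


def simulate_eds2(spine: SpineGeometry, ground_truth: CalibratedModel,
                  cfg: SynthConfig | None = None) -> IDPTable:
    """A pressure-experiment-shaped IDP table from a ground-truth model;
    SD column is ``max(floor, idp_sd_frac * mean)``; seeded noise optional."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed + 202)
    table = run_idp_protocol(spine, ground_truth)
    df = table.df.copy()
    if cfg.noise_idp_mpa > 0:
        df["idp_mean_mpa"] += rng.normal(0.0, cfg.noise_idp_mpa, len(df))
    df["idp_sd_mpa"] = np.maximum(cfg.idp_sd_floor_mpa, cfg.idp_sd_frac * df["idp_mean_mpa"].abs())
    return IDPTable(df)
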