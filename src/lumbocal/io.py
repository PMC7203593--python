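"""Readers and writers: geometry JSON, characteristic YAML/JSON, run manifests.

The geometry file is schema-validated JSON with all lengths in metres except
facet-local landmark/coefficient data, which is in millimetres (flagged by
the ``units`` block).  Characteristic parameter files are YAML with named
blocks (disk, ligaments, facets, prestrains); the packaged default set
reproduces the calibrated L4-L5 parameter tables, and alternative literature
sets load through the same schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata, resources
from pathlib import Path

import numpy as np
import yaml

from .calibration import CalibratedModel
from .force_elements import (
    DiskCharacteristic,
    DiskRotParams,
    LigamentCharacteristic,
    MuscleCableDef,
)
from .geometry import (
    FacetFrame,
    FacetSurfaceDef,
    GeometryError,
    LigamentDef,
    RigidBodyDef,
    SegmentGeometry,
    SpineGeometry,
)

__all__ = [
    "SchemaError",
    "RunManifest",
    "packaged_default_path",
    "load_characteristics",
    "save_characteristics",
    "load_geometry",
    "save_geometry",
]

GEOMETRY_SCHEMA = "lumbocal-geometry-v1"
CHARACTERISTICS_SCHEMA = "lumbocal-characteristics-v1"


class SchemaError(ValueError):
    """A file violates the documented schema; the message names the path."""


def _require(mapping, key, path):
    if key not in mapping:
        raise SchemaError(f"{path}: missing required key {key!r}")
    return mapping[key]


def packaged_default_path() -> Path:
    """Path of the packaged default characteristic set."""
    return Path(resources.files("lumbocal") / "data" / "default_characteristics.yaml")


# ---------------------------------------------------------------------------
# characteristics


def load_characteristics(path) -> CalibratedModel:
    """Load a characteristic parameter file (YAML or JSON)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: not a mapping")
    disk_raw = _require(raw, "disk", "disk")
    rot_raw = _require(disk_raw, "rot", "disk.rot")
    rot = {}
    for direction, p in rot_raw.items():
        try:
            rot[direction] = DiskRotParams(p1=float(p["p1"]), p2=float(p["p2"]),
                                           p3=float(p["p3"]))
        except (KeyError, TypeError, ValueError) as err:
            raise SchemaError(f"disk.rot.{direction}: {err}") from err
    try:
        disk = DiskCharacteristic(
            rot=rot,
            axial_quad=float(disk_raw.get("axial_quad", 690_234_060.0)),
            axial_lin=float(disk_raw.get("axial_lin", 659_748.0)),
            shear_stiffness=float(disk_raw.get("shear_stiffness", 260_000.0)),
            d_damp_tra=float(disk_raw.get("d_damp_tra", 400_000.0)),
            d_damp_rot=float(disk_raw.get("d_damp_rot", 100.0)),
        )
    except ValueError as err:
        raise SchemaError(f"disk: {err}") from err

    lig_raw = _require(raw, "ligaments", "ligaments")
    required = {"ALL", "PLL", "FL", "CL", "ISL", "SSL"}
    missing = required - set(lig_raw)
    if missing:
        raise SchemaError(f"ligaments: missing blocks {sorted(missing)}")
    ligaments = {}
    for name, p in lig_raw.items():
        try:
            neg = p.get("neg_branch")
            if neg is not None:
                neg = (float(neg["a"]), float(neg["b"]), float(neg["c"]), float(neg["d"]))
            ligaments[name] = LigamentCharacteristic(
                a=float(p["a"]), b=float(p["b"]), c=float(p["c"]), d=float(p["d"]),
                neg_branch=neg,
                damping_factor=float(p.get("damping_factor", 10.0)),
            )
        except (KeyError, TypeError, ValueError) as err:
            raise SchemaError(f"ligaments.{name}: {err}") from err

    fac = raw.get("facets", {})
    prestrains = {k: float(v) for k, v in raw.get("prestrains", {}).items()}
    return CalibratedModel(
        disk=disk,
        ligaments=ligaments,
        facet_stiffness=float(fac.get("stiffness", 12_000.0)),
        facet_damping=float(fac.get("damping", 4_000.0)),
        prestrains=prestrains,
        diagnostics=raw.get("diagnostics", {}),
    )


def save_characteristics(model: CalibratedModel, path) -> None:
    """Write a characteristic set in the loadable YAML schema."""
    doc = {
        "schema": CHARACTERISTICS_SCHEMA,
        "disk": {
            "rot": {
                k: {"p1": float(v.p1), "p2": float(v.p2), "p3": float(v.p3)}
                for k, v in model.disk.rot.items()
            },
            "axial_quad": float(model.disk.axial_quad),
            "axial_lin": float(model.disk.axial_lin),
            "shear_stiffness": float(model.disk.shear_stiffness),
            "d_damp_tra": float(model.disk.d_damp_tra),
            "d_damp_rot": float(model.disk.d_damp_rot),
        },
        "facets": {"stiffness": float(model.facet_stiffness),
                   "damping": float(model.facet_damping)},
        "ligaments": {},
        "prestrains": {k: float(v) for k, v in model.prestrains.items()},
    }
    for name, c in model.ligaments.items():
        entry = {"a": float(c.a), "b": float(c.b), "c": float(c.c), "d": float(c.d)}
        if c.neg_branch is not None:
            entry["neg_branch"] = dict(zip("abcd", (float(v) for v in c.neg_branch)))
        if c.damping_factor != 10.0:
            entry["damping_factor"] = float(c.damping_factor)
        doc["ligaments"][name] = entry
    if model.diagnostics:
        doc["diagnostics"] = _plain(model.diagnostics)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON emission."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# geometry


def _body_to_json(body: RigidBodyDef) -> dict:
    return {
        "name": body.name,
        "com": body.com.tolist(),
        "points": {k: v.tolist() for k, v in body.points.items()},
    }


def _body_from_json(raw, path) -> RigidBodyDef:
    try:
        return RigidBodyDef(
            name=_require(raw, "name", path),
            com=_require(raw, "com", f"{path}.com"),
            points={k: np.asarray(v, float) for k, v in raw.get("points", {}).items()},
        )
    except GeometryError as err:
        raise SchemaError(f"{path}: {err}") from err


def _facet_to_json(fs: FacetSurfaceDef) -> dict:
    return {
        "coefficients_mm": {"p30": fs.p30, "p03": fs.p03, "p20": fs.p20,
                            "p02": fs.p02, "p00": fs.p00},
        "frame": {"origin_m": fs.frame.origin.tolist(),
                  "axes": fs.frame.axes.tolist()} if fs.frame else None,
        "stiffness_n_per_m": fs.stiffness,
        "damping_ns_per_m": fs.damping,
        "probe_points_m": fs.probe_points.tolist() if fs.probe_points is not None else None,
    }


def _facet_from_json(raw, path) -> FacetSurfaceDef:
    c = _require(raw, "coefficients_mm", path)
    frame = None
    if raw.get("frame"):
        frame = FacetFrame(origin=raw["frame"]["origin_m"], axes=raw["frame"]["axes"])
    try:
        return FacetSurfaceDef(
            p30=float(c["p30"]), p03=float(c["p03"]), p20=float(c["p20"]),
            p02=float(c["p02"]), p00=float(c["p00"]),
            frame=frame,
            stiffness=float(raw.get("stiffness_n_per_m", 12_000.0)),
            damping=float(raw.get("damping_ns_per_m", 4_000.0)),
            probe_points=raw.get("probe_points_m"),
        )
    except (KeyError, GeometryError) as err:
        raise SchemaError(f"{path}: {err}") from err


def _segment_to_json(seg: SegmentGeometry, shared_bodies: bool = False) -> dict:
    doc = {
        "disk_centre": seg.disk_centre.tolist(),
        "csa_m2": seg.csa,
        "ligaments": [
            {
                "name": lig.name,
                "side": lig.side,
                "cranial_point": list(lig.cranial_point),
                "caudal_point": list(lig.caudal_point),
                "prestrain_pct": lig.prestrain,
                "characteristic": lig.characteristic,
            }
            for lig in seg.ligaments
        ],
        "facets": {side: (_facet_to_json(fs) if fs else None)
                   for side, fs in seg.facets.items()},
    }
    if shared_bodies:
        doc["cranial"] = seg.cranial.name
        doc["caudal"] = seg.caudal.name
    else:
        doc["cranial"] = _body_to_json(seg.cranial)
        doc["caudal"] = _body_to_json(seg.caudal)
    return doc


def _segment_from_json(raw, path, bodies: dict[str, RigidBodyDef] | None = None
                       ) -> SegmentGeometry:
    def resolve_body(key):
        b = _require(raw, key, f"{path}.{key}")
        if isinstance(b, str):
            if bodies is None or b not in bodies:
                raise SchemaError(f"{path}.{key}: unknown body reference {b!r}")
            return bodies[b]
        return _body_from_json(b, f"{path}.{key}")

    csa = float(_require(raw, "csa_m2", f"{path}.csa_m2"))
    ligaments = []
    for i, L in enumerate(raw.get("ligaments", [])):
        lp = f"{path}.ligaments[{i}]"
        try:
            ligaments.append(LigamentDef(
                name=_require(L, "name", lp),
                side=L.get("side", "midline"),
                cranial_point=tuple(_require(L, "cranial_point", lp)),
                caudal_point=tuple(_require(L, "caudal_point", lp)),
                prestrain=float(L.get("prestrain_pct", 0.0)),
                characteristic=L.get("characteristic"),
            ))
        except GeometryError as err:
            raise SchemaError(f"{lp}: {err}") from err
    facets = {}
    for side, f in raw.get("facets", {}).items():
        facets[side] = _facet_from_json(f, f"{path}.facets.{side}") if f else None
    try:
        return SegmentGeometry(
            cranial=resolve_body("cranial"), caudal=resolve_body("caudal"),
            disk_centre=_require(raw, "disk_centre", f"{path}.disk_centre"),
            ligaments=ligaments, facets=facets, csa=csa,
        )
    except GeometryError as err:
        raise SchemaError(f"{path}: {err}") from err


def save_geometry(geom: SegmentGeometry | SpineGeometry, path) -> None:
    """Write a geometry file (JSON).  Lengths are metres; facet-local data
    (surface coefficients, landmark coordinates) are millimetres."""
    units = {"length": "m", "facet_local": "mm"}
    if isinstance(geom, SpineGeometry):
        doc = {
            "schema": GEOMETRY_SCHEMA,
            "type": "spine",
            "units": units,
            "bodies": [_body_to_json(b) for b in geom.bodies],
            "segments": [_segment_to_json(s, shared_bodies=True) for s in geom.segments],
            "muscles": [
                {
                    "name": m.name,
                    "attachment": list(m.attachment),
                    "direction": m.direction.tolist(),
                    "force_n": m.force,
                    "group": m.group,
                }
                for m in geom.muscles
            ],
        }
    else:
        doc = {
            "schema": GEOMETRY_SCHEMA,
            "type": "segment",
            "units": units,
            "segment": _segment_to_json(geom),
        }
    Path(path).write_text(json.dumps(_plain(doc), indent=1))


def load_geometry(path) -> SegmentGeometry | SpineGeometry:
    """Load and validate a geometry file; raises :class:`SchemaError` naming
    the failing path on violation."""
    raw = json.loads(Path(path).read_text())
    if raw.get("schema") != GEOMETRY_SCHEMA:
        raise SchemaError(f"schema: expected {GEOMETRY_SCHEMA!r}, got {raw.get('schema')!r}")
    units = raw.get("units", {})
    if units.get("length", "m") != "m" or units.get("facet_local", "mm") != "mm":
        raise SchemaError(f"units: unsupported unit system {units!r}")
    kind = raw.get("type")
    if kind == "segment":
        return _segment_from_json(_require(raw, "segment", "segment"), "segment")
    if kind == "spine":
        bodies = {}
        body_list = []
        for i, b in enumerate(_require(raw, "bodies", "bodies")):
            body = _body_from_json(b, f"bodies[{i}]")
            if body.name in bodies:
                raise SchemaError(f"bodies[{i}]: duplicate body name {body.name!r}")
            bodies[body.name] = body
            body_list.append(body)
        segments = [
            _segment_from_json(s, f"segments[{i}]", bodies)
            for i, s in enumerate(_require(raw, "segments", "segments"))
        ]
        muscles = []
        for i, m in enumerate(raw.get("muscles", [])):
            mp = f"muscles[{i}]"
            try:
                muscles.append(MuscleCableDef(
                    name=_require(m, "name", mp),
                    attachment=tuple(_require(m, "attachment", mp)),
                    direction=_require(m, "direction", mp),
                    force=float(_require(m, "force_n", mp)),
                    group=m.get("group", ""),
                ))
            except ValueError as err:
                raise SchemaError(f"{mp}: {err}") from err
        try:
            return SpineGeometry(bodies=body_list, segments=segments, muscles=muscles)
        except GeometryError as err:
            raise SchemaError(str(err)) from err
    raise SchemaError(f"type: expected 'segment' or 'spine', got {kind!r}")


# ---------------------------------------------------------------------------
# run manifests


@dataclass
class RunManifest:
    """Provenance record written next to every batch output."""

    command: str
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    seed: int | None = None
    tolerances: dict[str, float] = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            try:
                self.package_version = metadata.version("lumbocal")
            except metadata.PackageNotFoundError:  # pragma: no cover
                self.package_version = "unknown"
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @staticmethod
    def digest(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = self.digest(path)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "command": self.command,
            "inputs": self.inputs,
            "seed": self.seed,
            "tolerances": self.tolerances,
            "package_version": self.package_version,
            "timestamp": self.timestamp,
        }, sort_keys=False))
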