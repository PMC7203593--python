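"""Backward stepwise-reduction calibration.

The stepwise reduction protocol removes the passive structures of a
functional spinal unit one at a time (supraspinous ligament, interspinous
ligament, flaval ligament, facet capsules, vertebral arches, posterior and
anterior longitudinal ligament), measuring the range of motion under pure
moments of {0, 1, 2.5, 5, 7.5, 10} Nm in four bending directions before
each cut.  Run backward, the experiment calibrates the model: the
most-reduced stage (disk only) fixes the disk torque-angle law; each
earlier stage then adds exactly one element whose force-strain behaviour is
the only unknown.

For every record of the stage that introduces an element, the loading-axis
rotation is constrained to the measured mean ROM, the remaining five
degrees of freedom are equilibrated with the already-calibrated elements,
and the residual moment about the loading axis — the deficit the known
elements cannot supply — is attributed to the new element.  Dividing the
deficit by the element's moment arm yields one force-strain (or, for the
facets, stiffness) sample per record.  Because the new element also shifts
the constrained pose and the stage's neutral reference, the extraction is
iterated to self-consistency: fit, re-equilibrate with the fitted estimate
included, re-extract.  The sampled points are finally fitted by trust-region
least squares with multi-start initialization.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .force_elements import (
    DiskCharacteristic,
    DiskRotParams,
    LigamentCharacteristic,
)
from .geometry import AXES, Pose, SegmentGeometry
from .statics import (
    DIRECTION_AXIS,
    ChainModel,
    LoadCase,
    SolverError,
    load_case_for,
    residual_wrench,
)

__all__ = [
    "CalibrationError",
    "InsufficientSpanError",
    "STAGES",
    "STAGE_REMOVED",
    "TORQUE_SET",
    "ROM_DIRECTIONS",
    "ROMTable",
    "CharacteristicPoint",
    "CalibratedModel",
    "extract_disk_points",
    "fit_disk_characteristic",
    "extract_facet_stiffness",
    "extract_ligament_points",
    "fit_ligament_characteristic",
    "run_backward_calibration",
]

log = logging.getLogger(__name__)

#: Reduction stages in experimental (removal) order.
STAGES = (
    "intact",
    "w/o SSL",
    "w/o ISL",
    "w/o FL",
    "w/o CL",
    "w/o VA",
    "w/o PLL",
    "w/o ALL",
)

#: Elements absent at each stage ("VA" removes the facet contact).
STAGE_REMOVED = {
    "intact": frozenset(),
    "w/o SSL": frozenset({"SSL"}),
    "w/o ISL": frozenset({"SSL", "ISL"}),
    "w/o FL": frozenset({"SSL", "ISL", "FL"}),
    "w/o CL": frozenset({"SSL", "ISL", "FL", "CL"}),
    "w/o VA": frozenset({"SSL", "ISL", "FL", "CL", "VA"}),
    "w/o PLL": frozenset({"SSL", "ISL", "FL", "CL", "VA", "PLL"}),
    "w/o ALL": frozenset({"SSL", "ISL", "FL", "CL", "VA", "PLL", "ALL"}),
}

#: Calibration order (most-reduced stage first): element <- stage whose
#: records isolate it.  The facet stiffness is extracted between the
#: longitudinal ligaments and the capsules.
CALIBRATION_SEQUENCE = (
    ("ALL", "w/o PLL"),
    ("PLL", "w/o VA"),
    ("facets", "w/o CL"),
    ("CL", "w/o FL"),
    ("FL", "w/o ISL"),
    ("ISL", "w/o SSL"),
    ("SSL", "intact"),
)

TORQUE_SET = (0.0, 1.0, 2.5, 5.0, 7.5, 10.0)
ROM_DIRECTIONS = ("flexion", "extension", "lateral", "axial")

#: A record contributes a force-strain sample only if it strains the new
#: ligament this much (percent) beyond its strain at the stage's neutral
#: pose; below that the deficit is reference-error noise, not ligament force.
SLACK_MARGIN_PCT = 0.5

ROM_COLUMNS = ["stage", "direction", "torque_nm", "rom_mean_deg", "rom_min_deg", "rom_max_deg"]


class CalibrationError(RuntimeError):
    pass


class InsufficientSpanError(CalibrationError):
    """The sampled strain interval is too narrow to constrain the fit."""


@dataclass
class ROMTable:
    """Stage x direction x torque table of mean ROM and experimental ranges.

    Backed by a DataFrame with columns ``stage, direction, torque_nm,
    rom_mean_deg, rom_min_deg, rom_max_deg``; min/max are absent (NaN) in
    the 0 Nm rows, where the protocol reports no range.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ROM_COLUMNS[:4] if c not in self.df.columns]
        if missing:
            raise CalibrationError(f"ROM table missing columns: {missing}")
        for c in ROM_COLUMNS[4:]:
            if c not in self.df.columns:
                self.df[c] = np.nan
        self.df = self.df[ROM_COLUMNS].reset_index(drop=True)
        bad_t = set(self.df["torque_nm"]) - set(TORQUE_SET)
        if bad_t:
            raise CalibrationError(f"torques outside the protocol set: {sorted(bad_t)}")
        have = self.df.dropna(subset=["rom_min_deg", "rom_max_deg"])
        ok = (have["rom_min_deg"] <= have["rom_mean_deg"] + 1e-12) & (
            have["rom_mean_deg"] <= have["rom_max_deg"] + 1e-12
        )
        if not ok.all():
            bad = have[~ok].iloc[0]
            raise CalibrationError(
                f"min <= mean <= max violated at ({bad['stage']}, {bad['direction']}, "
                f"{bad['torque_nm']} Nm)"
            )

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.df["stage"]))

    def stage_records(self, stage: str, nonzero_only: bool = True) -> pd.DataFrame:
        sub = self.df[self.df["stage"] == stage]
        if sub.empty:
            raise CalibrationError(f"ROM table has no stage {stage!r}")
        if nonzero_only:
            sub = sub[sub["torque_nm"] > 0]
        return sub

    @classmethod
    def from_csv(cls, path) -> "ROMTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CharacteristicPoint:
    """One sampled point of a characteristic curve with its provenance.

    ``weight`` carries the moment-arm magnitude (m) the force was inferred
    through: the force error of a deficit-derived sample scales with
    1/|arm|, so fits weight samples accordingly.
    """

    abscissa: float  # rad (disk) or percent strain (ligament)
    ordinate: float  # Nm (disk) or N (ligament)
    stage: str = ""
    direction: str = ""
    torque: float = 0.0
    weight: float = 1.0
    axis: int = 0  # loading axis the sample came from

    def __post_init__(self) -> None:
        if not (np.isfinite(self.abscissa) and np.isfinite(self.ordinate)):
            raise CalibrationError("characteristic point must be finite")


@dataclass
class CalibratedModel:
    """A complete characteristic set: disk law, facet stiffness, ligament
    curves, plus per-fit diagnostics (RMSE, point counts, strain spans)."""

    disk: DiskCharacteristic
    ligaments: dict[str, LigamentCharacteristic]
    facet_stiffness: float = 12_000.0
    facet_damping: float = 4_000.0
    prestrains: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def copy(self) -> "CalibratedModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# disk


def _fold_direction(name: str) -> str:
    if name.startswith("lateral"):
        return "lateral"
    if name.startswith("axial"):
        return "axial"
    return name


def extract_disk_points(rom: ROMTable) -> dict[str, np.ndarray]:
    """Disk torque-angle samples from the disk-only ("w/o ALL") stage.

    With every ligament and the arches gone, the applied moment is carried
    by the disk alone, so each record is directly a point (ROM in radians,
    torque) on the rotational spring law.  Flexion and extension stay
    separate (sagittal asymmetry); signed lateral/axial rows are folded onto
    one odd characteristic.  The origin (0, 0) is appended to each set.
    """
    recs = rom.stage_records("w/o ALL")
    points: dict[str, list[tuple[float, float]]] = {d: [] for d in ROM_DIRECTIONS}
    for _, row in recs.iterrows():
        d = _fold_direction(str(row["direction"]))
        if d not in points:
            raise CalibrationError(f"unknown bending direction {row['direction']!r}")
        points[d].append((abs(np.radians(row["rom_mean_deg"])), abs(row["torque_nm"])))
    out = {}
    for d, pts in points.items():
        pts = pts + [(0.0, 0.0)]
        arr = np.array(sorted(set((round(p, 12), round(t, 12)) for p, t in pts)))
        out[d] = arr
    return out


def fit_disk_characteristic(points: np.ndarray, direction: str = "") -> tuple[DiskRotParams, float]:
    """Trust-region least-squares fit of the tanh-cubic disk torque law.

    ``points`` is an (n, 2) array of (angle rad, torque Nm) samples.
    Multi-start over a coarse grid of initializations; the lowest-residual
    fit wins.  Returns the parameters and the fit RMSE (Nm).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise CalibrationError("need >= 4 (angle, torque) points to fit the disk law")
    phi, T = pts[:, 0], pts[:, 1]
    if len(np.unique(np.round(phi, 12))) < 4:
        raise CalibrationError("disk fit needs >= 4 distinct angles")

    def resid(p):
        return p[0] * np.tanh(phi**3 / p[1]) + p[2] * phi - T

    # p2 is the cube-angle scale of the saturating term; beyond ~0.05 rad^3
    # the tanh would stay linear over the whole physiological range and the
    # law degenerates into a plain cubic polynomial, so noisy samples could
    # alias into shapes with wrong curvature
    best = None
    for p1 in (1.0, 5.0, 20.0):
        for p2 in (1e-3, 1e-2):
            for p3 in (-5.0, 1.0, 20.0):
                try:
                    sol = least_squares(
                        resid, [p1, p2, p3], method="trf",
                        bounds=([0.0, 1e-8, -np.inf], [np.inf, 0.05, np.inf]),
                        x_scale=[10.0, 1e-3, 10.0], xtol=1e-15, ftol=1e-15, gtol=1e-15,
                    )
                except Exception:  # pragma: no cover - optimizer edge cases
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
    if best is None:
        raise CalibrationError(f"disk fit failed for direction {direction!r}")
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return DiskRotParams(*[float(v) for v in best.x]), rmse


# ---------------------------------------------------------------------------
# constrained-pose equilibration


#: Solver tolerances for calibration solves: deficits are needed to ~1e-3
#: Nm, so the statics defaults (1e-8 Nm) would only cost iterations.
_CAL_TOL = {"tol_force": 1e-4, "tol_torque": 1e-6}


def _neutral_reference(model: ChainModel, init=None):
    res = model.solve(LoadCase(), init=init, ramp=2, **_CAL_TOL)
    return res.poses


def _constrained_solve(model: ChainModel, direction: str, torque: float,
                       phi_target: float, init=None):
    """Equilibrate the five free DOFs with the loading-axis rotation pinned."""
    axis, _sign = DIRECTION_AXIS[direction]
    load = load_case_for(direction, torque)
    if init is None:
        p0 = Pose()
        p0.rot[axis] = phi_target
        init = [p0]
    res = model.solve(load, init=init, fixed={(0, axis): phi_target}, ramp=1,
                      **_CAL_TOL)
    return res, load, axis


def _axis_deficit(known_model: ChainModel, poses, load: LoadCase, axis: int) -> float:
    """Moment about the loading axis the known elements fail to supply."""
    R = residual_wrench(known_model, poses, load)
    return float(R[axis])


# ---------------------------------------------------------------------------
# facets


def extract_facet_stiffness(rom: ROMTable, geom: SegmentGeometry,
                            partial_model: CalibratedModel, *, n_iter: int = 10,
                            stage: str = "w/o CL") -> tuple[float, dict]:
    """Facet contact stiffness from the stage where only the facet joints
    were added to the already-calibrated disk and longitudinal ligaments.

    Engaging records (extension and axial rotation) are pose-constrained to
    their mean ROM; the deficit moment is divided by the facet moment per
    unit stiffness at that pose, giving one stiffness sample per record; the
    returned value is the least-squares scalar (the mean) over samples.
    """
    chars = partial_model.copy()
    removed = STAGE_REMOVED[stage]
    recs = rom.stage_records(stage)
    engaging = recs[recs["direction"].map(_fold_direction).isin(["extension", "axial"])]
    if engaging.empty:
        raise CalibrationError("no facet-engaging (extension/axial) records in stage")

    stiffness = None
    samples: list[tuple] = []
    for _ in range(max(n_iter, 2)):
        known = ChainModel.from_segment(geom, chars, removed=removed | {"VA"})
        if stiffness is None:
            full = known
        else:
            chars.facet_stiffness = stiffness
            full = ChainModel.from_segment(geom, chars, removed=removed)
        ref = _neutral_reference(full)
        samples = []
        for _, row in engaging.iterrows():
            direction = str(row["direction"])
            axis, sign = DIRECTION_AXIS[direction]
            phi_t = ref[0].rot[axis] + sign * np.radians(row["rom_mean_deg"])
            try:
                res, load, axis = _constrained_solve(full, direction, row["torque_nm"], phi_t)
            except SolverError as err:
                log.warning("facet extraction: solver failed at %s %s Nm: %s",
                            direction, row["torque_nm"], err)
                continue
            deficit = _axis_deficit(known, res.poses, load, axis)
            required = -deficit  # torque the facets must supply
            g = _facet_moment_per_unit_stiffness(geom, res.poses[0], axis)
            if abs(g) < 1e-9:
                log.info("facet extraction: no contact at %s %s Nm; skipped",
                         direction, row["torque_nm"])
                continue
            k = required / g
            if k < 0:
                log.info("facet extraction: negative stiffness sample at %s %s Nm; skipped",
                         direction, row["torque_nm"])
                continue
            samples.append((k, direction, float(row["torque_nm"]), float(g)))
        if not samples:
            log.warning("facet extraction: zero deficit in all records; stiffness 0")
            return 0.0, {"samples": [], "n": 0}
        # least-squares scalar through the origin of (g, M) pairs: records
        # with deeper contact carry proportionally more information
        gs = np.array([s[3] for s in samples])
        Ms = np.array([s[0] * s[3] for s in samples])
        new_stiffness = float((gs * Ms).sum() / (gs**2).sum())
        if stiffness is not None and abs(new_stiffness - stiffness) < 1e-3 * abs(stiffness):
            stiffness = new_stiffness
            break
        stiffness = new_stiffness
    diag = {"samples": samples, "n": len(samples)}
    return stiffness, diag


def _facet_moment_per_unit_stiffness(geom: SegmentGeometry, pose: Pose, axis: int) -> float:
    """Restoring moment about ``axis`` per unit contact stiffness (m^2-ish
    aggregate of penetration depth times lever) summed over both facets."""
    from .force_elements import facet_force

    total = 0.0
    ref = np.asarray(geom.disk_centre, float) + pose.trans
    for fs in geom.facets.values():
        if fs is None:
            continue
        _F, T = facet_force(fs, pose, geom.disk_centre, geom.cranial.com, geom.caudal.com,
                            ref_point=ref, stiffness=1.0)
        total += T[axis]
    return total


# ---------------------------------------------------------------------------
# ligaments


def extract_ligament_points(rom: ROMTable, stage: str, new_ligament: str,
                            partial_model: CalibratedModel, geom: SegmentGeometry,
                            estimate: LigamentCharacteristic | None = None,
                            keep_negative: bool = False,
                            ) -> list[CharacteristicPoint]:
    """Force-strain samples of the ligament first present at ``stage``.

    For each nonzero-torque record the loading-axis rotation is pinned to
    the stage's neutral reference plus the recorded mean ROM; free DOFs are
    equilibrated (with ``estimate`` standing in for the new ligament when
    supplied); the known-element deficit moment is divided by the ligament's
    moment arm.  Bilateral pairs split a symmetric-load deficit equally; in
    lateral/axial loading only the more strained side is credited.  Records
    are skipped (and logged) when the element would need to push (negative
    deficit), when its moment arm vanishes (< 1 mm), or when the record
    leaves the ligament slack — strained no further than at the stage's
    neutral pose, where the deficit is dominated by reference error rather
    than ligament force.
    """
    from .geometry import ligament_kinematics

    removed = STAGE_REMOVED[stage]
    chars = partial_model.copy()
    known = ChainModel.from_segment(geom, chars, removed=removed | {new_ligament})
    if estimate is not None:
        chars_full = chars.copy()
        chars_full.ligaments[new_ligament] = estimate
        full = ChainModel.from_segment(geom, chars_full, removed=removed)
    else:
        full = known
    ref = _neutral_reference(full)

    sides = [lig for lig in geom.ligaments if lig.name == new_ligament]
    if not sides:
        raise CalibrationError(f"geometry has no ligament named {new_ligament!r}")
    # strain of each side at the stage's neutral pose: the slack threshold
    ref_kins = [ligament_kinematics(geom, lig, ref[0]) for lig in sides]
    eps_ref = [k.strain for k in ref_kins]

    points: list[CharacteristicPoint] = []
    n_skipped = 0
    for _, row in rom.stage_records(stage).iterrows():
        direction = str(row["direction"])
        axis, sign = DIRECTION_AXIS[direction]
        phi_t = ref[0].rot[axis] + sign * np.radians(row["rom_mean_deg"])
        try:
            res, load, axis = _constrained_solve(full, direction, row["torque_nm"], phi_t,
                                                 init=ref)
        except SolverError as err:
            log.warning("ligament extraction (%s): solver failed at %s %s Nm: %s",
                        new_ligament, direction, row["torque_nm"], err)
            continue
        deficit = _axis_deficit(known, res.poses, load, axis)
        required = -deficit
        kins = [ligament_kinematics(geom, lig, res.poses[0]) for lig in sides]
        arms = np.array([k.moment_arm[AXES[axis]] for k in kins])
        strained = [i for i, k in enumerate(kins)
                    if k.strain > eps_ref[i] + SLACK_MARGIN_PCT]
        if not strained:
            n_skipped += 1
            log.info("ligament %s: not strained beyond neutral at %s %s Nm; skipped",
                     new_ligament, direction, row["torque_nm"])
            continue
        if _fold_direction(direction) in ("lateral", "axial") and len(strained) > 1:
            pick = [max(strained, key=lambda i: kins[i].strain)]
        else:
            pick = strained
        arm_sum = float(arms[pick].sum())
        if abs(arm_sum) < 1e-3:
            n_skipped += 1
            log.info("ligament %s: |moment arm| < 1 mm at %s %s Nm; skipped",
                     new_ligament, direction, row["torque_nm"])
            continue
        # sides not credited with the deficit (the less-strained side of a
        # bilateral pair in asymmetric loading) can still carry tension via
        # their prestrain; subtract their current-estimate contribution so
        # the deficit attributed to the picked side is theirs alone
        if estimate is not None:
            for i in range(len(sides)):
                if i not in pick:
                    f_other = float(np.maximum(estimate.spring_force(kins[i].strain), 0.0))
                    required -= float(arms[i]) * f_other
        force = required / arm_sum
        if force < 0 and not keep_negative:
            n_skipped += 1
            log.info("ligament %s: negative deficit at %s %s Nm; skipped",
                     new_ligament, direction, row["torque_nm"])
            continue
        for i in pick:
            points.append(CharacteristicPoint(
                abscissa=float(kins[i].strain), ordinate=float(force),
                stage=stage, direction=direction, torque=float(row["torque_nm"]),
                weight=abs(arm_sum), axis=axis,
            ))
    if not points:
        raise CalibrationError(
            f"ligament {new_ligament!r} is slack in every record of stage {stage!r}"
        )
    log.debug("ligament %s: %d points extracted, %d records skipped",
              new_ligament, len(points), n_skipped)
    return points


def fit_ligament_characteristic(points, *, min_points: int = 5, min_span: float = 5.0,
                                starts=None, positive_d: bool = False,
                                ) -> tuple[LigamentCharacteristic, float]:
    """Trust-region least-squares fit of the softplus force-strain law.

    Multi-start over a coarse parameter grid, including negative-``d``
    starts (needed for concave curves such as the flaval ligament's).
    Samples carry weights proportional to the moment arm they were inferred
    through (their force-error standard deviation scales with 1/|arm|).
    Ties within 1e-6 N RMSE are broken toward the smaller ``|b|`` solution.
    Returns the characteristic and the (weighted) fit RMSE (N).
    """
    pts = np.array([(p.abscissa, p.ordinate, p.weight)
                    if isinstance(p, CharacteristicPoint) else (*p, 1.0)[:3]
                    for p in points], dtype=float)
    if pts.shape[0] < min_points:
        raise CalibrationError(f"need >= {min_points} points, got {pts.shape[0]}")
    eps, F = pts[:, 0], pts[:, 1]
    w = pts[:, 2] / pts[:, 2].max()
    span = float(eps.max() - eps.min())
    if np.abs(F).max() < 0.5:
        log.warning("all sampled forces are ~0; returning the zero characteristic")
        char = LigamentCharacteristic(a=0.0, b=0.0, c=0.0, d=1.0)
        return char, float(np.sqrt(np.mean(F**2)))
    if span < min_span:
        raise InsufficientSpanError(
            f"strain span {span:.2f}% < {min_span}% cannot constrain the softplus fit"
        )
    sw = np.sqrt(w / w.sum())

    def resid(p):
        a, b, c, d = p
        return sw * (a * np.logaddexp(0.0, (eps + b) / d) + c - F)

    if starts is None:
        slope = (F.max() - F.min()) / max(span, 1e-6)
        mid = float(np.median(eps))
        d_grid = (0.03, 1.0, 5.0, 15.0, 60.0) if positive_d else (0.03, 1.0, 5.0, 15.0, 60.0, -11.0)
        starts = []
        for d in d_grid:
            for b in (-40.0, -mid, 0.0, 20.0):
                for a in (abs(slope * d) + 0.1, 50.0):
                    for c in (float(F.min()), 0.0):
                        starts.append((a, b, c, d))

    lb = [-np.inf, -np.inf, -np.inf, 1e-6 if positive_d else -np.inf]
    solutions = []
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="trf", bounds=(lb, np.inf),
                                x_scale=[50.0, 10.0, 20.0, 5.0],
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400)
        except Exception:  # pragma: no cover
            continue
        solutions.append(sol)
    if not solutions:
        raise CalibrationError("ligament fit failed from every start")
    # with sw normalised to unit total weight, sqrt(2 cost) is the weighted RMSE
    best_rmse = min(np.sqrt(2 * s.cost) for s in solutions)
    # Degeneracy guard: a quasi-linear point cloud is fitted equally well by
    # softplus curves of any knee sharpness.  Among all fits within 25% of
    # the best residual, prefer the widest transition (largest |d| — the
    # smoothest curve introduces no structure the samples do not demand),
    # then the smaller |b|.  A genuinely sharp knee inside the sampled range
    # makes every smooth candidate much worse than 25%, so it survives.
    near = [s for s in solutions if np.sqrt(2 * s.cost) <= best_rmse * 1.25 + 1e-6]
    chosen = min(near, key=lambda s: (-abs(s.x[3]), abs(s.x[1])))
    a, b, c, d = (float(v) for v in chosen.x)
    rmse = float(np.sqrt(np.sum(resid(chosen.x) ** 2)))
    return LigamentCharacteristic(a=a, b=b, c=c, d=d), rmse


# ---------------------------------------------------------------------------
# pipeline


def _fit_or_zero(pts, *, min_points, min_span, positive_d=False):
    """Fit the softplus law, degrading to the zero curve when the sampled
    forces are negligible over a too-narrow span."""
    try:
        return fit_ligament_characteristic(pts, min_points=min_points,
                                           min_span=min_span, positive_d=positive_d)
    except InsufficientSpanError:
        forces = [p.ordinate for p in pts]
        if max(np.abs(forces)) < 2.0:
            log.warning("narrow strain span with near-zero forces; zero curve")
            return (LigamentCharacteristic(a=0.0, b=0.0, c=0.0, d=1.0),
                    float(np.sqrt(np.mean(np.square(forces)))))
        raise


def _provisional_linear(pts) -> LigamentCharacteristic:
    """Degenerate bootstrap when too few samples exist for a real fit: the
    softplus in its deep linear regime through the available points (or a
    constant for a single point), clamped non-negative by the force law."""
    eps = np.array([p.abscissa for p in pts])
    F = np.array([p.ordinate for p in pts])
    span = float(eps.max() - eps.min())
    if len(pts) >= 2 and span > 1e-6:
        s = max((F.max() - F.min()) / span, 0.0)
    else:
        s = 0.0
    d = 20.0
    if s <= 1e-9:
        return LigamentCharacteristic(a=0.0, b=0.0, c=float(F.mean()), d=1.0)
    # linear regime: F ~ (a/d)(eps + b) + c with the knee pushed far left
    b = 60.0 - float(eps.min())
    c = float(F.min()) - s * (eps.min() + b)
    return LigamentCharacteristic(a=s * d, b=b, c=c, d=d)


def _low_strain_point(pts):
    """The lowest-strain reliable sample — the best observable proxy for
    the element's force at the stage's neutral pose.  Samples inferred
    through small moment arms are ignored (their force error blows up as
    1/arm)."""
    if not pts:
        return None
    wmax = max(p.weight for p in pts)
    good = [p for p in pts if p.weight >= 0.5 * wmax]
    return min(good, key=lambda p: p.abscissa)


def _bootstrap_neutral_force(rom, stage, element, model, geom):
    """Choose the basin for the fixed-point iteration of one ligament step.

    The stage's 0 Nm reference pose depends on the uncalibrated element's
    neutral tension, and the iteration's gain in that scalar is
    k(record)/k(ref), which exceeds one whenever the segment is stiffer at
    the recorded poses than at neutral (usual here, the disk torque law
    being soft near zero) — a cold start can then converge to a
    self-consistent but unphysical solution.  The physical basin is
    recognisable from the samples themselves: in it, every record yields a
    non-negative force and the forces vary smoothly with strain, whereas a
    reference error imprints the segment's stiffness profile on them.  The
    neutral force level is therefore scanned (coarse grid, then local
    refinement) with an affine provisional law, scoring each level by
    usable-record count and by the residual of a straight line through the
    reliable samples; the winner's own line becomes the starting estimate.
    """
    sides = [lig for lig in geom.ligaments if lig.name == element]
    eps_pre = float(np.mean([lig.prestrain for lig in sides])) if sides else 0.0
    if eps_pre < 0:
        # declared negative prestrain: the ligament is slack at neutral and
        # cannot bias the reference pose — no basin ambiguity to resolve
        log.debug("%s: slack at neutral (prestrain %.1f%%); zero-force start",
                  element, eps_pre)
        return LigamentCharacteristic(a=0.0, b=0.0, c=0.0, d=1.0)

    def linear_est(f_n, slope):
        # knee pushed far below the working range so the law is genuinely
        # affine there: F ~ slope * (eps + 80) + c
        d, b = 20.0, 80.0
        slope = max(slope, 0.0)
        return LigamentCharacteristic(a=slope * d, b=b,
                                      c=float(f_n - slope * (eps_pre + b)), d=d)

    def line_fit(pts):
        """Weighted straight line through the reliable samples; returns
        (intercept, slope, residual RMS)."""
        if not pts:
            return None
        wmax = max(p.weight for p in pts)
        good = [p for p in pts if p.weight >= 0.5 * wmax]
        if len(good) < 2:
            return None
        e = np.array([p.abscissa for p in good])
        F = np.array([p.ordinate for p in good])
        w = np.array([p.weight for p in good])
        if e.max() - e.min() < 1e-6:
            return None
        coef = np.polyfit(e, F, 1, w=np.sqrt(w))
        r = np.polyval(coef, e) - F
        return float(coef[1]), float(coef[0]), float(np.sqrt(np.mean(r**2)))

    def evaluate(f_n, slope):
        try:
            pts = extract_ligament_points(rom, stage, element, model, geom,
                                          estimate=linear_est(f_n, slope))
        except (CalibrationError, SolverError):
            return None
        lf = line_fit(pts)
        if lf is None:
            # too few reliable samples for a line: the probe level still
            # gets scored by how many records it explains
            return {"f": f_n, "n": len(pts), "resid": np.inf,
                    "intercept": f_n - 0.0 * eps_pre, "slope": 0.0, "pts": pts}
        return {"f": f_n, "n": len(pts), "resid": lf[2],
                "intercept": lf[0], "slope": lf[1], "pts": pts}

    first = evaluate(0.0, 0.0)
    slope = max(first["slope"], 0.0) if first is not None else 0.0

    def better(a, b):
        if a is None:
            return False
        if b is None:
            return True
        return (a["n"], -a["resid"]) > (b["n"], -b["resid"])

    best = evaluate(0.0, slope)
    for f_n in (5.0, 10.0, 20.0, 40.0, 80.0, 160.0):
        cand = evaluate(f_n, slope)
        if better(cand, best):
            best = cand
    if best is None:
        return linear_est(0.0, slope)
    for step in (5.0, 2.0):
        for f_n in (best["f"] - step, best["f"] + step):
            if f_n < 0:
                continue
            cand = evaluate(f_n, max(best["slope"], 0.0))
            if better(cand, best):
                best = cand
    slope_star = max(best["slope"], 0.0)
    f_star = max(best["intercept"] + slope_star * eps_pre, 0.0)
    log.debug("%s: neutral-force bootstrap %.1f N (slope %.2f N/%%, %d records, "
              "line residual %.2f N)", element, f_star, slope_star, best["n"],
              best["resid"])
    return linear_est(f_star, slope_star)


def _calibrate_ligament(rom, stage, element, model, geom, n_iter):
    """Fixed-point iteration of one ligament step: extract points with the
    current estimate in the loop, refit, repeat until the curve stops
    moving; the final fit must satisfy the full preconditions."""
    estimate = _bootstrap_neutral_force(rom, stage, element, model, geom)
    pts: list[CharacteristicPoint] = []
    for it in range(n_iter):
        try:
            pts = extract_ligament_points(rom, stage, element, model, geom,
                                          estimate=estimate)
        except SolverError:
            if estimate is None:
                raise
            log.warning("%s: solver rejected the provisional estimate; restarting "
                        "from the known-elements-only reference", element)
            estimate = None
            pts = extract_ligament_points(rom, stage, element, model, geom)
        except CalibrationError as err:
            # noisy data can leave an iteration with no engaged record at
            # all; keep whatever the previous iterations established
            if estimate is None:
                raise
            log.warning("%s: %s; keeping the previous estimate", element, err)
            break
        if len(pts) < 3:
            log.info("%s: only %d usable records this iteration; linear bootstrap",
                     element, len(pts))
            estimate = _provisional_linear(pts)
            continue
        # the first pass fits within the monotone positive-d family:
        # early point sets are sparse and reference-biased, and an
        # unconstrained 4-parameter fit of them can steer the iteration
        # into a spurious self-consistent basin
        new_est, rmse = _fit_or_zero(pts, min_points=3, min_span=1.0,
                                     positive_d=(it == 0))
        # blow-up guard: a provisional curve must stay commensurate with
        # the forces actually sampled
        strains = np.array([p.abscissa for p in pts])
        fmax = max(1.0, float(np.abs([p.ordinate for p in pts]).max()))
        probe = np.linspace(strains.min() - 5.0, strains.max() + 5.0, 50)
        if np.abs(new_est.spring_force(probe)).max() > 50.0 * fmax:
            # retry within the monotone positive-d family before giving up
            try:
                new_est, rmse = _fit_or_zero(pts, min_points=3, min_span=1.0,
                                             positive_d=True)
            except CalibrationError:
                new_est = None
            if new_est is None or np.abs(new_est.spring_force(probe)).max() > 50.0 * fmax:
                log.warning("%s: provisional fit diverged; keeping previous estimate",
                            element)
                new_est = estimate if estimate is not None else _provisional_linear(pts)
        if estimate is not None and new_est is not None:
            delta = float(np.abs(np.maximum(new_est.spring_force(strains), 0.0)
                                 - np.maximum(estimate.spring_force(strains), 0.0)).max())
            # no point iterating the curve below the samples' own noise floor
            if delta < max(0.02, 0.1 * rmse):
                estimate = new_est
                break
        estimate = new_est
    else:
        it = n_iter - 1
    # final fit at the full preconditions on the converged point set; when
    # noise leaves too few engaged records to satisfy them, the last
    # iterate (or bootstrap) estimate is kept — a weakly observed element
    # is reported as observed rather than aborting the whole pipeline
    try:
        estimate, rmse = _fit_or_zero(pts, min_points=5, min_span=5.0)
    except CalibrationError as err:
        if estimate is None:
            raise
        forces = [p.ordinate for p in pts] or [0.0]
        if max(np.abs(forces)) < 2.0:
            estimate = LigamentCharacteristic(a=0.0, b=0.0, c=0.0, d=1.0)
            rmse = float(np.sqrt(np.mean(np.square(forces))))
            log.warning("%s: %s; near-zero forces, zero curve kept", element, err)
        else:
            rmse = float("nan")
            log.warning("%s: %s; keeping the provisional estimate", element, err)
    return estimate, pts, rmse, it + 1


def run_backward_calibration(rom: ROMTable, geom: SegmentGeometry,
                             prestrains: dict[str, float] | None = None,
                             base: CalibratedModel | None = None,
                             n_iter: int = 10) -> CalibratedModel:
    """Full backward pipeline: disk <- "w/o ALL", then ALL, PLL, facet
    stiffness, CL, FL, ISL, SSL from successively less reduced stages.

    Each element is extracted by fixed-point iteration — extract points,
    fit, re-equilibrate with the fitted estimate included, re-extract —
    until the fitted curve stops moving (or ``n_iter`` is reached), then
    frozen before the next step.  ``base`` supplies the parts the ROM
    protocol cannot constrain (axial/shear disk stiffness, damping, the
    intertransverse ligament's zero-force default); it defaults to the
    packaged set.  ``prestrains`` overrides the per-ligament neutral strains
    declared in the geometry.
    """
    missing = [s for s in STAGES if s not in set(rom.df["stage"])]
    if missing:
        raise CalibrationError(f"ROM table is missing stages: {missing}")

    if base is None:
        from .io import load_characteristics, packaged_default_path
        base = load_characteristics(packaged_default_path())

    geom = copy.deepcopy(geom)
    if prestrains:
        for lig in geom.ligaments:
            if lig.name in prestrains:
                lig.prestrain = prestrains[lig.name]

    diagnostics: dict = {}

    disk_points = extract_disk_points(rom)
    rot = {}
    for direction, pts in disk_points.items():
        params, rmse = fit_disk_characteristic(pts, direction)
        rot[direction] = params
        diagnostics[f"disk_{direction}"] = {"rmse_nm": rmse, "n_points": len(pts)}
    disk = DiskCharacteristic(
        rot=rot, axial_quad=base.disk.axial_quad, axial_lin=base.disk.axial_lin,
        shear_stiffness=base.disk.shear_stiffness,
        d_damp_tra=base.disk.d_damp_tra, d_damp_rot=base.disk.d_damp_rot,
    )

    itl = base.ligaments.get("ITL", LigamentCharacteristic(a=0.0, b=0.0, c=0.0, d=1.0))
    model = CalibratedModel(
        disk=disk, ligaments={"ITL": itl},
        facet_stiffness=0.0, facet_damping=base.facet_damping,
        prestrains={lig.name: lig.prestrain for lig in geom.ligaments},
    )

    for element, stage in CALIBRATION_SEQUENCE:
        try:
            if element == "facets":
                stiffness, diag = extract_facet_stiffness(rom, geom, model,
                                                          n_iter=n_iter, stage=stage)
                model.facet_stiffness = stiffness
                diagnostics["facet_stiffness"] = {"value_n_per_m": stiffness, **diag}
                continue
            estimate, pts, rmse, n_used = _calibrate_ligament(
                rom, stage, element, model, geom, n_iter)
            model.ligaments[element] = estimate
            strains = [p.abscissa for p in pts] or [float("nan")]
            diagnostics[element] = {
                "rmse_n": rmse, "n_points": len(pts), "n_iterations": n_used,
                "strain_range_pct": (float(min(strains)), float(max(strains))),
            }
        except CalibrationError as err:
            raise CalibrationError(f"calibration failed at stage {stage!r} "
                                   f"({element}): {err}") from err

    model.diagnostics = diagnostics
    return model
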