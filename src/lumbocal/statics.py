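"""Quasi-static equilibrium of a motion segment or a lumbar chain.

The state of a chain with ``n`` mobile bodies is the stack of the ``n``
segment poses (rotation vector + disk-centre translation, expressed in each
caudal body's frame).  The residual is the generalized wrench (force,
torque) on every mobile body, assembled from disk bushing, ligament, facet
contact and muscle-cable elements plus the externally applied pure moment;
its zero is the equilibrium.  The residual torque of body ``i`` is taken
about the posed centre of its supporting disk — equilibrium (a zero wrench)
is independent of that reference choice.

The solver is a damped Newton iteration with a central finite-difference
Jacobian and a dynamic-relaxation fallback (damped explicit integration of
the equations of motion until the kinetic energy dies out), with the applied
load ramped in a few warm-started increments for robustness.  Equilibrium
results are damping-independent since all damping terms are linear in rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .force_elements import (
    DiskCharacteristic,
    LigamentCharacteristic,
    MuscleCableDef,
    disk_axial_spring_force,
    disk_force,
    disk_torque,
    ligament_force,
)
from .geometry import (
    AXES,
    GeometryError,
    Pose,
    SegmentGeometry,
    SpineGeometry,
    segment_transform,
)

__all__ = [
    "LoadCase",
    "EquilibriumResult",
    "SolverError",
    "ChainModel",
    "residual_wrench",
    "solve_equilibrium",
    "rom_from_result",
    "load_case_for",
    "DIRECTION_AXIS",
]

log = logging.getLogger(__name__)

#: Loading direction -> (rotation axis index, sign of the applied moment).
DIRECTION_AXIS = {
    "flexion": (0, +1),
    "extension": (0, -1),
    "lateral": (1, +1),
    "lateral+": (1, +1),
    "lateral-": (1, -1),
    "axial": (2, +1),
    "axial+": (2, +1),
    "axial-": (2, -1),
    "neutral": (0, 0),
}


class SolverError(RuntimeError):
    """Equilibrium search failed; carries the last residual for diagnosis."""

    def __init__(self, message: str, residual: np.ndarray | None = None):
        super().__init__(message)
        self.residual = residual


def _pose_from_q(q6: np.ndarray) -> Pose:
    """Pose from a state slice without invariant checks (solver internal:
    intermediate iterates may transiently leave the valid chart)."""
    p = object.__new__(Pose)
    p.rot = q6[:3].copy()
    p.trans = q6[3:6].copy()
    return p


@dataclass
class LoadCase:
    """A spine-tester loading scenario: a pure moment on the loaded (topmost)
    body, optionally with constant-force muscle cables active."""

    applied_torque: np.ndarray = field(default_factory=lambda: np.zeros(3))  # Nm, global
    direction: str = "neutral"
    muscles: list[MuscleCableDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.applied_torque = np.asarray(self.applied_torque, dtype=float)
        if self.applied_torque.shape != (3,):
            raise ValueError("applied_torque must be a 3-vector")


def load_case_for(direction: str, torque_nm: float, muscles=()) -> LoadCase:
    """Build the pure-moment load case for a named bending direction."""
    axis, sign = DIRECTION_AXIS[direction]
    tau = np.zeros(3)
    if sign:
        tau[axis] = sign * torque_nm
    return LoadCase(applied_torque=tau, direction=direction, muscles=list(muscles))


@dataclass
class EquilibriumResult:
    poses: list[Pose]
    converged: bool
    residual_force: float  # max |F| component over mobile bodies, N
    residual_torque: float  # max |T| component, Nm
    n_iterations: int
    element_state: dict | None = None


# ---------------------------------------------------------------------------


class _SegmentElements:
    """Precomputed element tables of one segment (caudal-frame, neutral)."""

    def __init__(self, seg: SegmentGeometry, chars, removed: frozenset[str],
                 facet_stiffness: float | None, facet_damping: float | None):
        self.seg = seg
        self.disk: DiskCharacteristic = chars.disk
        self.d = np.asarray(seg.disk_centre, float)
        # ligaments
        self.lig_keys: list[str] = []
        self.lig_chars: list[LigamentCharacteristic] = []
        p_cr, p_ca, L0 = [], [], []
        for lig in seg.ligaments:
            if lig.name in removed:
                continue
            char = chars.ligaments.get(lig.characteristic)
            if char is None:
                raise GeometryError(
                    f"no characteristic named {lig.characteristic!r} for ligament {lig.key}"
                )
            a = seg.cranial.point_neutral_world(lig.cranial_point[1]) \
                if lig.cranial_point[0] == seg.cranial.name \
                else seg.caudal.point_neutral_world(lig.cranial_point[1])
            b = seg.caudal.point_neutral_world(lig.caudal_point[1]) \
                if lig.caudal_point[0] == seg.caudal.name \
                else seg.cranial.point_neutral_world(lig.caudal_point[1])
            Ln = float(np.linalg.norm(a - b))
            if Ln <= 0:
                raise GeometryError(f"ligament {lig.key} has zero neutral length")
            self.lig_keys.append(lig.key)
            self.lig_chars.append(char)
            p_cr.append(a)
            p_ca.append(b)
            L0.append(Ln / (1.0 + lig.prestrain / 100.0))
        self.lig_p_cr = np.array(p_cr).reshape(-1, 3)
        self.lig_p_ca = np.array(p_ca).reshape(-1, 3)
        self.lig_L0 = np.array(L0)
        # facets
        self.facets = []
        if "VA" not in removed and "facets" not in removed:
            for side, fs in seg.facets.items():
                if fs is None:
                    continue
                k = facet_stiffness if facet_stiffness is not None else fs.stiffness
                probes = np.asarray(seg.cranial.com, float) + fs.probe_points
                origin = np.asarray(seg.caudal.com, float) + fs.frame.origin
                self.facets.append((side, fs, k, probes, origin))

    def local_wrench(self, pose: Pose, facet_scale: float = 1.0):
        """Element wrench on the cranial body about the posed disk centre,
        in the caudal body's frame.  Returns (F, T, state-dict)."""
        R, t = segment_transform(pose, self.d)
        ref = self.d + pose.trans
        F = disk_force(self.disk, pose.trans)
        T = disk_torque(self.disk, pose.rot)
        state = {
            "disk_r": pose.trans.copy(),
            "disk_phi": pose.rot.copy(),
            "disk_axial_compression_force": disk_axial_spring_force(self.disk, pose.trans[2]),
        }
        # ligaments
        lig_state = {}
        if len(self.lig_keys):
            p_cr = (self.lig_p_cr @ R.T) + t
            delta = self.lig_p_ca - p_cr
            L = np.linalg.norm(delta, axis=1)
            u = delta / L[:, None]
            eps = 100.0 * (L - self.lig_L0) / self.lig_L0
            for i, key in enumerate(self.lig_keys):
                f_mag = float(ligament_force(self.lig_chars[i], eps[i]))
                lig_state[key] = (float(eps[i]), f_mag)
                if f_mag > 0.0:
                    f = f_mag * u[i]
                    F += f
                    T += np.cross(p_cr[i] - ref, f)
        state["ligaments"] = lig_state
        # facet contact
        facet_state = {}
        for side, fs, k, probes, origin in self.facets:
            pts = (probes @ R.T) + t
            local = 1000.0 * ((pts - origin) @ fs.frame.axes.T)
            x, y = local[:, 0], local[:, 1]
            f_surf = fs.height(x, y)
            fx, fy = fs.gradient(x, y)
            scale = np.sqrt(1.0 + fx**2 + fy**2)
            depths = (f_surf - local[:, 2]) / scale / 1000.0
            mag = np.where(depths > 0, facet_scale * k * depths, 0.0)
            facet_state[side] = depths
            if np.any(mag > 0):
                normals = (np.column_stack([-fx, -fy, np.ones_like(fx)]) / scale[:, None]) \
                    @ fs.frame.axes
                f = mag[:, None] * normals
                F += f.sum(axis=0)
                T += np.cross(pts - ref, f).sum(axis=0)
        state["facet_depths"] = facet_state
        return F, T, state


class ChainModel:
    """A solvable model: geometry + characteristic set + active elements.

    ``characteristics`` may be any object exposing ``disk`` (a
    :class:`DiskCharacteristic`), ``ligaments`` (mapping name ->
    :class:`LigamentCharacteristic`) and optionally ``facet_stiffness`` /
    ``facet_damping``; the calibration module's ``CalibratedModel`` and the
    YAML loader both satisfy this.  ``removed`` lists ligament names and/or
    ``"VA"``/``"facets"`` to emulate reduction stages.  The applied moment
    always acts on the topmost body.
    """

    def __init__(self, geometry: SpineGeometry, characteristics, *,
                 removed=(), facet_stiffness: float | None = None):
        self.geometry = geometry
        self.characteristics = characteristics
        self.removed = frozenset(removed)
        if facet_stiffness is None:
            facet_stiffness = getattr(characteristics, "facet_stiffness", None)
        facet_damping = getattr(characteristics, "facet_damping", None)
        self._segments = [
            _SegmentElements(seg, characteristics, self.removed, facet_stiffness, facet_damping)
            for seg in geometry.segments
        ]
        self.n_mobile = geometry.n_mobile
        self.ndof = 6 * self.n_mobile
        # muscle attachments resolved to (body index, neutral-world point)
        self._muscle_cache: dict[int, tuple[int, np.ndarray]] = {}

    @classmethod
    def from_segment(cls, geom: SegmentGeometry, characteristics, **kw) -> "ChainModel":
        spine = SpineGeometry(bodies=[geom.cranial, geom.caudal], segments=[geom])
        return cls(spine, characteristics, **kw)

    def with_removed(self, removed) -> "ChainModel":
        return ChainModel(self.geometry, self.characteristics, removed=removed)

    # -- kinematics --------------------------------------------------------

    def _chain_transforms(self, poses: list[Pose]):
        """World affine map (R, t) of every body, fixed base last (identity)."""
        n = self.n_mobile
        maps = [None] * (n + 1)
        maps[n] = (np.eye(3), np.zeros(3))
        for k in range(n - 1, -1, -1):
            Rk, tk = segment_transform(poses[k], self._segments[k].d)
            Rc, tc = maps[k + 1]
            maps[k] = (Rc @ Rk, Rc @ tk + tc)
        return maps

    def _muscle_attachment(self, m: MuscleCableDef):
        key = id(m)
        if key not in self._muscle_cache:
            body_label, point_label = m.attachment
            for i, body in enumerate(self.geometry.bodies):
                if body.name == body_label:
                    if i == self.n_mobile:
                        raise GeometryError("muscle cables on the fixed base transmit nothing")
                    self._muscle_cache[key] = (i, body.point_neutral_world(point_label))
                    break
            else:
                raise GeometryError(f"muscle cable {m.name}: no body named {body_label!r}")
        return self._muscle_cache[key]

    # -- residual ----------------------------------------------------------

    def residual(self, q: np.ndarray, load: LoadCase, *, load_scale: float = 1.0,
                 want_state: bool = False):
        """Generalized wrench (6 per mobile body) at state ``q``."""
        n = self.n_mobile
        poses = [_pose_from_q(q[6 * k: 6 * k + 6]) for k in range(n)]
        maps = self._chain_transforms(poses)
        forces = [np.zeros(3) for _ in range(n)]
        torques = [np.zeros(3) for _ in range(n)]
        refs = []  # world reference point of each mobile body's residual torque
        for k in range(n):
            Rc, tc = maps[k + 1]
            refs.append(Rc @ (self._segments[k].d + poses[k].trans) + tc)

        states = []
        for k in range(n):
            Rc, tc = maps[k + 1]
            F_loc, T_loc, st = self._segments[k].local_wrench(poses[k])
            if want_state:
                states.append(st)
            F_w = Rc @ F_loc
            T_w = Rc @ T_loc
            forces[k] += F_w
            torques[k] += T_w
            if k + 1 < n:  # reaction on the mobile caudal body
                forces[k + 1] -= F_w
                torques[k + 1] -= T_w + np.cross(refs[k] - refs[k + 1], F_w)

        for m in load.muscles:
            i, p_neutral = self._muscle_attachment(m)
            Ri, ti = maps[i]
            p_w = Ri @ p_neutral + ti
            f = load_scale * m.force * m.direction
            forces[i] += f
            torques[i] += np.cross(p_w - refs[i], f)

        torques[0] += load_scale * load.applied_torque

        R = np.empty(self.ndof)
        for k in range(n):
            R[6 * k: 6 * k + 3] = torques[k]
            R[6 * k + 3: 6 * k + 6] = forces[k]
        if want_state:
            return R, poses, states
        return R

    def element_state(self, poses: list[Pose], load: LoadCase | None = None):
        """Per-segment strains, forces and contact depths at given poses."""
        q = np.concatenate([p.as_vector() for p in poses])
        _, _, states = self.residual(q, load or LoadCase(), want_state=True)
        return states

    # -- solving -----------------------------------------------------------

    def solve(self, load: LoadCase, init: list[Pose] | None = None, *,
              fixed: dict[tuple[int, int], float] | None = None,
              tol_force: float = 1e-6, tol_torque: float = 1e-8,
              max_iter: int = 80, ramp: int = 5, fd_step: float = 1e-7,
              raise_on_failure: bool = True) -> EquilibriumResult:
        """Find the equilibrium state under ``load``.

        ``fixed`` pins individual pose coordinates ``(segment index, coord
        0..2 rotation / 3..5 translation)`` to given values — used by the
        calibration's constrained-pose equilibration.  With a warm ``init``
        the load is applied in one step, otherwise ramped.
        """
        q = np.zeros(self.ndof)
        if init is not None:
            q = np.concatenate([p.as_vector() for p in init])
        free = np.ones(self.ndof, dtype=bool)
        if fixed:
            for (k, c), val in fixed.items():
                free[6 * k + c] = False
                q[6 * k + c] = val

        fractions = [1.0] if init is not None else list(np.linspace(1.0 / ramp, 1.0, ramp))
        total_iters = 0
        for frac in fractions:
            q, iters, ok = self._newton(q, load, frac, free, tol_force, tol_torque,
                                        max_iter, fd_step)
            total_iters += iters
            if not ok:
                log.debug("Newton stagnated at load fraction %.2f; dynamic relaxation", frac)
                q = self._dynamic_relaxation(q, load, frac, free, fd_step)
                q, iters, ok = self._newton(q, load, frac, free, tol_force, tol_torque,
                                            max_iter, fd_step)
                total_iters += iters
            if not ok and init is not None and not fixed:
                # the warm start may sit on the wrong side of a contact or
                # branch switch; retry cold with a full load ramp
                log.debug("warm-started solve stagnated; cold ramped restart")
                q = np.zeros(self.ndof)
                for sub in np.linspace(frac / max(ramp, 3), frac, max(ramp, 3)):
                    q, iters, ok = self._newton(q, load, sub, free, tol_force,
                                                tol_torque, max_iter, fd_step)
                    total_iters += iters
                    if not ok:
                        q = self._dynamic_relaxation(q, load, sub, free, fd_step)
                        q, iters, ok = self._newton(q, load, sub, free, tol_force,
                                                    tol_torque, max_iter, fd_step)
                        total_iters += iters
                    if not ok:
                        break
            if not ok:
                # last resort: Powell's hybrid method copes better with the
                # slack/contact kinks a damped Newton line search stalls on
                q, ok = self._hybr_polish(q, load, frac, free, tol_force, tol_torque)
            if not ok:
                R = self.residual(q, load, load_scale=frac)
                msg = (f"equilibrium not found at load fraction {frac:.2f}: "
                       f"max|T| = {self._tmax(R):.3g} Nm, max|F| = {self._fmax(R):.3g} N")
                if raise_on_failure:
                    raise SolverError(msg, residual=R)
                log.warning(msg)
                break

        R = self.residual(q, load)
        poses = [Pose.from_vector(q[6 * k: 6 * k + 6]) for k in range(self.n_mobile)]
        rf, rt = self._fmax(R), self._tmax(R)
        return EquilibriumResult(
            poses=poses,
            converged=bool(rf < tol_force and rt < tol_torque) if not fixed
            else bool(self._free_converged(R, free, tol_force, tol_torque)),
            residual_force=rf,
            residual_torque=rt,
            n_iterations=total_iters,
        )

    @staticmethod
    def _fmax(R):
        return float(max(np.abs(R[6 * k + 3: 6 * k + 6]).max() for k in range(len(R) // 6)))

    @staticmethod
    def _tmax(R):
        return float(max(np.abs(R[6 * k: 6 * k + 3]).max() for k in range(len(R) // 6)))

    @staticmethod
    def _scaled(R, free=None):
        w = np.ones_like(R)
        for k in range(len(R) // 6):
            w[6 * k: 6 * k + 3] = 100.0  # 1e-8 Nm ~ 1e-6 N on the shared scale
        v = R * w
        if free is not None:
            v = v[free]
        return float(np.linalg.norm(v))

    def _free_converged(self, R, free, tol_force, tol_torque):
        for k in range(len(R) // 6):
            for c in range(6):
                i = 6 * k + c
                if not free[i]:
                    continue
                tol = tol_torque if c < 3 else tol_force
                if abs(R[i]) >= tol:
                    return False
        return True

    def _newton(self, q, load, frac, free, tol_force, tol_torque, max_iter, h):
        q = q.copy()
        nfree = int(free.sum())
        for it in range(max_iter):
            R = self.residual(q, load, load_scale=frac)
            if self._free_converged(R, free, tol_force, tol_torque):
                return q, it, True
            J = np.empty((self.ndof, nfree))
            cols = np.flatnonzero(free)
            for j, c in enumerate(cols):
                qp = q.copy(); qp[c] += h
                qm = q.copy(); qm[c] -= h
                J[:, j] = (self.residual(qp, load, load_scale=frac)
                           - self.residual(qm, load, load_scale=frac)) / (2 * h)
            Jf = J[free, :]
            try:
                step = np.linalg.solve(Jf, -R[free])
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(Jf, -R[free], rcond=None)
            # keep rotations within the chart
            smax = np.abs(step).max()
            if smax > 0.3:
                step *= 0.3 / smax
            base = self._scaled(R, free)
            improved = False
            for damp in (1.0, 0.5, 0.25, 0.1, 0.03, 0.01):
                q_try = q.copy()
                q_try[free] += damp * step
                self._clip_rotations(q_try, free)
                if self._scaled(self.residual(q_try, load, load_scale=frac), free) < base:
                    q = q_try
                    improved = True
                    break
            if not improved:
                return q, it + 1, False
        R = self.residual(q, load, load_scale=frac)
        return q, max_iter, self._free_converged(R, free, tol_force, tol_torque)

    def _clip_rotations(self, q, free):
        """Keep free coordinates in a physically meaningful box: rotations
        inside the rotation-vector chart, translations below vertebral
        scale."""
        for k in range(self.n_mobile):
            for c in range(6):
                i = 6 * k + c
                if free[i]:
                    lim = 1.2 if c < 3 else 0.05
                    q[i] = np.clip(q[i], -lim, lim)

    def _hybr_polish(self, q, load, frac, free, tol_force, tol_torque):
        from scipy.optimize import root as scipy_root

        cols = np.flatnonzero(free)

        def fun(x):
            qq = q.copy()
            qq[cols] = x
            return self.residual(qq, load, load_scale=frac)[cols]

        sol = scipy_root(fun, q[cols], method="hybr",
                         options={"xtol": 1e-14, "maxfev": 4000})
        q_new = q.copy()
        q_new[cols] = sol.x
        R = self.residual(q_new, load, load_scale=frac)
        if self._free_converged(R, free, tol_force, tol_torque):
            return q_new, True
        if self._scaled(R, free) < self._scaled(self.residual(q, load, load_scale=frac),
                                                free):
            q = q_new
        return q, False

    def _dynamic_relaxation(self, q, load, frac, free, h, max_steps: int = 3000,
                            ke_tol: float = 1e-9):
        """Damped explicit integration of the equations of motion until the
        kinetic energy falls below ``ke_tol`` (J).  Generalized masses are
        1 kg / 0.01 kg m^2; per-coordinate damping is set near critical from
        a finite-difference stiffness estimate."""
        q = q.copy()
        cols = np.flatnonzero(free)
        mass = np.array([0.01 if (c % 6) < 3 else 1.0 for c in cols])
        R0 = self.residual(q, load, load_scale=frac)
        k_diag = np.empty(len(cols))
        for j, c in enumerate(cols):
            qp = q.copy(); qp[c] += h
            k_diag[j] = abs((self.residual(qp, load, load_scale=frac) - R0)[c] / h)
        k_diag = np.maximum(k_diag, 1.0)
        omega = np.sqrt(k_diag / mass)
        dt = 0.25 / omega.max()
        damp = 2.0 * np.sqrt(k_diag * mass)
        v = np.zeros(len(cols))
        best_q, best_norm = q.copy(), np.inf
        for step in range(max_steps):
            R = self.residual(q, load, load_scale=frac)
            norm = self._scaled(R, free)
            if norm < best_norm:
                best_norm, best_q = norm, q.copy()
            elif norm > 100.0 * best_norm:
                # hardening springs outran the stability estimate; restart
                # from the best state with a finer step
                q, v = best_q.copy(), np.zeros(len(cols))
                dt *= 0.25
                continue
            acc = (R[cols] - damp * v) / mass
            v += dt * acc
            q[cols] += dt * v
            self._clip_rotations(q, free)
            ke = 0.5 * float(np.sum(mass * v**2))
            if ke < ke_tol and np.abs(dt * v).max() < 1e-10:
                break
        return best_q if best_norm < self._scaled(self.residual(q, load, load_scale=frac),
                                                  free) else q


# ---------------------------------------------------------------------------
# module-level operation wrappers


def residual_wrench(model: ChainModel, poses: list[Pose], load: LoadCase) -> np.ndarray:
    """Generalized force vector (torque then force, 6 per mobile body)."""
    q = np.concatenate([p.as_vector() for p in poses])
    return model.residual(q, load)


def solve_equilibrium(model: ChainModel, load: LoadCase,
                      init: list[Pose] | None = None, **kw) -> EquilibriumResult:
    return model.solve(load, init=init, **kw)


def rom_from_result(res: EquilibriumResult, segment: int = 0, axis="x",
                    reference: EquilibriumResult | None = None) -> float:
    """Relative rotation (degrees) of a segment about a loading axis,
    optionally measured from a reference (0 Nm) equilibrium."""
    idx = axis if isinstance(axis, int) else AXES.index(axis)
    phi = res.poses[segment].rot[idx]
    if reference is not None:
        phi -= reference.poses[segment].rot[idx]
    return float(np.degrees(phi))
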