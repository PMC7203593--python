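"""Equilibrium solver: oracle equivalence, symmetry, composition,
damping independence and removal monotonicity."""

import numpy as np
import pytest
from scipy.optimize import brentq

from lumbocal import (
    ChainModel,
    DiskCharacteristic,
    LigamentCharacteristic,
    LoadCase,
    Pose,
    SynthConfig,
    load_case_for,
    make_synthetic_fsu,
    residual_wrench,
    rom_from_result,
)
from lumbocal.calibration import STAGE_REMOVED
from lumbocal.force_elements import DiskRotParams
from lumbocal.geometry import SpineGeometry
from lumbocal.statics import DIRECTION_AXIS


def _linear_disk(k_rot=30.0):
    """A disk whose rotational laws are plain linear springs T = k phi."""
    row = DiskRotParams(p1=0.0, p2=1.0, p3=k_rot)
    return DiskCharacteristic(rot={d: row for d in
                                   ("flexion", "extension", "lateral", "axial")})


class _Chars:
    """Minimal characteristic-set stand-in."""

    def __init__(self, disk, ligaments=None, facet_stiffness=12_000.0):
        self.disk = disk
        self.ligaments = ligaments or {}
        self.facet_stiffness = facet_stiffness
        self.facet_damping = 4_000.0


@pytest.fixture(scope="module")
def disk_only_model(fsu_geom, default_chars):
    return ChainModel.from_segment(fsu_geom, default_chars,
                                   removed=STAGE_REMOVED["w/o ALL"])


def test_linear_spring_closed_form(fsu_geom):
    """With a purely linear torsional disk, equilibrium under moment M sits
    exactly at phi = M / k."""
    chars = _Chars(_linear_disk(k_rot=30.0),
                   {"ITL": LigamentCharacteristic(0.0, 0.0, 0.0, 1.0)})
    model = ChainModel.from_segment(fsu_geom, chars, removed=STAGE_REMOVED["w/o ALL"])
    res = model.solve(load_case_for("lateral", 6.0))
    assert res.converged
    assert res.poses[0].rot[1] == pytest.approx(6.0 / 30.0, abs=1e-8)


def test_neutral_load_gives_identity_pose(disk_only_model):
    """No load and no prestrained elements: the identity pose is the
    equilibrium."""
    res = disk_only_model.solve(LoadCase())
    assert res.converged
    assert res.poses[0].as_vector() == pytest.approx(np.zeros(6), abs=1e-7)


def test_zero_residual_at_rest(disk_only_model):
    R = residual_wrench(disk_only_model, [Pose()], LoadCase())
    assert R == pytest.approx(np.zeros(6), abs=1e-9)


@pytest.mark.parametrize("torque", [1.0, 2.5, 5.0, 7.5, 10.0])
def test_disk_only_flexion_matches_scalar_oracle(disk_only_model, default_chars,
                                                 torque):
    """The six-DOF equilibrium of the disk-only unit reduces to a scalar
    root-find on the flexion torque law; both agree to < 1e-4 rad."""
    warm = None
    for t in [x for x in (1.0, 2.5, 5.0, 7.5, 10.0) if x <= torque]:
        res = disk_only_model.solve(load_case_for("flexion", t), init=warm)
        warm = res.poses
    phi_oracle = brentq(
        lambda p: default_chars.disk.rot["flexion"].torque(p) - torque, 0.0, 0.27)
    assert res.converged
    assert abs(res.poses[0].rot[0] - phi_oracle) < 1e-4
    assert np.degrees(abs(res.poses[0].rot[0] - phi_oracle)) < 0.01


def test_lateral_mirror_symmetry(fsu_geom, default_chars):
    model = ChainModel.from_segment(fsu_geom, default_chars)
    ref = model.solve(LoadCase(), ramp=2)
    plus = model.solve(load_case_for("lateral+", 5.0), init=ref.poses)
    minus = model.solve(load_case_for("lateral-", 5.0), init=ref.poses)
    assert plus.poses[0].rot[1] == pytest.approx(-minus.poses[0].rot[1], abs=2e-5)


def test_serial_chain_composes_segment_rotations(fsu_geom, default_chars):
    """Two identical disk-only segments under the same pure moment each
    rotate like the single unit, and the total equals the sum."""
    single = ChainModel.from_segment(fsu_geom, default_chars,
                                     removed=STAGE_REMOVED["w/o ALL"])
    top = make_synthetic_fsu(SynthConfig(seed=7), cranial_name="A",
                             caudal_name="B", z_offset=0.04)
    bottom = make_synthetic_fsu(SynthConfig(seed=7), cranial_name="B",
                                caudal_name="C", z_offset=0.0)
    bottom.cranial = top.caudal  # share the middle body
    spine = SpineGeometry(bodies=[top.cranial, top.caudal, bottom.caudal],
                          segments=[top, bottom])
    chain = ChainModel(spine, default_chars, removed=STAGE_REMOVED["w/o ALL"])
    torque = 5.0
    res1 = single.solve(load_case_for("flexion", torque), ramp=5)
    res2 = chain.solve(load_case_for("flexion", torque), ramp=5)
    assert res2.converged
    for k in range(2):
        assert res2.poses[k].rot[0] == pytest.approx(res1.poses[0].rot[0], abs=1e-5)
    total = sum(rom_from_result(res2, segment=k, axis="x") for k in range(2))
    assert total == pytest.approx(2 * rom_from_result(res1, 0, "x"), abs=1e-3)


def test_equilibrium_independent_of_damping(fsu_geom, default_chars):
    """Statics must not see the damping coefficients."""
    damped = default_chars.copy()
    damped.disk.d_damp_tra *= 10
    damped.disk.d_damp_rot *= 10
    for lig in damped.ligaments.values():
        lig.damping_factor *= 10
    a = ChainModel.from_segment(fsu_geom, default_chars).solve(
        load_case_for("flexion", 5.0), ramp=3)
    b = ChainModel.from_segment(fsu_geom, damped).solve(
        load_case_for("flexion", 5.0), ramp=3)
    assert b.poses[0].rot[0] == pytest.approx(a.poses[0].rot[0], rel=1e-6)


def test_rom_unit_conversion():
    res_like = type("R", (), {"poses": [Pose(rot=[0.1, 0, 0])]})()
    assert rom_from_result(res_like, 0, "x") == pytest.approx(5.72958, abs=1e-4)
    res_zero = type("R", (), {"poses": [Pose()]})()
    assert rom_from_result(res_zero, 0, "x") == 0.0


def resistive_variant(chars):
    """The characteristic set with the flaval row replaced by a monotone,
    rest-force-free curve, and prestrains zeroed: every element is then
    purely resistive, the premise of removal monotonicity."""
    out = chars.copy()
    out.ligaments["FL"] = LigamentCharacteristic(a=47.11, b=-15.0, c=0.0, d=5.0)
    return out


def test_removal_monotonicity_with_resistive_elements(fsu_geom, default_chars):
    """Deleting a passive element never decreases the flexion ROM at fixed
    torque when every element resists and nothing is prestrained (removing
    something can only soften the segment)."""
    chars = resistive_variant(default_chars)
    geom = make_synthetic_fsu(SynthConfig(seed=7))
    for lig in geom.ligaments:
        lig.prestrain = 0.0
    stage_order = ["intact", "w/o SSL", "w/o ISL", "w/o FL", "w/o CL",
                   "w/o VA", "w/o PLL", "w/o ALL"]
    # prestrain-free cables sit exactly on their slack-taut kink at neutral,
    # which limits how far the Newton polish can push the residual
    tol = {"tol_force": 1e-2, "tol_torque": 1e-4}
    roms = []
    for stage in stage_order:
        model = ChainModel.from_segment(geom, chars, removed=STAGE_REMOVED[stage])
        ref = model.solve(LoadCase(), ramp=2, **tol)
        warm = ref.poses
        for t in (1.0, 2.5, 5.0, 7.5, 10.0):
            res = model.solve(load_case_for("flexion", t), init=warm, **tol)
            warm = res.poses
        roms.append(np.degrees(res.poses[0].rot[0] - ref.poses[0].rot[0]))
    assert np.all(np.diff(roms) >= -1e-3), roms


def test_solver_failure_carries_residual(fsu_geom, default_chars):
    from lumbocal.statics import SolverError

    model = ChainModel.from_segment(fsu_geom, default_chars,
                                    removed=STAGE_REMOVED["w/o ALL"])
    # the flexion law saturates near 10.2 Nm: a vastly larger pure moment
    # has no equilibrium at all
    with pytest.raises(SolverError) as err:
        model.solve(load_case_for("flexion", 1e6), ramp=1)
    assert err.value.residual is not None
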