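"""Constitutive laws: disk bushing, ligament softplus, facet contact,
muscle cables and the intradiscal-pressure conversion."""

import numpy as np
import pytest

from lumbocal import (
    DiskCharacteristic,
    LigamentCharacteristic,
    MuscleCableDef,
    Pose,
    disk_force,
    disk_torque,
    facet_force,
    idp_from_force,
    ligament_force,
    muscle_wrench,
)
from lumbocal.force_elements import DiskRotParams, ligament_stiffness
from lumbocal.geometry import FacetFrame, FacetSurfaceDef


@pytest.fixture(scope="module")
def disk(default_chars):
    return default_chars.disk


class TestDiskForce:
    def test_neutral_is_force_free(self, disk):
        assert disk_force(disk, np.zeros(3)) == pytest.approx(np.zeros(3))

    def test_axial_compression_polynomial(self, disk):
        """1 mm of compression carries 690,234,060e-6 + 659,748e-3 N."""
        F = disk_force(disk, [0, 0, -0.001])
        assert F[2] == pytest.approx(690_234_060 * 1e-6 + 659_748 * 1e-3)
        assert F[2] == pytest.approx(1349.98, abs=0.02)

    def test_axial_tension_transmits_nothing(self, disk):
        """The disk cannot transmit traction: spring force is zero when the
        bodies separate axially."""
        assert disk_force(disk, [0, 0, +0.001])[2] == pytest.approx(0.0)

    def test_shear_is_linear(self, disk):
        F = disk_force(disk, [1e-4, -2e-4, 0])
        assert F[0] == pytest.approx(-disk.shear_stiffness * 1e-4)
        assert F[1] == pytest.approx(disk.shear_stiffness * 2e-4)

    def test_damping_vanishes_at_rest(self, disk):
        at_rest = disk_force(disk, [1e-4, 0, -1e-4], dr=np.zeros(3))
        moving = disk_force(disk, [1e-4, 0, -1e-4], dr=[0.01, 0, 0])
        assert at_rest[0] != pytest.approx(moving[0])
        assert disk_force(disk, [1e-4, 0, -1e-4]) == pytest.approx(at_rest)


class TestDiskTorque:
    def test_zero_rotation_zero_torque(self, disk):
        assert disk_torque(disk, np.zeros(3)) == pytest.approx(np.zeros(3))

    def test_flexion_value(self, disk):
        """T(0.3 rad) with the flexion row: 10.67 tanh(0.027/0.005913)
        - 1.685*0.3 ~ 10.16 Nm of restoring torque."""
        T = disk_torque(disk, [0.3, 0, 0])
        assert -T[0] == pytest.approx(10.162, abs=2e-3)

    def test_flexion_extension_rows_differ(self, disk):
        assert disk_torque(disk, [0.1, 0, 0])[0] != pytest.approx(
            -disk_torque(disk, [-0.1, 0, 0])[0])

    @pytest.mark.parametrize("axis", [1, 2], ids=["lateral", "axial"])
    def test_lateral_axial_odd_symmetry(self, disk, axis):
        for phi in np.linspace(0.01, 0.3, 7):
            v = np.zeros(3)
            v[axis] = phi
            assert disk_torque(disk, v)[axis] == pytest.approx(
                -disk_torque(disk, -v)[axis], rel=1e-12)

    def test_flexion_row_increasing_over_working_range(self, disk):
        """The flexion spring torque grows monotonically over the angles the
        protocol reaches (0.02-0.27 rad; below ~0.018 rad the negative
        linear term wins, and the curve saturates and rolls over past its
        ~10.19 Nm peak at ~0.273 rad)."""
        phi = np.linspace(0.02, 0.27, 500)
        T = disk.rot["flexion"].torque(phi)
        assert np.all(np.diff(T) > 0)

    @pytest.mark.parametrize("row", ["lateral", "axial", "extension"])
    def test_positive_rows_strictly_increasing(self, disk, row):
        phi = np.linspace(0.0, 0.35, 500)
        T = disk.rot[row].torque(phi)
        assert np.all(np.diff(T) > 0)

    def test_p2_zero_rejected(self):
        with pytest.raises(ValueError):
            DiskRotParams(p1=1.0, p2=0.0, p3=1.0)


class TestLigamentForce:
    def test_isl_linear_regime_value(self, default_chars):
        """The interspinous row at 5% strain is deep in its linear regime:
        F ~ 0.4517 * (5 - 3.502) / 0.02414 ~ 28 N."""
        F = ligament_force(default_chars.ligaments["ISL"], 5.0)
        assert F == pytest.approx(28.03, abs=0.05)

    def test_softplus_saturating_slope(self, default_chars):
        """dF/deps tends to a/d at large strain and to 0 at deep slack;
        the numeric slope matches the analytic one in between."""
        c = default_chars.ligaments["ALL"]
        assert c.slope(300.0) == pytest.approx(c.a / c.d, rel=1e-6)
        assert c.slope(-300.0) == pytest.approx(0.0, abs=1e-9)
        for eps in (-5.0, 0.0, 8.0, 20.0):
            h = 1e-6
            num = (c.spring_force(eps + h) - c.spring_force(eps - h)) / (2 * h)
            assert num == pytest.approx(c.slope(eps), rel=1e-6)

    def test_deep_slack_asymptote_is_clamped_offset(self):
        c = LigamentCharacteristic(a=100.0, b=-10.0, c=5.0, d=2.0)
        assert c.spring_force(-1e3) == pytest.approx(5.0, abs=1e-6)
        assert ligament_force(c, -1e3) == pytest.approx(5.0, abs=1e-6)
        neg = LigamentCharacteristic(a=100.0, b=-10.0, c=-5.0, d=2.0)
        assert ligament_force(neg, -1e3) == pytest.approx(0.0)  # cables cannot push

    def test_ssl_branches_continuous_at_zero(self, default_chars):
        """The supraspinous ligament's positive row and its negative-strain
        branch agree at zero strain to within 0.1 N."""
        ssl = default_chars.ligaments["SSL"]
        pos = ssl.a * np.logaddexp(0, (0 + ssl.b) / ssl.d) + ssl.c
        na, nb, nc, nd = ssl.neg_branch
        neg = na * np.logaddexp(0, (0 + nb) / nd) + nc
        assert abs(pos - neg) < 0.1
        # branch selection: negative strain follows the negative row
        assert ssl.spring_force(-5.0) == pytest.approx(
            na * np.logaddexp(0, (-5.0 + nb) / nd) + nc)

    def test_discontinuous_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            LigamentCharacteristic(a=1.0, b=-20.0, c=0.0, d=1.0,
                                   neg_branch=(0.0, 0.0, 5.0, 1.0))

    def test_stiffness_zero_where_clamped(self, default_chars):
        c = default_chars.ligaments["ALL"]
        assert ligament_stiffness(c, -50.0) == pytest.approx(0.0)
        assert ligament_stiffness(c, 20.0) > 0

    def test_d_zero_rejected(self):
        with pytest.raises(ValueError):
            LigamentCharacteristic(a=1.0, b=0.0, c=0.0, d=0.0)


def _flat_facet(p00_mm=0.0, gap_mm=-1.0):
    """A horizontal contact plane with one probe ``gap_mm`` above it
    (negative = penetrating)."""
    frame = FacetFrame(origin=[0, 0, 0], axes=np.eye(3))
    probe = np.array([[0.0, 0.0, (p00_mm + gap_mm) / 1000.0]])
    return FacetSurfaceDef(p30=0, p03=0, p20=0, p02=0, p00=p00_mm, frame=frame,
                           stiffness=12_000.0, damping=4_000.0,
                           probe_points=probe)


class TestFacetContact:
    COM = np.zeros(3)

    def test_separated_probe_gives_zero_wrench(self):
        fs = _flat_facet(gap_mm=+0.5)
        F, T = facet_force(fs, Pose(), [0, 0, 0], self.COM, self.COM)
        assert F == pytest.approx(np.zeros(3)) and T == pytest.approx(np.zeros(3))

    def test_one_mm_penetration_of_flat_plane(self):
        """A probe 1 mm below a flat plane at 12,000 N/m carries 12 N along
        the plane normal."""
        fs = _flat_facet(gap_mm=-1.0)
        F, _T = facet_force(fs, Pose(), [0, 0, 0], self.COM, self.COM)
        assert F[2] == pytest.approx(12.0)
        assert F[:2] == pytest.approx([0.0, 0.0])

    def test_force_linear_in_penetration(self):
        f1, _ = facet_force(_flat_facet(gap_mm=-1.0), Pose(), [0, 0, 0],
                            self.COM, self.COM)
        f2, _ = facet_force(_flat_facet(gap_mm=-2.0), Pose(), [0, 0, 0],
                            self.COM, self.COM)
        assert f2[2] == pytest.approx(2 * f1[2])


class TestMuscleCable:
    def test_offset_attachment_lever(self):
        """40 N pulled caudally from a point 30 mm off-axis torques 1.2 Nm
        about the medio-lateral axis."""
        m = MuscleCableDef("m", ("b", "p"), direction=[0, 0, -1], force=40.0)
        F, T = muscle_wrench(m, attachment_world=[0, 0.03, 0], ref_point=[0, 0, 0])
        assert F == pytest.approx([0, 0, -40.0])
        assert np.linalg.norm(T) == pytest.approx(1.2)
        assert T[0] == pytest.approx(-1.2)

    def test_on_axis_pull_is_pure_force(self):
        m = MuscleCableDef("m", ("b", "p"), direction=[0, 0, -1], force=40.0)
        _F, T = muscle_wrench(m, attachment_world=[0, 0, 0.05], ref_point=[0, 0, 0])
        assert T == pytest.approx(np.zeros(3))

    def test_mirrored_pair_axial_torques_cancel(self):
        left = MuscleCableDef("l", ("b", "p"), direction=[0.15, 0.1, -1] / np.linalg.norm([0.15, 0.1, -1]), force=40.0)
        right = MuscleCableDef("r", ("b", "p"), direction=[-0.15, 0.1, -1] / np.linalg.norm([0.15, 0.1, -1]), force=40.0)
        _fl, tl = muscle_wrench(left, [0.02, 0.03, 0], [0, 0, 0])
        _fr, tr = muscle_wrench(right, [-0.02, 0.03, 0], [0, 0, 0])
        assert tl[2] + tr[2] == pytest.approx(0.0, abs=1e-12)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            MuscleCableDef("m", ("b", "p"), direction=[0, 0, -2], force=40.0)


class TestIntradiscalPressure:
    def test_brinckmann_conversion(self):
        """500 N over 5 cm^2 gives 1.68 * 10^6 Pa."""
        assert idp_from_force(500.0, 5e-4) == pytest.approx(1.68e6)

    def test_zero_force_zero_pressure(self):
        assert idp_from_force(0.0, 5e-4) == 0.0

    def test_linearity(self):
        assert idp_from_force(1000.0, 5e-4) == pytest.approx(
            2 * idp_from_force(500.0, 5e-4))

    def test_invalid_area_rejected(self):
        with pytest.raises(ValueError):
            idp_from_force(100.0, 0.0)


def test_rest_model_transmits_nothing(default_chars):
    """With zero deformation and prestrain-free, zero-offset cables the
    whole element set is force-free."""
    assert disk_force(default_chars.disk, np.zeros(3)) == pytest.approx(np.zeros(3))
    assert disk_torque(default_chars.disk, np.zeros(3)) == pytest.approx(np.zeros(3))
    plain = LigamentCharacteristic(a=10.0, b=-60.0, c=0.0, d=1.0)
    assert ligament_force(plain, 0.0) == pytest.approx(0.0, abs=1e-9)
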