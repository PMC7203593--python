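"""Backward calibration: point extraction, curve fits, facet stiffness."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from lumbocal import (
    CalibratedModel,
    CalibrationError,
    CharacteristicPoint,
    LigamentCharacteristic,
    ROMTable,
    extract_disk_points,
    extract_ligament_points,
    fit_disk_characteristic,
    fit_ligament_characteristic,
    run_backward_calibration,
)
from lumbocal.calibration import ROM_DIRECTIONS, STAGES, TORQUE_SET


def _rom_row(stage, direction, torque, mean, frac=0.15):
    if torque == 0:
        return (stage, direction, 0.0, 0.0, np.nan, np.nan)
    half = max(0.1, frac * mean)
    return (stage, direction, torque, mean, mean - half, mean + half)


def _table_from_disk_law(disk):
    """A disk-only stage table generated by inverting the torque laws."""
    rows = []
    for direction in ROM_DIRECTIONS:
        prm = disk.rot[direction]
        for t in TORQUE_SET:
            if t == 0:
                rows.append(_rom_row("w/o ALL", direction, 0.0, 0.0))
                continue
            phi = brentq(lambda p: prm.torque(p) - t, 0.0, 0.27)
            rows.append(_rom_row("w/o ALL", direction, t, np.degrees(phi)))
    return ROMTable(pd.DataFrame(rows, columns=[
        "stage", "direction", "torque_nm", "rom_mean_deg", "rom_min_deg",
        "rom_max_deg"]))


class TestDiskExtraction:
    def test_points_lie_on_generating_curve(self, default_chars):
        table = _table_from_disk_law(default_chars.disk)
        points = extract_disk_points(table)
        for direction, pts in points.items():
            prm = default_chars.disk.rot[direction]
            assert len(pts) == 6  # five torques plus the origin
            assert pts[0] == pytest.approx([0.0, 0.0])
            for phi, torque in pts[1:]:
                assert prm.torque(phi) == pytest.approx(torque, abs=1e-9)

    def test_signed_lateral_rows_fold_to_one_odd_set(self, default_chars):
        table = _table_from_disk_law(default_chars.disk)
        df = table.df.copy()
        mirrored = df[df.direction == "lateral"].copy()
        mirrored["direction"] = "lateral-"  # same magnitudes, negative arm
        table2 = ROMTable(pd.concat([df, mirrored], ignore_index=True))
        pts = extract_disk_points(table2)["lateral"]
        assert len(pts) == 6  # duplicates collapse onto the odd branch

    def test_missing_stage_raises(self):
        table = ROMTable(pd.DataFrame(
            [_rom_row("intact", "flexion", 5.0, 4.0)],
            columns=["stage", "direction", "torque_nm", "rom_mean_deg",
                     "rom_min_deg", "rom_max_deg"]))
        with pytest.raises(CalibrationError):
            extract_disk_points(table)


class TestDiskFit:
    @pytest.mark.parametrize("direction", ROM_DIRECTIONS)
    def test_recovers_published_rows_from_noiseless_samples(self, default_chars,
                                                            direction):
        prm = default_chars.disk.rot[direction]
        phi = np.linspace(0.0, 0.30, 50)
        fit, rmse = fit_disk_characteristic(
            np.column_stack([phi, prm.torque(phi)]), direction)
        assert rmse < 1e-7
        assert fit.p1 == pytest.approx(prm.p1, rel=1e-4)
        assert fit.p2 == pytest.approx(prm.p2, rel=1e-4)
        assert fit.p3 == pytest.approx(prm.p3, rel=1e-4)

    def test_linear_data_degenerates_to_linear_term(self):
        phi = np.linspace(0.0, 0.3, 30)
        fit, rmse = fit_disk_characteristic(np.column_stack([phi, 3.0 * phi]))
        assert rmse < 1e-6
        model = fit.torque(phi)
        assert model == pytest.approx(3.0 * phi, abs=1e-5)

    def test_too_few_points_rejected(self):
        with pytest.raises(CalibrationError):
            fit_disk_characteristic(np.array([[0.0, 0.0], [0.1, 1.0]]))


class TestLigamentFit:
    def test_recovers_anterior_longitudinal_row(self, default_chars):
        """100 noiseless samples over 0-20% strain, initialization perturbed
        10% from truth: the fitted a returns to 173.5 N (4 s.f.)."""
        g = default_chars.ligaments["ALL"]
        eps = np.linspace(0.0, 20.0, 100)
        pts = [CharacteristicPoint(e, f) for e, f in zip(eps, g.spring_force(eps))]
        fit, rmse = fit_ligament_characteristic(
            pts, starts=[(g.a * 1.1, g.b * 1.1, g.c * 1.1, g.d * 1.1)])
        assert float(f"{fit.a:.4g}") == 173.5
        assert rmse < 1e-8

    def test_recovers_concave_flaval_row_with_negative_d(self, default_chars):
        g = default_chars.ligaments["FL"]
        eps = np.linspace(0.0, 30.0, 100)
        pts = [CharacteristicPoint(e, f) for e, f in zip(eps, g.spring_force(eps))]
        fit, _ = fit_ligament_characteristic(pts)
        assert fit.d < 0
        assert fit.spring_force(eps) == pytest.approx(g.spring_force(eps), abs=1e-4)

    def test_linear_limit(self):
        eps = np.linspace(0.0, 20.0, 40)
        pts = [CharacteristicPoint(e, 2.0 * e) for e in eps]
        fit, rmse = fit_ligament_characteristic(pts)
        assert rmse < 1e-3
        assert fit.spring_force(eps) == pytest.approx(2.0 * eps, abs=5e-3)

    def test_all_zero_points_give_zero_curve(self, caplog):
        pts = [CharacteristicPoint(e, 0.0) for e in np.linspace(0, 20, 10)]
        fit, rmse = fit_ligament_characteristic(pts)
        assert rmse == 0.0
        assert np.all(np.maximum(fit.spring_force(np.linspace(-10, 30, 50)), 0) == 0)

    def test_insufficient_points_rejected(self):
        with pytest.raises(CalibrationError):
            fit_ligament_characteristic(
                [CharacteristicPoint(0, 1), CharacteristicPoint(5, 2)])


class TestLigamentExtraction:
    def test_points_land_on_generating_curve(self, eds1_noise_free, fsu_geom,
                                             default_chars):
        """With the already-known elements and the generating curve supplied
        as the estimate, every extracted anterior-longitudinal sample lies
        on that curve to well within 1 N."""
        partial = CalibratedModel(
            disk=default_chars.disk,
            ligaments={"ITL": default_chars.ligaments["ITL"]},
            facet_stiffness=0.0)
        pts = extract_ligament_points(eds1_noise_free, "w/o PLL", "ALL", partial,
                                      fsu_geom,
                                      estimate=default_chars.ligaments["ALL"])
        assert len(pts) >= 5
        truth = default_chars.ligaments["ALL"]
        for p in pts:
            expected = max(0.0, float(truth.spring_force(p.abscissa)))
            assert p.ordinate == pytest.approx(expected, abs=1.0)

    def test_slack_direction_records_are_skipped(self, eds1_noise_free, fsu_geom,
                                                 default_chars):
        """The anterior ligament slackens in flexion, so no flexion record
        may contribute a force-strain sample."""
        partial = CalibratedModel(
            disk=default_chars.disk,
            ligaments={"ITL": default_chars.ligaments["ITL"]},
            facet_stiffness=0.0)
        pts = extract_ligament_points(eds1_noise_free, "w/o PLL", "ALL", partial,
                                      fsu_geom,
                                      estimate=default_chars.ligaments["ALL"])
        assert all(p.direction != "flexion" for p in pts)
        assert any(p.direction == "extension" for p in pts)


def test_stiffness_sample_pooling_matches_equal_weight_mean():
    """Consistent stiffness samples observed through equal contact geometry
    pool to their mean (10k, 12k, 14k N/m -> 12k)."""
    g = np.full(3, 2.0e-5)  # identical moment-per-unit-stiffness
    k_samples = np.array([10_000.0, 12_000.0, 14_000.0])
    M = k_samples * g
    pooled = float((g * M).sum() / (g**2).sum())
    assert pooled == pytest.approx(12_000.0)


class TestPipeline:
    def test_missing_stage_aborts_with_stage_name(self, eds1_noise_free, fsu_geom,
                                                  default_chars):
        df = eds1_noise_free.df
        truncated = ROMTable(df[df.stage != "w/o VA"].copy())
        with pytest.raises(CalibrationError, match="w/o VA"):
            run_backward_calibration(truncated, fsu_geom, base=default_chars)

    def test_identical_consecutive_stages_give_null_element(self, calibrated):
        """The supraspinous ligament never engages within the protocol's
        strain range, so the intact and first-reduction tables coincide and
        its recovered curve is (numerically) the zero curve."""
        ssl = calibrated.ligaments["SSL"]
        eps = np.linspace(-10.0, 25.0, 100)
        assert np.abs(np.maximum(ssl.spring_force(eps), 0.0)).max() < 0.5

    def test_diagnostics_cover_every_fitted_element(self, calibrated):
        for key in ("disk_flexion", "disk_extension", "disk_lateral",
                    "disk_axial", "facet_stiffness", "ALL", "PLL", "CL",
                    "FL", "ISL", "SSL"):
            assert key in calibrated.diagnostics
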