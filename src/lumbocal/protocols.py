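"""Forward validation protocols and outlier counting.

Two experiment-shaped drivers: the stepwise-reduction ROM protocol (eight
stages x four bending directions x torques {0, 1, 2.5, 5, 7.5, 10} Nm on a
functional unit — 160 nonzero-torque scenarios) and the intradiscal
pressure protocol (seven muscle-cable configurations x seven load cases of
+-3.75 Nm pure moments on the topmost vertebra of an L2-S1 chain — 49
scenarios, pressure read in the L4-L5 disk).  Model outputs are compared to
experiment-shaped reference tables by outlier counting: a value is an
outlier when it leaves the reported min-max range (ROM; boundary values are
inside, 0 Nm rows carry no range) or deviates from the mean by more than
one standard deviation (IDP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .calibration import (
    ROM_DIRECTIONS,
    ROMTable,
    STAGE_REMOVED,
    STAGES,
    TORQUE_SET,
    CalibrationError,
)
from .force_elements import idp_from_force
from .geometry import SegmentGeometry, SpineGeometry
from .statics import (
    DIRECTION_AXIS,
    ChainModel,
    LoadCase,
    SolverError,
    load_case_for,
)

__all__ = [
    "IDPTable",
    "IDP_LOAD_CASES",
    "MUSCLE_CONFIG_NAMES",
    "enumerate_rom_scenarios",
    "enumerate_idp_scenarios",
    "run_stepwise_forward",
    "run_idp_protocol",
    "count_outliers",
]

log = logging.getLogger(__name__)

#: The seven pure-moment load cases of the pressure protocol: neutral plus
#: +-3.75 Nm about each anatomical axis.
IDP_LOAD_CASES = (
    ("neutral", 0.0),
    ("flexion", 3.75),
    ("extension", 3.75),
    ("lateral+", 3.75),
    ("lateral-", 3.75),
    ("axial+", 3.75),
    ("axial-", 3.75),
)

#: The seven muscle-cable configurations: none, each of the five pairs
#: separately, and all five acting jointly.
MUSCLE_CONFIG_NAMES = (
    "none",
    "multifidus_caudal",
    "iliocostalis_longissimus",
    "psoas_corpus",
    "psoas_transversus",
    "multifidus_cranial",
    "all",
)

IDP_COLUMNS = ["muscle_config", "load_case", "idp_mean_mpa", "idp_sd_mpa"]


@dataclass
class IDPTable:
    """Muscle configuration x load case table of intradiscal pressure."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in IDP_COLUMNS[:3] if c not in self.df.columns]
        if missing:
            raise CalibrationError(f"IDP table missing columns: {missing}")
        if "idp_sd_mpa" not in self.df.columns:
            self.df["idp_sd_mpa"] = np.nan
        self.df = self.df[IDP_COLUMNS].reset_index(drop=True)
        sd = self.df["idp_sd_mpa"].dropna()
        if (sd < 0).any():
            raise CalibrationError("idp_sd_mpa must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "IDPTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)


def enumerate_rom_scenarios(nonzero_only: bool = True):
    """All (stage, direction, torque) cells of the stepwise ROM protocol."""
    torques = [t for t in TORQUE_SET if t > 0] if nonzero_only else list(TORQUE_SET)
    return [(s, d, t) for s, d, t in product(STAGES, ROM_DIRECTIONS, torques)]


def enumerate_idp_scenarios():
    """All (muscle configuration, load case) cells of the pressure protocol."""
    return [(m, c) for m, (c, _t) in product(MUSCLE_CONFIG_NAMES, IDP_LOAD_CASES)]


def run_stepwise_forward(model, geom: SegmentGeometry, *,
                         stages=STAGES, directions=ROM_DIRECTIONS,
                         torques=TORQUE_SET) -> ROMTable:
    """Forward-simulate the stepwise reduction experiment.

    For each stage the removed elements are taken out, the 0 Nm neutral
    equilibrium is solved as the per-stage ROM reference, and each direction
    is swept over ascending torques with warm starts.  ``model`` is a
    characteristic set (``CalibratedModel`` or equivalent).  Solver failures
    are logged and reported as NaN rows rather than aborting the batch.
    Returns a ROM table whose mean column holds the model output (min/max
    left empty).
    """
    rows = []
    for stage in stages:
        chain = ChainModel.from_segment(geom, model, removed=STAGE_REMOVED[stage])
        try:
            ref = chain.solve(LoadCase(), ramp=2)
        except SolverError as err:
            log.error("stage %s: neutral solve failed: %s", stage, err)
            for d, t in product(directions, torques):
                rows.append((stage, d, t, np.nan))
            continue
        for direction in directions:
            axis, sign = DIRECTION_AXIS[direction]
            warm = ref.poses
            for torque in sorted(torques):
                if torque == 0:
                    rows.append((stage, direction, 0.0, 0.0))
                    continue
                load = load_case_for(direction, torque)
                try:
                    res = chain.solve(load, init=warm)
                except SolverError as err:
                    log.error("stage %s %s %.1f Nm: %s", stage, direction, torque, err)
                    rows.append((stage, direction, torque, np.nan))
                    continue
                warm = res.poses
                rom = sign * np.degrees(res.poses[0].rot[axis] - ref.poses[0].rot[axis])
                rows.append((stage, direction, float(torque), float(rom)))
    df = pd.DataFrame(rows, columns=["stage", "direction", "torque_nm", "rom_mean_deg"])
    return ROMTable(df)


def run_idp_protocol(spine: SpineGeometry, model, *,
                     segment: str = "L4-L5") -> IDPTable:
    """Forward-simulate the intradiscal-pressure experiment on a chain.

    For every muscle configuration and +-3.75 Nm load case the 24-DOF chain
    equilibrium is solved (sacrum fixed, moment on the topmost body), the
    axial compressive force in the monitored disk is read off, and converted
    to pressure via IDP = 1.68 F / CSA.  Returns the model column of an IDP
    table (SD left empty); per-scenario solver failures become NaN rows.
    """
    groups: dict[str, list] = {}
    for m in spine.muscles:
        groups.setdefault(m.group or m.name, []).append(m)
    missing = [g for g in MUSCLE_CONFIG_NAMES[1:-1] if g not in groups]
    if missing:
        raise CalibrationError(f"spine geometry lacks muscle groups: {missing}")
    try:
        seg_idx = spine.segment_index(segment)
    except Exception:
        seg_idx = max(0, spine.n_mobile - 2)

    chain = ChainModel(spine, model)
    csa = spine.segments[seg_idx].csa
    rows = []
    for config in MUSCLE_CONFIG_NAMES:
        if config == "none":
            muscles = []
        elif config == "all":
            muscles = [m for g in groups.values() for m in g]
        else:
            muscles = groups[config]
        warm = None
        for case, torque in IDP_LOAD_CASES:
            load = load_case_for(case, torque, muscles=muscles)
            try:
                res = chain.solve(load, init=warm)
                warm = res.poses if case == "neutral" else warm
                state = chain.element_state(res.poses)
                F = state[seg_idx]["disk_axial_compression_force"]
                idp = idp_from_force(F, csa) / 1e6  # MPa
            except SolverError as err:
                log.error("IDP %s/%s: %s", config, case, err)
                idp = np.nan
            rows.append((config, case, float(idp)))
    df = pd.DataFrame(rows, columns=["muscle_config", "load_case", "idp_mean_mpa"])
    return IDPTable(df)


def count_outliers(model_values, reference, mode: str = "range"):
    """Count model outputs falling outside the experimental envelope.

    ``mode="range"``: outlier iff value < min or value > max (closed
    interval — a value exactly on the boundary is inside); rows without a
    range (the 0 Nm neutral rows) are excluded.  ``mode="sd"``: outlier iff
    |value - mean| > sd.  Returns ``(count, outlier key list)``; the count
    is invariant under row order.
    """
    if mode not in ("range", "sd"):
        raise ValueError(f"mode must be 'range' or 'sd', got {mode!r}")
    if mode == "range":
        keys = ["stage", "direction", "torque_nm"]
        mdf = model_values.df if isinstance(model_values, ROMTable) else model_values
        rdf = reference.df if isinstance(reference, ROMTable) else reference
        value_col = "rom_mean_deg"
        merged = mdf[keys + [value_col]].merge(
            rdf[keys + ["rom_min_deg", "rom_max_deg"]], on=keys, how="left",
            validate="one_to_one", indicator=True,
        )
        if (merged["_merge"] != "both").any():
            bad = merged[merged["_merge"] != "both"][keys].iloc[0].tolist()
            raise CalibrationError(f"reference table lacks key {bad}")
        merged = merged.dropna(subset=["rom_min_deg", "rom_max_deg"])
        out = merged[(merged[value_col] < merged["rom_min_deg"])
                     | (merged[value_col] > merged["rom_max_deg"])
                     | (merged[value_col].isna() & merged["rom_min_deg"].notna())]
    else:
        keys = ["muscle_config", "load_case"]
        mdf = model_values.df if isinstance(model_values, IDPTable) else model_values
        rdf = reference.df if isinstance(reference, IDPTable) else reference
        value_col = "idp_mean_mpa"
        merged = mdf[keys + [value_col]].merge(
            rdf[keys + ["idp_mean_mpa", "idp_sd_mpa"]], on=keys, how="left",
            suffixes=("_model", "_ref"), validate="one_to_one", indicator=True,
        )
        if (merged["_merge"] != "both").any():
            bad = merged[merged["_merge"] != "both"][keys].iloc[0].tolist()
            raise CalibrationError(f"reference table lacks key {bad}")
        dev = (merged["idp_mean_mpa_model"] - merged["idp_mean_mpa_ref"]).abs()
        # a scenario missing on both sides carries no evidence of deviation
        both_nan = merged["idp_mean_mpa_model"].isna() & merged["idp_mean_mpa_ref"].isna()
        out = merged[((dev > merged["idp_sd_mpa"])
                      | merged["idp_mean_mpa_model"].isna()) & ~both_nan]
    outliers = [tuple(r) for r in out[keys].itertuples(index=False, name=None)]
    return len(outliers), outliers
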