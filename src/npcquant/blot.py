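"""Western-blot densitometry: normalized levels, fold changes, glycoform fractions.

Band signals are arbitrary fluorescence units; every output here is a
ratio, so results are invariant to the densitometer's scale. Signals are
assumed background-corrected upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "LaneDensitometry",
    "GlycoformDensitometry",
    "FoldChange",
    "relative_npc1_level",
    "fold_change_vs_control",
    "glycoform_fractions",
    "process_lane_table",
    "process_glycoform_table",
    "fold_changes_by_condition",
]


@dataclass(frozen=True)
class LaneDensitometry:
    """One lane: target-band signal and its loading-control (beta-actin) signal."""

    npc1_signal: float
    actin_signal: float
    lane_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.npc1_signal < 0:
            raise ValidationError(f"lane {self.lane_id!r}: negative NPC1 signal")
        if self.actin_signal <= 0:
            raise DomainError(f"lane {self.lane_id!r}: actin signal must be > 0")


@dataclass(frozen=True)
class GlycoformDensitometry:
    """Endo H-resistant (~170 kDa) and Endo H-sensitive (~130 kDa) band signals."""

    endoH_R_signal: float
    endoH_S_signal: float
    lane_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.endoH_R_signal < 0 or self.endoH_S_signal < 0:
            raise ValidationError(f"lane {self.lane_id!r}: negative glycoform signal")
        if self.endoH_R_signal + self.endoH_S_signal <= 0:
            raise DomainError(f"lane {self.lane_id!r}: both glycoform signals are zero")


@dataclass(frozen=True)
class FoldChange:
    value: float
    numerator_condition: str = ""
    denominator_condition: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise DomainError(f"fold change must be > 0, got {self.value}")


def relative_npc1_level(lane: LaneDensitometry) -> float:
    """Target signal normalized to the loading control (dimensionless)."""
    return lane.npc1_signal / lane.actin_signal


def fold_change_vs_control(
    treated_level: float,
    control_level: float,
    treated_condition: str = "",
    control_condition: str = "",
) -> FoldChange:
    """Ratio of a treated normalized level to its matched control level."""
    if control_level <= 0:
        raise DomainError(f"control level must be > 0, got {control_level}")
    if treated_level < 0:
        raise DomainError(f"treated level must be >= 0, got {treated_level}")
    return FoldChange(
        value=treated_level / control_level,
        numerator_condition=treated_condition,
        denominator_condition=control_condition,
    )


def glycoform_fractions(g: GlycoformDensitometry) -> tuple[float, float]:
    """Fractions (f_R, f_S) of total signal; they sum to 1 exactly."""
    total = g.endoH_R_signal + g.endoH_S_signal
    f_r = g.endoH_R_signal / total
    return f_r, 1.0 - f_r


def process_lane_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``level`` column (npc1/actin) to a tidy lane table.

    Expects columns lane_id, condition, npc1_signal, actin_signal.
    """
    required = {"lane_id", "condition", "npc1_signal", "actin_signal"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"lane table missing columns: {sorted(missing)}")
    out = table.copy()
    levels = []
    for _, row in out.iterrows():
        lane = LaneDensitometry(
            npc1_signal=float(row["npc1_signal"]),
            actin_signal=float(row["actin_signal"]),
            lane_id=str(row["lane_id"]),
            condition=str(row["condition"]),
        )
        levels.append(relative_npc1_level(lane))
    out["level"] = levels
    return out


def process_glycoform_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-lane ``f_R``/``f_S`` columns to a tidy glycoform table.

    Fractions are computed per lane (not on summed signals) before any
    averaging.
    """
    required = {"lane_id", "condition", "endoH_R", "endoH_S"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"glycoform table missing columns: {sorted(missing)}")
    out = table.copy()
    f_r, f_s = [], []
    for _, row in out.iterrows():
        g = GlycoformDensitometry(
            endoH_R_signal=float(row["endoH_R"]),
            endoH_S_signal=float(row["endoH_S"]),
            lane_id=str(row["lane_id"]),
            condition=str(row["condition"]),
        )
        fr, fs = glycoform_fractions(g)
        f_r.append(fr)
        f_s.append(fs)
    out["f_R"] = f_r
    out["f_S"] = f_s
    return out


def fold_changes_by_condition(
    levels: pd.DataFrame, control_condition: str
) -> pd.DataFrame:
    """Per-condition mean fold change versus the control condition.

    Condition means of the normalized levels are ratioed against the
    control-condition mean; per-condition SD of lane-wise folds is
    reported alongside (arithmetic aggregation).
    """
    if "level" not in levels.columns:
        levels = process_lane_table(levels)
    if control_condition not in set(levels["condition"].astype(str)):
        raise ValidationError(f"control condition {control_condition!r} not present")
    control_mean = float(
        levels.loc[levels["condition"].astype(str) == control_condition, "level"].mean()
    )
    if control_mean <= 0:
        raise DomainError("control mean level must be > 0")
    rows = []
    for cond, grp in levels.groupby("condition", sort=False):
        lane_folds = np.asarray(grp["level"], dtype=float) / control_mean
        rows.append(
            {
                "condition": str(cond),
                "n_lanes": len(grp),
                "mean_level": float(grp["level"].mean()),
                "fold_vs_control": float(grp["level"].mean()) / control_mean,
                "fold_sd": float(lane_folds.std(ddof=1)) if len(grp) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
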