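"""Conversion of raw oocyte currents to activation probabilities.

Two-electrode voltage-clamp responses are anchored per cell between a
zero-activation reference (a saturating channel blocker, picrotoxin,
assumed P_A = 0) and a full-activation reference (high agonist plus a
strongly efficacious co-agonist, GABA + propofol, assumed P_A = 1).  Any
amplitude then maps linearly onto an activation probability.

Two measurement protocols are distinguished by the cell's constitutive
activity P_A,constitutive:

* ``potentiation`` (P_A,constitutive <= 0.02): the modulator is co-applied
  on top of a low-agonist background response, and the background P_A is
  the low-agonist steady state.  The background is used uncorrected for
  constitutive activity when the latter is below 0.01; in the 0.01-0.02
  band the record is flagged for audit but the value is not altered.
* ``direct_activation`` (P_A,constitutive > 0.02): the modulator is applied
  alone and the constitutive activity itself is the background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

__all__ = [
    "Protocol",
    "CONSTITUTIVE_DIRECT_THRESHOLD",
    "CONSTITUTIVE_CORRECTION_THRESHOLD",
    "AmplitudeRecord",
    "CellActivationProfile",
    "normalize_amplitude",
    "select_protocol",
    "background_pa",
    "modulation_percent",
    "profiles_from_amplitudes",
    "read_amplitude_table",
    "read_profile_table",
    "write_profile_table",
]

#: Above this constitutive P_A the modulator is applied without agonist.
CONSTITUTIVE_DIRECT_THRESHOLD = 0.02
#: Below this constitutive P_A the background needs no correction at all.
CONSTITUTIVE_CORRECTION_THRESHOLD = 0.01

#: Condition labels recognized as the normalization anchors.
ZERO_ANCHOR_CONDITION = "picrotoxin"
FULL_ANCHOR_CONDITION = "GABA+propofol_max"


class Protocol(str, Enum):
    POTENTIATION = "potentiation"
    DIRECT_ACTIVATION = "direct_activation"


@dataclass(frozen=True)
class AmplitudeRecord:
    """One measured current amplitude for one cell and condition."""

    cell_id: str
    receptor: str
    condition: str
    amplitude_nA: float
    epoch: str = ""


@dataclass
class CellActivationProfile:
    """Activation probabilities for one cell, ready for efficacy analysis."""

    cell_id: str
    receptor: str
    compound: str
    p_constitutive: float
    p_background: float
    p_modulated: float
    protocol: Protocol | None = None
    correction_flag: bool = False

    def __post_init__(self) -> None:
        for name in ("p_constitutive", "p_background", "p_modulated"):
            v = getattr(self, name)
            if v is None or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.protocol is None:
            self.protocol = select_protocol(self.p_constitutive)
        else:
            self.protocol = Protocol(self.protocol)
        # audit flag: constitutive activity in the band where no stated
        # correction rule exists (0.01 <= p_const <= 0.02)
        if (
            self.protocol is Protocol.POTENTIATION
            and self.p_constitutive >= CONSTITUTIVE_CORRECTION_THRESHOLD
        ):
            self.correction_flag = True


def normalize_amplitude(amplitude: float, zero_anchor: float, full_anchor: float) -> float:
    """Map a current amplitude onto [0, 1] between the two anchors.

    Affine-invariant: any common offset or gain applied to all three
    currents cancels.  Either current polarity works, as long as the
    anchors bracket the responses with a consistent sign convention.
    """
    span = full_anchor - zero_anchor
    if not math.isfinite(span) or abs(span) < 1e-12 * max(
        1.0, abs(full_anchor), abs(zero_anchor)
    ):
        raise ValueError(
            f"degenerate anchors: zero={zero_anchor!r}, full={full_anchor!r}"
        )
    p = (amplitude - zero_anchor) / span
    return min(max(p, 0.0), 1.0)


def denormalize_probability(p: float, zero_anchor: float, full_anchor: float) -> float:
    """Inverse of :func:`normalize_amplitude` (used by the simulator)."""
    return zero_anchor + p * (full_anchor - zero_anchor)


def select_protocol(p_constitutive: float) -> Protocol:
    """Choose the measurement protocol from the constitutive activity.

    Direct activation applies strictly above the 0.02 threshold; a cell at
    exactly 0.02 is still measured by potentiation.
    """
    if not 0.0 <= p_constitutive <= 1.0:
        raise ValueError(f"p_constitutive must lie in [0, 1], got {p_constitutive!r}")
    if p_constitutive > CONSTITUTIVE_DIRECT_THRESHOLD:
        return Protocol.DIRECT_ACTIVATION
    return Protocol.POTENTIATION


def background_pa(profile: CellActivationProfile) -> float:
    """Background activation probability against which modulation is judged.

    Potentiation protocol: the measured low-agonist background, used as-is
    (no constitutive correction is applied; records in the 0.01-0.02
    constitutive band carry ``correction_flag=True``).  Direct-activation
    protocol: the constitutive activity.
    """
    if profile.protocol is Protocol.DIRECT_ACTIVATION:
        return profile.p_constitutive
    return profile.p_background


def modulation_percent(profile: CellActivationProfile) -> float:
    """Modulated response as a percentage of the background (100 = no effect)."""
    base = background_pa(profile)
    if base <= 0.0:
        raise ValueError(f"zero background activity for cell {profile.cell_id!r}")
    return 100.0 * profile.p_modulated / base


# ---------------------------------------------------------------------------
# table-level plumbing

_AMPLITUDE_COLUMNS = ["cell_id", "receptor", "condition", "amplitude_nA"]
_PROFILE_COLUMNS = [
    "cell_id",
    "receptor",
    "compound",
    "p_constitutive",
    "p_background",
    "p_modulated",
    "protocol",
    "correction_flag",
]


def profiles_from_amplitudes(table: pd.DataFrame, compound: str) -> pd.DataFrame:
    """Normalize an amplitude table into per-cell activation profiles.

    The table must contain, per cell, exactly one zero anchor
    (``condition == "picrotoxin"``), one full anchor
    (``condition == "GABA+propofol_max"``), a ``baseline`` record
    (holding current, giving P_A,constitutive), and ``background`` /
    ``modulated`` records.
    """
    missing = [c for c in _AMPLITUDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"amplitude table missing columns: {missing}")
    rows = []
    for cell_id, group in table.groupby("cell_id", sort=False):
        conditions = group.set_index("condition")["amplitude_nA"]
        for anchor in (ZERO_ANCHOR_CONDITION, FULL_ANCHOR_CONDITION):
            n = (group["condition"] == anchor).sum()
            if n != 1:
                raise ValueError(
                    f"cell {cell_id!r} must carry exactly one {anchor!r} record, found {n}"
                )
        zero = float(conditions[ZERO_ANCHOR_CONDITION])
        full = float(conditions[FULL_ANCHOR_CONDITION])
        for needed in ("baseline", "background", "modulated"):
            if needed not in conditions.index:
                raise ValueError(f"cell {cell_id!r} missing condition {needed!r}")
        profile = CellActivationProfile(
            cell_id=str(cell_id),
            receptor=str(group["receptor"].iloc[0]),
            compound=compound,
            p_constitutive=normalize_amplitude(float(conditions["baseline"]), zero, full),
            p_background=normalize_amplitude(float(conditions["background"]), zero, full),
            p_modulated=normalize_amplitude(float(conditions["modulated"]), zero, full),
        )
        rows.append(
            {
                "cell_id": profile.cell_id,
                "receptor": profile.receptor,
                "compound": profile.compound,
                "p_constitutive": profile.p_constitutive,
                "p_background": profile.p_background,
                "p_modulated": profile.p_modulated,
                "protocol": profile.protocol.value,
                "correction_flag": profile.correction_flag,
            }
        )
    return pd.DataFrame(rows, columns=_PROFILE_COLUMNS)


def read_amplitude_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in _AMPLITUDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table


def read_profile_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = _PROFILE_COLUMNS[:6]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if table.empty:
        raise ValueError(f"{path}: table has no rows")
    for col in ("p_constitutive", "p_background", "p_modulated"):
        bad = table[(table[col] < 0) | (table[col] > 1)]
        if not bad.empty:
            raise ValueError(
                f"{path}: column {col} outside [0, 1] in rows {list(bad.index)}"
            )
    if "protocol" not in table.columns:
        table["protocol"] = [
            select_protocol(p).value for p in table["p_constitutive"]
        ]
    if "correction_flag" not in table.columns:
        table["correction_flag"] = False
    return table


def write_profile_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
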