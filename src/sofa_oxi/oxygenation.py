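"""Gas-exchange relations linking PaO2, SpO2, FiO2 and oxygen-delivery devices.

This module holds the pure functions at the bottom of the scoring stack:

* :func:`severinghaus_saturation` — the forward oxyhemoglobin dissociation
  curve (PaO2 -> SaO2), used by the synthetic-cohort generator so that
  simulated SpO2 values are physiologically coupled to the latent PaO2.
* :func:`estimate_pao2_piecewise` — the simplified piecewise-linear
  SpO2 -> PaO2 conversion (4 mmHg per % down to 90%, 1.5 mmHg per % down to
  80%, half the SpO2 value below 80%).
* :func:`estimate_pao2_hill` — a Hill-type inversion of the dissociation
  curve with P50 = 27.8 mmHg and exponent 2.8.
* :func:`estimate_fio2` — device/flow -> FiO2 conversion for patients on
  supplemental oxygen.

All saturation arguments are in percent (clinical convention); fractions are
internal. Functions accept scalars or numpy arrays and return the same shape.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "OxygenDevice",
    "OxygenDelivery",
    "FiO2LookupRow",
    "severinghaus_saturation",
    "estimate_pao2_piecewise",
    "estimate_pao2_hill",
    "estimate_fio2",
    "load_fio2_lookup",
]

ArrayLike = Union[float, np.ndarray]

#: Hill parameters of the SpO2 -> PaO2 inversion: P50 in mmHg, numerator
#: exponent, and root exponent (slightly unequal in the published fit).
HILL_P50 = 27.8
HILL_NUM_EXPONENT = 2.81
HILL_ROOT_EXPONENT = 2.8
#: Offset in the denominator 1 - 0.99*s keeping the inversion finite at s = 1.
HILL_SHRINK = 0.99


class OxygenDevice(enum.Enum):
    """Oxygen-delivery hardware, ordered roughly by escalation of support."""

    ROOM_AIR = "room_air"
    NASAL_CANNULA = "nasal_cannula"
    SIMPLE_MASK = "simple_mask"
    RESERVOIR_MASK = "reservoir_mask"
    HIGH_FLOW = "high_flow"
    MECHANICAL_VENT = "mechanical_vent"


@dataclass(frozen=True)
class OxygenDelivery:
    """How a patient receives oxygen: device, flow (L/min) and/or set FiO2.

    Invariants: room air carries no flow; high-flow and ventilator circuits
    must state the set FiO2 directly.
    """

    device: OxygenDevice = OxygenDevice.ROOM_AIR
    flow_lpm: Optional[float] = None
    set_fio2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.device is OxygenDevice.ROOM_AIR:
            if self.flow_lpm not in (None, 0, 0.0):
                raise ValueError("room air carries no oxygen flow")
        if self.flow_lpm is not None and (
            not math.isfinite(self.flow_lpm) or self.flow_lpm < 0
        ):
            raise ValueError(f"flow must be a finite value >= 0 L/min, got {self.flow_lpm}")
        if self.device in (OxygenDevice.HIGH_FLOW, OxygenDevice.MECHANICAL_VENT):
            if self.set_fio2 is None:
                raise ValueError(f"{self.device.value} requires an explicit set_fio2")
        if self.set_fio2 is not None and not (0.21 <= self.set_fio2 <= 1.0):
            raise ValueError(f"set_fio2 must lie in [0.21, 1.0], got {self.set_fio2}")

    @property
    def supported(self) -> bool:
        """True for any respiratory support beyond breathing room air."""
        return self.device is not OxygenDevice.ROOM_AIR


@dataclass(frozen=True)
class FiO2LookupRow:
    device: OxygenDevice
    flow_min: float
    flow_max: float
    fio2: float


def _as_array(x: ArrayLike) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _check_spo2(spo2: np.ndarray) -> None:
    if np.any(~np.isfinite(spo2)) or np.any(spo2 <= 0) or np.any(spo2 > 100):
        raise ValueError("SpO2 must be a finite percentage in (0, 100]")


def severinghaus_saturation(pao2: ArrayLike) -> ArrayLike:
    """Forward oxyhemoglobin dissociation curve (Severinghaus form).

    S = 100 / (23400 / (P^3 + 150 P) + 1), with P in mmHg and S in percent.
    Strictly increasing in P, S -> 100 as P -> infinity, and S = 50 near the
    physiologic P50 of ~26.9 mmHg.
    """
    p, scalar = _as_array(pao2)
    if np.any(~np.isfinite(p)) or np.any(p <= 0):
        raise ValueError("PaO2 must be a finite value > 0 mmHg")
    sat = 100.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)
    return float(sat) if scalar else sat


def estimate_pao2_piecewise(spo2: ArrayLike) -> ArrayLike:
    """Piecewise-linear SpO2 -> PaO2 estimate (methods A/B).

    Segments: SpO2 100 -> 90 maps PaO2 100 -> 60 mmHg (4 mmHg per point);
    90 -> 80 maps 60 -> 45 mmHg (1.5 mmHg per point); below 80% the SpO2
    value is halved. Continuous on [80, 100] with SpO2 = 80 scored on the
    upper segment (45 mmHg).
    """
    s, scalar = _as_array(spo2)
    _check_spo2(s)
    pao2 = np.where(
        s >= 90.0,
        100.0 - 4.0 * (100.0 - s),
        np.where(s >= 80.0, 60.0 - 1.5 * (90.0 - s), s / 2.0),
    )
    return float(pao2) if scalar else pao2


def estimate_pao2_hill(spo2: ArrayLike) -> ArrayLike:
    """Hill-type SpO2 -> PaO2 inversion (methods C/D).

    PaO2 = (27.8^2.81 * s / (1 - 0.99 s))^(1/2.8) with s = SpO2/100. The
    0.99 shrink keeps the estimate finite at s = 1 (~146 mmHg); the curve
    passes through ~59.8 mmHg at 90%, matching the classic 90% -> 60 mmHg
    anchor.
    """
    s, scalar = _as_array(spo2)
    _check_spo2(s)
    frac = s / 100.0
    pao2 = (HILL_P50**HILL_NUM_EXPONENT * frac / (1.0 - HILL_SHRINK * frac)) ** (
        1.0 / HILL_ROOT_EXPONENT
    )
    return float(pao2) if scalar else pao2


def load_fio2_lookup(path: Union[str, Path]) -> list[FiO2LookupRow]:
    """Read a device/flow -> FiO2 override table.

    CSV columns: device, flow_lpm_min, flow_lpm_max, fio2. Device names match
    :class:`OxygenDevice` values.
    """
    rows: list[FiO2LookupRow] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                FiO2LookupRow(
                    device=OxygenDevice(rec["device"]),
                    flow_min=float(rec["flow_lpm_min"]),
                    flow_max=float(rec["flow_lpm_max"]),
                    fio2=float(rec["fio2"]),
                )
            )
    return rows


def _simple_mask_fio2(flow: float) -> float:
    # 5-6 L -> 0.40, 7-8 L -> 0.50, 9-10 L -> 0.60; out-of-range flows clamp
    # to the nearest band.
    if flow <= 6.0:
        return 0.40
    if flow <= 8.0:
        return 0.50
    return 0.60


def estimate_fio2(
    delivery: OxygenDelivery,
    lookup: Optional[Sequence[FiO2LookupRow]] = None,
) -> float:
    """Estimate FiO2 (fraction, [0.21, 1.0]) from an oxygen-delivery setting.

    Default conversion (a standard bedside table, overridable via ``lookup``):

    * room air -> 0.21
    * nasal cannula -> 0.21 + 0.04 per L/min, flow capped at 6 L/min
    * simple mask -> banded: 5-6 L 0.40, 7-8 L 0.50, 9-10 L 0.60
    * reservoir (non-rebreather) mask -> 0.21 + 0.10 per L/min, within
      [0.60, 0.90]
    * high-flow / mechanical ventilation -> the set FiO2 verbatim
    """
    if delivery.device in (OxygenDevice.HIGH_FLOW, OxygenDevice.MECHANICAL_VENT):
        assert delivery.set_fio2 is not None  # enforced by OxygenDelivery
        return float(delivery.set_fio2)
    if delivery.device is OxygenDevice.ROOM_AIR:
        return 0.21

    if delivery.flow_lpm is None:
        raise ValueError(f"{delivery.device.value} requires an oxygen flow in L/min")
    flow = float(delivery.flow_lpm)

    if lookup is not None:
        for row in lookup:
            if row.device is delivery.device and row.flow_min <= flow <= row.flow_max:
                return float(np.clip(row.fio2, 0.21, 1.0))
        raise ValueError(
            f"no lookup row covers {delivery.device.value} at {flow} L/min"
        )

    if delivery.device is OxygenDevice.NASAL_CANNULA:
        fio2 = 0.21 + 0.04 * min(flow, 6.0)
    elif delivery.device is OxygenDevice.SIMPLE_MASK:
        fio2 = _simple_mask_fio2(flow)
    elif delivery.device is OxygenDevice.RESERVOIR_MASK:
        fio2 = min(max(0.21 + 0.10 * flow, 0.60), 0.90)
    else:  # pragma: no cover - exhaustive over enum
        raise ValueError(f"unhandled device {delivery.device}")
    return float(np.clip(fio2, 0.21, 1.0))
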