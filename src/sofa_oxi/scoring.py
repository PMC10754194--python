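"""SOFA scoring: seven respiratory strategies plus the five other organ rows.

The respiratory sub-score is the only SOFA component that differs between
strategies. The conventional approach (``Method.CONV``) scores the
PaO2/FiO2 (PF) ratio and treats a missing PaO2 as normal; the six
alternatives substitute pulse-oximetry information either for every patient
(A, C, E) or only where PaO2 was never measured (B, D, F):

====== =============================================================
CONV   PF ratio; missing PaO2 imputed as normal (100 mmHg by default)
A / B  piecewise-linear SpO2 -> PaO2 estimate, then PF scoring
C / D  Hill-equation SpO2 -> PaO2 estimate, then PF scoring
E / F  direct SpO2 thresholds + one point for respiratory support
====== =============================================================

Non-respiratory rows (coagulation, liver, cardiovascular, CNS, renal) follow
the original SOFA thresholds and are identical across strategies. Renal
scoring uses creatinine only (no urine output).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .oxygenation import (
    OxygenDelivery,
    estimate_fio2,
    estimate_pao2_hill,
    estimate_pao2_piecewise,
)

__all__ = [
    "Method",
    "Vasopressor",
    "PatientRecord",
    "SofaBreakdown",
    "NonRespiratoryScores",
    "ConvImputation",
    "pf_ratio",
    "resp_sofa_from_pf",
    "resp_sofa_spo2_thresholds",
    "respiratory_sofa",
    "nonrespiratory_sofa",
    "total_sofa",
    "score_cohort",
]

#: PaO2 (mmHg) imputed for a missing measurement under the conventional method.
NORMAL_PAO2_MMHG = 100.0


class Method(enum.Enum):
    """The seven respiratory-SOFA calculation strategies."""

    CONV = "CONV"
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"


class ConvImputation(enum.Enum):
    """How the conventional method handles a missing PaO2."""

    IMPUTE_PAO2_100 = "impute_pao2_100"  # impute PaO2 = 100 mmHg, keep actual FiO2
    SCORE_ZERO = "score_zero"  # assign respiratory sub-score 0 outright


class Vasopressor(enum.Enum):
    """Vasopressor dose categories of the SOFA cardiovascular row."""

    NONE = "none"
    DOPAMINE_LE5 = "dopamine_le5"  # dopamine <=5 ug/kg/min or dobutamine
    DOPAMINE_5_15_OR_EPI_LE01 = "dopamine_5_15_or_epi_le01"
    DOPAMINE_GT15_OR_EPI_GT01 = "dopamine_gt15_or_epi_gt01"


@dataclass(frozen=True)
class PatientRecord:
    """Worst-in-first-24h physiology and outcome for one patient.

    ``pao2`` is ``None`` when no arterial blood gas was drawn; SpO2 is always
    present (patients without it are excluded upstream). All values are the
    worst observed in the first 24 hours after arrival.
    """

    spo2: float
    pao2: Optional[float] = None
    delivery: OxygenDelivery = field(default_factory=OxygenDelivery)
    platelets: float = 250.0  # 10^3/uL
    bilirubin: float = 0.7  # mg/dL
    map_mmhg: float = 80.0
    vasopressor: Vasopressor = Vasopressor.NONE
    gcs: int = 15
    creatinine: float = 0.9  # mg/dL
    died_in_hospital: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.spo2 <= 100.0) or not math.isfinite(self.spo2):
            raise ValueError(f"spo2 must lie in (0, 100], got {self.spo2}")
        if self.pao2 is not None and (
            not math.isfinite(self.pao2) or self.pao2 <= 0
        ):
            raise ValueError(f"pao2 must be finite and > 0 mmHg, got {self.pao2}")
        for name in ("platelets", "bilirubin", "map_mmhg", "creatinine"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (isinstance(self.gcs, int) and 3 <= self.gcs <= 15):
            raise ValueError(f"gcs must be an integer in [3, 15], got {self.gcs}")

    @property
    def pao2_missing(self) -> bool:
        return self.pao2 is None

    @property
    def fio2(self) -> float:
        return estimate_fio2(self.delivery)

    @property
    def on_support(self) -> bool:
        return self.delivery.supported


class NonRespiratoryScores(NamedTuple):
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int


@dataclass(frozen=True)
class SofaBreakdown:
    """The six organ sub-scores (0-4 each) and their total under one method."""

    respiratory: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int
    method: Method

    @property
    def total(self) -> int:
        return (
            self.respiratory
            + self.coagulation
            + self.liver
            + self.cardiovascular
            + self.cns
            + self.renal
        )


def pf_ratio(pao2: float, fio2: float) -> float:
    """PaO2/FiO2 ratio — the gas-exchange index of the respiratory row."""
    if not (pao2 > 0 and math.isfinite(pao2)):
        raise ValueError(f"pao2 must be finite and > 0, got {pao2}")
    if not (0.21 <= fio2 <= 1.0):
        raise ValueError(f"fio2 must lie in [0.21, 1.0], got {fio2}")
    return pao2 / fio2


def resp_sofa_from_pf(pf: float, support: bool) -> int:
    """Respiratory SOFA from the PF ratio (original SOFA thresholds).

    >=400 -> 0; <400 -> 1; <300 -> 2; <200 -> 3 and <100 -> 4, the last two
    only with respiratory support (without it the score caps at 2).
    """
    if not (pf > 0 and math.isfinite(pf)):
        raise ValueError(f"PF ratio must be finite and > 0, got {pf}")
    if pf >= 400:
        return 0
    if pf >= 300:
        return 1
    if not support:
        return 2
    if pf >= 200:
        return 2
    if pf >= 100:
        return 3
    return 4


def resp_sofa_spo2_thresholds(spo2: float, support: bool) -> int:
    """Respiratory SOFA from SpO2 thresholds (methods E/F).

    Base score: >94% -> 0; (90, 94] -> 1; (85, 90] -> 2; <=85% -> 3. One
    point is added for any respiratory support, capped at 4.
    """
    if not (0.0 < spo2 <= 100.0):
        raise ValueError(f"spo2 must lie in (0, 100], got {spo2}")
    if spo2 > 94:
        score = 0
    elif spo2 > 90:
        score = 1
    elif spo2 > 85:
        score = 2
    else:
        score = 3
    if support:
        score = min(score + 1, 4)
    return score


def _pf_score(record: PatientRecord, pao2: float) -> int:
    return resp_sofa_from_pf(pf_ratio(pao2, record.fio2), record.on_support)


def respiratory_sofa(
    record: PatientRecord,
    method: Method,
    conv_imputation: ConvImputation = ConvImputation.IMPUTE_PAO2_100,
) -> int:
    """Respiratory sub-score (0-4) for one patient under one strategy."""
    if not isinstance(method, Method):
        raise ValueError(f"unknown method {method!r}")

    if method is Method.CONV:
        if record.pao2 is not None:
            return _pf_score(record, record.pao2)
        if conv_imputation is ConvImputation.SCORE_ZERO:
            return 0
        return _pf_score(record, NORMAL_PAO2_MMHG)

    if method is Method.A:
        return _pf_score(record, estimate_pao2_piecewise(record.spo2))
    if method is Method.C:
        return _pf_score(record, estimate_pao2_hill(record.spo2))
    if method is Method.E:
        return resp_sofa_spo2_thresholds(record.spo2, record.on_support)

    # B/D/F: estimation only fills the gap; measured PaO2 is scored as CONV.
    if record.pao2 is not None:
        return _pf_score(record, record.pao2)
    if method is Method.B:
        return _pf_score(record, estimate_pao2_piecewise(record.spo2))
    if method is Method.D:
        return _pf_score(record, estimate_pao2_hill(record.spo2))
    return resp_sofa_spo2_thresholds(record.spo2, record.on_support)  # Method.F


_VASO_SCORE = {
    Vasopressor.DOPAMINE_LE5: 2,
    Vasopressor.DOPAMINE_5_15_OR_EPI_LE01: 3,
    Vasopressor.DOPAMINE_GT15_OR_EPI_GT01: 4,
}


def nonrespiratory_sofa(record: PatientRecord) -> NonRespiratoryScores:
    """The five non-respiratory organ sub-scores (original SOFA thresholds)."""
    p = record.platelets
    coagulation = 0 if p >= 150 else 1 if p >= 100 else 2 if p >= 50 else 3 if p >= 20 else 4

    b = record.bilirubin
    liver = 0 if b < 1.2 else 1 if b < 2.0 else 2 if b < 6.0 else 3 if b < 12.0 else 4

    if record.vasopressor is not Vasopressor.NONE:
        cardiovascular = _VASO_SCORE[record.vasopressor]
    else:
        cardiovascular = 0 if record.map_mmhg >= 70 else 1

    g = record.gcs
    cns = 0 if g == 15 else 1 if g >= 13 else 2 if g >= 10 else 3 if g >= 6 else 4

    c = record.creatinine
    renal = 0 if c < 1.2 else 1 if c < 2.0 else 2 if c < 3.5 else 3 if c < 5.0 else 4

    return NonRespiratoryScores(coagulation, liver, cardiovascular, cns, renal)


def total_sofa(
    record: PatientRecord,
    method: Method,
    conv_imputation: ConvImputation = ConvImputation.IMPUTE_PAO2_100,
) -> SofaBreakdown:
    """Full six-organ SOFA breakdown for one patient under one strategy."""
    resp = respiratory_sofa(record, method, conv_imputation)
    other = nonrespiratory_sofa(record)
    return SofaBreakdown(
        respiratory=resp,
        coagulation=other.coagulation,
        liver=other.liver,
        cardiovascular=other.cardiovascular,
        cns=other.cns,
        renal=other.renal,
        method=method,
    )


def score_cohort(
    records: Sequence[PatientRecord],
    methods: Iterable[Method] = tuple(Method),
    conv_imputation: ConvImputation = ConvImputation.IMPUTE_PAO2_100,
) -> pd.DataFrame:
    """Score every patient under every requested strategy.

    Returns a tidy frame with one row per patient: ``patient_id``,
    ``died_in_hospital`` and, per method M, ``resp_M`` and ``total_M``
    columns.
    """
    methods = list(methods)
    out: dict[str, list] = {
        "patient_id": list(range(len(records))),
        "died_in_hospital": [int(r.died_in_hospital) for r in records],
    }
    nonresp_totals = [sum(nonrespiratory_sofa(r)) for r in records]
    for m in methods:
        resp = [respiratory_sofa(r, m, conv_imputation) for r in records]
        out[f"resp_{m.value}"] = resp
        out[f"total_{m.value}"] = [s + nr for s, nr in zip(resp, nonresp_totals)]
    return pd.DataFrame(out)
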