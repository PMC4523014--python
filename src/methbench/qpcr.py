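"""Real-time qPCR quantification: Cq summaries, restriction-enzyme
delta-delta-Cq methylation, and MethyLight standard-curve quantification.

Two percent-methylation calculations live here.  The RE route compares
digested template against a mock digest on unconverted genomic DNA:

    dCq   = mean Cq(mock) - mean Cq(digest)
    ddCq  = dCq(sample) - dCq(control)
    MSRE: percent = 100 * 2**ddCq        (control = 100% methylated)
    MDRE: percent = 100 * (1 - 2**ddCq)  (control = 0% methylated)

The MethyLight route interpolates copy numbers of the methylation-specific
p14 assay from a standard curve, normalises to the methylation-independent
COL2A1 assay, and rescales to the fully methylated sample.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EnzymeClass, EnzymeKind

__all__ = [
    "UNDETECTED",
    "Undetected",
    "CqSummary",
    "WellSet",
    "StandardCurve",
    "QpcrQuantResult",
    "mean_cq",
    "re_qpcr_percent",
    "fit_standard_curve",
    "interpolate_copies",
    "methylight_qpcr_percent",
]


class Undetected(enum.Enum):
    """Sentinel for a well with no amplification within the run's cycles.

    UNDETECTED never enters Cq arithmetic; summaries are computed over
    detected wells only and an all-undetected well set stays UNDETECTED.
    """

    token = "UNDETECTED"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDETECTED"


UNDETECTED = Undetected.token

CqValue = float | Undetected


def _detected(wells: Sequence[CqValue]) -> list[float]:
    return [w for w in wells if w is not UNDETECTED]


@dataclass(frozen=True)
class CqSummary:
    """Mean/sd of detected wells in a replicate set."""

    mean: CqValue
    sd: float
    n_detected: int
    n_total: int

    @property
    def detected(self) -> bool:
        return self.mean is not UNDETECTED


@dataclass(frozen=True)
class WellSet:
    """Replicate Cq measurements of one sample under one treatment."""

    sample: str
    treatment: str  # MSRE_digest | MDRE_digest | mock | none
    assay: str
    wells: tuple[CqValue, ...]

    def __post_init__(self) -> None:
        if len(self.wells) == 0:
            raise ValueError("a WellSet needs at least one well")

    def summary(self) -> CqSummary:
        return mean_cq(self)


def mean_cq(wells: WellSet | Sequence[CqValue]) -> CqSummary:
    """Summarise replicate wells over detected values only.

    An all-UNDETECTED set propagates the sentinel.  ``sd`` is the
    population-corrected (ddof=1) standard deviation, 0.0 when fewer
    than two wells were detected.
    """
    values = wells.wells if isinstance(wells, WellSet) else tuple(wells)
    if len(values) == 0:
        raise ValueError("cannot summarise an empty well list")
    det = _detected(values)
    if not det:
        return CqSummary(UNDETECTED, 0.0, 0, len(values))
    sd = float(np.std(det, ddof=1)) if len(det) > 1 else 0.0
    return CqSummary(float(np.mean(det)), sd, len(det), len(values))


@dataclass(frozen=True)
class QpcrQuantResult:
    delta_cq: float | None
    delta_delta_cq: float | None
    percent: float


def re_qpcr_percent(
    sample_digest: WellSet | Sequence[CqValue],
    sample_mock: WellSet | Sequence[CqValue],
    control_digest: WellSet | Sequence[CqValue],
    control_mock: WellSet | Sequence[CqValue],
    enzyme: EnzymeClass,
) -> QpcrQuantResult:
    """Percent methylation from MSRE/MDRE digestion qPCR.

    The control is the 100% methylated sample for MSRE (nothing should
    cut) and the 0% sample for MDRE.  An UNDETECTED sample digest means
    complete digestion: 0% methylation for MSRE, 100% for MDRE.  An
    UNDETECTED control mock makes normalisation impossible and raises.
    """
    s_dig, s_mock = mean_cq(sample_digest), mean_cq(sample_mock)
    c_dig, c_mock = mean_cq(control_digest), mean_cq(control_mock)
    if not c_mock.detected or not s_mock.detected:
        raise ValueError("mock digest Cq undetected; normalisation impossible")
    if not c_dig.detected:
        raise ValueError("control digest Cq undetected; normalisation impossible")
    if not s_dig.detected:
        pct = 0.0 if enzyme.kind is EnzymeKind.MSRE else 100.0
        return QpcrQuantResult(None, None, pct)
    delta = s_mock.mean - s_dig.mean
    delta_control = c_mock.mean - c_dig.mean
    ddcq = delta - delta_control
    surviving = 2.0**ddcq
    if enzyme.kind is EnzymeKind.MSRE:
        pct = 100.0 * surviving
    else:
        pct = 100.0 * (1.0 - surviving)
    return QpcrQuantResult(delta, ddcq, pct)


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Cq against log10(copies).

    ``slope`` is Cq per decade (negative; -3.32 at 100% amplification
    efficiency), ``intercept`` is the Cq of a single copy.
    """

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(
                f"standard-curve slope must be negative, got {self.slope}"
            )

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification gain: 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(
    points: Sequence[tuple[float, CqValue | Sequence[CqValue]]],
) -> StandardCurve:
    """Ordinary least squares of per-level mean Cq on log10(copies).

    ``points`` maps copy numbers to a Cq or replicate Cqs per dilution
    level; replicate wells are averaged before the fit.  At least three
    distinct, detected levels with positive copy numbers are required.
    """
    xs, ys = [], []
    for copies, cq in points:
        if copies <= 0:
            raise ValueError(f"standard-curve copies must be positive, got {copies}")
        if isinstance(cq, (float, int)) or cq is UNDETECTED:
            summary = mean_cq([cq])
        else:
            summary = mean_cq(cq)
        if not summary.detected:
            raise ValueError(f"standard point at {copies} copies is undetected")
        xs.append(math.log10(copies))
        ys.append(summary.mean)
    if len(set(xs)) < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return StandardCurve(float(slope), float(intercept), r2)


def interpolate_copies(
    curve: StandardCurve, cq: CqValue
) -> tuple[float, bool]:
    """Invert the standard curve: copies = 10**((cq - intercept)/slope).

    Returns ``(copies, detected)``; an UNDETECTED Cq maps to 0 copies
    with ``detected=False`` so callers can distinguish true zeroes.
    """
    if cq is UNDETECTED:
        return 0.0, False
    return 10.0 ** ((float(cq) - curve.intercept) / curve.slope), True


def methylight_qpcr_percent(
    p14_copies: float, col2a1_copies: float, ref_ratio: float
) -> float:
    """MethyLight percent methylation with COL2A1 normalisation.

    ``ref_ratio`` is the p14/COL2A1 copy ratio of the 100% methylated
    sample measured in the same run.  A zero COL2A1 signal indicates
    sample loss or inhibition and raises rather than returning a value.
    """
    if col2a1_copies <= 0:
        raise ValueError("COL2A1 signal absent: sample loss or PCR inhibition")
    if ref_ratio <= 0:
        raise ValueError(f"ref_ratio must be positive, got {ref_ratio}")
    return 100.0 * (p14_copies / col2a1_copies) / ref_ratio
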