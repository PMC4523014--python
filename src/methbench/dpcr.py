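"""Digital PCR quantification from partition counts.

A microfluidic dPCR panel distributes a reaction over ``n`` chambers and
reports how many (``k``) amplified.  Under Poisson occupancy the mean
molecules per chamber is

    lambda = -ln(1 - k/n)

and the estimated number of target molecules is ``n * lambda``.  Percent
methylation is then computed exactly as in the qPCR module but with
estimated targets in place of interpolated copies: digests are normalised
to mock digests and to a fully (un)methylated control, MethyLight targets
to the methylation-independent COL2A1 assay.

The duplex machinery supports a two-channel MethyLight assay in which the
two strands of bisulfite-converted DNA — no longer complementary after
conversion — are counted separately and summed for absolute
quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EnzymeClass, EnzymeKind
from .qpcr import methylight_qpcr_percent

__all__ = [
    "PanelCount",
    "TargetEstimate",
    "ChamberMatrix",
    "lambda_hat",
    "estimated_targets",
    "pool_panels",
    "re_dpcr_percent",
    "methylight_dpcr_percent",
    "combine_duplex",
    "double_positive_rate",
]

#: Chambers per panel of the 48-panel integrated fluidic circuit.
DEFAULT_PARTITIONS = 770


@dataclass(frozen=True)
class PanelCount:
    """Positive-chamber count for one panel (or pooled panels)."""

    k: int
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"partition count must be positive, got {self.n}")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")


@dataclass(frozen=True)
class TargetEstimate:
    """Poisson-corrected molecule count with a 95% confidence interval."""

    lam: float
    targets: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def variance(self) -> float:
        half = (self.ci_high - self.ci_low) / 2.0
        return (half / 1.959963984540054) ** 2


class SaturationError(ValueError):
    """All chambers positive: lambda is unbounded and the panel is
    outside the quantifiable range."""


def lambda_hat(count: PanelCount) -> float:
    """Mean molecules per chamber, ``-ln(1 - k/n)``.

    Raises :class:`SaturationError` when every chamber is positive;
    these assays operate at lambda < 0.2, so saturation signals a bad
    input rather than a high concentration to be clamped.
    """
    if count.k == count.n:
        raise SaturationError(
            f"all {count.n} chambers positive; lambda is undefined"
        )
    return -math.log1p(-count.k / count.n)


def estimated_targets(count: PanelCount) -> TargetEstimate:
    """Estimated molecules ``n * lambda`` with a normal-approximation CI.

    The binomial variance of p = k/n propagated through the Poisson
    correction gives var(lambda) = p / ((1-p) n); the 95% interval on
    targets is truncated at zero.
    """
    lam = lambda_hat(count)
    p = count.k / count.n
    targets = count.n * lam
    var_lam = p / ((1.0 - p) * count.n)
    sd_targets = count.n * math.sqrt(var_lam)
    z = 1.959963984540054
    return TargetEstimate(
        lam=lam,
        targets=targets,
        ci_low=max(0.0, targets - z * sd_targets),
        ci_high=targets + z * sd_targets,
        n=count.n,
    )


def pool_panels(counts: Sequence[PanelCount]) -> PanelCount:
    """Pool panels loaded from one reaction by summing k and n.

    Lambda is then computed on the pooled totals; for equally loaded
    panels this equals the per-panel lambda.
    """
    if len(counts) == 0:
        raise ValueError("cannot pool an empty panel list")
    return PanelCount(sum(c.k for c in counts), sum(c.n for c in counts))


def re_dpcr_percent(
    digest: TargetEstimate,
    mock: TargetEstimate,
    control_rq: float,
    enzyme: EnzymeClass,
) -> float:
    """Percent methylation from restriction-enzyme digestion dPCR.

    %RQ = 100 * (digest targets / mock targets) / control_rq, where
    ``control_rq`` is the digest/mock target ratio of the 100%
    methylated sample (MSRE) or the 0% sample (MDRE).  MSRE reports %RQ
    directly; MDRE reports 100 - %RQ because its surviving template is
    the unmethylated fraction.
    """
    if mock.targets <= 0:
        raise ValueError("mock digest has zero estimated targets")
    if control_rq <= 0:
        raise ValueError(f"control_rq must be positive, got {control_rq}")
    rq = 100.0 * (digest.targets / mock.targets) / control_rq
    return rq if enzyme.kind is EnzymeKind.MSRE else 100.0 - rq


def methylight_dpcr_percent(
    p14: TargetEstimate | float, col2a1: TargetEstimate | float, ref_ratio: float
) -> float:
    """MethyLight dPCR percent methylation (COL2A1-normalised).

    Identical in form to the qPCR calculation, with estimated targets in
    place of interpolated copies; invariant to uniform scaling of both
    channels, which is what makes it robust to sample loss.
    """
    p14_t = p14.targets if isinstance(p14, TargetEstimate) else float(p14)
    col_t = col2a1.targets if isinstance(col2a1, TargetEstimate) else float(col2a1)
    return methylight_qpcr_percent(p14_t, col_t, ref_ratio)


def combine_duplex(m: TargetEstimate, m2: TargetEstimate) -> TargetEstimate:
    """Sum the sense- and antisense-strand target estimates of a duplex
    run; CIs combine as independent variances."""
    targets = m.targets + m2.targets
    sd = math.sqrt(m.variance + m2.variance)
    z = 1.959963984540054
    return TargetEstimate(
        lam=m.lam + m2.lam,
        targets=targets,
        ci_low=max(0.0, targets - z * sd),
        ci_high=targets + z * sd,
        n=m.n,
    )


@dataclass(frozen=True)
class ChamberMatrix:
    """Per-chamber boolean calls for the two channels of a duplex run."""

    call_a: np.ndarray
    call_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.call_a, dtype=bool)
        b = np.asarray(self.call_b, dtype=bool)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("channel call vectors must be 1-D and equal length")
        object.__setattr__(self, "call_a", a)
        object.__setattr__(self, "call_b", b)

    @property
    def n(self) -> int:
        return self.call_a.size

    def counts(self) -> tuple[PanelCount, PanelCount]:
        return (
            PanelCount(int(self.call_a.sum()), self.n),
            PanelCount(int(self.call_b.sum()), self.n),
        )


def double_positive_rate(chambers: ChamberMatrix) -> float:
    """Fraction of positive chambers that amplified in both channels.

    Denominator is chambers positive in at least one channel.  For
    independently partitioned single strands this converges to the
    Poisson co-occupancy expectation (well under 1% at lambda < 0.2);
    double-stranded template drives it toward 1 because both strands of
    a duplex land in the same chamber.  Raises when no chamber is
    positive.
    """
    both = int(np.sum(chambers.call_a & chambers.call_b))
    any_pos = int(np.sum(chambers.call_a | chambers.call_b))
    if any_pos == 0:
        raise ValueError("no positive chambers; double-positive rate undefined")
    return both / any_pos


def expected_double_positive_rate(lam_a: float, lam_b: float) -> float:
    """Closed-form co-occupancy rate for independent channels:
    P(A+ and B+) / P(A+ or B+) with P(X+) = 1 - exp(-lambda_X)."""
    pa = 1.0 - math.exp(-lam_a)
    pb = 1.0 - math.exp(-lam_b)
    p_any = pa + pb - pa * pb
    if p_any == 0:
        raise ValueError("both lambdas are zero")
    return pa * pb / p_any
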