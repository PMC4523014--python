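"""Shared domain types and rules for methylation-quantification assays.

A benchmarking experiment runs one or more quantification methods over a
panel of DNA standards mixed from fully methylated and fully unmethylated
genomic DNA in known ratios.  Every estimator in this package returns a
:class:`MethylationEstimate` on the 0-100 percent scale, and all of them
share the unit conversions, viability rules and restriction-enzyme
working-range conventions defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Method",
    "EnzymeKind",
    "EnzymeClass",
    "MSRE",
    "MDRE",
    "PanelStandard",
    "MethylationEstimate",
    "DEFAULT_PANEL_FRACTIONS",
    "DEFAULT_GENOME_MASS_PG",
    "mass_to_copies",
    "viability_filter",
    "optimal_range_subset",
]

#: Expected methylated fractions of the seven-member standards panel.
DEFAULT_PANEL_FRACTIONS: tuple[float, ...] = (1.0, 0.9, 0.75, 0.5, 0.25, 0.1, 0.0)

#: Mass of one haploid human genome in picograms.  5 ng of genomic DNA is
#: ~1500 haploid genome equivalents at this value.
DEFAULT_GENOME_MASS_PG: float = 3.3


class Method(str, enum.Enum):
    """Quantification method tags carried by every estimate."""

    MSRE_QPCR = "MSRE_qPCR"
    MDRE_QPCR = "MDRE_qPCR"
    MSRE_DPCR = "MSRE_dPCR"
    MDRE_DPCR = "MDRE_dPCR"
    ML_QPCR = "ML_qPCR"
    ML_DPCR_SINGLE = "ML_dPCR_single"
    ML_DPCR_DUPLEX = "ML_dPCR_duplex"
    NGS_SBE = "NGS_SBE"
    NGS_RBE = "NGS_RBE"


class EnzymeKind(str, enum.Enum):
    #: methylation-sensitive: cuts only unmethylated recognition sites
    MSRE = "MSRE"
    #: methylation-dependent: cuts only methylated recognition sites
    MDRE = "MDRE"


@dataclass(frozen=True)
class EnzymeClass:
    """A restriction-enzyme class and its optimal template range.

    MSRE digestion quantifies methylation best when most template is
    unmethylated (0-50% methylated), MDRE when most is methylated
    (50-100%); outside those ranges the digested template differs from
    the normalisation control by less than typical technical noise.
    """

    kind: EnzymeKind
    optimal_range: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        rng = (0.0, 50.0) if self.kind is EnzymeKind.MSRE else (50.0, 100.0)
        object.__setattr__(self, "optimal_range", rng)

    def in_optimal_range(self, expected_percent: float) -> bool:
        lo, hi = self.optimal_range
        return lo <= expected_percent <= hi


MSRE = EnzymeClass(EnzymeKind.MSRE)
MDRE = EnzymeClass(EnzymeKind.MDRE)


@dataclass(frozen=True)
class PanelStandard:
    """One member of the methylated/unmethylated standards panel.

    Parameters
    ----------
    label
        Human-readable identifier, e.g. ``"50%"``.
    expected_fraction
        Fraction of genomes that are fully methylated, in [0, 1].
    nominal_mass
        Input DNA mass per reaction in nanograms.
    nominal_copies
        Haploid genome equivalents; derived from ``nominal_mass`` when
        not given explicitly.
    """

    label: str
    expected_fraction: float
    nominal_mass: float = 5.0
    nominal_copies: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.expected_fraction <= 1.0:
            raise ValueError(
                f"expected_fraction must be in [0, 1], got {self.expected_fraction}"
            )
        if self.nominal_copies is None:
            object.__setattr__(
                self, "nominal_copies", mass_to_copies(self.nominal_mass)
            )

    @property
    def expected_percent(self) -> float:
        return 100.0 * self.expected_fraction


@dataclass(frozen=True)
class MethylationEstimate:
    """A percent-methylation measurement from one replicate of one method.

    ``percent`` may fall outside [0, 100] before filtering: ratio-based
    estimators can over- or under-shoot when the digested template is
    close to the normalisation control.  ``viable`` records whether the
    value lies inside the assay's feasible range.
    """

    percent: float
    method: Method
    replicate: int = 0
    expected_percent: float | None = None
    label: str | None = None

    @property
    def viable(self) -> bool:
        return 0.0 <= self.percent <= 100.0


def mass_to_copies(mass: float, genome_mass: float = DEFAULT_GENOME_MASS_PG) -> float:
    """Convert DNA mass in ng to haploid genome equivalents.

    Parameters
    ----------
    mass
        Input DNA in nanograms (>= 0).
    genome_mass
        Picograms per haploid genome; 3.3 pg for human.

    Returns
    -------
    float
        ``1000 * mass / genome_mass``, unrounded.  5 ng of human DNA is
        ~1515 copies, 25 ng is ~7576 (the top point of the MethyLight
        standard curve).
    """
    if genome_mass <= 0:
        raise ValueError(f"genome_mass must be positive, got {genome_mass}")
    if mass < 0:
        raise ValueError(f"mass must be non-negative, got {mass}")
    return 1000.0 * mass / genome_mass


def viability_filter(
    estimates: Iterable[MethylationEstimate],
) -> tuple[list[MethylationEstimate], list[dict]]:
    """Drop estimates outside the feasible 0-100% range.

    Returns the retained estimates (order preserved) and a removal log
    with one record per dropped estimate.  Idempotent: filtering twice
    removes nothing new.  The bounds are inclusive — exactly 0% and
    exactly 100% are valid measurements.
    """
    kept: list[MethylationEstimate] = []
    removed: list[dict] = []
    for est in estimates:
        if est.viable:
            kept.append(est)
        else:
            removed.append(
                {
                    "method": est.method.value,
                    "replicate": est.replicate,
                    "percent": est.percent,
                    "label": est.label,
                }
            )
    return kept, removed


def optimal_range_subset(
    estimates: Sequence[MethylationEstimate], enzyme: EnzymeClass
) -> list[MethylationEstimate]:
    """Keep estimates whose *expected* methylation lies in the enzyme's
    optimal working range (endpoints inclusive; 50% belongs to both
    classes).

    Estimates must carry ``expected_percent`` labels.
    """
    out = []
    for est in estimates:
        if est.expected_percent is None:
            raise ValueError("estimate lacks an expected_percent label")
        if enzyme.in_optimal_range(est.expected_percent):
            out.append(est)
    return out
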