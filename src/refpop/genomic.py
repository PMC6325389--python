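"""Reliability of genomic breeding values and its preselection adjustment.

The unselected (random-sample) reliability of GEBV follows the classical
deterministic prediction

    r2_GEBV = lambda r2 / (lambda r2 + 1),      lambda = nP / nG,

where nP is the reference-population size, r2 the reliability linking a
reference animal's genotype to its phenotype source (h2 for a cow with an
own record, the progeny-test reliability for a bull), and nG = 2 NE L the
effective number of independent chromosome segments given historical
effective population size NE and genome length L in Morgans.

When the reference animals were preselected by truncation on an EBV with
reliability r2_EBV (variance reduction k of the criterion), the genetic
variance among them shrinks by 1 - k r2_EBV, and the reliability and the
regression of true breeding value on GEBV (the bias criterion) become

    r2*_GEBV = r2_GEBV (1 - k r2_EBV) / (1 - k r2_EBV r2_GEBV)
    b*       =          (1 - k r2_EBV) / (1 - k r2_EBV r2_GEBV)

so that b* equals the ratio r2*/r2 exactly: a slope below 1 means GEBV of
preselected animals are inflated.  The adjustment treats preselection as a
single generation of truncation; no iterated (Bulmer-equilibrium) variance
reduction is applied.  Prediction errors of EBV and GEBV are assumed
uncorrelated throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

from .truncation import SelectionRegime

__all__ = [
    "GenomeParams",
    "ReferenceGroup",
    "ReliabilityResult",
    "effective_segments",
    "unselected_reliability",
    "required_reference_size",
    "preselection_adjust",
    "deselect_reliability",
]


@dataclass(frozen=True)
class GenomeParams:
    """Genome-level constants: historical Ne and map length (Morgans)."""

    ne: float
    length_morgans: float

    def __post_init__(self) -> None:
        if self.ne <= 0 or self.length_morgans <= 0:
            raise ValueError("NE and genome length must be positive")

    @property
    def n_segments(self) -> float:
        """Effective number of chromosome segments, 2 * NE * L."""
        return 2.0 * self.ne * self.length_morgans


def effective_segments(genome: GenomeParams) -> float:
    """Effective number of independent chromosome segments, nG = 2 NE L."""
    return genome.n_segments


@dataclass(frozen=True)
class ReferenceGroup:
    """One homogeneous reference-population group (bulls or cows).

    ``r2_info`` links a genotyped animal to its phenotype source (h2 for a
    phenotyped cow, progeny-test reliability for a bull); ``r2_presel`` is
    the reliability of the EBV the group was truncation-selected on.
    """

    label: str
    n_ref: float
    r2_info: float
    r2_presel: float
    regime: SelectionRegime

    def __post_init__(self) -> None:
        if self.n_ref < 0:
            raise ValueError("reference-population size must be >= 0")
        for name in ("r2_info", "r2_presel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")

    def reliability(self, genome: GenomeParams) -> "ReliabilityResult":
        """Unselected and preselection-adjusted GEBV reliability of the group."""
        r2_u = unselected_reliability(self.n_ref, genome.n_segments, self.r2_info)
        return preselection_adjust(r2_u, self.regime.k, self.r2_presel)


@dataclass(frozen=True)
class ReliabilityResult:
    """GEBV reliability before/after preselection, with the bias slope.

    ``bias_slope`` is the regression of true breeding value on GEBV among
    the preselected animals and equals ``ratio = r2_selected/r2_unselected``.
    """

    r2_unselected: float
    r2_selected: float
    bias_slope: float

    @property
    def ratio(self) -> float:
        return self.bias_slope


def unselected_reliability(n_ref: float, n_segments: float, r2_info: float) -> float:
    """Random-sample GEBV reliability, lambda r2 / (lambda r2 + 1)."""
    if n_ref < 0:
        raise ValueError("reference-population size must be >= 0")
    if n_segments <= 0:
        raise ValueError("segment count must be positive")
    if not 0.0 <= r2_info <= 1.0:
        raise ValueError(f"r2_info must be in [0, 1], got {r2_info!r}")
    lam_r2 = (n_ref / n_segments) * r2_info
    return lam_r2 / (lam_r2 + 1.0)


def required_reference_size(r2_target: float, n_segments: float, r2_info: float) -> float:
    """Reference size giving a target unselected reliability (exact inverse).

    nP = nG r2_target / (r2_info (1 - r2_target)).
    """
    if not 0.0 <= r2_target < 1.0:
        raise ValueError(f"target reliability must be in [0, 1), got {r2_target!r}")
    if n_segments <= 0:
        raise ValueError("segment count must be positive")
    if not 0.0 < r2_info <= 1.0:
        raise ValueError(f"r2_info must be in (0, 1], got {r2_info!r}")
    return n_segments * r2_target / (r2_info * (1.0 - r2_target))


def _check_unit(name: str, v: float) -> None:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {v!r}")


def preselection_adjust(
    r2_unselected: float, k: float, r2_presel: float
) -> ReliabilityResult:
    """Reliability and bias of GEBV after truncation preselection on EBV.

    ``k`` is the variance reduction of the preselection criterion,
    ``r2_presel`` the reliability of that EBV.  ``k = 0`` (random
    selection) leaves the reliability unchanged with slope 1.
    """
    _check_unit("r2_unselected", r2_unselected)
    _check_unit("r2_presel", r2_presel)
    if k < 0:
        raise ValueError(f"variance reduction k must be >= 0, got {k!r}")
    kr = k * r2_presel
    if kr >= 1.0:
        raise ValueError("degenerate selection: k * r2_presel must be < 1")
    slope = (1.0 - kr) / (1.0 - kr * r2_unselected)
    return ReliabilityResult(
        r2_unselected=r2_unselected,
        r2_selected=r2_unselected * slope,
        bias_slope=slope,
    )


def deselect_reliability(r2_selected: float, k: float, r2_presel: float) -> float:
    """Back out the unselected reliability from a preselected one.

    Exact inverse of :func:`preselection_adjust`:
    r2 = r2* / (1 - k r2_EBV + k r2* r2_EBV).
    """
    _check_unit("r2_selected", r2_selected)
    _check_unit("r2_presel", r2_presel)
    if k < 0:
        raise ValueError(f"variance reduction k must be >= 0, got {k!r}")
    denom = 1.0 - k * r2_presel + k * r2_selected * r2_presel
    if denom <= 0.0:
        raise ValueError("non-positive denominator: inputs outside the valid region")
    return r2_selected / denom
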