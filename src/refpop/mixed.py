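"""Bull-per-cow equivalence and mixed bull+cow reference populations.

Three questions about reference-population design are answered here.

1. *How many progeny-tested bulls contribute as much GEBV reliability as
   one phenotyped, genotyped cow?*  Under equal adjusted reliabilities the
   ratio of required reference sizes collapses to

       nP_m / nP_f = (r2_f / r2_m) * (1 - k_f r2_EBV_f) / (1 - k_m r2_EBV_m),

   which depends only on the information reliabilities of the two sexes
   and on how strongly each was preselected.  The general (unequal
   adjusted reliabilities) ratio is also provided.

2. *What is the reliability of GEBV when preselected bulls and cows are
   combined in one reference population?*  Treating the two groups' GEBV
   as two correlated index sources with per-group adjusted reliabilities
   a and c gives the closed form

       r2_combined = (a + c - 2 a c) / (1 - a c),

   symmetric, at least max(a, c), and below a + c because the marker
   information of the groups overlaps.

3. *What is a cow worth inside the mixed population?*  The reliability
   gained by adding cows to a bulls-only population is back-converted to
   the unselected scale, translated into an equivalent number of extra
   bulls via the reference-size inversion, and divided by the number of
   cows added.  This route does not numerically agree with the collapsed
   ratio of (1) under the index reconstruction used here; both are
   exposed so they can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genomic import (
    GenomeParams,
    preselection_adjust,
    required_reference_size,
    unselected_reliability,
)
from .truncation import SelectionRegime

__all__ = [
    "EquivalenceInputs",
    "MixedResult",
    "bull_cow_equivalence",
    "general_equivalence",
    "combined_reliability",
    "cow_value_mixed",
]


@dataclass(frozen=True)
class EquivalenceInputs:
    """Per-sex information and preselection parameters (m=bulls, f=cows)."""

    r2_info_m: float
    r2_info_f: float
    r2_presel_m: float = 0.0
    r2_presel_f: float = 0.0
    k_m: float = 0.0
    k_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r2_info_m", "r2_info_f", "r2_presel_m", "r2_presel_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for kname, rname in (("k_m", "r2_presel_m"), ("k_f", "r2_presel_f")):
            k = getattr(self, kname)
            if k < 0:
                raise ValueError(f"{kname} must be >= 0")
            if k * getattr(self, rname) >= 1.0:
                raise ValueError(f"degenerate selection: {kname} * {rname} must be < 1")


@dataclass(frozen=True)
class MixedResult:
    """Outcome of combining bull and cow reference groups."""

    r2_m_star: float
    r2_f_star: float
    r2_combined: float
    b1: float
    b2: float
    delta_r2: Optional[float] = None
    n_bull_equiv: Optional[float] = None


def bull_cow_equivalence(inp: EquivalenceInputs) -> float:
    """Bulls per cow under equal adjusted GEBV reliabilities.

    (r2_f / r2_m) * (1 - k_f r2_EBV_f) / (1 - k_m r2_EBV_m); with no
    preselection the ratio reduces to r2_f / r2_m.
    """
    if inp.r2_info_m == 0.0:
        raise ValueError("r2_info_m must be positive")
    return (
        (inp.r2_info_f / inp.r2_info_m)
        * (1.0 - inp.k_f * inp.r2_presel_f)
        / (1.0 - inp.k_m * inp.r2_presel_m)
    )


def general_equivalence(
    inp: EquivalenceInputs, r2_m_star: float, r2_f_star: float
) -> float:
    """Ratio of required bull to cow reference sizes, nP_m / nP_f.

    Full form before imposing equal adjusted reliabilities:

        (r2_f / r2_m) * (a / c) * (1 - k_f r2_EBV_f)(1 - c)
                                / ((1 - k_m r2_EBV_m)(1 - a))

    with a, c the male/female adjusted reliabilities.  Equals
    :func:`bull_cow_equivalence` when a == c.
    """
    for name, v in (("r2_m_star", r2_m_star), ("r2_f_star", r2_f_star)):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {v!r}")
    if inp.r2_info_m == 0.0 or r2_f_star == 0.0:
        raise ValueError("r2_info_m and r2_f_star must be positive")
    return (
        (inp.r2_info_f / inp.r2_info_m)
        * (r2_m_star / r2_f_star)
        * (1.0 - inp.k_f * inp.r2_presel_f)
        * (1.0 - r2_f_star)
        / ((1.0 - inp.k_m * inp.r2_presel_m) * (1.0 - r2_m_star))
    )


def combined_reliability(r2_m_star: float, r2_f_star: float) -> MixedResult:
    """Reliability of GEBV in a mixed bull+cow reference population.

    Solves the two-source index system with P = [[a, ac], [ac, c]],
    g = [a, c]; closed form (a + c - 2ac) / (1 - ac).  A zero argument
    drops the corresponding group.
    """
    a, c = r2_m_star, r2_f_star
    for name, v in (("r2_m_star", a), ("r2_f_star", c)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    if a * c == 1.0:
        raise ValueError("degenerate index: both groups fully informative")
    denom = 1.0 - a * c
    b1 = (1.0 - c) / denom
    b2 = (1.0 - a) / denom
    combined = (a + c - 2.0 * a * c) / denom
    return MixedResult(r2_m_star=a, r2_f_star=c, r2_combined=combined, b1=b1, b2=b2)


def cow_value_mixed(
    genome: GenomeParams,
    n_bulls: float,
    n_cows: float,
    r2_info_m: float,
    r2_presel_m: float,
    regime_m: SelectionRegime,
    r2_f_star: float,
) -> MixedResult:
    """Bulls-per-cow value of cows added to a bulls-only reference population.

    The gain ``r2_combined - r2_m_star`` is back-converted to the
    unselected scale through the male preselection adjustment, expressed
    as an equivalent number of unselected bulls via the reference-size
    inversion, and divided by the number of cows added.
    """
    if n_cows <= 0:
        raise ValueError("number of cows must be positive")
    r2_u_m = unselected_reliability(n_bulls, genome.n_segments, r2_info_m)
    res_m = preselection_adjust(r2_u_m, regime_m.k, r2_presel_m)
    a = res_m.r2_selected
    mixed = combined_reliability(a, r2_f_star)
    delta_star = mixed.r2_combined - a
    kr = regime_m.k * r2_presel_m
    delta_r2 = delta_star / (1.0 - kr + kr * delta_star)
    if delta_r2 == 0.0:
        n_equiv = 0.0
    else:
        n_equiv = required_reference_size(
            delta_r2, genome.n_segments, r2_info_m
        ) / n_cows
    return MixedResult(
        r2_m_star=a,
        r2_f_star=r2_f_star,
        r2_combined=mixed.r2_combined,
        b1=mixed.b1,
        b2=mixed.b2,
        delta_r2=delta_r2,
        n_bull_equiv=n_equiv,
    )
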