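"""Truncation selection on a normally distributed criterion.

When the top fraction ``p`` of a population is kept on a standard-normal
selection criterion, three classical quantities describe the regime: the
standardized truncation point ``x`` (the abscissa with upper-tail mass
``p``), the selection intensity ``i = phi(x)/p`` (the mean of the selected
tail, in criterion standard deviations), and the proportional reduction in
the variance of the criterion among the selected,

    k = i * (i - x),

which equals ``1 - Var(Z | Z > x)`` for a standard normal ``Z``.  ``k``
drives every downstream preselection adjustment: selecting on an EBV with
reliability ``r2`` shrinks the genetic variance by the factor
``1 - k * r2``.

Two precision conventions for the underlying normal constants are offered:

``"exact"``
    Full double-precision quantile and density (the library default).
``"textbook"``
    ``x`` and ``i`` rounded to three decimals before forming ``k``, the
    precision of the selection-intensity tables printed in classical
    quantitative-genetics textbooks.  Deterministic breeding-program
    studies computed by hand from such tables are only reproducible to
    their printed digits under this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "SelectionRegime",
    "truncation_point",
    "selection_intensity",
    "variance_reduction",
]

_CONVENTIONS = ("exact", "textbook")


@dataclass(frozen=True)
class SelectionRegime:
    """Fully specified truncation-selection regime.

    Attributes
    ----------
    p : float
        Selected proportion, in (0, 1].
    x : float
        Standardized truncation point; ``-inf`` when ``p == 1`` (no
        selection, the threshold is below every candidate).
    i : float
        Selection intensity in criterion standard deviations.
    k : float
        Proportional reduction of the criterion variance, ``i * (i - x)``.
    """

    p: float
    x: float
    i: float
    k: float


def _check_p(p: float, *, allow_one: bool) -> None:
    hi = "<=" if allow_one else "<"
    if not (0.0 < p <= 1.0 if allow_one else 0.0 < p < 1.0):
        raise ValueError(
            f"selected proportion must satisfy 0 < p {hi} 1, got {p!r}"
        )


def truncation_point(p: float) -> float:
    """Standardized truncation point ``x`` with upper-tail mass ``p``.

    Solves ``Phi(x) = 1 - p``.  Accurate to better than 1e-9 (delegates to
    the scipy normal quantile).

    Parameters
    ----------
    p : float
        Selected proportion, strictly between 0 and 1.
    """
    _check_p(p, allow_one=False)
    return float(stats.norm.ppf(1.0 - p))


def selection_intensity(p: float) -> float:
    """Selection intensity ``i = phi(x) / p``; 0 when ``p == 1``.

    Equals the mean of the selected upper tail, ``E[Z | Z > x]``.
    """
    _check_p(p, allow_one=True)
    if p == 1.0:
        return 0.0
    x = truncation_point(p)
    return float(stats.norm.pdf(x)) / p


def variance_reduction(p: float, constants: str = "exact") -> SelectionRegime:
    """Truncation-selection regime for selected proportion ``p``.

    ``p == 1`` means random (no) selection and returns ``k = 0``, ``i = 0``
    and ``x = -inf`` exactly, bypassing the truncation math.

    Parameters
    ----------
    p : float
        Selected proportion in (0, 1].
    constants : {"exact", "textbook"}
        Precision convention for ``x`` and ``i`` (see module docstring).
    """
    if constants not in _CONVENTIONS:
        raise ValueError(f"constants must be one of {_CONVENTIONS}, got {constants!r}")
    _check_p(p, allow_one=True)
    if p == 1.0:
        return SelectionRegime(p=1.0, x=-math.inf, i=0.0, k=0.0)
    x = truncation_point(p)
    i = float(stats.norm.pdf(x)) / p
    if constants == "textbook":
        x = round(x, 3)
        i = round(i, 3)
    return SelectionRegime(p=p, x=x, i=i, k=i * (i - x))
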