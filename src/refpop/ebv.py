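"""Reliability of conventional (pedigree + phenotype) breeding values.

Reliability is the squared correlation between a predictor and the true
breeding value G.  Four information sources appear in dairy reference
populations:

* progeny test of a bull on N half-sib daughters,
* a cow's own record (reliability = heritability),
* parent average (PA) built from the sire and dam EBVs,
* a selection index combining PA with the cow's own record (the "cow EBV"
  used when cows are preselected on their individual records).

All algebra is on the genetic-variance-standardized scale (sigma_G^2 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InformationSource",
    "IndexProblem",
    "progeny_test_reliability",
    "own_record_reliability",
    "parent_average_reliability",
    "index_reliability",
    "cow_ebv_reliability",
]


@dataclass(frozen=True)
class InformationSource:
    """A single predictor of true breeding value with reliability ``r2``."""

    label: str
    r2: float
    kind: str = "index"  # progeny_test | own_record | parent_average | index

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"reliability must be in [0, 1], got {self.r2!r}")


@dataclass(frozen=True)
class IndexProblem:
    """Selection-index system on the sigma_G^2 = 1 scale.

    ``P`` holds the variances/covariances of the index sources, ``g`` their
    covariances with G.  The index reliability is ``g' P^-1 g``.
    """

    P: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1] or g.shape != (P.shape[0],):
            raise ValueError("P must be square and g conformable")
        if not np.allclose(P, P.T):
            raise ValueError("P must be symmetric")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "g", g)


def _check_h2(h2: float) -> None:
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"heritability must be in (0, 1], got {h2!r}")


def progeny_test_reliability(n_daughters: int, h2: float) -> float:
    """Reliability of a bull's EBV from ``n_daughters`` half-sib records.

    r2 = 0.25 N h2 / (1 + 0.25 (N - 1) h2), the classical half-sib
    progeny-test accuracy.  Increasing in both arguments, -> 1 as N -> inf.
    """
    if n_daughters < 1 or int(n_daughters) != n_daughters:
        raise ValueError(f"daughter count must be a positive integer, got {n_daughters!r}")
    _check_h2(h2)
    n = float(n_daughters)
    return 0.25 * n * h2 / (1.0 + 0.25 * (n - 1.0) * h2)


def own_record_reliability(h2: float) -> float:
    """Reliability of an EBV from a single own record: equals ``h2``."""
    _check_h2(h2)
    return h2


def parent_average_reliability(r2_sire: float, r2_dam: float) -> float:
    """Reliability of the parent average, (r2_sire + r2_dam) / 4.

    The PA is the mean of two parental EBVs, each transmitting half the
    genes; perfectly known parents give the pedigree ceiling of 0.5.
    """
    for name, v in (("r2_sire", r2_sire), ("r2_dam", r2_dam)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    return 0.25 * (r2_sire + r2_dam)


def index_reliability(problem: IndexProblem) -> float:
    """Selection-index reliability ``g' P^-1 g`` on the sigma_G^2 = 1 scale."""
    try:
        sol = np.linalg.solve(problem.P, problem.g)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular index variance matrix P") from exc
    return float(problem.g @ sol)


def cow_ebv_reliability(h2: float, sire_daughters: int = 50) -> float:
    """Reliability of a cow's EBV: index of parent average and own record.

    The PA combines the sire EBV (progeny test on ``sire_daughters``
    records) with the dam's own record; the index then adds the cow's own
    phenotype.  Covariance structure on the sigma_G^2 = 1 scale:
    Var(PA) = Cov(PA, G) = Cov(PA, record) = r2_PA; Var(record) = 1/h2;
    Cov(record, G) = 1 (prediction errors uncorrelated with the record).
    """
    _check_h2(h2)
    r2_pa = parent_average_reliability(
        progeny_test_reliability(sire_daughters, h2), own_record_reliability(h2)
    )
    problem = IndexProblem(
        P=np.array([[r2_pa, r2_pa], [r2_pa, 1.0 / h2]]),
        g=np.array([r2_pa, 1.0]),
    )
    return index_reliability(problem)
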