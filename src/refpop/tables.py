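"""Scenario engine: expand parameter grids into result tables.

Seven standard layouts are produced (matching the published deterministic
study this package reimplements):

1. bull reference populations — unselected reliability at 100% preselection
   and the preselected/unselected ratio below 100%,
2. cow reference populations — adjusted reliabilities,
3. reliabilities of the preselection EBVs themselves,
4. bias slopes for preselected bulls,
5. bias slopes for preselected cows,
6. bulls-per-cow equivalence,
7. mixed bull+cow reference populations (per-group and combined
   reliabilities).

Output is tidy long format: one row per cell with explicit coordinates
(h2, n_ref, daughters, criterion, percent_m, percent_f, statistic).
Transcribed reference versions of all seven tables ship with the package;
:func:`compare_to_reference` reports any cell that disagrees after
round-half-up display rounding.  Reference cells whose printed value is
known to disagree with recomputation (last-digit rounding artifacts and
outright misprints in the source) carry a non-empty ``note`` and are meant
to be excluded from hard equality checks.

Two truncation-constant conventions are threaded through the grids because
the source tables were evidently computed with 3-decimal textbook
selection constants on the bull side and full-precision constants on the
cow side; see :mod:`refpop.truncation`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ebv import (
    cow_ebv_reliability,
    own_record_reliability,
    parent_average_reliability,
    progeny_test_reliability,
)
from .genomic import GenomeParams, preselection_adjust, unselected_reliability
from .mixed import EquivalenceInputs, bull_cow_equivalence, combined_reliability
from .truncation import variance_reduction

__all__ = [
    "ScenarioGrid",
    "published_grid",
    "build_table",
    "build_all_tables",
    "load_reference",
    "compare_to_reference",
    "table2_label_swap_report",
    "grid_from_yaml",
]

#: Coordinate columns identifying one table cell.
COORDS = ["h2", "n_ref", "daughters", "criterion", "percent_m", "percent_f", "statistic"]

_DEFAULT_GENOME = GenomeParams(ne=100.0, length_morgans=30.0)


@dataclass(frozen=True)
class ScenarioGrid:
    """Cross-product of scenario parameters defining one table layout.

    Percentages are supplied on the 0-100 scale and divided by 100 at this
    boundary; all internal math uses fractions.
    """

    table_id: int
    heritabilities: Sequence[float] = (0.1, 0.3, 0.5)
    reference_sizes: Sequence[int] = (5000, 10000, 20000, 40000)
    male_presel_percents: Sequence[float] = (5.0, 30.0, 100.0)
    female_presel_percents: Sequence[float] = (70.0, 80.0, 90.0, 100.0)
    daughters_per_bull: Sequence[int] = (50, 100)
    genome: GenomeParams = _DEFAULT_GENOME
    male_constants: str = "exact"
    female_constants: str = "exact"
    cow_index_daughters: int = 50
    n_bulls_mixed: int = 10000

    def __post_init__(self) -> None:
        if self.table_id not in range(1, 8):
            raise ValueError(f"table_id must be in 1..7, got {self.table_id!r}")
        for p in list(self.male_presel_percents) + list(self.female_presel_percents):
            if not 0.0 < p <= 100.0:
                raise ValueError(f"percentages must be in (0, 100], got {p!r}")
        if any(n <= 0 for n in self.reference_sizes):
            raise ValueError("reference sizes must be positive")


def published_grid(table_id: int) -> ScenarioGrid:
    """Grid reproducing one published table under its stated conventions."""
    base = ScenarioGrid(table_id=table_id)
    if table_id == 1:
        return replace(base, male_constants="textbook")
    if table_id == 2:
        return base
    if table_id == 3:
        return replace(base, daughters_per_bull=(50,))
    if table_id == 4:
        return replace(
            base, male_constants="textbook", male_presel_percents=(5.0, 30.0)
        )
    if table_id == 5:
        return replace(base, female_presel_percents=(70.0, 90.0))
    if table_id == 6:
        return replace(
            base,
            daughters_per_bull=(50,),
            male_presel_percents=(5.0, 30.0),
            female_presel_percents=(70.0, 100.0),
        )
    return replace(
        base,
        daughters_per_bull=(100,),
        male_presel_percents=(5.0, 30.0),
        female_presel_percents=(70.0, 100.0),
        reference_sizes=(10000, 20000),
        male_constants="textbook",
        cow_index_daughters=100,
    )


def _row(value, h2, statistic, n_ref=np.nan, daughters=np.nan,
         criterion="", percent_m=np.nan, percent_f=np.nan):
    return {
        "h2": h2, "n_ref": n_ref, "daughters": daughters, "criterion": criterion,
        "percent_m": percent_m, "percent_f": percent_f,
        "statistic": statistic, "value": value,
    }


def _bull_rows(grid: ScenarioGrid, statistic: str) -> list[dict]:
    rows = []
    for h2 in grid.heritabilities:
        for n_ref in grid.reference_sizes:
            for nd in grid.daughters_per_bull:
                r2_pt = progeny_test_reliability(nd, h2)
                r2_u = unselected_reliability(n_ref, grid.genome.n_segments, r2_pt)
                r2_pa = parent_average_reliability(r2_pt, own_record_reliability(h2))
                for pct in grid.male_presel_percents:
                    if pct == 100.0:
                        if statistic == "bias":
                            continue  # slope is identically 1, not tabulated
                        rows.append(_row(r2_u, h2, "reliability", n_ref, nd, "pa", pct))
                        continue
                    regime = variance_reduction(pct / 100.0, grid.male_constants)
                    res = preselection_adjust(r2_u, regime.k, r2_pa)
                    rows.append(_row(res.bias_slope, h2,
                                     "ratio" if statistic == "ratio" else "bias",
                                     n_ref, nd, "pa", pct))
    return rows


def _cow_presel_r2(grid: ScenarioGrid, h2: float, criterion: str) -> float:
    if criterion == "pa":
        return parent_average_reliability(
            progeny_test_reliability(grid.cow_index_daughters, h2),
            own_record_reliability(h2),
        )
    return cow_ebv_reliability(h2, grid.cow_index_daughters)


def _cow_rows(grid: ScenarioGrid, statistic: str) -> list[dict]:
    rows = []
    for h2 in grid.heritabilities:
        for n_ref in grid.reference_sizes:
            r2_u = unselected_reliability(n_ref, grid.genome.n_segments, h2)
            for criterion in ("pa", "own_ebv"):
                r2_e = _cow_presel_r2(grid, h2, criterion)
                for pct in grid.female_presel_percents:
                    if pct == 100.0:
                        if statistic == "bias":
                            continue
                        rows.append(
                            _row(r2_u, h2, "reliability", n_ref, np.nan, criterion,
                                 percent_f=pct))
                        continue
                    regime = variance_reduction(pct / 100.0, grid.female_constants)
                    res = preselection_adjust(r2_u, regime.k, r2_e)
                    value = res.bias_slope if statistic == "bias" else res.r2_selected
                    rows.append(_row(value, h2,
                                     "bias" if statistic == "bias" else "reliability",
                                     n_ref, np.nan, criterion, percent_f=pct))
    return rows


def _ebv_rows(grid: ScenarioGrid) -> list[dict]:
    nd = grid.daughters_per_bull[0]
    rows = []
    for h2 in grid.heritabilities:
        r2_pt = progeny_test_reliability(nd, h2)
        rows.append(_row(r2_pt, h2, "reliability", daughters=nd, criterion="progeny_test"))
        rows.append(_row(cow_ebv_reliability(h2, nd), h2, "reliability",
                         daughters=nd, criterion="own_ebv"))
        rows.append(_row(
            parent_average_reliability(r2_pt, own_record_reliability(h2)),
            h2, "reliability", daughters=nd, criterion="pa"))
    return rows


def _equivalence_rows(grid: ScenarioGrid) -> list[dict]:
    nd = grid.daughters_per_bull[0]
    rows = []
    for h2 in grid.heritabilities:
        r2_m = progeny_test_reliability(nd, h2)
        r2_presel_m = parent_average_reliability(r2_m, own_record_reliability(h2))
        for pct_m in grid.male_presel_percents:
            k_m = variance_reduction(pct_m / 100.0, grid.male_constants).k
            for criterion in ("own_ebv", "pa"):
                for pct_f in grid.female_presel_percents:
                    k_f = variance_reduction(pct_f / 100.0, grid.female_constants).k
                    inp = EquivalenceInputs(
                        r2_info_m=r2_m, r2_info_f=h2,
                        r2_presel_m=r2_presel_m,
                        r2_presel_f=_cow_presel_r2(grid, h2, criterion),
                        k_m=k_m, k_f=k_f,
                    )
                    rows.append(_row(bull_cow_equivalence(inp), h2, "equivalence",
                                     daughters=nd, criterion=criterion,
                                     percent_m=pct_m, percent_f=pct_f))
    return rows


def _mixed_rows(grid: ScenarioGrid) -> list[dict]:
    nd = grid.daughters_per_bull[0]
    nG = grid.genome.n_segments
    rows = []
    for h2 in grid.heritabilities:
        r2_m = progeny_test_reliability(nd, h2)
        r2_presel_m = parent_average_reliability(r2_m, own_record_reliability(h2))
        r2_u_m = unselected_reliability(grid.n_bulls_mixed, nG, r2_m)
        r2_idx = cow_ebv_reliability(h2, grid.cow_index_daughters)
        for n_cows in grid.reference_sizes:
            r2_u_f = unselected_reliability(n_cows, nG, h2)
            for pct_m in grid.male_presel_percents:
                k_m = variance_reduction(pct_m / 100.0, grid.male_constants).k
                a = preselection_adjust(r2_u_m, k_m, r2_presel_m).r2_selected
                for pct_f in grid.female_presel_percents:
                    if pct_f == 100.0:
                        c = r2_u_f
                    else:
                        k_f = variance_reduction(pct_f / 100.0, grid.female_constants).k
                        c = preselection_adjust(r2_u_f, k_f, r2_idx).r2_selected
                    combined = combined_reliability(a, c).r2_combined
                    for stat, value in (
                        ("bulls_only", a), ("cows_only", c), ("combined", combined)
                    ):
                        rows.append(_row(value, h2, stat, n_ref=n_cows, daughters=nd,
                                         criterion="own_ebv",
                                         percent_m=pct_m, percent_f=pct_f))
    return rows


def build_table(grid: ScenarioGrid) -> pd.DataFrame:
    """Expand a grid into its tidy table.  Deterministic for a given grid."""
    builders = {
        1: lambda g: _bull_rows(g, "ratio"),
        2: lambda g: _cow_rows(g, "reliability"),
        3: _ebv_rows,
        4: lambda g: _bull_rows(g, "bias"),
        5: lambda g: _cow_rows(g, "bias"),
        6: _equivalence_rows,
        7: _mixed_rows,
    }
    rows = builders[grid.table_id](grid)
    return pd.DataFrame(rows, columns=COORDS + ["value"])


def build_all_tables() -> dict[int, pd.DataFrame]:
    """Regenerate all seven tables under their publication conventions."""
    return {tid: build_table(published_grid(tid)) for tid in range(1, 8)}


def load_reference(table_id: int) -> pd.DataFrame:
    """Transcribed reference table shipped with the package.

    Columns: the :data:`COORDS` coordinates, ``value`` (the printed
    number), ``note`` (empty, or the reason the cell is excluded from
    hard equality checks), and for table 2 ``printed_label`` (the
    criterion label the source printed over the block, which is swapped
    relative to the values; see :func:`table2_label_swap_report`).
    """
    ref = importlib.resources.files("refpop.data") / f"table{table_id}.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, keep_default_na=False,
                         na_values=[""], dtype={"criterion": str, "statistic": str})
    df["note"] = df["note"].fillna("")
    return df


def round_half_up(value: float, decimals: int) -> float:
    """Display rounding with ties away from zero (as printed tables use)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def compare_to_reference(
    computed: pd.DataFrame,
    reference: pd.DataFrame,
    decimals: int,
    include_noted: bool = True,
) -> pd.DataFrame:
    """Cells whose round-half-up values differ; empty frame means pass.

    Raises if the two layouts do not cover identical coordinates.  With
    ``include_noted=False``, reference cells carrying a non-empty ``note``
    (known last-digit discrepancies in the source) are dropped first.
    """
    ref = reference.copy()
    if "note" not in ref.columns:
        ref["note"] = ""
    if not include_noted:
        ref = ref[ref["note"] == ""]
    merged = computed.merge(ref, on=COORDS, how="outer",
                            suffixes=("_computed", "_reference"), indicator=True)
    if include_noted and (merged["_merge"] != "both").any():
        raise ValueError("layout mismatch between computed and reference tables")
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    rc = merged["value_computed"].map(lambda v: round_half_up(v, decimals))
    rr = merged["value_reference"].map(lambda v: round_half_up(v, decimals))
    out = merged.loc[(rc - rr).abs() > 1e-12].copy()
    return out.reset_index(drop=True)


def table2_label_swap_report() -> dict:
    """Compare table 2 under the printed and the computational block labels.

    The source prints the lower of the two preselected blocks under the
    parent-average label, although selecting on the less reliable PA must
    reduce reliability the least.  The report regenerates the table, scores
    it against the transcription under both label assignments, and flags
    the swap when the printed assignment fits worse.
    """
    computed = build_table(published_grid(2))
    reference = load_reference(2)
    as_computed = len(compare_to_reference(computed, reference, 4))
    swapped = reference.copy()
    swapped["criterion"] = swapped["printed_label"]
    as_printed = len(compare_to_reference(computed, swapped, 4))
    return {
        "mismatches_under_computational_labels": as_computed,
        "mismatches_under_printed_labels": as_printed,
        "swap_detected": as_printed > as_computed,
    }


def grid_from_yaml(path) -> ScenarioGrid:
    """Load a :class:`ScenarioGrid` from a YAML mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    genome_cfg = cfg.pop("genome", None)
    if genome_cfg is not None:
        cfg["genome"] = GenomeParams(**genome_cfg)
    return ScenarioGrid(**cfg)
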