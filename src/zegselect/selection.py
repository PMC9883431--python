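"""Threshold-based embryo selection on ZEG samples and its evaluation.

Selection happens on the minimally invasive ZEG sample: an embryo is
selected when its ZEG somatic editing frequency for the chosen outcome
exceeds the threshold (strict ``>``).  Enrichment is then evaluated on the
paired whole-embryo (WE) samples: average WE SEF of the selected fish
versus all fish, summarized as a fold increase

    fold = (avg_selected - avg_all) / avg_all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import AlleleCallTable, average_sef, sef_series


class SelectionError(ValueError):
    pass


@dataclass
class SelectionPartition:
    """A threshold split of embryos with its evaluation summary.

    ``selected``/``excluded`` partition the evaluated embryos; the averages
    are computed on the evaluation (whole-embryo) table, not on the ZEG
    table used for selection.  ``unevaluated`` lists embryos that were
    partitioned but had no usable WE sample.
    """

    selector: str
    threshold: float
    selected: tuple[str, ...]
    excluded: tuple[str, ...]
    avg_all: float = math.nan
    avg_selected: float = math.nan
    avg_excluded: float = math.nan
    fold: float = math.nan
    unevaluated: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def summary_row(self) -> dict:
        """One row mirroring the familiar selection-table columns (percent)."""
        return {
            "selector": self.selector,
            "threshold_pct": 100 * self.threshold,
            "n_selected": self.n_selected,
            "n_excluded": self.n_excluded,
            "avg_sef_all_pct": 100 * self.avg_all,
            "avg_sef_excluded_pct": 100 * self.avg_excluded,
            "avg_sef_selected_pct": 100 * self.avg_selected,
            "fold_increase": self.fold,
        }


def select_embryos(
    zeg_table: AlleleCallTable, selector: str, threshold: float
) -> SelectionPartition:
    """Partition embryos by ZEG SEF: selected iff SEF(selector) > threshold.

    An empty selected set (threshold above the maximum) is a valid outcome,
    not an error.  Embryos should already have passed the minimum-read
    filter; embryos dropped by that filter are neither selected nor
    excluded.
    """
    if threshold < 0:
        raise SelectionError("threshold must be >= 0")
    if not len(zeg_table.counts):
        raise SelectionError("empty ZEG table: nothing to select from")
    values = sef_series(zeg_table, selector)
    selected = tuple(e for e, v in values.items() if v > threshold)
    excluded = tuple(e for e, v in values.items() if v <= threshold)
    return SelectionPartition(
        selector=selector, threshold=threshold, selected=selected, excluded=excluded
    )


def fold_increase(avg_all: float, avg_selected: float) -> float:
    """(avg_selected - avg_all) / avg_all; both on the same scale.

    Scale-invariant: percentages and fractions give the same fold.
    """
    if avg_all <= 0:
        raise SelectionError("fold increase undefined: average SEF of all fish is 0")
    return (avg_selected - avg_all) / avg_all


def evaluate_partition(
    partition: SelectionPartition,
    we_table: AlleleCallTable,
    selector: str | None = None,
) -> SelectionPartition:
    """Fill in WE-based averages and the fold increase for a ZEG partition.

    Embryos missing from the WE table (failed sample, read filter) are
    reported in ``unevaluated`` and excluded from all three averages.
    """
    selector = selector or partition.selector
    available = set(we_table.embryos)
    sel = [e for e in partition.selected if e in available]
    exc = [e for e in partition.excluded if e in available]
    missing = tuple(
        e for e in (*partition.selected, *partition.excluded) if e not in available
    )
    evaluated = sel + exc
    if not evaluated:
        raise SelectionError("no partitioned embryo has a whole-embryo sample")
    avg_all = average_sef(we_table, selector, evaluated)
    avg_sel = average_sef(we_table, selector, sel) if sel else math.nan
    avg_exc = average_sef(we_table, selector, exc) if exc else math.nan
    fold = fold_increase(avg_all, avg_sel) if sel and avg_all > 0 else math.nan
    partition.avg_all = avg_all
    partition.avg_selected = avg_sel
    partition.avg_excluded = avg_exc
    partition.fold = fold
    partition.unevaluated = missing
    return partition


def selection_table(
    zeg_table: AlleleCallTable,
    we_table: AlleleCallTable,
    selector: str,
    thresholds: Sequence[float] = (0.02, 0.05, 0.10),
) -> pd.DataFrame:
    """Evaluate one selector across several thresholds; one summary row each."""
    rows = []
    for t in thresholds:
        part = evaluate_partition(select_embryos(zeg_table, selector, t), we_table)
        rows.append(part.summary_row())
    return pd.DataFrame(rows)


def normalize_we_counts(
    we_table: AlleleCallTable, zeg_totals: pd.Series
) -> AlleleCallTable:
    """Scale each embryo's WE counts by (ZEG total / WE total).

    Puts both sample kinds on a common sequencing-depth scale before
    count-based correlation; within-embryo allele ratios are unchanged.
    """
    common = [e for e in we_table.embryos if e in zeg_totals.index]
    if not common:
        raise SelectionError("no embryos shared between WE table and ZEG totals")
    counts = we_table.counts.loc[common].astype(float)
    we_totals = counts.sum(axis=1)
    if (we_totals == 0).any():
        bad = list(we_totals.index[we_totals == 0])
        raise SelectionError(f"zero WE total for embryos {bad}")
    scale = zeg_totals.loc[common].astype(float) / we_totals
    return AlleleCallTable(
        counts=counts.mul(scale, axis=0), ki_bit=we_table.ki_bit
    )


def correlation(
    x: Sequence[float], y: Sequence[float], transform: str = "sqrt"
) -> tuple[float, float, int]:
    """Pearson correlation of paired values, optionally sqrt-transformed.

    Returns (r, two-sided p, n).  The square-root transform tames the
    right-skew of editing frequencies before computing r, as is standard
    for ZEG-versus-whole-embryo concordance plots.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SelectionError("paired vectors differ in length")
    if x.size < 3:
        raise SelectionError("need at least 3 pairs")
    if transform == "sqrt":
        if (x < 0).any() or (y < 0).any():
            raise SelectionError("sqrt transform needs non-negative values")
        x, y = np.sqrt(x), np.sqrt(y)
    elif transform != "identity":
        raise SelectionError(f"unknown transform {transform!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SelectionError("constant vector: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def transmission_fraction(n_transmitting: int, n_raised: int) -> float:
    """Share of raised founders with germline transmission, as a percentage."""
    if n_raised <= 0:
        raise SelectionError("n_raised must be positive")
    if not 0 <= n_transmitting <= n_raised:
        raise SelectionError("n_transmitting must be between 0 and n_raised")
    return 100.0 * n_transmitting / n_raised
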