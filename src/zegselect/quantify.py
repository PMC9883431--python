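"""Per-embryo somatic editing frequencies (SEF) and derived summaries.

The central container is :class:`AlleleCallTable`, an embryo x allele matrix
of consensus-read counts.  SEF for an outcome selector is that outcome's
count share of the embryo's total consensus reads; averages across embryos
are unweighted.  Selectors: ``"KI"`` (HDR reads carrying the knock-in
marker base), ``"all_indels"`` (indels plus imperfect-HDR junction events),
or any single allele key.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .locus_model import AlleleKind
from .readproc import ReadCall
from .synthetic_data import PeakTable


class QuantifyError(ValueError):
    pass


def kind_of_key(key: str) -> AlleleKind:
    """Infer the outcome category from a canonical allele key."""
    if key == "WT":
        return AlleleKind.WT
    if key == "OTHER_SUB":
        return AlleleKind.OTHER_SUB
    if key.startswith("HDR["):
        return AlleleKind.IMPERFECT_HDR if "+" in key else AlleleKind.HDR
    return AlleleKind.INDEL


def _hdr_bits(key: str) -> str:
    return key[4 : key.index("]")]


@dataclass
class AlleleCallTable:
    """Embryo x allele consensus-read count matrix.

    ``ki_bit`` is the index of the KI marker within the locus marker list,
    needed to interpret the bitstrings of HDR allele keys.
    """

    counts: pd.DataFrame
    ki_bit: int | None = None
    dropped_embryos: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise QuantifyError("negative counts")
        if self.counts.index.has_duplicates:
            raise QuantifyError("duplicate embryo ids")

    @property
    def embryos(self) -> list[str]:
        return list(self.counts.index)

    @property
    def allele_keys(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def columns_of_kind(self, kinds: Iterable[AlleleKind]) -> list[str]:
        kinds = set(kinds)
        return [k for k in self.counts.columns if kind_of_key(k) in kinds]


def _column_order(counts: pd.DataFrame) -> list[str]:
    """WT first, HDR alleles, indels by descending global count, OTHER_SUB last."""
    cols = list(counts.columns)
    wt = [c for c in cols if c == "WT"]
    hdr = sorted(c for c in cols if kind_of_key(c) is AlleleKind.HDR)
    indel_like = [
        c for c in cols if kind_of_key(c) in (AlleleKind.INDEL, AlleleKind.IMPERFECT_HDR)
    ]
    indel_like.sort(key=lambda c: (-counts[c].sum(), c))
    other = [c for c in cols if c == "OTHER_SUB"]
    return wt + hdr + indel_like + other


def tabulate(
    calls_per_embryo: Mapping[str, Sequence[ReadCall]], ki_bit: int | None = None
) -> AlleleCallTable:
    """Count consensus-read calls into an embryo x allele matrix."""
    rows: dict[str, dict[str, int]] = {}
    for embryo, calls in calls_per_embryo.items():
        row: dict[str, int] = {}
        for call in calls:
            row[call.allele_key] = row.get(call.allele_key, 0) + 1
        rows[embryo] = row
    counts = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    counts = counts.reindex(sorted(rows), axis=0)
    if not counts.empty:
        counts = counts[_column_order(counts)]
    return AlleleCallTable(counts=counts, ki_bit=ki_bit)


def filter_min_reads(
    table: AlleleCallTable, min_total: int = 100
) -> tuple[AlleleCallTable, list[str]]:
    """Drop embryos with fewer than ``min_total`` consensus reads.

    Embryos with exactly ``min_total`` reads are kept.  Returns the filtered
    table and the dropped embryo ids; the dropped ids are also recorded on
    the returned table.
    """
    if min_total < 0:
        raise QuantifyError("min_total must be >= 0")
    keep = table.totals >= min_total
    dropped = [e for e, ok in keep.items() if not ok]
    return (
        replace(
            table,
            counts=table.counts.loc[keep],
            dropped_embryos=table.dropped_embryos + tuple(dropped),
        ),
        dropped,
    )


def _selector_columns(table: AlleleCallTable, selector: str) -> list[str]:
    if selector in ("all_indels", "all indels"):
        return table.columns_of_kind((AlleleKind.INDEL, AlleleKind.IMPERFECT_HDR))
    if selector == "KI":
        if table.ki_bit is None:
            raise QuantifyError("table has no KI marker index; cannot use selector 'KI'")
        return [
            k
            for k in table.allele_keys
            if kind_of_key(k) is AlleleKind.HDR and _hdr_bits(k)[table.ki_bit] == "1"
        ]
    return [selector] if selector in table.allele_keys else []


def sef(table: AlleleCallTable, embryo: str, selector: str) -> float:
    """Somatic editing frequency of one outcome in one embryo (fraction)."""
    if embryo not in table.counts.index:
        raise QuantifyError(f"unknown embryo {embryo!r}")
    total = int(table.totals[embryo])
    if total == 0:
        raise QuantifyError(f"embryo {embryo!r} has zero reads")
    cols = _selector_columns(table, selector)
    if not cols:
        return 0.0
    return float(table.counts.loc[embryo, cols].sum()) / total


def sef_series(table: AlleleCallTable, selector: str) -> pd.Series:
    """Per-embryo SEF for a selector, as a fraction."""
    cols = _selector_columns(table, selector)
    totals = table.totals.astype(float)
    if not cols:
        return totals * 0.0
    return table.counts[cols].sum(axis=1) / totals


def average_sef(
    table: AlleleCallTable, selector: str, embryos: Sequence[str] | None = None
) -> float:
    """Unweighted mean of per-embryo SEFs (the mean of ratios, not the pooled
    ratio — embryos count equally regardless of read depth)."""
    values = sef_series(table, selector)
    if embryos is not None:
        if len(embryos) == 0:
            raise QuantifyError("empty embryo subset: no fish to average over")
        missing = set(embryos) - set(values.index)
        if missing:
            raise QuantifyError(f"unknown embryos {sorted(missing)}")
        values = values.loc[list(embryos)]
    if values.empty:
        raise QuantifyError("empty table: no fish to average over")
    return float(values.mean())


def top_indels(table: AlleleCallTable, n: int = 10) -> list[str]:
    """The ``n`` indel alleles with the highest average SEF (ties: key order)."""
    if n < 1:
        raise QuantifyError("n must be >= 1")
    keys = table.columns_of_kind((AlleleKind.INDEL, AlleleKind.IMPERFECT_HDR))
    ranked = sorted(keys, key=lambda k: (-average_sef(table, k), k))
    return ranked[:n]


def frequency_classes(
    table: AlleleCallTable,
    alleles: Sequence[str],
    bounds: tuple[float, float] = (0.01, 0.05),
) -> dict[str, str]:
    """Group alleles by average SEF into low/middle/high frequency classes.

    With the default bounds the labels match the conventional grouping
    "<1%", "1-5%" and ">5%"; boundary values fall into the middle class
    because the outer labels are strict inequalities.
    """
    lo, hi = bounds
    if not lo < hi:
        raise QuantifyError("bounds must be increasing")
    labels = (
        f"<{lo:.0%}",
        f"{lo:.0%}-{hi:.0%}".replace("%-", "-", 1),
        f">{hi:.0%}",
    )
    out: dict[str, str] = {}
    for key in alleles:
        avg = average_sef(table, key)
        if avg < lo:
            out[key] = labels[0]
        elif avg > hi:
            out[key] = labels[2]
        else:
            out[key] = labels[1]
    return out


def incorporation_by_distance(
    table: AlleleCallTable, ref
) -> pd.DataFrame:
    """Per-marker incorporation rate against distance from the cut site.

    For each marker: the fraction of an embryo's consensus reads whose
    incorporation vector is true at that marker (HDR and imperfect-HDR reads
    both carry vectors), averaged unweighted across embryos.  This is the
    distance-to-cut analysis: under a conversion-tract model the rate decays
    with distance.
    """
    from .locus_model import marker_distance  # local import to avoid cycle noise

    if not ref.markers:
        raise QuantifyError("locus has no markers")
    totals = table.totals.astype(float)
    records = []
    for i, m in enumerate(ref.markers):
        cols = [
            k
            for k in table.allele_keys
            if k.startswith("HDR[") and _hdr_bits(k)[i] == "1"
        ]
        if cols:
            per_embryo = table.counts[cols].sum(axis=1) / totals
        else:
            per_embryo = totals * 0.0
        records.append(
            {
                "marker_offset_bp": m.offset_bp,
                "distance_bp": marker_distance(m, ref),
                "role": m.role.value,
                "mean_incorporation": float(per_embryo.mean()),
            }
        )
    return pd.DataFrame(records).sort_values("distance_bp", ignore_index=True)


def crispr_stat_estimate(peaks: PeakTable) -> float:
    """Indel percentage from a fragment-analysis peak table.

    Summed intensity of all non-wildtype peaks divided by the total peak
    intensity, as a percentage.
    """
    total = peaks.total
    if total <= 0:
        raise QuantifyError("peak table has zero total intensity")
    wt = peaks.intensities.get(peaks.wt_length, 0.0)
    return 100.0 * (1.0 - wt / total)
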