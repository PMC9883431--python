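"""End-to-end orchestration: raw paired reads -> per-embryo count tables.

Thin glue over the stage functions in :mod:`readproc` and
:mod:`quantify`: demultiplex, trim barcode+UMI, merge mates, collapse UMI
families to consensus, align, classify, tabulate.  Alignment and
classification are memoized per distinct consensus sequence, which is what
makes deep simulated runs cheap — after consensus most reads collapse onto
a handful of true allele sequences.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .locus_model import AmpliconReference
from .quantify import AlleleCallTable, filter_min_reads, tabulate
from .readproc import (
    ReadCall,
    ReadRecord,
    ReadTooShortError,
    UmiScheme,
    align_global,
    classify_read,
    demultiplex,
    extract_umi,
    merge_pairs,
    umi_consensus,
)
from .synthetic_data import SimulatedExperiment


@dataclass
class RunLog:
    """Per-run accounting of what happened to the reads."""

    reads_in: int = 0
    unassigned: int = 0
    too_short: int = 0
    merge_failed: int = 0
    families: int = 0
    consensus_reads: int = 0
    dropped_embryos: dict[str, list[str]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "unassigned": self.unassigned,
            "too_short": self.too_short,
            "merge_failed": self.merge_failed,
            "families": self.families,
            "consensus_reads": self.consensus_reads,
            "dropped_embryos": self.dropped_embryos,
        }


@dataclass
class PipelineResult:
    tables: dict[str, AlleleCallTable]  # by sample kind (ZEG/WE/...)
    calls: dict[str, dict[str, list[ReadCall]]]  # kind -> embryo -> calls
    log: RunLog


def classify_sample_reads(
    reads: Iterable[ReadRecord],
    ref: AmpliconReference,
    scheme: UmiScheme,
    log: RunLog,
    min_overlap: int = 20,
    window: int = 20,
    caches: tuple[dict, dict] | None = None,
) -> list[ReadCall]:
    """UMI-collapse and classify the (already demultiplexed) reads of one sample."""
    merge_cache, call_cache = caches if caches is not None else ({}, {})
    families: dict[str, list[str]] = defaultdict(list)
    for read in reads:
        try:
            umi, trimmed = extract_umi(read, scheme)
        except ReadTooShortError:
            log.too_short += 1
            continue
        key = (trimmed.seq1, trimmed.seq2)
        if key in merge_cache:
            merged = merge_cache[key]
        else:
            merged = merge_pairs(
                trimmed.seq1, trimmed.qual1, trimmed.seq2, trimmed.qual2,
                min_overlap=min_overlap,
            )
            merge_cache[key] = merged
        if merged is None:
            log.merge_failed += 1
            continue
        families[umi].append(merged)
    calls: list[ReadCall] = []
    for umi, members in families.items():
        log.families += 1
        consensus = umi_consensus(umi, members)
        log.consensus_reads += 1
        cached = call_cache.get(consensus.sequence)
        if cached is None:
            aln = align_global(consensus.sequence, ref)
            cached = classify_read(aln, ref, window=window)
            call_cache[consensus.sequence] = cached
        calls.append(
            ReadCall(
                category=cached.category,
                allele_key=cached.allele_key,
                incorporation=cached.incorporation,
                indels=cached.indels,
                family_size=consensus.family_size,
            )
        )
    return calls


def run_pipeline(
    reads: Iterable[ReadRecord],
    ref: AmpliconReference,
    barcode_map: Mapping[str, str],
    sample_meta: Mapping[str, tuple[str, str]],  # sample_id -> (embryo_id, kind)
    scheme: UmiScheme | None = None,
    max_barcode_mismatch: int = 1,
    min_total_reads: int = 100,
    window: int = 20,
) -> PipelineResult:
    """Process raw paired reads into filtered per-kind count tables.

    ``sample_meta`` ties each sample barcode to its embryo and sample kind
    (ZEG or WE); embryos falling under ``min_total_reads`` consensus reads
    are dropped from the tables and listed in the run log.
    """
    reads = list(reads)
    if scheme is None:
        blen = len(next(iter(barcode_map.values())))
        scheme = UmiScheme(umi_len=8, barcode_len=blen)
    log = RunLog(reads_in=len(reads))
    assigned, unassigned = demultiplex(reads, barcode_map, max_mismatch=max_barcode_mismatch)
    log.unassigned = len(unassigned)

    ki_bit = ref.ki_marker_index if ref.markers else None
    caches: tuple[dict, dict] = ({}, {})
    calls_by_kind: dict[str, dict[str, list[ReadCall]]] = defaultdict(dict)
    for sample_id, sample_reads in assigned.items():
        if sample_id not in sample_meta:
            continue
        embryo_id, kind = sample_meta[sample_id]
        calls = classify_sample_reads(
            sample_reads, ref, scheme, log, window=window, caches=caches
        )
        calls_by_kind[kind].setdefault(embryo_id, []).extend(calls)

    tables: dict[str, AlleleCallTable] = {}
    for kind, per_embryo in calls_by_kind.items():
        table = tabulate(per_embryo, ki_bit=ki_bit)
        table, dropped = filter_min_reads(table, min_total=min_total_reads)
        log.dropped_embryos[kind] = dropped
        tables[kind] = table
    return PipelineResult(tables=tables, calls=dict(calls_by_kind), log=log)


def process_experiment(
    exp: SimulatedExperiment,
    min_total_reads: int = 100,
    window: int = 20,
) -> PipelineResult:
    """Run the full pipeline on a simulated experiment's raw reads."""
    meta = {s.sample_id: (s.embryo_id, s.kind) for s in exp.samples}
    scheme = UmiScheme(
        umi_len=exp.params.umi_length, barcode_len=exp.params.barcode_length
    )
    return run_pipeline(
        exp.all_reads,
        exp.locus,
        exp.barcode_map,
        meta,
        scheme=scheme,
        min_total_reads=min_total_reads,
        window=window,
    )
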