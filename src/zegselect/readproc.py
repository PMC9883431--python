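"""From raw paired amplicon reads to per-embryo classified editing outcomes.

The stages mirror a UMI-aware amplicon pipeline: inline sample-barcode
demultiplexing, UMI extraction, merging of overlapping mates, per-UMI-family
majority consensus (PCR duplicate collapse), global alignment against the
amplicon reference, and rule-based classification into wildtype / indel /
HDR categories.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .locus_model import (
    AlleleKind,
    AmpliconReference,
    IndelDescriptor,
    canonical_indel,
    _indel_key,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DemuxError(ValueError):
    """Barcode table unusable: unequal lengths or barcodes too close."""


class ReadTooShortError(ValueError):
    """Read shorter than the barcode+UMI prefix it is supposed to carry."""


@dataclass
class ReadRecord:
    """One read pair; ``sample``/``umi`` are filled in by demux/extraction."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    sample: str | None = None
    umi: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class UmiScheme:
    """Inline prefix layout on mate 1: sample barcode, then UMI, then insert."""

    umi_len: int = 8
    barcode_len: int = 0


@dataclass(frozen=True)
class ConsensusRead:
    umi: str
    family_size: int
    sequence: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_map: Mapping[str, str],
    max_mismatch: int = 1,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to samples by the inline barcode at the start of mate 1.

    A read is assigned to the unique barcode within ``max_mismatch`` Hamming
    distance, otherwise left unassigned.  Uniqueness is guaranteed up front:
    the barcode table must have equal lengths and pairwise distance greater
    than ``2 * max_mismatch``, otherwise the whole run is refused.
    """
    samples = list(barcode_map)
    barcodes = [barcode_map[s] for s in samples]
    if not barcodes:
        raise DemuxError("empty barcode table")
    blen = len(barcodes[0])
    if any(len(b) != blen for b in barcodes):
        raise DemuxError("barcodes must all have the same length")
    for i in range(len(barcodes)):
        for j in range(i + 1, len(barcodes)):
            d = _hamming(barcodes[i], barcodes[j])
            if d <= 2 * max_mismatch:
                raise DemuxError(
                    f"barcodes {barcodes[i]} and {barcodes[j]} are Hamming distance "
                    f"{d} apart; need > {2 * max_mismatch} for unambiguous assignment"
                )
    exact = {b: s for s, b in barcode_map.items()}
    assigned: dict[str, list[ReadRecord]] = {s: [] for s in samples}
    unassigned: list[ReadRecord] = []
    for read in reads:
        prefix = read.seq1[:blen]
        hit = exact.get(prefix)
        if hit is None and max_mismatch > 0:
            for s, b in zip(samples, barcodes):
                if _hamming(prefix, b) <= max_mismatch:
                    hit = s
                    break
        if hit is None:
            unassigned.append(read)
        else:
            read.sample = hit
            assigned[hit].append(read)
    return assigned, unassigned


def extract_umi(read: ReadRecord, scheme: UmiScheme) -> tuple[str, ReadRecord]:
    """Cut the UMI out of the mate-1 prefix; returns (umi, trimmed read).

    The sample barcode (if the scheme has one) is trimmed along with the UMI.
    """
    prefix = scheme.barcode_len + scheme.umi_len
    if len(read.seq1) < prefix:
        raise ReadTooShortError(
            f"read {read.id}: mate 1 has {len(read.seq1)} bases, "
            f"scheme needs {prefix}"
        )
    umi = read.seq1[scheme.barcode_len : prefix]
    trimmed = replace(
        read,
        seq1=read.seq1[prefix:],
        qual1=read.qual1[prefix:],
        umi=umi,
    )
    return umi, trimmed


def merge_pairs(
    seq1: str,
    qual1: str,
    seq2: str,
    qual2: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> str | None:
    """Merge overlapping mates into the full insert; ``None`` when impossible.

    Mate 2 is reverse-complemented; the best overlap of at least
    ``min_overlap`` bases is taken, provided its mismatch fraction stays at or
    below ``max_mismatch_frac``.  Conflicting overlap bases are resolved by
    the higher base quality; quality ties become ``N``.
    """
    r2 = revcomp(seq2)
    q2 = qual2[::-1]
    a1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(r2.encode(), dtype=np.uint8)
    n1, n2 = len(a1), len(a2)
    best_ov, best_matches = -1, -1
    for ov in range(min(n1, n2), min_overlap - 1, -1):
        matches = int(np.count_nonzero(a1[n1 - ov :] == a2[:ov]))
        if ov - matches <= max_mismatch_frac * ov and matches > best_matches:
            best_ov, best_matches = ov, matches
    if best_ov < 0:
        return None
    ov = best_ov
    head = seq1[: n1 - ov]
    tail = r2[ov:]
    mid = []
    for k in range(ov):
        b1, b2 = seq1[n1 - ov + k], r2[k]
        if b1 == b2:
            mid.append(b1)
        else:
            c1, c2 = qual1[n1 - ov + k], q2[k]
            if c1 > c2:
                mid.append(b1)
            elif c2 > c1:
                mid.append(b2)
            else:
                mid.append("N")
    return head + "".join(mid) + tail


# ---------------------------------------------------------------------------
# UMI-family consensus


def _vote_column(chars: Sequence[str]) -> str:
    counts = Counter(c for c in chars if c != "N")
    if not counts:
        return "N"
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "N"
    return ranked[0][0]


def _consensus_equal_length(members: Sequence[str]) -> str:
    mat = np.frombuffer("".join(members).encode(), dtype=np.uint8).reshape(
        len(members), -1
    )
    out = []
    for col in mat.T:
        out.append(_vote_column([chr(c) for c in col]))
    return "".join(out)


def umi_consensus(umi: str, members: Sequence[str]) -> ConsensusRead:
    """Collapse one UMI family of merged reads into a consensus sequence.

    Per-column majority vote; ties become ``N``.  Singleton families pass
    through unchanged.  Length-discordant members are projected onto the
    longest member by pairwise global alignment before voting; columns where
    a majority of members vote for a gap are dropped.
    """
    if not members:
        raise ValueError("empty UMI family")
    if len(members) == 1:
        return ConsensusRead(umi=umi, family_size=1, sequence=members[0])
    if len({len(m) for m in members}) == 1:
        return ConsensusRead(
            umi=umi, family_size=len(members), sequence=_consensus_equal_length(members)
        )
    anchor = max(members, key=len)
    columns: list[list[str]] = [[] for _ in range(len(anchor))]
    gap_votes = [0] * len(anchor)
    for m in members:
        if m is anchor or m == anchor:
            for i, c in enumerate(m):
                columns[i].append(c)
            continue
        aln = align_global(m, _as_plain_ref(anchor))
        for i in range(len(anchor)):
            c = aln.cols[i]
            if c is None:
                gap_votes[i] += 1
            else:
                columns[i].append(c)
    out = []
    half = len(members) / 2
    for i in range(len(anchor)):
        if gap_votes[i] > half:
            continue
        out.append(_vote_column(columns[i]))
    return ConsensusRead(umi=umi, family_size=len(members), sequence="".join(out))


def group_by_umi(reads: Iterable[tuple[str, str]]) -> dict[str, list[str]]:
    """Group (umi, merged sequence) pairs into families."""
    fam: dict[str, list[str]] = defaultdict(list)
    for umi, seq in reads:
        fam[umi].append(seq)
    return dict(fam)


# ---------------------------------------------------------------------------
# global alignment


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


DEFAULT_SCORING = AlignScoring()


@dataclass(frozen=True)
class Alignment:
    """A global alignment projected onto reference coordinates.

    ``cols[p]`` is the query character aligned to reference position ``p``
    (``None`` where the query deletes it); ``indels`` are the left-aligned
    canonical indel events.  Insertions are anchored at the reference
    position before which the bases are inserted.
    """

    score: float
    query: str
    cols: tuple[str | None, ...]
    indels: tuple[IndelDescriptor, ...]

    def mismatch_positions(self, ref_seq: str) -> list[int]:
        return [
            p
            for p, c in enumerate(self.cols)
            if c is not None and c != "N" and c != ref_seq[p]
        ]


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # N from consensus ties: neutral against anything
    aligner.wildcard = "N"
    return aligner


@dataclass(frozen=True)
class _PlainRef:
    sequence: str


def _as_plain_ref(seq: str) -> "_PlainRef":
    return _PlainRef(seq)


def align_global(
    seq: str,
    ref: AmpliconReference | _PlainRef,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> Alignment:
    """Optimal global alignment of a read against the amplicon reference.

    Affine gap penalties; indels are normalized by left-shifting through
    repeats so that the same physical event always yields the same
    descriptor.  Where the optimizer leaves both an unaligned reference and
    an unaligned query segment at one junction, the deletion is emitted
    before the insertion.
    """
    if not seq:
        raise ValueError("empty query sequence")
    ref_seq = ref.sequence
    aligner = _make_aligner(scoring)
    aln = aligner.align(ref_seq, seq)[0]
    t_blocks, q_blocks = aln.aligned

    cols: list[str | None] = [None] * len(ref_seq)
    raw: list[tuple[int, int, str]] = []  # (ref_start, deleted_len, inserted_seq)
    prev_t, prev_q = 0, 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        del_len = ts - prev_t
        ins_seq = seq[prev_q:qs]
        if del_len or ins_seq:
            raw.append((prev_t, del_len, ins_seq))
        for k in range(te - ts):
            cols[ts + k] = seq[qs + k]
        prev_t, prev_q = te, qe
    if prev_t < len(ref_seq) or prev_q < len(seq):
        raw.append((prev_t, len(ref_seq) - prev_t, seq[prev_q:]))

    indels: list[IndelDescriptor] = []
    for start, del_len, ins_seq in raw:
        if del_len and ins_seq:
            indels.append(IndelDescriptor(start, del_len, ins_seq))
            continue
        before = canonical_indel(ref_seq, start, del_len, ins_seq)
        if before.start < start:
            s_new = before.start
            if del_len:
                # positions freed on the right of the shifted deletion are
                # repeat matches by construction
                for p in range(max(start, s_new + del_len), start + del_len):
                    cols[p] = ref_seq[p]
                for p in range(s_new, min(start, s_new + del_len)):
                    cols[p] = None
            else:
                for p in range(s_new, start):
                    cols[p] = ref_seq[p]
        indels.append(before)
    indels.sort(key=lambda d: (d.start, d.deleted_len, d.inserted_seq))
    return Alignment(
        score=float(aln.score), query=seq, cols=tuple(cols), indels=tuple(indels)
    )


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ReadCall:
    """Editing-outcome call for one consensus read."""

    category: AlleleKind
    allele_key: str
    incorporation: tuple[bool, ...] | None = None
    indels: tuple[IndelDescriptor, ...] = field(default_factory=tuple)
    family_size: int = 1


def _overlaps_window(d: IndelDescriptor, lo: int, hi: int) -> bool:
    a, b = d.ref_span
    if a == b:  # insertion: zero-width junction
        return lo <= a <= hi
    return a < hi and b > lo


def classify_read(
    aln: Alignment,
    ref: AmpliconReference,
    window: int = 20,
    max_stray_mismatch: int = 1,
    family_size: int = 1,
) -> ReadCall:
    """Assign one consensus read to an editing-outcome category.

    Primer regions are ignored.  Any indel overlapping ``cut_index ± window``
    makes the read INDEL — or IMPERFECT_HDR when the KI marker base is also
    present.  Without an indel, marker substitutions define an HDR call with
    the observed incorporation vector (a partial conversion tract may carry
    synonymous markers but not the KI base).  Reads with neither indel nor
    marker edits are WT up to ``max_stray_mismatch`` residual mismatches and
    OTHER_SUB beyond that.
    """
    ref_seq = ref.sequence
    lo, hi = ref.callable_region
    win_lo = max(lo, ref.cut_index - window)
    win_hi = min(hi, ref.cut_index + window)

    relevant = tuple(d for d in aln.indels if _overlaps_window(d, win_lo, win_hi))

    marker_pos = [ref.marker_position(m) for m in ref.markers]
    incorporation = tuple(
        aln.cols[p] == m.alt_base for p, m in zip(marker_pos, ref.markers)
    )
    marker_set = set(marker_pos)
    stray = sum(
        1 for p in aln.mismatch_positions(ref_seq) if lo <= p < hi and p not in marker_set
    )
    # a marker position showing neither ref nor alt counts as stray
    stray += sum(
        1
        for p, m in zip(marker_pos, ref.markers)
        if aln.cols[p] is not None and aln.cols[p] not in (m.ref_base, m.alt_base, "N")
    )

    if relevant:
        ki_present = ref.markers and incorporation[ref.ki_marker_index]
        indel_key = "+".join(_indel_key(d) for d in relevant)
        if ki_present:
            bits = "".join("1" if b else "0" for b in incorporation)
            return ReadCall(
                category=AlleleKind.IMPERFECT_HDR,
                allele_key=f"HDR[{bits}]+{indel_key}",
                incorporation=incorporation,
                indels=relevant,
                family_size=family_size,
            )
        return ReadCall(
            category=AlleleKind.INDEL,
            allele_key=indel_key,
            indels=relevant,
            family_size=family_size,
        )
    if any(incorporation):
        bits = "".join("1" if b else "0" for b in incorporation)
        return ReadCall(
            category=AlleleKind.HDR,
            allele_key=f"HDR[{bits}]",
            incorporation=incorporation,
            family_size=family_size,
        )
    if stray <= max_stray_mismatch:
        return ReadCall(category=AlleleKind.WT, allele_key="WT", family_size=family_size)
    return ReadCall(
        category=AlleleKind.OTHER_SUB, allele_key="OTHER_SUB", family_size=family_size
    )
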