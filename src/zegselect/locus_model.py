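"""Amplicon coordinate frame, marker geometry and editing-outcome alleles.

Everything downstream (simulation, read classification, quantification)
shares the coordinate conventions fixed here:

* positions are 0-based, intervals half-open;
* the blunt Cas9 cut falls between ``cut_index - 1`` and ``cut_index``;
* marker offsets are reported as base-pair distances from the cut, with
  distance 1 meaning the nucleotide immediately adjacent to the cut on the
  PAM-distal side (positive offsets are PAM-distal, negative PAM-proximal).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import yaml

_VALID_BASES = frozenset("ACGT")


class MarkerRole(str, Enum):
    KI = "KI"
    SYNONYMOUS = "SYNONYMOUS"


class AlleleKind(str, Enum):
    WT = "WT"
    INDEL = "INDEL"
    HDR = "HDR"
    IMPERFECT_HDR = "IMPERFECT_HDR"
    OTHER_SUB = "OTHER_SUB"


class LocusModelError(ValueError):
    """Raised when a locus description or allele is internally inconsistent."""


@dataclass(frozen=True)
class Marker:
    """A single-base template edit at a fixed distance from the cut site.

    ``offset_bp`` is the signed distance from the cut; positive values lie on
    the PAM-distal side.  The KI marker carries the intended mutation, the
    synonymous markers block re-cutting of repaired alleles and double as
    probes for the extent of the conversion tract.
    """

    offset_bp: int
    ref_base: str
    alt_base: str
    role: MarkerRole = MarkerRole.SYNONYMOUS

    def __post_init__(self) -> None:
        if self.ref_base not in _VALID_BASES or self.alt_base not in _VALID_BASES:
            raise LocusModelError(
                f"marker bases must be A/C/G/T, got {self.ref_base!r}>{self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise LocusModelError("marker ref_base equals alt_base")
        if self.offset_bp == 0:
            raise LocusModelError("marker offset_bp must be nonzero (distance 1 is adjacent)")


@dataclass(frozen=True)
class AmpliconReference:
    """An amplicon sequence with cut-site coordinate, primers and markers."""

    locus_id: str
    sequence: str
    cut_index: int
    pam_side: str  # side of the protospacer PAM relative to the cut: left|right
    primer_fwd_len: int = 0
    primer_rev_len: int = 0
    markers: tuple[Marker, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if set(self.sequence) - _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise LocusModelError(f"sequence contains non-ACGT characters: {bad}")
        if not 0 < self.cut_index < len(self.sequence):
            raise LocusModelError(
                f"cut_index {self.cut_index} outside sequence of length {len(self.sequence)}"
            )
        if self.pam_side not in ("left", "right"):
            raise LocusModelError(f"pam_side must be 'left' or 'right', got {self.pam_side!r}")
        n_ki = sum(1 for m in self.markers if m.role is MarkerRole.KI)
        if self.markers and n_ki != 1:
            raise LocusModelError(f"expected exactly one KI marker, found {n_ki}")
        lo, hi = self.callable_region
        for m in self.markers:
            pos = self.marker_position(m)
            if not lo <= pos < hi:
                raise LocusModelError(
                    f"marker at offset {m.offset_bp} maps to position {pos}, "
                    f"outside callable region [{lo}, {hi})"
                )
            if self.sequence[pos] != m.ref_base:
                raise LocusModelError(
                    f"marker at offset {m.offset_bp}: reference has "
                    f"{self.sequence[pos]!r} at position {pos}, marker says {m.ref_base!r}"
                )

    @property
    def callable_region(self) -> tuple[int, int]:
        """Half-open interval of positions eligible for variant calling."""
        return self.primer_fwd_len, len(self.sequence) - self.primer_rev_len

    def marker_position(self, marker: Marker) -> int:
        """Absolute 0-based position of a marker.

        With the cut between ``cut_index - 1`` and ``cut_index``, distance 1 on
        the left means position ``cut_index - 1`` and distance 1 on the right
        means position ``cut_index``.  Positive offsets are PAM-distal.
        """
        on_left = (self.pam_side == "right") == (marker.offset_bp > 0)
        d = abs(marker.offset_bp)
        return self.cut_index - d if on_left else self.cut_index + d - 1

    @property
    def ki_marker_index(self) -> int:
        for i, m in enumerate(self.markers):
            if m.role is MarkerRole.KI:
                return i
        raise LocusModelError(f"locus {self.locus_id} has no KI marker")

    @property
    def wt_length(self) -> int:
        return len(self.sequence)


def marker_distance(marker: Marker, ref: AmpliconReference) -> int:
    """Distance of a marker from the cut site in base pairs (always >= 1)."""
    if marker not in ref.markers:
        raise LocusModelError("marker does not belong to this locus")
    return abs(marker.offset_bp)


@dataclass(frozen=True)
class IndelDescriptor:
    """A deletion/insertion in reference coordinates, left-aligned canonical.

    ``start`` is the first deleted base (deletions) or the position before
    which ``inserted_seq`` is inserted (insertions).  Use
    :func:`canonical_indel` to construct one from arbitrary coordinates.
    """

    start: int
    deleted_len: int = 0
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.deleted_len < 0:
            raise LocusModelError("deleted_len must be >= 0")
        if self.deleted_len == 0 and not self.inserted_seq:
            raise LocusModelError("indel must delete and/or insert something")
        # N allowed: consensus reads carry N at within-family ties
        if set(self.inserted_seq) - (_VALID_BASES | {"N"}):
            raise LocusModelError("inserted_seq must be A/C/G/T/N only")

    @property
    def net_length_change(self) -> int:
        return len(self.inserted_seq) - self.deleted_len

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval the event touches (insertion: zero-width at start)."""
        return self.start, self.start + self.deleted_len


def canonical_indel(
    ref_seq: str, start: int, deleted_len: int = 0, inserted_seq: str = ""
) -> IndelDescriptor:
    """Left-align an indel through repeats, VCF style.

    A deletion of one ``A`` from ``AAAA`` is shifted to the leftmost ``A``; an
    insertion whose last base matches the preceding reference base is rotated
    and shifted left.  Two indels describing the same edited sequence thus get
    the same descriptor, which keeps allele keys unique.
    """
    start, deleted_len = int(start), int(deleted_len)
    if start < 0 or start + deleted_len > len(ref_seq):
        raise LocusModelError(f"indel at {start} (del {deleted_len}) out of range")
    ins = inserted_seq
    if deleted_len > 0 and not ins:
        while start > 0 and ref_seq[start - 1] == ref_seq[start + deleted_len - 1]:
            start -= 1
    elif deleted_len == 0 and ins:
        while start > 0 and ref_seq[start - 1] == ins[-1]:
            ins = ins[-1] + ins[:-1]
            start -= 1
    # mixed delins events are kept where they are: left-shifting is ambiguous
    return IndelDescriptor(start=start, deleted_len=deleted_len, inserted_seq=ins)


@dataclass(frozen=True)
class AlleleSpec:
    """One editing outcome: wildtype, an indel, or a marker-incorporation HDR.

    ``incorporation`` is a boolean vector aligned to the locus marker list; a
    full knock-in has the KI entry true, partial conversion tracts may carry
    only synonymous markers.  ``key`` is a deterministic text identifier used
    as the column name in count tables.
    """

    kind: AlleleKind
    indel: IndelDescriptor | None = None
    incorporation: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        k = self.kind
        if k is AlleleKind.WT and (self.indel or self.incorporation):
            raise LocusModelError("WT allele carries no descriptor")
        if k is AlleleKind.INDEL and (self.indel is None or self.incorporation):
            raise LocusModelError("INDEL allele needs an indel descriptor only")
        if k is AlleleKind.HDR and (self.incorporation is None or self.indel):
            raise LocusModelError("HDR allele needs an incorporation vector only")
        if k is AlleleKind.HDR and not any(self.incorporation):
            raise LocusModelError("HDR allele must incorporate at least one marker")
        if k is AlleleKind.IMPERFECT_HDR and (self.indel is None or self.incorporation is None):
            raise LocusModelError("IMPERFECT_HDR needs both indel and incorporation")

    @property
    def key(self) -> str:
        return allele_key(self)


def _indel_key(d: IndelDescriptor) -> str:
    if d.deleted_len and d.inserted_seq:
        return f"delins{d.deleted_len}>{d.inserted_seq}@{d.start}"
    if d.deleted_len:
        return f"del{d.deleted_len}@{d.start}"
    return f"ins{d.inserted_seq}@{d.start}"


def allele_key(allele: AlleleSpec) -> str:
    """Canonical text identifier, stable across runs and processes."""
    if allele.kind is AlleleKind.WT:
        return "WT"
    if allele.kind is AlleleKind.INDEL:
        return _indel_key(allele.indel)
    bits = "".join("1" if b else "0" for b in allele.incorporation or ())
    if allele.kind is AlleleKind.HDR:
        return f"HDR[{bits}]"
    if allele.kind is AlleleKind.IMPERFECT_HDR:
        return f"HDR[{bits}]+{_indel_key(allele.indel)}"
    return "OTHER_SUB"


WT_ALLELE = AlleleSpec(kind=AlleleKind.WT)


def build_allele_sequence(ref: AmpliconReference, allele: AlleleSpec) -> str:
    """Realize the amplicon sequence carrying exactly the allele's edits.

    Marker substitutions are applied first (HDR/IMPERFECT_HDR), then the
    indel, so imperfect repair products carry both the template bases and
    the junction error.
    """
    seq = ref.sequence
    if allele.incorporation is not None:
        if len(allele.incorporation) != len(ref.markers):
            raise LocusModelError(
                f"incorporation vector length {len(allele.incorporation)} != "
                f"{len(ref.markers)} markers"
            )
        chars = list(seq)
        for m, inc in zip(ref.markers, allele.incorporation):
            if inc:
                chars[ref.marker_position(m)] = m.alt_base
        seq = "".join(chars)
    if allele.indel is not None:
        d = allele.indel
        if d.start + d.deleted_len > len(seq) or d.start < 0:
            raise LocusModelError(
                f"indel at position {d.start} (del {d.deleted_len}) does not fit "
                f"amplicon of length {len(seq)}"
            )
        seq = seq[: d.start] + d.inserted_seq + seq[d.start + d.deleted_len :]
    return seq


@dataclass
class EmbryoProfile:
    """Per-embryo mixture of editing outcomes (a mosaic F0 genotype).

    ``frequencies`` maps allele keys to cell fractions; they must be
    non-negative and sum to 1.
    """

    embryo_id: str
    frequencies: dict[str, float]

    def validate(self) -> list[str]:
        return validate_profile(self)


def validate_profile(
    profile: EmbryoProfile, known_keys: Sequence[str] | None = None, tol: float = 1e-9
) -> list[str]:
    """Report invariant violations; an empty list means the profile is valid."""
    problems: list[str] = []
    for key, f in profile.frequencies.items():
        if f < 0:
            problems.append(f"negative fraction {f} for allele {key!r}")
        elif f > 1:
            problems.append(f"fraction {f} > 1 for allele {key!r}")
        if known_keys is not None and key not in known_keys:
            problems.append(f"unknown allele key {key!r}")
    total = sum(profile.frequencies.values())
    if abs(total - 1.0) > tol:
        problems.append(f"frequencies sum to {total!r}, not 1")
    return problems


# ---------------------------------------------------------------------------
# locus configuration files


def _locus_from_mapping(doc: Mapping) -> AmpliconReference:
    markers = tuple(
        Marker(
            offset_bp=int(m["offset_bp"]),
            ref_base=str(m["ref_base"]),
            alt_base=str(m["alt_base"]),
            role=MarkerRole(m.get("role", "SYNONYMOUS")),
        )
        for m in doc.get("markers", [])
    )
    return AmpliconReference(
        locus_id=str(doc["locus_id"]),
        sequence=str(doc["sequence"]).upper(),
        cut_index=int(doc["cut_index"]),
        pam_side=str(doc["pam_side"]),
        primer_fwd_len=int(doc.get("primer_fwd_len", 0)),
        primer_rev_len=int(doc.get("primer_rev_len", 0)),
        markers=markers,
    )


_PACKAGED = {"toyLQTS": "toy_lqts.yaml", "toyBrS": "toy_brs.yaml"}


def load_locus(source: str | Path) -> AmpliconReference:
    """Load a locus config from YAML; ``"toyLQTS"``/``"toyBrS"`` name packaged fixtures.

    The packaged toy loci are synthetic 220-bp sequences mirroring the marker
    geometry of the two cacna1c sites studied with this workflow: toyLQTS has
    synonymous markers at 1/3/6 bp and the KI at 5 bp from the cut, toyBrS has
    synonymous markers at 1/12 bp and the KI at 8 bp.
    """
    if isinstance(source, str) and source in _PACKAGED:
        res = importlib.resources.files("zegselect.data") / _PACKAGED[source]
        doc = yaml.safe_load(res.read_text())
    else:
        doc = yaml.safe_load(Path(source).read_text())
    return _locus_from_mapping(doc)
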