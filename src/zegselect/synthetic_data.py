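"""Synthetic mosaic embryos and UMI-tagged amplicon reads with full truth.

The generator emulates the experiment end to end: each injected embryo is a
mosaic mixture of editing outcomes (Dirichlet over an allele spectrum, WT as
the remainder); a minimally invasive ZEG sample draws ~21 surface cells and a
whole-embryo (WE) lysate draws a few thousand; each sampled template molecule
founds a UMI family whose size follows a geometric PCR-duplication model; and
reads carry an inline sample barcode + UMI prefix plus independent per-base
substitution errors.  Every stage records its truth so the pipeline can be
validated without any external sequencing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_model import (
    AlleleKind,
    AlleleSpec,
    AmpliconReference,
    EmbryoProfile,
    IndelDescriptor,
    WT_ALLELE,
    build_allele_sequence,
    canonical_indel,
    marker_distance,
)
from .readproc import ReadRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# substream labels hashed into the root SeedSequence; order is part of the API
_STREAM_PROFILE = 1
_STREAM_CELLS = 2
_STREAM_READS = 3
_STREAM_BARCODES = 4


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition knobs for the synthetic experiment.

    Defaults follow the experimental setup this pipeline is built for: ~21
    cells shed by the embryo genotyper versus a whole-embryo lysate, 2x150 bp
    paired-end reads over a ~220 bp amplicon, an 8 bp UMI and 8 bp sample
    barcode, and editing levels typical of Cas9-protein injections (around
    half of cells carrying indels, a few percent carrying HDR events).
    """

    n_embryos: int = 24
    mean_indel_fraction: float = 0.5
    mean_ki_fraction: float = 0.03
    dirichlet_concentration: float = 4.0
    zeg_cells: int = 21
    we_cells: int = 2000
    read_depth: int = 1000
    read_len: int = 150
    umi_length: int = 8
    barcode_length: int = 8
    pcr_duplication: float = 3.0
    seq_error_rate: float = 0.001
    tract_p_max: float = 0.95
    tract_decay_bp: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_indel_fraction", "mean_ki_fraction", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_indel_fraction + self.mean_ki_fraction > 1.0:
            raise ValueError("mean edited fraction exceeds 1")
        if self.zeg_cells < 1 or self.we_cells < 1:
            raise ValueError("cell counts must be >= 1")
        if self.umi_length < 4 or self.barcode_length < 4:
            raise ValueError("umi/barcode lengths must be >= 4")
        if self.pcr_duplication < 1.0:
            raise ValueError("pcr_duplication is a mean family size, must be >= 1")


def _rng(params: SimulationParams, stream: int, *index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((params.seed, stream, *index)))


# ---------------------------------------------------------------------------
# allele spectrum


@dataclass(frozen=True)
class AlleleSpectrum:
    """Editing outcomes available to a locus plus their concentration weights."""

    alleles: tuple[AlleleSpec, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.weights):
            raise ValueError("alleles and weights differ in length")
        keys = [a.key for a in self.alleles]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate allele keys in spectrum")

    @property
    def by_key(self) -> dict[str, AlleleSpec]:
        return {a.key: a for a in self.alleles}


# relative within-class weights for the ten default indel alleles: a few
# abundant events and a long tail, so average SEFs span the <1%, 1-5% and
# >5% frequency classes used for reporting
_INDEL_WEIGHTS = (0.30, 0.20, 0.13, 0.10, 0.08, 0.06, 0.05, 0.04, 0.025, 0.015)


def default_indel_alleles(ref: AmpliconReference) -> tuple[AlleleSpec, ...]:
    """Ten distinct NHEJ outcomes at the cut: deletions of 1-10 bp and small insertions."""
    cut = ref.cut_index
    specs: list[AlleleSpec] = []
    for L in (1, 2, 3, 4, 5, 7, 10):
        d = canonical_indel(ref.sequence, cut - (L + 1) // 2, deleted_len=L)
        specs.append(AlleleSpec(kind=AlleleKind.INDEL, indel=d))
    for ins in ("A", "AT", "GAT"):
        d = canonical_indel(ref.sequence, cut, inserted_seq=ins)
        specs.append(AlleleSpec(kind=AlleleKind.INDEL, indel=d))
    keys = [a.key for a in specs]
    if len(set(keys)) != len(keys):  # pragma: no cover - guards odd references
        raise ValueError(f"default indel set not unique on {ref.locus_id}: {keys}")
    return tuple(specs)


def hdr_pattern_weights(
    ref: AmpliconReference, p_max: float, decay_bp: float
) -> dict[tuple[bool, ...], float]:
    """Relative weights of marker-incorporation patterns under the tract model.

    Each marker is incorporated independently with probability
    ``p_max * exp(-distance / decay_bp)`` — a proxy for conversion tracts that
    reach distant template edits less often.  Patterns incorporating nothing
    are indistinguishable from WT and are excluded; the remaining weights are
    renormalized.
    """
    probs = [
        p_max * math.exp(-marker_distance(m, ref) / decay_bp) for m in ref.markers
    ]
    patterns: dict[tuple[bool, ...], float] = {}
    k = len(ref.markers)
    for code in range(1, 2**k):
        bits = tuple(bool(code >> i & 1) for i in range(k))
        w = 1.0
        for p, b in zip(probs, bits):
            w *= p if b else 1.0 - p
        patterns[bits] = w
    total = sum(patterns.values())
    return {bits: w / total for bits, w in patterns.items()}


def random_allele(
    ref: AmpliconReference,
    rng: np.random.Generator,
    window: int = 20,
    max_indel: int = 10,
) -> AlleleSpec:
    """Draw a random editing outcome for classifier round-trip checks.

    Kinds are WT / INDEL / HDR / IMPERFECT_HDR; indels are placed near the
    cut so their left-aligned canonical form still overlaps the calling
    window, and HDR patterns are uniform over non-empty incorporation
    vectors.
    """
    kinds = ["WT", "INDEL", "HDR", "IMPERFECT_HDR"] if ref.markers else ["WT", "INDEL"]
    kind = kinds[rng.integers(len(kinds))]
    if kind == "WT":
        return WT_ALLELE

    def _draw_indel() -> IndelDescriptor:
        cut = ref.cut_index
        for _ in range(100):
            if rng.random() < 0.6:
                L = int(rng.integers(1, max_indel + 1))
                start = int(rng.integers(cut - window // 2, cut + window // 2 - L + 1))
                d = canonical_indel(ref.sequence, start, deleted_len=L)
            else:
                L = int(rng.integers(1, max_indel + 1))
                ins = _random_bases(rng, L)
                start = int(rng.integers(cut - window // 2, cut + window // 2 + 1))
                d = canonical_indel(ref.sequence, start, inserted_seq=ins)
            a, b = d.ref_span
            if a < ref.cut_index + window and b > ref.cut_index - window:
                return d
        raise RuntimeError("failed to draw an indel inside the window")

    if kind == "INDEL":
        return AlleleSpec(kind=AlleleKind.INDEL, indel=_draw_indel())
    k = len(ref.markers)
    code = int(rng.integers(1, 2**k))
    bits = tuple(bool(code >> i & 1) for i in range(k))
    if kind == "HDR":
        return AlleleSpec(kind=AlleleKind.HDR, incorporation=bits)
    ki = ref.ki_marker_index
    bits = tuple(True if i == ki else b for i, b in enumerate(bits))
    # keep the indel well clear of substituted markers: a gap adjacent to a
    # mismatch can legitimately be realigned to absorb it, making the
    # (indel, substitution) decomposition ambiguous
    marker_pos = [ref.marker_position(m) for m in ref.markers]
    for _ in range(200):
        d = _draw_indel()
        a, b = d.ref_span
        margin = d.deleted_len + len(d.inserted_seq) + 4
        if all(p < a - margin or p >= b + margin for p in marker_pos):
            return AlleleSpec(kind=AlleleKind.IMPERFECT_HDR, indel=d, incorporation=bits)
    raise RuntimeError("failed to draw an indel avoiding marker positions")


def default_spectrum(ref: AmpliconReference, params: SimulationParams) -> AlleleSpectrum:
    """WT + ten indels + all marker-incorporation patterns, weighted so the
    Dirichlet mean matches the configured class fractions."""
    alleles: list[AlleleSpec] = [WT_ALLELE]
    weights: list[float] = [1.0 - params.mean_indel_fraction - params.mean_ki_fraction]
    indels = default_indel_alleles(ref)
    for indel_spec, w in zip(indels, _INDEL_WEIGHTS):
        alleles.append(indel_spec)
        weights.append(params.mean_indel_fraction * w)
    if ref.markers:
        for bits, w in sorted(hdr_pattern_weights(ref, params.tract_p_max, params.tract_decay_bp).items()):
            alleles.append(AlleleSpec(kind=AlleleKind.HDR, incorporation=bits))
            weights.append(params.mean_ki_fraction * w)
    return AlleleSpectrum(alleles=tuple(alleles), weights=tuple(weights))


# ---------------------------------------------------------------------------
# embryos and cells


def simulate_embryo_profile(
    params: SimulationParams,
    embryo_index: int,
    spectrum: AlleleSpectrum,
) -> EmbryoProfile:
    """Draw one mosaic embryo: Dirichlet allele fractions over the spectrum.

    The Dirichlet concentration is ``dirichlet_concentration * weight``, so
    the across-embryo mean of each allele equals its spectrum weight while
    individual embryos are strongly mosaic.  Deterministic given
    ``(params.seed, embryo_index)``.
    """
    if not spectrum.alleles:
        raise ValueError("empty allele spectrum")
    rng = _rng(params, _STREAM_PROFILE, embryo_index)
    keys = [a.key for a in spectrum.alleles]
    w = np.asarray(spectrum.weights, dtype=float)
    if w.min() < 0:
        raise ValueError("negative spectrum weight")
    freqs = np.zeros(len(w))
    live = w > 0
    if live.sum() == 1:
        freqs[live] = 1.0
    else:
        freqs[live] = rng.dirichlet(params.dirichlet_concentration * w[live])
    return EmbryoProfile(
        embryo_id=f"emb{embryo_index:03d}",
        frequencies={k: float(f) for k, f in zip(keys, freqs)},
    )


def sample_cells(
    profile: EmbryoProfile, n_cells: int, rng: np.random.Generator | int
) -> dict[str, int]:
    """Multinomial draw of ``n_cells`` cells from the embryo's allele mixture."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    problems = profile.validate()
    if problems:
        raise ValueError(f"invalid profile {profile.embryo_id}: {problems}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    keys = sorted(profile.frequencies)
    p = np.asarray([profile.frequencies[k] for k in keys], dtype=float)
    counts = rng.multinomial(n_cells, p / p.sum())
    return {k: int(c) for k, c in zip(keys, counts) if c > 0}


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class FamilyTruth:
    """Generating allele and size of one UMI family."""

    sample_id: str
    umi: str
    allele_key: str
    family_size: int


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_reads(
    cell_counts: Mapping[str, int],
    ref: AmpliconReference,
    params: SimulationParams,
    sample_id: str,
    barcode: str,
    spectrum: AlleleSpectrum,
    rng: np.random.Generator,
) -> tuple[list[ReadRecord], list[FamilyTruth]]:
    """Emit UMI families of paired reads for one sample.

    Each family picks a template allele proportional to the cell counts, a
    fresh UMI and a geometric family size; every read carries the
    barcode+UMI prefix on mate 1, the two mates covering the amplicon from
    either end, with independent per-base substitution errors.
    """
    if params.read_depth <= 0:
        return [], []
    if not cell_counts:
        raise ValueError("empty cell counts")
    keys = sorted(cell_counts)
    counts = np.asarray([cell_counts[k] for k in keys], dtype=float)
    p = counts / counts.sum()
    by_key = spectrum.by_key
    amplicons = {k: build_allele_sequence(ref, by_key[k]) for k in keys}

    n_families = max(1, int(round(params.read_depth / params.pcr_duplication)))
    family_alleles = rng.choice(len(keys), size=n_families, p=p)
    family_sizes = rng.geometric(1.0 / params.pcr_duplication, size=n_families)

    seen_umis: set[str] = set()
    reads: list[ReadRecord] = []
    truth: list[FamilyTruth] = []
    insert_len = params.read_len - params.barcode_length - params.umi_length
    for j in range(n_families):
        umi = _random_bases(rng, params.umi_length)
        while umi in seen_umis:
            umi = _random_bases(rng, params.umi_length)
        seen_umis.add(umi)
        key = keys[family_alleles[j]]
        amp = amplicons[key]
        truth.append(FamilyTruth(sample_id, umi, key, int(family_sizes[j])))
        r1_clean = barcode + umi + amp[:insert_len]
        r2_clean = revcomp(amp)[: params.read_len]
        for r in range(int(family_sizes[j])):
            s1 = _mutate(r1_clean, rng, params.seq_error_rate)
            s2 = _mutate(r2_clean, rng, params.seq_error_rate)
            reads.append(
                ReadRecord(
                    id=f"{sample_id}:fam{j:05d}:r{r}",
                    seq1=s1,
                    qual1="I" * len(s1),
                    seq2=s2,
                    qual2="I" * len(s2),
                )
            )
    return reads, truth


# ---------------------------------------------------------------------------
# fragment-analysis peaks


@dataclass
class PeakTable:
    """Capillary-electrophoresis peak intensities by fragment length (bp)."""

    intensities: dict[int, float]
    wt_length: int

    def __post_init__(self) -> None:
        if not self.intensities:
            raise ValueError("peak table must contain at least one peak")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("peak intensities must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.intensities.values()))


def simulate_fragment_peaks(
    profile: EmbryoProfile,
    ref: AmpliconReference,
    spectrum: AlleleSpectrum,
    resolution_sigma: float = 0.0,
) -> PeakTable:
    """Fragment-length peaks for an embryo, with finite sizing resolution.

    One peak per allele at its amplicon length, intensity proportional to
    frequency.  Finite resolution is modeled through peak merging: two
    Gaussian peaks of width ``resolution_sigma`` separated by ``d`` base
    pairs overlap by ``erfc(d / (2 sigma sqrt 2))`` (their Gaussian overlap
    coefficient), and that unresolvable share of a non-wildtype peak is
    credited to the wildtype bin.  The merged fraction grows monotonically
    with sigma and shrinks with distance — which is exactly why 1-2 bp
    indels are hard to see on a capillary trace while a 10 bp deletion is
    obvious.  ``resolution_sigma = 0`` gives perfectly resolved peaks.
    """
    if resolution_sigma < 0:
        raise ValueError("resolution_sigma must be >= 0")
    by_key = spectrum.by_key
    wt_len = ref.wt_length
    intensities: dict[int, float] = {}
    for key, f in profile.frequencies.items():
        if f <= 0:
            continue
        L = len(build_allele_sequence(ref, by_key[key]))
        d = abs(L - wt_len)
        if d == 0 or resolution_sigma == 0:
            merged = 1.0 if d == 0 else 0.0
        else:
            merged = math.erfc(d / (2.0 * resolution_sigma * math.sqrt(2.0)))
        intensities[wt_len] = intensities.get(wt_len, 0.0) + f * merged
        if d > 0 and merged < 1.0:
            intensities[L] = intensities.get(L, 0.0) + f * (1.0 - merged)
    if not intensities:
        intensities = {wt_len: 0.0}
    return PeakTable(intensities=intensities, wt_length=wt_len)


# ---------------------------------------------------------------------------
# whole experiment


@dataclass
class SampleRecord:
    sample_id: str
    embryo_id: str
    kind: str  # ZEG | WE
    barcode: str
    cell_counts: dict[str, int]
    reads: list[ReadRecord] = field(default_factory=list)
    families: list[FamilyTruth] = field(default_factory=list)


@dataclass
class SimulatedExperiment:
    params: SimulationParams
    locus: AmpliconReference
    spectrum: AlleleSpectrum
    profiles: list[EmbryoProfile]
    samples: list[SampleRecord]

    @property
    def barcode_map(self) -> dict[str, str]:
        return {s.sample_id: s.barcode for s in self.samples}

    @property
    def all_reads(self) -> list[ReadRecord]:
        return [r for s in self.samples for r in s.reads]

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "embryo_id": s.embryo_id,
                    "kind": s.kind,
                    "barcode": s.barcode,
                    "n_cells": sum(s.cell_counts.values()),
                }
                for s in self.samples
            ]
        )


def _make_barcodes(
    rng: np.random.Generator, n: int, length: int, min_dist: int = 3
) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_dist (greedy)."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = _random_bases(rng, length)
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("barcode generation failed; increase barcode length")
        if all(sum(a != b for a, b in zip(cand, kept)) >= min_dist for kept in out):
            out.append(cand)
    return out


def simulate_experiment(
    params: SimulationParams,
    locus: AmpliconReference,
    spectrum: AlleleSpectrum | None = None,
    kinds: Sequence[str] = ("ZEG", "WE"),
) -> SimulatedExperiment:
    """Simulate the paired design: every embryo gets one ZEG and one WE sample
    drawn from the same mosaic profile."""
    if spectrum is None:
        spectrum = default_spectrum(locus, params)
    barcode_rng = _rng(params, _STREAM_BARCODES)
    barcodes = _make_barcodes(
        barcode_rng, params.n_embryos * len(kinds), params.barcode_length
    )
    profiles: list[EmbryoProfile] = []
    samples: list[SampleRecord] = []
    b = 0
    for i in range(params.n_embryos):
        profile = simulate_embryo_profile(params, i, spectrum)
        profiles.append(profile)
        for kind in kinds:
            n_cells = params.zeg_cells if kind == "ZEG" else params.we_cells
            cells_rng = _rng(params, _STREAM_CELLS, i, kinds.index(kind))
            cells = sample_cells(profile, n_cells, cells_rng)
            sample_id = f"{profile.embryo_id}_{kind}"
            reads_rng = _rng(params, _STREAM_READS, i, kinds.index(kind))
            reads, families = generate_reads(
                cells, locus, params, sample_id, barcodes[b], spectrum, reads_rng
            )
            samples.append(
                SampleRecord(
                    sample_id=sample_id,
                    embryo_id=profile.embryo_id,
                    kind=kind,
                    barcode=barcodes[b],
                    cell_counts=cells,
                    reads=reads,
                    families=families,
                )
            )
            b += 1
    return SimulatedExperiment(
        params=params, locus=locus, spectrum=spectrum, profiles=profiles, samples=samples
    )


# ---------------------------------------------------------------------------
# truth tables and FASTQ output


def truth_tables(exp: SimulatedExperiment) -> dict[str, pd.DataFrame]:
    """Tidy truth tables keyed by stage: profiles, cells, families."""
    prof = pd.DataFrame(
        [
            {"embryo_id": p.embryo_id, "allele_key": k, "frequency": f}
            for p in exp.profiles
            for k, f in sorted(p.frequencies.items())
        ]
    )
    cells = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "embryo_id": s.embryo_id,
                "kind": s.kind,
                "allele_key": k,
                "n_cells": c,
            }
            for s in exp.samples
            for k, c in sorted(s.cell_counts.items())
        ]
    )
    fams = pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "umi": f.umi,
                "allele_key": f.allele_key,
                "family_size": f.family_size,
            }
            for s in exp.samples
            for f in s.families
        ]
    )
    return {"profiles": prof, "cells": cells, "families": fams}


def write_truth(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write truth tables and the sample sheet as TSV; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tables = truth_tables(exp)
    tables["sample_sheet"] = exp.sample_sheet()
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        try:
            df.to_csv(path, sep="\t", index=False)
        except OSError as err:  # pragma: no cover
            raise OSError(f"failed writing truth table {path}: {err}") from err
        paths[name] = path
    return paths


def write_fastq(
    reads: Iterable[ReadRecord], path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write mate files as plain 4-line FASTQ."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.id}/1\n{r.seq1}\n+\n{r.qual1}\n")
            f2.write(f"@{r.id}/2\n{r.seq2}\n+\n{r.qual2}\n")


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> list[ReadRecord]:
    """Load paired 4-line FASTQ files back into read records."""
    from Bio import SeqIO

    records = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(path_r1), "fastq"), SeqIO.parse(str(path_r2), "fastq")
    ):
        records.append(
            ReadRecord(
                id=rec1.id.rsplit("/", 1)[0],
                seq1=str(rec1.seq),
                qual1="".join(
                    chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
                ),
                seq2=str(rec2.seq),
                qual2="".join(
                    chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
                ),
            )
        )
    return records
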