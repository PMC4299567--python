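"""Depth-based copy-number profiling against a dual (host + endosymbiont) reference.

The central quantity is the *copy number* of a genomic window: its mean
sequencing depth divided by the modal depth of the single-copy host genome.
A nuclear insertion of endosymbiont DNA (a nuwt) present in ``c`` copies per
haploid genome shows up as windows with copy number ``c`` on the endosymbiont
reference.  The module covers the whole chain from mapped reads to windowed
profiles: SAM input/output, coordinate-key duplicate removal, per-base depth
pileup, modal-depth estimation, windowed normalization, cross-mapping audits
between homologous references, read-fraction statistics and the
back-of-the-envelope insertion-size estimate they support.

Coordinates are 0-based half-open throughout; SAM's 1-based positions are
converted at the parser boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "AlignmentRecord",
    "AlignmentSet",
    "DepthTrack",
    "CopyNumberProfile",
    "MappingStats",
    "read_alignments",
    "write_sam",
    "mark_duplicates",
    "depth_track",
    "modal_depth",
    "windowed_modal_depth",
    "copy_number_profile",
    "cross_mapping_audit",
    "read_fraction_stats",
    "estimate_lgt_size",
    "profile_ratio",
]

_MULTI_TAG = "XR"  # custom tag: read also maps to a homologous reference


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read: where it landed and how it is keyed for duplicate removal."""

    reference: str
    start: int
    length: int
    strand: str
    read_id: str
    is_duplicate: bool = False
    mate_reference: str | None = None
    mate_start: int | None = None
    is_multi: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for read {self.read_id!r}")
        if self.length <= 0:
            raise ValueError(f"non-positive length {self.length} for read {self.read_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def key(self) -> tuple:
        """Coordinate key used for duplicate detection (Picard-style)."""
        return (self.reference, self.start, self.strand, self.mate_reference, self.mate_start)


@dataclass
class AlignmentSet:
    """Mapped reads against one or more named references of known length."""

    references: dict[str, int]
    records: list[AlignmentRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AlignmentRecord]:
        return iter(self.records)

    def for_reference(self, name: str) -> list[AlignmentRecord]:
        return [r for r in self.records if r.reference == name]

    def read_ids(self) -> set[str]:
        return {r.read_id for r in self.records}

    def validate(self) -> None:
        for rec in self.records:
            ref_len = self.references.get(rec.reference)
            if ref_len is None:
                raise ValueError(f"read {rec.read_id!r} on unknown reference {rec.reference!r}")
            if rec.end > ref_len:
                raise ValueError(
                    f"read {rec.read_id!r} spans [{rec.start},{rec.end}) beyond "
                    f"reference {rec.reference!r} of length {ref_len}"
                )


def read_alignments(path: str) -> AlignmentSet:
    """Parse a SAM file into an :class:`AlignmentSet`.

    Unmapped records are skipped.  Records are validated against the ``@SQ``
    header lengths; the 0x400 flag is carried through as ``is_duplicate`` and
    the ``XR`` tag as the multi-reference flag.
    """
    with pysam.AlignmentFile(path, "r", check_sq=True) as sam:
        references = {name: length for name, length in zip(sam.references, sam.lengths)}
        records: list[AlignmentRecord] = []
        for i, aln in enumerate(sam.fetch(until_eof=True), start=1):
            if aln.is_unmapped:
                continue
            length = aln.query_alignment_length or (aln.reference_end or 0) - aln.reference_start
            if length <= 0:
                raise ValueError(f"record {i} ({aln.query_name!r}): no aligned length")
            ref = aln.reference_name
            if aln.reference_start + length > references[ref]:
                raise ValueError(
                    f"record {i} ({aln.query_name!r}) extends beyond reference "
                    f"{ref!r} of length {references[ref]}"
                )
            mate_ref = None
            mate_start = None
            if aln.is_paired and aln.next_reference_id >= 0:
                mate_ref = sam.get_reference_name(aln.next_reference_id)
                mate_start = aln.next_reference_start
            records.append(
                AlignmentRecord(
                    reference=ref,
                    start=aln.reference_start,
                    length=length,
                    strand="-" if aln.is_reverse else "+",
                    read_id=aln.query_name,
                    is_duplicate=aln.is_duplicate,
                    mate_reference=mate_ref,
                    mate_start=mate_start,
                    is_multi=bool(aln.has_tag(_MULTI_TAG) and aln.get_tag(_MULTI_TAG)),
                )
            )
    return AlignmentSet(references, records)


def write_sam(aset: AlignmentSet, path: str, *, comments: Sequence[str] = ()) -> None:
    """Write an :class:`AlignmentSet` as a minimal SAM file.

    Emits an ``@SQ`` header per reference and the 11 mandatory columns per
    record; duplicate records carry the 0x400 flag, multi-reference records
    the ``XR:i:1`` tag.
    """
    names = list(aset.references)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": aset.references[n]} for n in names],
    }
    if comments:
        header["CO"] = list(comments)
    index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in aset.records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if rec.is_duplicate:
                flag |= 0x400
            if rec.mate_start is not None:
                flag |= 0x1
            a.flag = flag
            a.reference_id = index[rec.reference]
            a.reference_start = rec.start
            a.mapping_quality = 60
            a.cigartuples = [(0, rec.length)]
            if rec.mate_start is not None and rec.mate_reference is not None:
                a.next_reference_id = index[rec.mate_reference]
                a.next_reference_start = rec.mate_start
            if rec.is_multi:
                a.set_tag(_MULTI_TAG, 1, "i")
            out.write(a)


def mark_duplicates(aset: AlignmentSet) -> AlignmentSet:
    """Remove coordinate duplicates, keeping one record per coordinate key.

    Among records sharing ``(reference, start, strand, mate_reference,
    mate_start)`` exactly one is retained (the lexicographically smallest
    ``read_id``, which makes the operation order-insensitive and idempotent).
    Output is position-sorted.
    """
    best: dict[tuple, AlignmentRecord] = {}
    for rec in aset.records:
        cur = best.get(rec.key)
        if cur is None or rec.read_id < cur.read_id:
            best[rec.key] = rec
    records = sorted(best.values(), key=lambda r: (r.reference, r.start, r.read_id))
    return AlignmentSet(dict(aset.references), records)


@dataclass
class DepthTrack:
    """Per-base read depth over one reference."""

    reference: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")

    def __len__(self) -> int:
        return int(self.depth.size)


def depth_track(
    records: AlignmentSet | Iterable[AlignmentRecord],
    reference: str,
    ref_length: int | None = None,
) -> DepthTrack:
    """Pile up per-base depth for retained (non-duplicate) records on ``reference``.

    ``depth[i]`` counts records whose half-open span covers position ``i``, so
    the conservation identity ``depth.sum() == sum of aligned lengths`` holds.
    """
    if isinstance(records, AlignmentSet):
        if ref_length is None:
            ref_length = records.references.get(reference)
        recs: Iterable[AlignmentRecord] = records.records
    else:
        recs = records
    if ref_length is None or ref_length <= 0:
        raise ValueError(f"unknown or non-positive length for reference {reference!r}")
    diff = np.zeros(ref_length + 1, dtype=np.int64)
    for rec in recs:
        if rec.reference != reference or rec.is_duplicate:
            continue
        if rec.start < 0 or rec.end > ref_length:
            raise ValueError(
                f"read {rec.read_id!r} at [{rec.start},{rec.end}) outside [0,{ref_length})"
            )
        diff[rec.start] += 1
        diff[rec.end] -= 1
    return DepthTrack(reference, np.cumsum(diff[:-1]))


def modal_depth(track: DepthTrack) -> int:
    """Most frequent per-base depth among covered positions (histogram bin 1).

    Zero-depth positions are excluded so assembly gaps cannot dominate the
    histogram; exact ties break toward the larger depth, which yields the more
    conservative (lower) copy-number calls downstream.
    """
    covered = track.depth[track.depth > 0]
    if covered.size == 0:
        raise ValueError(f"track {track.reference!r} has no covered positions")
    counts = np.bincount(covered)
    top = counts.max()
    return int(np.flatnonzero(counts == top).max())


def _window_bounds(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Window starts at 0, step, 2*step, ...; a terminal partial window is kept
    only when its span exceeds half the window."""
    if window < step or step <= 0:
        raise ValueError(f"need window >= step > 0, got window={window}, step={step}")
    bounds = []
    for s in range(0, length, step):
        e = min(s + window, length)
        if 2 * (e - s) <= window and (e - s) < window:
            continue
        bounds.append((s, e))
    return bounds


def _window_means(track: DepthTrack, window: int, step: int) -> pd.DataFrame:
    bounds = _window_bounds(len(track), window, step)
    csum = np.concatenate([[0], np.cumsum(track.depth)])
    rows = [(s, e, (csum[e] - csum[s]) / (e - s)) for s, e in bounds]
    return pd.DataFrame(rows, columns=["start", "end", "mean_depth"])


def windowed_modal_depth(track: DepthTrack, window: int = 1000, step: int = 500) -> int:
    """Modal depth estimated from windowed mean depths, binned at width 1.

    The per-base mode is ambiguous when the single-copy depth sits at an
    integer Poisson rate lambda, because Poisson(lambda) puts exactly equal
    mass on lambda-1 and lambda; window means concentrate tightly around the
    true single-copy depth and give a stable mode.  This is the normalizer the
    pipeline uses on the host track.
    """
    means = _window_means(track, window, step)["mean_depth"].to_numpy()
    vals = np.rint(means).astype(int)
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError(f"track {track.reference!r} has no covered windows")
    counts = np.bincount(vals)
    top = counts.max()
    return int(np.flatnonzero(counts == top).max())


@dataclass
class CopyNumberProfile:
    """Windowed mean depth and copy number (mean depth / modal depth)."""

    reference: str
    window: int
    step: int
    modal_depth: int
    rows: pd.DataFrame  # columns: start, end, mean_depth, copy_number

    def copy_at(self, position: int) -> float:
        """Mean copy number over the windows covering ``position``."""
        mask = (self.rows["start"] <= position) & (position < self.rows["end"])
        if not mask.any():
            raise ValueError(f"position {position} not covered by any window")
        return float(self.rows.loc[mask, "copy_number"].mean())

    def to_tsv(self, path: str, *, comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in comments:
                fh.write(f"# {line}\n")
            fh.write(
                f"# reference={self.reference} window={self.window} "
                f"step={self.step} modal_depth={self.modal_depth}\n"
            )
            self.rows.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def to_bedgraph(self, path: str, *, comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in comments:
                fh.write(f"# {line}\n")
            for row in self.rows.itertuples(index=False):
                fh.write(f"{self.reference}\t{row.start}\t{row.end}\t{row.copy_number:.6g}\n")


def copy_number_profile(
    track: DepthTrack, modal: int, window: int = 1000, step: int = 500
) -> CopyNumberProfile:
    """Windowed copy-number profile: mean depth over each window divided by ``modal``.

    Defaults follow the standard 1 kbp window every 500 bp.
    """
    if modal <= 0:
        raise ValueError(f"modal depth must be positive, got {modal}")
    rows = _window_means(track, window, step)
    rows["copy_number"] = rows["mean_depth"] / modal
    return CopyNumberProfile(track.reference, window, step, int(modal), rows)


def cross_mapping_audit(
    endo_set: AlignmentSet, other_set: AlignmentSet
) -> tuple[int, list[str]]:
    """Reads mapping to both references, by read id.

    Used to audit the mitochondria/endosymbiont shared-ancestry concern: a
    handful of cross-mapped reads is expected and harmless, a large number
    would compromise the depth-based copy calls.
    """
    shared = sorted(endo_set.read_ids() & other_set.read_ids())
    return len(shared), shared


@dataclass(frozen=True)
class MappingStats:
    """Read-fraction summary in the shape of a sequencing-run statistics table."""

    total_reads: int
    host_mapped: int
    endo_mapped: int
    host_pct: float
    endo_pct: float
    endo_to_host_ratio_pct: float

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "host_mapped": self.host_mapped,
            "endo_mapped": self.endo_mapped,
            "host_pct": self.host_pct,
            "endo_pct": self.endo_pct,
            "endo_to_host_ratio_pct": self.endo_to_host_ratio_pct,
        }


def read_fraction_stats(total: int, host_mapped: int, endo_mapped: int) -> MappingStats:
    """Mapped percentages and the endosymbiont:host read ratio.

    All values are kept at full precision; rounding to a table's printed
    precision belongs at presentation time.
    """
    if min(total, host_mapped, endo_mapped) < 0:
        raise ValueError("read counts must be non-negative")
    if host_mapped + endo_mapped > total:
        raise ValueError("mapped read counts exceed total reads")
    if total == 0:
        raise ValueError("total read count must be positive")
    if endo_mapped == 0:
        ratio = 0.0
    elif host_mapped == 0:
        raise ValueError("endosymbiont:host ratio undefined with zero host-mapped reads")
    else:
        ratio = 100.0 * endo_mapped / host_mapped
    return MappingStats(
        total_reads=total,
        host_mapped=host_mapped,
        endo_mapped=endo_mapped,
        host_pct=100.0 * host_mapped / total,
        endo_pct=100.0 * endo_mapped / total,
        endo_to_host_ratio_pct=ratio,
    )


def estimate_lgt_size(ratio_pct: float, genome_size_mbp: float) -> float:
    """Insertion span implied by the read ratio: (ratio%/100) x genome size, in Mbp.

    A tandem nuwt array making up r% of the sequenced reads occupies roughly
    r% of the genome, e.g. a 2.3% ratio on a 215 Mbp genome implies ~5 Mbp.
    """
    if ratio_pct < 0:
        raise ValueError("ratio must be non-negative")
    if genome_size_mbp <= 0:
        raise ValueError("genome size must be positive")
    return ratio_pct / 100.0 * genome_size_mbp


def profile_ratio(a: CopyNumberProfile, b: CopyNumberProfile) -> pd.DataFrame:
    """Row-wise copy-number ratio a/b on an identical window grid.

    Comparing two lines' profiles over the same endosymbiont reference exposes
    shared versus line-specific duplication structure.  Windows where ``b`` has
    copy 0 yield a missing value rather than infinity.
    """
    same_grid = (
        a.reference == b.reference
        and a.window == b.window
        and a.step == b.step
        and len(a.rows) == len(b.rows)
        and (a.rows["start"].to_numpy() == b.rows["start"].to_numpy()).all()
    )
    if not same_grid:
        raise ValueError("profiles are not on the same reference/window/step grid")
    num = a.rows["copy_number"].to_numpy(dtype=float)
    den = b.rows["copy_number"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return pd.DataFrame(
        {"start": a.rows["start"], "end": a.rows["end"], "ratio": ratio}
    )
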