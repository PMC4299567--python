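"""Synthetic genomes, alignments and qPCR tables with the statistical
structure the downstream analysis assumes.

The generator emulates re-sequencing of a fly line whose nuclear genome
carries a tandem array of endosymbiont (Wolbachia-like) segments:

* a host reference, an endosymbiont reference, and optionally a small
  mitochondrial reference sharing a verbatim homology block with the
  endosymbiont (the shared-ancestry cross-mapping decoy);
* a nuwt architecture assigning each endosymbiont segment an integer copy
  count per haploid genome, optionally scaled by a global representation
  factor (< 1 models a line whose insertion is underrepresented in DNA);
* paired short reads placed directly as alignment records: fragment starts
  are Poisson with rate proportional to the local copy number, each fragment
  yields a forward and a reverse read joined by mate coordinates, PCR
  duplicates are injected as exact-coordinate copies, a residual bacterial
  titer adds uniform endosymbiont reads, and mitochondrial reads falling
  inside the homology block also appear on the endosymbiont reference
  (flagged multi-reference);
* qPCR cycle thresholds with multiplicative template / additive noise
  structure: template(nuwt amplicon) = u * c + B for stage representation u,
  haploid copy c and bacterial titer B; Ct = C0 - log_E(template) + noise,
  truncated at the 45-cycle limit.

Reads are emitted as placed alignment records rather than FASTQ run through
an external aligner: the inference chain starts at mapped reads, and this
keeps the pipeline desk-scale and aligner-independent.  A FASTQ writer is
provided for interoperability.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .coverage_profile import AlignmentRecord, AlignmentSet
from .qpcr_model import Amplicon, AmpliconPanel, CtTable, MAX_CYCLES

__all__ = [
    "GenomePair",
    "NuwtArchitecture",
    "ReadoutConfig",
    "SimulatedReadout",
    "HAWAII_COPY_PATTERN",
    "SINGLE_COPY_GENES",
    "simulate_genome_pair",
    "build_nuwt_architecture",
    "simulate_alignments",
    "simulate_qpcr",
    "simulate_offspring_presence",
    "panel_for_architecture",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Piecewise copy classes of an unevenly duplicated (Hawaii-like) insertion:
#: ten equal segments, majority at 2 copies, extremes at 1 and 12.
HAWAII_COPY_PATTERN: tuple[int, ...] = (2, 1, 4, 2, 8, 2, 12, 2, 4, 8)

#: Default single-copy host reference genes for the qPCR panel.
SINGLE_COPY_GENES: tuple[str, ...] = ("Adh", "Gpdh", "Act5C", "RpL32", "Tbp", "eEF1a")


@dataclass(frozen=True)
class GenomePair:
    """Host + endosymbiont (+ optional mitochondrial) reference sequences."""

    host_id: str
    host_seq: str
    endo_id: str
    endo_seq: str
    mito_id: str | None = None
    mito_seq: str | None = None
    homology_block: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.host_seq) == 0 or len(self.endo_seq) == 0:
            raise ValueError("host and endosymbiont references must be non-empty")
        names = [self.host_id, self.endo_id] + ([self.mito_id] if self.mito_id else [])
        if len(set(names)) != len(names):
            raise ValueError("reference names must be unique")
        if self.homology_block is not None:
            (e0, e1), (m0, m1) = self.homology_block
            if self.mito_seq is None:
                raise ValueError("homology block requires a mitochondrial reference")
            if not (0 <= e0 < e1 <= len(self.endo_seq)):
                raise ValueError("homology block endo interval out of range")
            if not (0 <= m0 < m1 <= len(self.mito_seq)):
                raise ValueError("homology block mito interval out of range")
            if (e1 - e0) != (m1 - m0):
                raise ValueError("homology block intervals must have equal length")

    @property
    def host_length(self) -> int:
        return len(self.host_seq)

    @property
    def endo_length(self) -> int:
        return len(self.endo_seq)

    @property
    def mito_length(self) -> int:
        return len(self.mito_seq) if self.mito_seq else 0

    def references(self) -> dict[str, int]:
        refs = {self.host_id: self.host_length, self.endo_id: self.endo_length}
        if self.mito_id:
            refs[self.mito_id] = self.mito_length
        return refs

    def write_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(self.host_seq), id=self.host_id, description="host"),
            SeqRecord(Seq(self.endo_seq), id=self.endo_id, description="endosymbiont"),
        ]
        if self.mito_id and self.mito_seq:
            records.append(SeqRecord(Seq(self.mito_seq), id=self.mito_id, description="mito"))
        SeqIO.write(records, path, "fasta")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_genome_pair(
    host_length: int,
    endo_length: int,
    mito_length: int = 0,
    homology_length: int = 0,
    seed: int = 0,
    *,
    host_id: str = "host_scaffold",
    endo_id: str = "wRi_like",
    mito_id: str = "mito",
) -> GenomePair:
    """Random reference sequences, optionally sharing a verbatim endo/mito block.

    The homology block is copied from a random endosymbiont interval into a
    random mitochondrial interval, modelling the shared ancestry that lets
    mitochondrial reads cross-map onto the endosymbiont reference.
    """
    for name, val in (("host", host_length), ("endo", endo_length),
                      ("mito", mito_length), ("homology", homology_length)):
        if val < 0:
            raise ValueError(f"{name}_length must be non-negative, got {val}")
    if host_length == 0 or endo_length == 0:
        raise ValueError("host and endosymbiont lengths must be positive")
    if homology_length > 0 and mito_length == 0:
        raise ValueError("homology block requires a mitochondrial reference")
    if homology_length > min(endo_length, mito_length) and homology_length > 0:
        raise ValueError("homology block longer than a reference")
    rng = np.random.default_rng(seed)
    host_seq = _random_seq(rng, host_length)
    endo_seq = _random_seq(rng, endo_length)
    mito_seq = _random_seq(rng, mito_length) if mito_length else None
    block = None
    if homology_length > 0:
        e0 = int(rng.integers(0, endo_length - homology_length + 1))
        m0 = int(rng.integers(0, mito_length - homology_length + 1))
        mito_seq = (
            mito_seq[:m0] + endo_seq[e0 : e0 + homology_length] + mito_seq[m0 + homology_length :]
        )
        block = ((e0, e0 + homology_length), (m0, m0 + homology_length))
    return GenomePair(
        host_id=host_id,
        host_seq=host_seq,
        endo_id=endo_id,
        endo_seq=endo_seq,
        mito_id=mito_id if mito_length else None,
        mito_seq=mito_seq,
        homology_block=block,
    )


@dataclass(frozen=True)
class NuwtArchitecture:
    """Ground truth of an insertion: endosymbiont segments with per-haploid
    copy counts, plus a global representation factor in (0, 1]."""

    endo_length: int
    segments: tuple[tuple[int, int, int], ...]  # (start, end, copies), half-open
    insertion_chromosome: str = "chr4"
    global_representation: float = 1.0

    def __post_init__(self) -> None:
        if self.endo_length <= 0:
            raise ValueError("endosymbiont length must be positive")
        if not 0 < self.global_representation <= 1:
            raise ValueError("global representation must be in (0, 1]")
        prev_end = 0
        for start, end, copies in sorted(self.segments):
            if not (0 <= start < end <= self.endo_length):
                raise ValueError(f"segment [{start},{end}) outside [0,{self.endo_length})")
            if start < prev_end:
                raise ValueError(f"segments overlap at {start}")
            if copies < 0 or int(copies) != copies:
                raise ValueError("copy counts must be non-negative integers")
            prev_end = end
        object.__setattr__(self, "segments", tuple(sorted(self.segments)))

    @property
    def total_span(self) -> int:
        """Total nuwt span per haploid genome: sum of copies x segment length."""
        return sum(c * (e - s) for s, e, c in self.segments)

    @property
    def copy_classes(self) -> tuple[int, ...]:
        return tuple(sorted({c for _, _, c in self.segments}))

    def copy_array(self) -> np.ndarray:
        arr = np.zeros(self.endo_length, dtype=np.int64)
        for s, e, c in self.segments:
            arr[s:e] = c
        return arr

    def copy_at(self, start: int, end: int | None = None) -> float:
        """Length-weighted mean copy count over [start, end) (one base if end None)."""
        if end is None:
            end = start + 1
        if not (0 <= start < end <= self.endo_length):
            raise ValueError(f"interval [{start},{end}) outside the endosymbiont reference")
        return float(self.copy_array()[start:end].mean())


def build_nuwt_architecture(
    preset: str,
    endo_length: int,
    *,
    copies: int = 5,
    representation: float | None = None,
    segments: Sequence[tuple[int, int, int]] | None = None,
    insertion_chromosome: str = "chr4",
) -> NuwtArchitecture:
    """Construct an insertion architecture from a named preset.

    ``hawaii_like``
        piecewise copy classes from {1, 2, 4, 8, 12} over ten equal segments
        (an unevenly duplicated array).
    ``indonesia_like``
        one segment covering the whole endosymbiont reference at ``copies``
        copies (near-identical whole-genome duplicates, default 5).
    ``india_like``
        the hawaii-like copy map with ``global_representation =
        representation`` < 1 (same duplication pattern, globally
        underrepresented in extracted DNA).
    ``custom``
        explicit ``segments``; an empty list is a nuwt-free line.
    """
    if endo_length <= 0:
        raise ValueError("endosymbiont length must be positive")
    if preset in ("hawaii_like", "india_like"):
        n = len(HAWAII_COPY_PATTERN)
        bounds = np.linspace(0, endo_length, n + 1).astype(int)
        segs = tuple(
            (int(bounds[i]), int(bounds[i + 1]), HAWAII_COPY_PATTERN[i]) for i in range(n)
        )
        if preset == "india_like":
            rep = 0.5 if representation is None else representation
            if not 0 < rep < 1:
                raise ValueError("india_like requires a representation factor in (0, 1)")
        else:
            rep = 1.0
        return NuwtArchitecture(endo_length, segs, insertion_chromosome, rep)
    if preset == "indonesia_like":
        if copies <= 0:
            raise ValueError("indonesia_like requires a positive copy count")
        return NuwtArchitecture(
            endo_length, ((0, endo_length, int(copies)),), insertion_chromosome, 1.0
        )
    if preset == "custom":
        if segments is None:
            raise ValueError("custom preset requires explicit segments (may be empty)")
        return NuwtArchitecture(
            endo_length,
            tuple(tuple(s) for s in segments),
            insertion_chromosome,
            1.0 if representation is None else representation,
        )
    raise ValueError(f"unknown preset {preset!r}")


@dataclass(frozen=True)
class ReadoutConfig:
    """Sequencing-readout parameters.

    ``mean_single_copy_depth`` is the expected fold-coverage of single-copy
    host sequence (the study design point is ~5x); ``bacterial_titer`` is the
    number of free endosymbiont genomes per haploid host genome (an uncured
    line carries ~4); ``duplicate_rate`` is the per-fragment probability of an
    exact-coordinate PCR duplicate; ``contaminant_rate`` the fraction of
    unmappable (rRNA-like) contaminant reads.
    """

    mean_single_copy_depth: float = 5.0
    read_length: int = 40
    insert_size: int = 300
    insert_sd: float = 30.0
    duplicate_rate: float = 0.0
    bacterial_titer: float = 0.0
    contaminant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_single_copy_depth <= 0:
            raise ValueError("mean single-copy depth must be positive")
        if self.read_length <= 0:
            raise ValueError("read length must be positive")
        if self.insert_size < 2 * self.read_length:
            raise ValueError("insert size must be at least two read lengths")
        for name in ("duplicate_rate", "contaminant_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.bacterial_titer < 0:
            raise ValueError("bacterial titer must be non-negative")


@dataclass
class SimulatedReadout:
    """Simulated mapping outcome: host-side and endosymbiont-side alignment
    sets plus exact read bookkeeping.

    ``total_reads`` counts every sequenced read exactly once:
    unique mapped reads + injected duplicates + unmappable contaminants.
    Multi-reference reads (present in both sets) are counted once.
    """

    host: AlignmentSet
    endo: AlignmentSet
    total_reads: int
    n_duplicates: int = 0
    n_contaminants: int = 0
    n_multi: int = 0

    def __iter__(self) -> Iterator:
        return iter((self.host, self.endo, self.total_reads))


def _poisson_starts(rng: np.random.Generator, rate: np.ndarray) -> np.ndarray:
    counts = rng.poisson(rate)
    return np.repeat(np.arange(rate.size), counts)


def _emit_fragments(
    rng: np.random.Generator,
    ref_name: str,
    ref_length: int,
    rate: np.ndarray,
    cfg: ReadoutConfig,
    counter: itertools.count,
    out: list[AlignmentRecord],
) -> tuple[int, int]:
    """Place paired fragments; returns (n_primary_reads, n_duplicate_reads).

    Fragment starts are Poisson with the given per-base rate; each fragment
    yields a forward read at its start and a reverse read ending at
    start+insert, with mate coordinates linking the pair (so exact-coordinate
    PCR duplicates are detectable by coordinate key without collapsing
    independent fragments).
    """
    rl = cfg.read_length
    max_start = ref_length - 2 * rl
    if max_start < 0:
        return 0, 0
    starts = _poisson_starts(rng, rate[: max_start + 1])
    inserts = np.rint(rng.normal(cfg.insert_size, cfg.insert_sd, starts.size)).astype(int)
    inserts = np.clip(inserts, 2 * rl, ref_length - starts)
    dup_draw = rng.random(starts.size) < cfg.duplicate_rate
    n_primary = 0
    n_dup = 0
    for p, ins, dup in zip(starts.tolist(), inserts.tolist(), dup_draw.tolist()):
        rid = f"frag{next(counter):08d}"
        r2_start = p + ins - rl
        r1 = AlignmentRecord(ref_name, p, rl, "+", rid, mate_reference=ref_name,
                             mate_start=r2_start)
        r2 = AlignmentRecord(ref_name, r2_start, rl, "-", rid, mate_reference=ref_name,
                             mate_start=p)
        out.extend((r1, r2))
        n_primary += 2
        if dup:
            out.append(AlignmentRecord(ref_name, p, rl, "+", rid + "dup",
                                       mate_reference=ref_name, mate_start=r2_start))
            out.append(AlignmentRecord(ref_name, r2_start, rl, "-", rid + "dup",
                                       mate_reference=ref_name, mate_start=p))
            n_dup += 2
    return n_primary, n_dup


def simulate_alignments(
    pair: GenomePair, arch: NuwtArchitecture, cfg: ReadoutConfig
) -> SimulatedReadout:
    """Simulate the dual-reference mapping outcome of sequencing a nuwt+ line.

    Read placement is Poisson with rate proportional to local copy number
    times ``mean_single_copy_depth``: host (and mitochondrial) positions are
    copy 1, endosymbiont positions carry ``representation x copies`` from the
    architecture plus the uniform bacterial titer.  Nuwt-derived reads are
    reported at their endosymbiont-reference coordinates, the way a real
    aligner places them.  Mitochondrial reads falling entirely inside the
    homology block also appear on the endosymbiont reference, flagged
    multi-reference with the same read id.
    """
    if arch.endo_length != pair.endo_length:
        raise ValueError(
            f"architecture is over {arch.endo_length} bp but the endosymbiont "
            f"reference is {pair.endo_length} bp"
        )
    rng = np.random.default_rng(cfg.seed)
    counter = itertools.count()
    frag_rate = cfg.mean_single_copy_depth / (2 * cfg.read_length)

    host_records: list[AlignmentRecord] = []
    endo_records: list[AlignmentRecord] = []

    host_rate = np.full(pair.host_length, frag_rate)
    n_host, d_host = _emit_fragments(
        rng, pair.host_id, pair.host_length, host_rate, cfg, counter, host_records
    )

    n_mito = d_mito = 0
    mito_start_idx = len(host_records)
    if pair.mito_id:
        mito_rate = np.full(pair.mito_length, frag_rate)
        n_mito, d_mito = _emit_fragments(
            rng, pair.mito_id, pair.mito_length, mito_rate, cfg, counter, host_records
        )

    endo_rate = (
        arch.global_representation * arch.copy_array() + cfg.bacterial_titer
    ) * frag_rate
    n_endo, d_endo = _emit_fragments(
        rng, pair.endo_id, pair.endo_length, endo_rate, cfg, counter, endo_records
    )

    # Mitochondrial reads wholly inside the shared block cross-map onto the
    # endosymbiont reference at the homologous coordinates.
    n_multi = 0
    if pair.homology_block is not None:
        (e0, _e1), (m0, m1) = pair.homology_block
        for rec in host_records[mito_start_idx:]:
            if rec.reference == pair.mito_id and rec.start >= m0 and rec.end <= m1:
                endo_records.append(
                    AlignmentRecord(
                        pair.endo_id,
                        e0 + (rec.start - m0),
                        rec.length,
                        rec.strand,
                        rec.read_id,
                        is_multi=True,
                    )
                )
                n_multi += 1

    n_primary = n_host + n_mito + n_endo
    n_dup = d_host + d_mito + d_endo
    n_contam = int(rng.poisson(cfg.contaminant_rate * n_primary))
    total = n_primary + n_dup + n_contam

    host_set = AlignmentSet(
        {pair.host_id: pair.host_length, **({pair.mito_id: pair.mito_length} if pair.mito_id else {})},
        host_records,
    )
    endo_set = AlignmentSet({pair.endo_id: pair.endo_length}, endo_records)
    return SimulatedReadout(
        host=host_set,
        endo=endo_set,
        total_reads=total,
        n_duplicates=n_dup,
        n_contaminants=n_contam,
        n_multi=n_multi,
    )


def panel_for_architecture(
    arch: NuwtArchitecture,
    *,
    amplicons_per_segment: int | None = None,
    total_amplicons: int = 24,
    amplicon_length: int = 100,
    single_copy_genes: Sequence[str] = SINGLE_COPY_GENES,
    heterochromatic_controls: Sequence[str] = (),
) -> AmpliconPanel:
    """Design a panel with amplicons placed inside each architecture segment.

    Mirrors the real assay design: ~24 primer pairs spread over the predicted
    copy classes, normalized against six single-copy host genes.  Amplicons
    are evenly spaced in the interior of each segment so each inherits an
    unambiguous copy class.
    """
    segs = [s for s in arch.segments if s[2] > 0]
    if not segs:
        return AmpliconPanel((), tuple(single_copy_genes), tuple(heterochromatic_controls))
    per_seg = amplicons_per_segment or max(1, round(total_amplicons / len(segs)))
    amplicons = []
    for s, e, c in segs:
        usable = (e - s) - amplicon_length
        if usable <= 0:
            continue
        # central placement keeps the 1 kbp windows that cover an amplicon
        # inside its own copy-class segment
        offsets = np.linspace(0.3, 0.7, per_seg) * usable
        for j, off in enumerate(offsets):
            start = s + int(off)
            amplicons.append(
                Amplicon(f"nuwt_{s}_{c}x_{j}", start, start + amplicon_length, float(c))
            )
    return AmpliconPanel(tuple(amplicons), tuple(single_copy_genes),
                         tuple(heterochromatic_controls))


def simulate_qpcr(
    panel: AmpliconPanel,
    arch: NuwtArchitecture,
    *,
    sample: str = "adult",
    stage_representation: float = 1.0,
    bacterial_titer: float = 0.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
    baseline_ct: float = 24.0,
    control_representation: Mapping[str, float] | None = None,
    stage: str | None = None,
) -> CtTable:
    """Simulate replicate Ct values under the multiplicative-template model.

    Template for a nuwt amplicon with haploid copy ``c`` is ``u*c + B``
    (stage representation u, bacterial titer B); a single-copy host gene has
    template 1 unless it is a designated heterochromatic control with its own
    representation factor.  ``Ct = C0 - log_E(template) + Normal(0,
    noise_sd)``, truncated at the 45-cycle limit; zero template never
    amplifies (Ct absent).
    """
    if not 1 < efficiency <= 2:
        raise ValueError("amplification efficiency must be in (1, 2]")
    if not 0 < stage_representation <= 1:
        raise ValueError("stage representation must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if bacterial_titer < 0:
        raise ValueError("bacterial titer must be non-negative")
    control_representation = dict(control_representation or {})
    rng = np.random.default_rng(seed)
    log_e = math.log(efficiency)

    templates: list[tuple[str, float]] = []
    for amp in panel.nuwt_amplicons:
        c = arch.copy_at(amp.start, amp.end) * arch.global_representation
        templates.append((amp.name, stage_representation * c + bacterial_titer))
    for gene in panel.single_copy_genes:
        templates.append((gene, 1.0))
    for gene in panel.heterochromatic_controls:
        templates.append((gene, float(control_representation.get(gene, 1.0))))

    rows = []
    for name, template in templates:
        for rep in range(1, replicates + 1):
            noise = float(rng.normal(0.0, noise_sd))
            if template <= 0:
                ct = float("nan")
            else:
                ct = baseline_ct - math.log(template) / log_e + noise
                if ct > MAX_CYCLES:
                    ct = float("nan")
                else:
                    ct = max(ct, 1e-6)
            row = {"sample": sample, "amplicon": name, "replicate": rep, "ct": ct}
            if stage is not None:
                row["stage"] = stage
            rows.append(row)
    return CtTable(pd.DataFrame(rows))


def simulate_offspring_presence(
    n_offspring: int, parent_heterozygous: bool, seed: int = 0
) -> list[str]:
    """Presence calls for single-copy nuwt regions in F1 offspring of a cross
    with a nuwt-free line.

    A homozygous parent transmits the insertion to every offspring; a
    heterozygous parent transmits it to each offspring with probability 1/2.
    """
    if n_offspring < 1:
        raise ValueError("need at least one offspring")
    rng = np.random.default_rng(seed)
    if not parent_heterozygous:
        return ["present"] * n_offspring
    return ["present" if rng.random() < 0.5 else "absent" for _ in range(n_offspring)]


def write_fastq(aset: AlignmentSet, pair: GenomePair, path: str) -> None:
    """Write read sequences for an alignment set as FASTQ (uniform qualities).

    Provided for interoperability with external aligners; sequences are taken
    from the reference at the aligned coordinates (reverse-complemented for
    minus-strand reads).
    """
    seqs = {pair.host_id: pair.host_seq, pair.endo_id: pair.endo_seq}
    if pair.mito_id and pair.mito_seq:
        seqs[pair.mito_id] = pair.mito_seq
    with open(path, "w") as fh:
        for rec in aset.records:
            seq = seqs[rec.reference][rec.start : rec.end]
            if rec.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            fh.write(f"@{rec.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
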