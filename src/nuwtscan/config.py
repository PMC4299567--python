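"""Structured run configuration with validation and a stable content hash."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    """Parameters of an end-to-end simulate-and-analyse run.

    Defaults mirror the study design: 1 kbp windows every 500 bp, ~5x
    single-copy depth, 45-cycle qPCR with six single-copy reference genes,
    4-fold larval underrepresentation.
    """

    seed: int = 1
    # synthetic references
    host_length: int = 60_000
    endo_length: int = 20_000
    mito_length: int = 3_000
    homology_length: int = 200
    # insertion architecture
    preset: str = "hawaii_like"
    copies: int = 5          # indonesia_like
    representation: float = 0.5  # india_like
    # sequencing readout
    mean_single_copy_depth: float = 5.0
    read_length: int = 40
    insert_size: int = 300
    insert_sd: float = 30.0
    duplicate_rate: float = 0.05
    bacterial_titer: float = 0.0
    contaminant_rate: float = 0.01
    # windowing
    window: int = 1000
    step: int = 500
    # qPCR
    normalization: str = "aggregate"
    ct_cutoff: float = 40.0
    qpcr_noise_sd: float = 0.2
    qpcr_replicates: int = 3
    larval_representation: float = 0.25
    control_representation: float = 0.25  # dsx-like controls in larvae
    # decision thresholds
    het_ratio_band: tuple[float, float] = (0.35, 0.65)
    het_shift_band: tuple[float, float] = (0.7, 1.3)
    heterochromatin_fold: float = 2.0
    n_offspring: int = 44
    # origin model
    genome_size: int = 231_000_000
    n_origins: int = 7_329
    max_origin_gap: int = 447_000

    def validate(self) -> "RunConfig":
        if self.window < self.step or self.step <= 0:
            raise ValueError(f"need window >= step > 0, got window={self.window}, step={self.step}")
        if not 0 < self.ct_cutoff <= 45:
            raise ValueError("Ct cutoff must be in (0, 45]")
        if not 0 < self.larval_representation <= 1:
            raise ValueError("larval representation must be in (0, 1]")
        for band in (self.het_ratio_band, self.het_shift_band):
            if not (len(band) == 2 and band[0] < band[1]):
                raise ValueError(f"threshold band must be (low, high), got {band}")
        if self.heterochromatin_fold <= 0:
            raise ValueError("heterochromatin fold threshold must be positive")
        if self.preset not in ("hawaii_like", "indonesia_like", "india_like"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_offspring < 1:
            raise ValueError("need at least one offspring")
        return self

    def as_dict(self) -> dict:
        d = asdict(self)
        d["het_ratio_band"] = list(self.het_ratio_band)
        d["het_shift_band"] = list(self.het_shift_band)
        return d

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("het_ratio_band", "het_shift_band"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc).validate()
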