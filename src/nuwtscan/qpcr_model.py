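"""Relative-quantification qPCR model for copy-number estimation.

A duplicated target amplifies earlier than a single-copy reference gene, so
its cycle threshold (Ct) is lower.  With perfect doubling per cycle the
abundance ratio between target and reference is

    fold = 2 ** dCt,      dCt = Ct(single-copy reference) - Ct(target),

and ``fold`` should equal the target's copy number per haploid genome.  The
sign convention makes duplicated targets give dCt > 0 and fold > 1; a target
at half dosage (e.g. an F1 heterozygote) shifts dCt by -1 cycle.

The module computes dCt estimates from replicate Ct tables, calls
presence/absence against a cycle cutoff, and validates qPCR folds against
sequencing-derived copy numbers by ordinary least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "Amplicon",
    "AmpliconPanel",
    "CtTable",
    "CopyEstimate",
    "RegressionFit",
    "ReferenceDispersionWarning",
    "MAX_CYCLES",
    "delta_ct",
    "validate_against_sequencing",
    "presence_call",
]

MAX_CYCLES = 45.0  # amplification runs 45 cycles; later Cts are never observed


class ReferenceDispersionWarning(UserWarning):
    """Single-copy reference genes disagree by more than the expected <1 Ct."""


@dataclass(frozen=True)
class Amplicon:
    """A primer pair targeting an interval of the endosymbiont reference."""

    name: str
    start: int
    end: int
    copy_class: float  # predicted copies per haploid genome

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad amplicon interval [{self.start},{self.end})")
        if self.copy_class <= 0:
            raise ValueError("predicted copy class must be positive")


@dataclass(frozen=True)
class AmpliconPanel:
    """Assay design: nuwt amplicons, single-copy reference genes, optional
    heterochromatic control genes (dsx-like)."""

    nuwt_amplicons: tuple[Amplicon, ...]
    single_copy_genes: tuple[str, ...]
    heterochromatic_controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.single_copy_genes) < 1:
            raise ValueError("panel needs at least one single-copy reference gene")
        names = (
            [a.name for a in self.nuwt_amplicons]
            + list(self.single_copy_genes)
            + list(self.heterochromatic_controls)
        )
        if len(set(names)) != len(names):
            raise ValueError("amplicon/gene names must be unique")

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.nuwt_amplicons) + self.heterochromatic_controls

    def to_yaml(self, path: str) -> None:
        doc = {
            "nuwt_amplicons": [
                {"name": a.name, "start": a.start, "end": a.end, "copy_class": a.copy_class}
                for a in self.nuwt_amplicons
            ],
            "single_copy_genes": list(self.single_copy_genes),
            "heterochromatic_controls": list(self.heterochromatic_controls),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "AmpliconPanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            nuwt_amplicons=tuple(Amplicon(**a) for a in doc.get("nuwt_amplicons", [])),
            single_copy_genes=tuple(doc.get("single_copy_genes", [])),
            heterochromatic_controls=tuple(doc.get("heterochromatic_controls", [])),
        )


@dataclass
class CtTable:
    """Cycle-threshold measurements, one row per (sample, amplicon, replicate).

    ``ct`` is NaN for reactions that never amplified within the cycle limit.
    An optional ``stage`` column carries life-stage annotations.
    """

    df: pd.DataFrame

    REQUIRED = ("sample", "amplicon", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"Ct table missing columns {missing}")
        ct = self.df["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > MAX_CYCLES))
        if bad.any():
            raise ValueError(f"Ct values outside (0, {MAX_CYCLES}]: {ct[bad].tolist()}")

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.df[self.df["sample"] == sample]

    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def to_tsv(self, path: str, *, comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in comments:
                fh.write(f"# {line}\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str) -> "CtTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df)

    @classmethod
    def concat(cls, tables: Iterable["CtTable"]) -> "CtTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


@dataclass(frozen=True)
class CopyEstimate:
    """Relative copy-number estimate for one amplicon.

    ``fold`` is derived from ``delta_ct`` (fold = efficiency ** dCt), never
    stored, so the two can never disagree.
    """

    amplicon: str
    delta_ct: float
    replicate_sd: float = 0.0
    undetected: bool = False
    efficiency: float = 2.0

    @property
    def fold(self) -> float:
        if self.undetected:
            return float("nan")
        return float(self.efficiency**self.delta_ct)


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit with a two-sided t-test on the slope."""

    slope: float | None
    intercept: float | None
    p_value: float | None
    n: int
    no_correlation_expected: bool = False
    r_value: float | None = None


def _aggregate(values: pd.Series, how: str) -> float:
    if how == "mean":
        return float(values.mean())
    if how == "median":
        return float(values.median())
    raise ValueError(f"unknown replicate aggregation {how!r}")


def delta_ct(
    table: CtTable,
    panel: AmpliconPanel,
    sample: str,
    normalization: str = "aggregate",
    *,
    agg: str = "mean",
    efficiency: float = 2.0,
) -> list[CopyEstimate]:
    """dCt copy estimates for every target amplicon of ``panel`` in ``sample``.

    ``normalization='aggregate'`` pools all single-copy reference Ct values
    into one mean; ``'per_gene'`` computes one dCt per reference gene and
    averages.  The two agree whenever every reference gene has equal replicate
    counts.  Targets with no amplification in any replicate are flagged
    ``undetected``.  A warning is emitted when the reference genes span more
    than 1 Ct, which in a well-behaved assay they should not.
    """
    if normalization not in ("aggregate", "per_gene"):
        raise ValueError(f"unknown normalization {normalization!r}")
    df = table.for_sample(sample)
    ref_values: dict[str, pd.Series] = {}
    for gene in panel.single_copy_genes:
        vals = df.loc[df["amplicon"] == gene, "ct"].dropna()
        if vals.empty:
            raise ValueError(f"no Ct for reference gene {gene!r} in sample {sample!r}")
        ref_values[gene] = vals
    gene_means = {g: _aggregate(v, agg) for g, v in ref_values.items()}
    if max(gene_means.values()) - min(gene_means.values()) > 1.0:
        warnings.warn(
            f"single-copy reference genes span "
            f"{max(gene_means.values()) - min(gene_means.values()):.2f} Ct in "
            f"sample {sample!r}; expected <1 Ct",
            ReferenceDispersionWarning,
            stacklevel=2,
        )
    if normalization == "aggregate":
        pooled = pd.concat(list(ref_values.values()))
        reference_ct = _aggregate(pooled, agg)
    else:
        reference_ct = float(np.mean(list(gene_means.values())))

    estimates = []
    for name in panel.target_names:
        vals = df.loc[df["amplicon"] == name, "ct"].dropna()
        if vals.empty:
            estimates.append(
                CopyEstimate(name, float("nan"), float("nan"), undetected=True,
                             efficiency=efficiency)
            )
            continue
        target_ct = _aggregate(vals, agg)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        estimates.append(
            CopyEstimate(name, reference_ct - target_ct, sd, efficiency=efficiency)
        )
    return estimates


def validate_against_sequencing(
    estimates: Sequence[CopyEstimate], seq_copies: Mapping[str, float]
) -> RegressionFit:
    """Regress sequencing copy number (y) on qPCR fold (x) by OLS.

    With an accurate assay the points fall on the identity line.  When the
    sequencing copies are constant across amplicons (an evenly-duplicated
    insertion) no correlation is expected and the fit is flagged instead of
    reported: the scatter then only shows the assay's random variation.
    """
    pairs = [
        (e.fold, float(seq_copies[e.amplicon]))
        for e in estimates
        if not e.undetected and e.amplicon in seq_copies
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 paired points for a fit, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.allclose(y, y[0]):
        if np.allclose(x, x[0]):
            raise ValueError("degenerate fit: both qPCR folds and sequencing copies constant")
        return RegressionFit(None, None, None, len(pairs), no_correlation_expected=True)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: qPCR folds are constant")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=len(pairs),
        r_value=float(res.rvalue),
    )


def presence_call(
    table: CtTable, amplicon: str, sample: str, *, ct_cutoff: float = 40.0
) -> str:
    """'present' if any replicate amplifies at or below ``ct_cutoff``, else 'absent'."""
    if not 0 < ct_cutoff <= MAX_CYCLES:
        raise ValueError(f"ct_cutoff must be in (0, {MAX_CYCLES}]")
    df = table.for_sample(sample)
    vals = df.loc[df["amplicon"] == amplicon, "ct"].dropna()
    return "present" if (vals <= ct_cutoff).any() else "absent"
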