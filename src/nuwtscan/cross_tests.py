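"""Genetic-cross dosage tests for a chromosomal endosymbiont insertion.

Because *Wolbachia* endosymbionts are inherited strictly through the egg
cytoplasm while a nuclear insertion (nuwt) segregates as a chromosome, a
cross between an infected/insertion-bearing line and a naive line separates
the two signals:

* an F1 from a nuwt+ parent and a nuwt- parent carries one parental
  chromosome set, so every nuwt amplicon drops to half dosage — the dCt
  intercept shifts by +1 cycle and the fold ratio F1/parent is 0.5;
* if the parent were heterozygous, ~50% of F1 offspring would lack
  single-copy nuwt regions entirely (exact binomial segregation test);
* a cross through a naive mother sheds the maternal infection in one
  generation, so persistence of endosymbiont signal in such an F1 is
  chromosomal, not bacterial;
* in an uncured (infected) fly, free bacterial genomes add a constant
  template B to every endosymbiont amplicon, so qPCR fold regressed on
  sequencing copy number has slope ~1 and intercept B — the bacterial titer
  in genomes per haploid host genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .qpcr_model import CopyEstimate, RegressionFit

__all__ = [
    "ParentLine",
    "CrossDesign",
    "DosageVerdict",
    "TiterFit",
    "CuringReport",
    "heterozygosity_test",
    "f1_dosage_to_parent",
    "per_nucleus_copies",
    "bacterial_titer_fit",
    "curing_cross_check",
    "delta_ct_intercept",
]


@dataclass(frozen=True)
class ParentLine:
    line: str
    wolbachia: bool
    nuwt: bool


@dataclass(frozen=True)
class CrossDesign:
    """A single cross; F1 infection status follows the mother (maternal
    inheritance), F1 nuwt dosage follows chromosome segregation."""

    mother: ParentLine
    father: ParentLine
    n_offspring: int = 1

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ValueError("a cross needs at least one offspring")

    @property
    def f1_wolbachia(self) -> bool:
        return self.mother.wolbachia


@dataclass(frozen=True)
class DosageVerdict:
    hypothesis: str  # homozygous | heterozygous | lost
    f1_fold_ratio: float
    intercept_shift: float
    segregation_p: float
    n_offspring: int
    n_present: int
    warning: str | None = None


def delta_ct_intercept(
    estimates: Sequence[CopyEstimate], seq_copies: Mapping[str, float]
) -> RegressionFit:
    """OLS fit of dCt against log2(sequencing copy number).

    For a full-dosage sample the line is dCt = log2(c) (intercept 0); a
    half-dosage F1 runs parallel one cycle lower (intercept -1).
    """
    pairs = [
        (np.log2(float(seq_copies[e.amplicon])), e.delta_ct)
        for e in estimates
        if not e.undetected and e.amplicon in seq_copies
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 points for an intercept fit, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate intercept fit: sequencing copies constant")
    res = stats.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept), float(res.pvalue),
                         len(pairs), r_value=float(res.rvalue))


def _as_present(value) -> bool:
    if isinstance(value, str):
        return value == "present"
    return bool(value)


def heterozygosity_test(
    parent_estimates: Sequence[CopyEstimate],
    f1_estimates: Sequence[CopyEstimate],
    offspring_presence: Sequence[str | bool],
    *,
    seq_copies: Mapping[str, float] | None = None,
    ratio_band: tuple[float, float] = (0.35, 0.65),
    shift_band: tuple[float, float] = (0.7, 1.3),
) -> DosageVerdict:
    """Decide whether the parental insertion is homozygous, heterozygous or lost.

    Combines three observables from a cross against a nuwt-free line:
    the mean F1/parent fold ratio over shared amplicons (0.5 for a homozygous
    parent), the dCt intercept shift of the F1 fit versus the parental fit
    (+1 cycle for halved dosage; computed against ``seq_copies`` when given,
    otherwise as the mean per-amplicon dCt difference), and presence calls for
    single-copy regions in each offspring.  The segregation p-value is the
    exact binomial probability of seeing at least the observed number of
    nuwt-positive offspring if the parent were heterozygous (all 44 offspring
    positive has probability 0.5**44).
    """
    pmap = {e.amplicon: e for e in parent_estimates if not e.undetected}
    fmap = {e.amplicon: e for e in f1_estimates}
    shared = sorted(set(pmap) & set(fmap))
    if not shared:
        raise ValueError("parent and F1 estimates share no amplicons")
    detected = [a for a in shared if not fmap[a].undetected]

    presence = [_as_present(p) for p in offspring_presence]
    n = len(presence)
    n_present = sum(presence)
    segregation_p = float(stats.binom.sf(n_present - 1, n, 0.5)) if n else float("nan")

    if not detected or (n > 0 and n_present == 0):
        return DosageVerdict("lost", 0.0, float("nan"), segregation_p, n, n_present)

    ratio = float(np.mean([fmap[a].fold / pmap[a].fold for a in detected]))
    if seq_copies is not None:
        shift = (
            delta_ct_intercept([pmap[a] for a in detected], seq_copies).intercept
            - delta_ct_intercept([fmap[a] for a in detected], seq_copies).intercept
        )
    else:
        shift = float(np.mean([pmap[a].delta_ct - fmap[a].delta_ct for a in detected]))

    warning = None
    if n_present == n:
        hypothesis = "homozygous"
        if not ratio_band[0] <= ratio <= ratio_band[1]:
            warning = (
                f"F1/parent fold ratio {ratio:.2f} outside the half-dosage band "
                f"{ratio_band}; cross or assay may be inconsistent"
            )
        elif not shift_band[0] <= shift <= shift_band[1]:
            warning = (
                f"dCt intercept shift {shift:.2f} outside the +1 cycle band "
                f"{shift_band}; cross or assay may be inconsistent"
            )
    elif n_present == 0:
        hypothesis = "lost"
    else:
        hypothesis = "heterozygous"
    return DosageVerdict(hypothesis, ratio, float(shift), segregation_p, n, n_present, warning)


def f1_dosage_to_parent(f1_fold: float) -> float:
    """Parental fold implied by an F1 hybrid fold: exactly double.

    An F1 of a cross with a naive line carries one parental chromosome set,
    so e.g. 2.6x endosymbiont DNA in the F1 implies 5.2x in the parent.
    """
    if f1_fold < 0:
        raise ValueError("fold must be non-negative")
    return 2.0 * f1_fold


def per_nucleus_copies(haploid_copies: float) -> float:
    """Copies per diploid nucleus: twice the per-haploid count (8 -> 16)."""
    if haploid_copies < 0:
        raise ValueError("copy count must be non-negative")
    return 2.0 * haploid_copies


@dataclass(frozen=True)
class TiterFit:
    """Bacterial titer inferred from uncured-fly qPCR: fold = slope*copy + titer."""

    titer: float
    slope: float
    fit: RegressionFit


def bacterial_titer_fit(
    uncured_estimates: Sequence[CopyEstimate], cured_copies: Mapping[str, float]
) -> TiterFit:
    """Fit the additive bacterial-template model to uncured-fly estimates.

    Free endosymbiont genomes contribute an equal extra template B to every
    endosymbiont amplicon, so the uncured fold is ``copy + B``: least squares
    of fold against the cured-line sequencing copy number recovers slope ~1
    and intercept B (genomes per haploid host genome).  With B = 0 this
    reduces to the plain sequencing validation.
    """
    pairs = [
        (float(cured_copies[e.amplicon]), e.fold)
        for e in uncured_estimates
        if not e.undetected and e.amplicon in cured_copies
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 amplicons for a titer fit, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate titer fit: amplicons span a single copy class")
    res = stats.linregress(x, y)
    fit = RegressionFit(float(res.slope), float(res.intercept), float(res.pvalue),
                        len(pairs), r_value=float(res.rvalue))
    return TiterFit(titer=float(res.intercept), slope=float(res.slope), fit=fit)


@dataclass(frozen=True)
class CuringReport:
    f1_wolbachia: bool
    nuwt_status: str  # retained | lost
    classification: str
    caveats: tuple[str, ...] = ()


def curing_cross_check(
    design: CrossDesign, f1_presence: Mapping[str, str]
) -> CuringReport:
    """Interpret a maternal-curing cross from F1 presence calls.

    The F1 infection status follows the mother; nuwt presence in the F1 of a
    naive-mother cross demonstrates paternal chromosomal transmission.  When
    the mother is infected, any endosymbiont signal may instead come from a
    residual infection, and the report carries that caveat regardless of the
    presence calls.
    """
    f1_wb = design.f1_wolbachia
    any_present = any(_as_present(v) for v in f1_presence.values())
    nuwt_status = "retained" if any_present else "lost"
    caveats: tuple[str, ...] = ()
    if f1_wb:
        caveats = (
            "residual infection suspected: mother was infected, so endosymbiont "
            "signal may be bacterial rather than chromosomal",
        )
        classification = f"nuwt {nuwt_status}; residual infection suspected"
    elif any_present:
        classification = "nuwt retained, no infection (paternal chromosomal transmission)"
    else:
        classification = "nuwt lost"
    return CuringReport(f1_wb, nuwt_status, classification, caveats)
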