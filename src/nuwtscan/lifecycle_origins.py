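"""Life-stage underrepresentation and replication-origin spacing.

In endoreplicating tissues (salivary-gland polytene chromosomes of third
instar larvae being the textbook case) heterochromatic regions are not
replicated to the ploidy of the cell and end up underrepresented in
extracted DNA.  Regressing the adult sequencing copy number of each nuwt
amplicon on its stage-resolved qPCR fold gives a stage slope: ~1 when the
insertion replicates with the rest of the genome, 1/u when its template is
underrepresented by a factor u (a slope of ~4 means 4-fold underreplication).
Heterochromatic host genes such as *dsx* show the same behaviour (2- to
8-fold) and serve as positive controls.

A bacterial insertion carries no host origins of replication, so a tandem
array larger than the largest origin-free interval the host can replicate is
a mechanistic candidate for underreplication: the module compares the total
insertion span against the maximum gap between origin-recognition-complex
(ORC) sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .qpcr_model import AmpliconPanel, CopyEstimate, CtTable, RegressionFit, delta_ct
from .synthetic_data import NuwtArchitecture

__all__ = [
    "StageProfile",
    "OriginModel",
    "ControlCall",
    "ControlReport",
    "UnderreplicationRisk",
    "stage_regression",
    "classify_controls",
    "origin_spacing",
    "underreplication_risk",
]


@dataclass(frozen=True)
class StageProfile:
    """Per-stage dosage fit: adult sequencing copy (y) vs stage qPCR fold (x).

    ``underrep_fold`` is the through-origin slope, interpretable as the
    reciprocal of the stage's template representation factor; ``fit`` is the
    free-intercept OLS kept for diagnostics.
    """

    stage: str
    fit: RegressionFit
    underrep_fold: float
    heterochromatin_like: bool
    n: int


def stage_regression(
    stage_table: CtTable,
    panel: AmpliconPanel,
    adult_seq_copies: Mapping[str, float],
    *,
    sample: str,
    stage: str | None = None,
    normalization: str = "aggregate",
    heterochromatin_threshold: float = 2.0,
) -> StageProfile:
    """Fit adult sequencing copy number against stage qPCR fold.

    The slope is fit through the origin so that slope x representation = 1
    exactly under the noise-free template model; a free-intercept fit is
    reported alongside.  A stage whose slope reaches the heterochromatin
    threshold (default 2, the lower edge of the *dsx*-like control range) is
    flagged heterochromatin-like.
    """
    estimates = delta_ct(stage_table, panel, sample, normalization)
    pairs = [
        (e.fold, float(adult_seq_copies[e.amplicon]))
        for e in estimates
        if not e.undetected and e.amplicon in adult_seq_copies
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 amplicons for a stage fit, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if len(set(np.round(y, 9))) < 2:
        raise ValueError("degenerate stage fit: amplicons span a single copy class")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate stage fit: qPCR folds are constant")
    slope0 = float(np.dot(x, y) / np.dot(x, x))
    res = stats.linregress(x, y)
    fit = RegressionFit(float(res.slope), float(res.intercept), float(res.pvalue),
                        len(pairs), r_value=float(res.rvalue))
    if slope0 <= 0:
        raise ValueError("stage fit produced a non-positive slope")
    return StageProfile(
        stage=stage or sample,
        fit=fit,
        underrep_fold=slope0,
        heterochromatin_like=slope0 >= heterochromatin_threshold,
        n=len(pairs),
    )


@dataclass(frozen=True)
class ControlCall:
    gene: str
    underrep_fold: float
    flagged: bool


@dataclass(frozen=True)
class ControlReport:
    controls: tuple[ControlCall, ...]
    nuwt_underrep_fold: float
    verdict: str


def classify_controls(
    larval_estimates: Sequence[CopyEstimate],
    panel: AmpliconPanel,
    nuwt_underrep_fold: float,
    *,
    band: tuple[float, float] = (2.0, 8.0),
) -> ControlReport:
    """Compare nuwt underrepresentation with heterochromatic control genes.

    A control gene's larval underrepresentation fold is the reciprocal of its
    qPCR fold (controls are single copy, so full representation gives fold 1).
    Controls falling in the 2-8x band behave like heterochromatin; the nuwt is
    called consistent with heterochromatin when its own fold sits within a
    factor of two of the flagged controls.
    """
    emap = {e.amplicon: e for e in larval_estimates}
    calls = []
    for gene in panel.heterochromatic_controls:
        est = emap.get(gene)
        if est is None or est.undetected:
            continue
        fold_under = 1.0 / est.fold
        calls.append(ControlCall(gene, fold_under, band[0] <= fold_under <= band[1]))
    flagged = [c.underrep_fold for c in calls if c.flagged]
    if not flagged:
        verdict = "no heterochromatic control in the expected band"
    else:
        ref = float(np.median(flagged))
        if 0.5 <= nuwt_underrep_fold / ref <= 2.0:
            verdict = "nuwt underrepresentation consistent with heterochromatin"
        else:
            verdict = "nuwt underrepresentation inconsistent with heterochromatic controls"
    return ControlReport(tuple(calls), float(nuwt_underrep_fold), verdict)


@dataclass(frozen=True)
class OriginModel:
    """Replication-origin landscape of the host genome.

    Defaults reflect published *D. melanogaster* ORC-site predictions: 7,329
    non-overlapping sites with a maximum inter-site gap of 447 kbp.
    """

    genome_size: int
    n_origins: int = 7329
    max_gap: int = 447_000

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome size must be positive")
        if self.n_origins < 1:
            raise ValueError("need at least one origin")
        if self.max_gap <= 0:
            raise ValueError("maximum origin gap must be positive")


def origin_spacing(model: OriginModel) -> float:
    """Expected origin spacing under even placement: genome_size / n_origins.

    Note the literal division: 231 Mbp over 7,329 sites gives ~31.5 kbp.
    """
    return model.genome_size / model.n_origins


@dataclass(frozen=True)
class UnderreplicationRisk:
    at_risk: bool
    nuwt_span: int
    max_gap: int
    message: str


def underreplication_risk(arch: NuwtArchitecture, model: OriginModel) -> UnderreplicationRisk:
    """Flag an insertion whose tandem span exceeds the largest origin-free gap.

    The total contiguous span (sum of copies x segment length) is compared
    against ``max_gap`` with a strict inequality: a span exactly at the gap is
    not flagged.
    """
    span = arch.total_span
    at_risk = span > model.max_gap
    if at_risk:
        message = (
            f"tandem nuwt span {span:,} bp exceeds the maximum origin gap "
            f"{model.max_gap:,} bp; underreplication plausible from origin scarcity alone"
        )
    else:
        message = (
            f"tandem nuwt span {span:,} bp within the maximum origin gap "
            f"{model.max_gap:,} bp"
        )
    return UnderreplicationRisk(at_risk, span, model.max_gap, message)
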