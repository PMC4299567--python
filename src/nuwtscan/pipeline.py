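"""End-to-end orchestration: simulate -> depth -> copy number -> qPCR ->
cross -> life stages -> origin report.

Every output file carries the seed and config hash in a comment header, and
a fixed seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .config import RunConfig
from .coverage_profile import (
    AlignmentSet,
    copy_number_profile,
    cross_mapping_audit,
    depth_track,
    estimate_lgt_size,
    mark_duplicates,
    read_fraction_stats,
    windowed_modal_depth,
    write_sam,
)
from .cross_tests import heterozygosity_test
from .lifecycle_origins import (
    OriginModel,
    classify_controls,
    origin_spacing,
    stage_regression,
    underreplication_risk,
)
from .qpcr_model import delta_ct, validate_against_sequencing
from .synthetic_data import (
    ReadoutConfig,
    build_nuwt_architecture,
    panel_for_architecture,
    simulate_alignments,
    simulate_genome_pair,
    simulate_offspring_presence,
    simulate_qpcr,
)

logger = logging.getLogger("nuwtscan")

STAGES = ("simulate", "depth", "copynum", "stats", "qpcr", "cross", "stages", "origins")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute all stages in dependency order; returns the summary dict.

    Stops at the first failing stage with a stage-named error.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = [f"nuwtscan run seed={config.seed} config={config.config_hash}"]
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash, "outputs": {}}

    def _record(name: str, path: Path) -> None:
        summary["outputs"][name] = path.name

    stage = "simulate"
    t0 = time.perf_counter()
    try:
        pair = simulate_genome_pair(
            config.host_length, config.endo_length, config.mito_length,
            config.homology_length, seed=config.seed,
        )
        arch = build_nuwt_architecture(
            config.preset, config.endo_length,
            copies=config.copies, representation=config.representation,
        )
        rcfg = ReadoutConfig(
            mean_single_copy_depth=config.mean_single_copy_depth,
            read_length=config.read_length,
            insert_size=config.insert_size,
            insert_sd=config.insert_sd,
            duplicate_rate=config.duplicate_rate,
            bacterial_titer=config.bacterial_titer,
            contaminant_rate=config.contaminant_rate,
            seed=config.seed + 1,
        )
        sim = simulate_alignments(pair, arch, rcfg)
        pair.write_fasta(out / "references.fasta")
        write_sam(sim.host, str(out / "host.sam"), comments=meta)
        write_sam(sim.endo, str(out / "endo.sam"), comments=meta)
        for name in ("references.fasta", "host.sam", "endo.sam"):
            _record(name.split(".")[0], out / name)
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    stage = "depth"
    t0 = time.perf_counter()
    try:
        host_dedup = mark_duplicates(sim.host)
        endo_dedup = mark_duplicates(sim.endo)
        host_track = depth_track(host_dedup, pair.host_id)
        endo_track = depth_track(endo_dedup, pair.endo_id)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    stage = "copynum"
    t0 = time.perf_counter()
    try:
        modal = windowed_modal_depth(host_track, config.window, config.step)
        host_profile = copy_number_profile(host_track, modal, config.window, config.step)
        endo_profile = copy_number_profile(endo_track, modal, config.window, config.step)
        host_profile.to_tsv(str(out / "host_profile.tsv"), comments=meta)
        endo_profile.to_tsv(str(out / "endo_profile.tsv"), comments=meta)
        endo_profile.to_bedgraph(str(out / "endo_profile.bedgraph"), comments=meta)
        summary["modal_depth"] = modal
        for name in ("host_profile.tsv", "endo_profile.tsv", "endo_profile.bedgraph"):
            _record(name.replace(".", "_"), out / name)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    stage = "stats"
    t0 = time.perf_counter()
    try:
        endo_unique = len(sim.endo) - sim.n_multi
        stats = read_fraction_stats(sim.total_reads, len(sim.host), endo_unique)
        mito_set = AlignmentSet(
            {pair.mito_id: pair.mito_length} if pair.mito_id else {},
            sim.host.for_reference(pair.mito_id) if pair.mito_id else [],
        )
        shared_n, _ = cross_mapping_audit(sim.endo, mito_set)
        lgt_bp = estimate_lgt_size(stats.endo_to_host_ratio_pct, config.host_length / 1e6) * 1e6
        with open(out / "mapping_stats.tsv", "w") as fh:
            for line in meta:
                fh.write(f"# {line}\n")
            fh.write("total_reads\thost_mapped\tendo_mapped\thost_pct\tendo_pct\t"
                     "endo_to_host_ratio_pct\tcross_mapped_reads\testimated_lgt_bp\n")
            fh.write(
                f"{stats.total_reads}\t{stats.host_mapped}\t{stats.endo_mapped}\t"
                f"{stats.host_pct:.4g}\t{stats.endo_pct:.4g}\t"
                f"{stats.endo_to_host_ratio_pct:.4g}\t{shared_n}\t{lgt_bp:.4g}\n"
            )
        summary["mapping"] = stats.as_dict()
        summary["cross_mapped_reads"] = shared_n
        summary["estimated_lgt_bp"] = round(lgt_bp, 1)
        _record("mapping_stats", out / "mapping_stats.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    stage = "qpcr"
    t0 = time.perf_counter()
    try:
        panel = panel_for_architecture(arch, heterochromatic_controls=("dsx", "polr3"))
        adult = simulate_qpcr(
            panel, arch, sample="adult", noise_sd=config.qpcr_noise_sd,
            replicates=config.qpcr_replicates, seed=config.seed + 2, stage="adult",
        )
        adult.to_tsv(str(out / "ct_adult.tsv"), comments=meta)
        estimates = delta_ct(adult, panel, "adult", config.normalization)
        seq_copies = {
            a.name: endo_profile.copy_at((a.start + a.end) // 2)
            for a in panel.nuwt_amplicons
        }
        fit = validate_against_sequencing(estimates, seq_copies)
        with open(out / "qpcr_regression.tsv", "w") as fh:
            for line in meta:
                fh.write(f"# {line}\n")
            fh.write("slope\tintercept\tp_value\tn\tno_correlation_expected\n")
            fh.write(
                f"{_fmt(fit.slope)}\t{_fmt(fit.intercept)}\t{_fmt(fit.p_value)}\t"
                f"{fit.n}\t{fit.no_correlation_expected}\n"
            )
        summary["qpcr_fit"] = {
            "slope": _round(fit.slope), "intercept": _round(fit.intercept),
            "p_value": fit.p_value, "n": fit.n,
            "no_correlation_expected": fit.no_correlation_expected,
        }
        _record("ct_adult", out / "ct_adult.tsv")
        _record("qpcr_regression", out / "qpcr_regression.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    stage = "cross"
    t0 = time.perf_counter()
    try:
        f1 = simulate_qpcr(
            panel, arch, sample="f1", stage_representation=0.5,
            noise_sd=config.qpcr_noise_sd, replicates=config.qpcr_replicates,
            seed=config.seed + 3,
        )
        f1_estimates = delta_ct(f1, panel, "f1", config.normalization)
        presence = simulate_offspring_presence(
            config.n_offspring, parent_heterozygous=False, seed=config.seed + 4
        )
        truth = {a.name: float(a.copy_class) for a in panel.nuwt_amplicons}
        verdict = heterozygosity_test(
            estimates, f1_estimates, presence, seq_copies=truth,
            ratio_band=config.het_ratio_band, shift_band=config.het_shift_band,
        )
        summary["cross"] = {
            "hypothesis": verdict.hypothesis,
            "f1_fold_ratio": _round(verdict.f1_fold_ratio),
            "intercept_shift": _round(verdict.intercept_shift),
            "segregation_p": verdict.segregation_p,
            "n_offspring": verdict.n_offspring,
            "n_present": verdict.n_present,
            "warning": verdict.warning,
        }
        with open(out / "cross_verdict.json", "w") as fh:
            json.dump({"meta": meta[0], **summary["cross"]}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _record("cross_verdict", out / "cross_verdict.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    stage = "stages"
    t0 = time.perf_counter()
    try:
        larva = simulate_qpcr(
            panel, arch, sample="larva3",
            stage_representation=config.larval_representation,
            control_representation={g: config.control_representation
                                    for g in panel.heterochromatic_controls},
            noise_sd=config.qpcr_noise_sd, replicates=config.qpcr_replicates,
            seed=config.seed + 5, stage="larva3",
        )
        larva.to_tsv(str(out / "ct_larva3.tsv"), comments=meta)
        profile = stage_regression(
            larva, panel, truth, sample="larva3", stage="larva3",
            normalization=config.normalization,
            heterochromatin_threshold=config.heterochromatin_fold,
        )
        larval_estimates = delta_ct(larva, panel, "larva3", config.normalization)
        controls = classify_controls(larval_estimates, panel, profile.underrep_fold)
        with open(out / "stage_slopes.tsv", "w") as fh:
            for line in meta:
                fh.write(f"# {line}\n")
            fh.write("stage\tunderrep_fold\theterochromatin_like\tn\tverdict\n")
            fh.write(
                f"{profile.stage}\t{profile.underrep_fold:.4g}\t"
                f"{profile.heterochromatin_like}\t{profile.n}\t{controls.verdict}\n"
            )
        summary["stages"] = {
            "larva3_underrep_fold": _round(profile.underrep_fold),
            "heterochromatin_like": profile.heterochromatin_like,
            "control_verdict": controls.verdict,
        }
        _record("ct_larva3", out / "ct_larva3.tsv")
        _record("stage_slopes", out / "stage_slopes.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    stage = "origins"
    t0 = time.perf_counter()
    try:
        model = OriginModel(config.genome_size, config.n_origins, config.max_origin_gap)
        risk = underreplication_risk(arch, model)
        summary["origins"] = {
            "expected_spacing_bp": _round(origin_spacing(model)),
            "max_gap_bp": model.max_gap,
            "nuwt_span_bp": risk.nuwt_span,
            "at_risk": risk.at_risk,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _fmt(value) -> str:
    return "NA" if value is None else f"{value:.6g}"


def _round(value, digits: int = 4):
    if value is None:
        return None
    if isinstance(value, float) and not np.isfinite(value):
        return None
    return round(float(value), digits)
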