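"""End-to-end orchestration: simulate → normalize → screen → validate →
combine → interactions → report.

The run is driven by one :class:`RunConfig` (loadable from YAML).  Inputs
are either files on disk or a synthetic dataset generated in-place; outputs
are a candidates table, validation decisions, an eligibility-funnel summary,
a run manifest (full config, seed, package version, config hash) and, when
ground truth is available, a recovery report.

The funnel counts are monotone by construction — each step filters the
survivors of the previous one:

    measured → detected (expressed in >=1 screening sample)
             → >=det_frac per group×day cell for >=1 contrast
             → screened candidates → validated → Bonferroni survivors
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .data_io import (
    QCThresholds,
    SampleMeta,
    qc_filter_samples,
    read_ct_long,
    read_samples,
    write_candidates,
    write_ct_long,
    write_samples,
)
from .interactions import ColumnMap, classify_reciprocity, export_graph, filter_interactions
from .normalization import detect_calls, median_normalize, write_normalized
from .stage1 import (
    CandidateRecord,
    ScreenConfig,
    _cells_for_contrast,
    detection_filter,
    flag_bonferroni,
    screen_contrast,
)
from .stage2 import ValidationDecision, apply_bonferroni, combined_analysis, validate_candidates
from .synthetic import (
    RecoveryReport,
    SyntheticConfig,
    TruthRecord,
    design_summary,
    evaluate_recovery,
    generate_dataset,
    write_truth,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "summarize_report", "load_config"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; fully serialized into the manifest."""

    out_dir: str
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    synthetic: SyntheticConfig | None = None
    samples_path: str | None = None
    ct_path: str | None = None
    interactions_path: str | None = None
    interaction_colmap: ColumnMap = field(default_factory=ColumnMap)
    interaction_species: str = "9606"
    mrna_list: tuple[str, ...] = ()
    mrna_directions: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"


@dataclass
class ReportBundle:
    """All run outputs in memory: funnel, tables, recovery, manifest."""

    funnel: dict[str, int]
    stage1_records: list[CandidateRecord]
    decisions: list[ValidationDecision]
    combined_records: list[CandidateRecord]
    bonferroni_thresholds: dict[str, float]
    excluded_samples: list[tuple[SampleMeta, str]]
    design: dict[str, int]
    recovery: RecoveryReport | None
    manifest: dict


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _config_hash(d: dict) -> str:
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Nested sections ``screen``, ``qc``, ``synthetic`` and ``interactions``
    map onto the corresponding dataclasses; ``synthetic.planted`` rows map
    onto :class:`TruthRecord`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    screen = ScreenConfig(**{
        k: tuple(tuple(c) for c in v) if k == "contrasts" else
        (tuple(v) if k == "days" else v)
        for k, v in (raw.get("screen") or {}).items()
    })
    qc = QCThresholds(**(raw.get("qc") or {}))
    synth = None
    if "synthetic" in raw and raw["synthetic"] is not None:
        s = dict(raw["synthetic"])
        planted = tuple(TruthRecord(**t) for t in s.pop("planted", []))
        for key in ("baseline_ct_range", "planted_baseline_range"):
            if key in s:
                s[key] = tuple(s[key])
        s.setdefault("seed", raw.get("seed", 0))
        synth = SyntheticConfig(planted=planted, **s)
    inter = raw.get("interactions") or {}
    colmap = ColumnMap(**(inter.get("columns") or {}))
    return RunConfig(
        out_dir=raw.get("out", "run"),
        seed=raw.get("seed", 0),
        screen=screen,
        qc=qc,
        synthetic=synth,
        samples_path=raw.get("samples"),
        ct_path=raw.get("ct"),
        interactions_path=inter.get("path"),
        interaction_colmap=colmap,
        interaction_species=str(inter.get("species", "9606")),
        mrna_list=tuple(inter.get("mrnas", [])),
        mrna_directions=dict(inter.get("mrna_directions", {})),
        log_level=raw.get("log_level", "INFO"),
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full two-stage analysis and write all artifacts.

    Errors in any stage abort with the stage name and context attached.
    Identical config + seed produce byte-identical candidate tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    truths: list[TruthRecord] = []
    if config.synthetic is not None:
        samples, ctm, truths = generate_dataset(config.synthetic)
        write_samples(samples, out / "samples.tsv")
        write_ct_long(ctm, out / "ct_long.tsv")
        write_truth(truths, out / "truth.tsv")
    elif config.samples_path and config.ct_path:
        samples = read_samples(config.samples_path)
        ctm = read_ct_long(config.ct_path, samples)
    else:
        raise ValueError(
            "run_pipeline: either a synthetic config or samples+ct paths required"
        )

    # --- QC and stage split ----------------------------------------------
    kept, excluded = qc_filter_samples(samples, config.qc)
    for s, reason in excluded:
        logger.info("QC excluded %s (%s)", s.sample_id, reason)
    kept_ids = {s.sample_id for s in kept}
    samples1 = [s for s in kept if s.stage == "I"]
    samples2 = [s for s in kept if s.stage == "II"]
    if not samples1:
        raise ValueError("stage I: no samples after QC")

    # --- normalization (one pass over all cards) --------------------------
    mask = detect_calls(ctm, config.screen.ct_max)
    norm = median_normalize(ctm, mask)
    write_normalized(norm, out / "normalized.tsv")

    # --- funnel bookkeeping on stage-I samples -----------------------------
    s1_cols = [norm.sample_index(s.sample_id) for s in samples1]
    detected_any = {
        m for m in norm.mirna_ids if mask[norm.mirna_index(m), s1_cols].any()
    }
    det75: set[str] = set()
    for case_grade, ref_grade in config.screen.contrasts:
        cells = _cells_for_contrast(samples1, case_grade, ref_grade, config.screen.days)
        if any(len(v) == 0 for v in cells.values()):
            continue
        det75 |= detection_filter(norm.mask, norm, cells, config.screen.det_frac)
    det75 &= detected_any

    # --- stage I screen ----------------------------------------------------
    stage1_records: list[CandidateRecord] = []
    for case_grade, ref_grade in config.screen.contrasts:
        try:
            stage1_records.extend(
                screen_contrast(norm, samples1, config.screen, case_grade, ref_grade)
            )
        except ValueError as exc:
            raise ValueError(f"stage I screen, contrast {case_grade}: {exc}") from exc

    # --- stage II validation ----------------------------------------------
    decisions: list[ValidationDecision] = []
    if samples2:
        decisions = validate_candidates(
            stage1_records,
            norm,
            samples2,
            config.screen,
            stage1_sample_ids=[s.sample_id for s in samples1],
        )

    # --- Bonferroni flagging ----------------------------------------------
    # Contrasts with a validation arm: family = validated set (validation
    # figure).  Contrasts without one: family = screen-passing set (the
    # screening figure carries the correction there).
    thresholds: dict[str, float] = apply_bonferroni(decisions, config.screen.alpha)
    for case_grade, ref_grade in config.screen.contrasts:
        contrast = f"{case_grade} vs {ref_grade}"
        has_arm = any(d.contrast == contrast and d.validatable for d in decisions)
        if not has_arm:
            contrast_records = [r for r in stage1_records if r.contrast == contrast]
            thr = flag_bonferroni(contrast_records, config.screen.alpha)
            if thr is not None:
                thresholds[contrast + " (screen)"] = thr

    # --- combined analysis on validated candidates -------------------------
    validated_keys = {
        (d.mirna_id, d.contrast, d.day_set) for d in decisions if d.validated
    }
    validated_stage1 = [
        r
        for r in stage1_records
        if (r.mirna_id, r.contrast, r.day_set) in validated_keys
    ]
    combined_records: list[CandidateRecord] = []
    if validated_stage1:
        combined_records = combined_analysis(
            norm, samples1 + samples2, validated_stage1, config.screen
        )
        by_contrast: dict[str, list[CandidateRecord]] = {}
        for r in combined_records:
            by_contrast.setdefault(r.contrast, []).append(r)
        for contrast, recs in by_contrast.items():
            m = len({r.mirna_id for r in recs})
            thr = config.screen.alpha / m
            thresholds[contrast + " (combined)"] = thr
            for r in recs:
                r.bonferroni_pass = r.fit.p < thr

    # --- serialize tables ---------------------------------------------------
    stage2_records = [d.record for d in decisions if d.record is not None]
    all_records = stage1_records + stage2_records + combined_records
    write_candidates(all_records, out / "candidates.tsv")
    _write_decisions(decisions, out / "decisions.tsv")

    # --- interactions -------------------------------------------------------
    if config.interactions_path and config.mrna_list:
        candidate_mirnas = sorted(
            {r.mirna_id for r in stage1_records if r.passes_screen}
        )
        records = filter_interactions(
            config.interactions_path,
            candidate_mirnas,
            config.mrna_list,
            species=config.interaction_species,
            colmap=config.interaction_colmap,
        )
        mirna_dirs = _mirna_directions(stage1_records)
        records = [
            classify_reciprocity(r, mirna_dirs, config.mrna_directions)
            for r in records
        ]
        if records:
            export_graph(records, out / "interactions.graphml", "graphml")
            export_graph(records, out / "interactions.sif", "sif")

    # --- funnel, recovery, manifest ----------------------------------------
    screened_mirnas = {r.mirna_id for r in stage1_records if r.passes_screen}
    validated_mirnas = {d.mirna_id for d in decisions if d.validated}
    bonf_mirnas = {d.mirna_id for d in decisions if d.bonferroni_pass}
    if not any(d.validatable for d in decisions):
        # No validation arm at all: the funnel ends at the screen.
        validated_mirnas = set()
        bonf_mirnas = set()
    funnel = {
        "measured": len(norm.mirna_ids),
        "detected": len(detected_any),
        "detected_75pct": len(det75),
        "screened": len(screened_mirnas),
        "validated": len(validated_mirnas),
        "bonferroni_survivors": len(bonf_mirnas),
    }
    steps = list(funnel.values())
    assert all(a >= b for a, b in zip(steps, steps[1:])), "funnel must be monotone"

    recovery = (
        evaluate_recovery(truths, stage1_records, decisions, len(norm.mirna_ids))
        if truths
        else None
    )

    cfg_dict = _config_dict(config)
    manifest = {
        "package": "mirhars",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": _config_hash(cfg_dict),
        "n_samples_in": len(samples),
        "n_samples_qc_excluded": len(excluded),
        "funnel": funnel,
        "bonferroni_thresholds": thresholds,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    bundle = ReportBundle(
        funnel=funnel,
        stage1_records=stage1_records,
        decisions=decisions,
        combined_records=combined_records,
        bonferroni_thresholds=thresholds,
        excluded_samples=excluded,
        design=design_summary(samples),
        recovery=recovery,
        manifest=manifest,
    )
    with open(out / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(summarize_report(bundle))
    return bundle


def _mirna_directions(records: Sequence[CandidateRecord]) -> dict[str, str]:
    """Consensus direction per screen-passing miRNA (first passing record)."""
    dirs: dict[str, str] = {}
    for r in records:
        if r.passes_screen and r.mirna_id not in dirs and r.fc.direction != "flat":
            dirs[r.mirna_id] = r.fc.direction
    return dirs


def _write_decisions(decisions: Sequence[ValidationDecision], path: Path) -> None:
    cols = (
        "mirna_id",
        "contrast",
        "day_set",
        "validatable",
        "direction_match",
        "p_ok",
        "fc_ok",
        "conc_ok",
        "validated",
        "bonferroni_pass",
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in decisions:
            bp = "NA" if d.bonferroni_pass is None else str(d.bonferroni_pass).lower()
            fh.write(
                "\t".join(
                    [
                        d.mirna_id,
                        d.contrast,
                        d.day_set,
                        str(d.validatable).lower(),
                        str(d.direction_match).lower(),
                        str(d.p_ok).lower(),
                        str(d.fc_ok).lower(),
                        str(d.conc_ok).lower(),
                        str(d.validated).lower(),
                        bp,
                    ]
                )
                + "\n"
            )


def _format_record_row(r: CandidateRecord) -> str:
    c = r.comparison
    f = r.fit
    def fmt(v, spec=".3f"):
        return "NA" if v is None else format(v, spec)
    return (
        f"{r.mirna_id:<16} {r.day_set:<7} {r.stage:<9} "
        f"n={c.n_case if c else '?'}/{c.n_ref if c else '?'} "
        f"FC={r.fc.value:.1f} ({r.fc.direction}) "
        f"t_p={fmt(c.t_p if c else None)} "
        f"OR={fmt(f.or_value)} CI=[{fmt(f.ci_low)},{fmt(f.ci_high)}] "
        f"p={f.p:.4g} ({f.p_source}) conc={f.concordance:.2f}"
        + (" *" if r.bonferroni_pass else "")
    )


def summarize_report(bundle: ReportBundle) -> str:
    """Human-readable run summary: funnel, per-contrast tables, recovery."""
    lines: list[str] = []
    lines.append("== design ==")
    for k, v in bundle.design.items():
        lines.append(f"  {k}: {v}")
    lines.append("== eligibility funnel (miRNAs) ==")
    for step, n in bundle.funnel.items():
        lines.append(f"  {step}: {n}")
    if bundle.excluded_samples:
        lines.append("== QC-excluded samples ==")
        for s, reason in bundle.excluded_samples:
            lines.append(f"  {s.sample_id}: {reason}")

    passing = [r for r in bundle.stage1_records if r.passes_screen]
    lines.append(f"== stage I candidates ({len(passing)} records) ==")
    if not passing:
        lines.append("  zero candidates passed the screen")
    by_contrast: dict[str, list[CandidateRecord]] = {}
    for r in passing:
        by_contrast.setdefault(r.contrast, []).append(r)
    for contrast in sorted(by_contrast):
        lines.append(f"-- {contrast} --")
        for r in by_contrast[contrast]:
            lines.append("  " + _format_record_row(r))

    validated = [d for d in bundle.decisions if d.validated]
    lines.append(f"== stage II validation ({len(validated)} validated records) ==")
    for d in validated:
        assert d.record is not None
        lines.append("  " + _format_record_row(d.record))
    not_validatable = [d for d in bundle.decisions if not d.validatable]
    if not_validatable:
        mirnas = sorted({d.mirna_id for d in not_validatable})
        lines.append(
            f"  ({len(mirnas)} candidate miRNAs had no stage-II samples "
            "for their contrast and could not be validated)"
        )

    if bundle.combined_records:
        lines.append(
            f"== combined stages I+II ({len(bundle.combined_records)} records) =="
        )
        for r in bundle.combined_records:
            lines.append("  " + _format_record_row(r))

    if bundle.bonferroni_thresholds:
        lines.append("== Bonferroni thresholds (strict <) ==")
        for name, thr in sorted(bundle.bonferroni_thresholds.items()):
            lines.append(f"  {name}: {thr:.6f}")

    if bundle.recovery is not None:
        rec = bundle.recovery
        lines.append("== planted-truth recovery ==")
        lines.append(
            f"  recovered {rec.n_recovered}/{rec.n_planted} "
            f"(sensitivity {rec.sensitivity:.2f}); "
            f"validated false positives: {rec.false_positive_validated} "
            f"({100 * rec.false_positive_fraction:.1f}% of panel)"
        )
        for pattern, (hit, total) in sorted(rec.per_pattern.items()):
            lines.append(f"  {pattern}: {hit}/{total}")
    return "\n".join(lines) + "\n"
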