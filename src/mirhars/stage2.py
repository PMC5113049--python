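"""Stage-II independent validation, Bonferroni flagging, combined analysis.

Stage II re-measures the Stage-I candidates on a disjoint sample set.  A
candidate validates only when *all four* criteria hold on the Stage-II
samples — the conjunction, in contrast to the screen's disjunction:

* the fold-change direction matches Stage I (up stays up, down stays down),
* the group difference is significant (t-test p < alpha),
* |log2 FC| >= log2 fc_min (the two-fold rule again),
* concordance >= conc_min.

Candidates of a contrast with no Stage-II case samples at all (the H1-2
situation in the reference design, where every mild-HARS sample was spent
in the screen) are *not validatable*: they are excluded from the validation
Bonferroni family and keep their Stage-I-only status.

Multiple-comparison adjustment happens here, not at the screen: the
Bonferroni family of a contrast is its set of distinct validated miRNAs
(the per-figure convention, e.g. 15 validated candidates give a
0.05/15 ≈ 0.0033 threshold), compared with strict ``<``.

The combined analysis recomputes the same statistics on the pooled Stage
I + II samples; its Bonferroni family is the validated set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import SampleMeta
from .normalization import NormalizedMatrix, group_fold_change
from .stage1 import CandidateRecord, ScreenConfig, _build_record

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationDecision",
    "validate_candidates",
    "apply_bonferroni",
    "combined_analysis",
]

_DAY_SET_DAYS = {"day1": (1,), "day2": (2,), "merged": (1, 2)}


@dataclass
class ValidationDecision:
    """Outcome of re-testing one Stage-I candidate on Stage-II samples.

    ``validatable`` is False when the contrast has no Stage-II case samples;
    all criterion flags are then False and the decision is excluded from the
    Bonferroni family.  ``record`` carries the recomputed Stage-II
    statistics when available.
    """

    mirna_id: str
    contrast: str
    day_set: str
    validatable: bool
    direction_match: bool
    p_ok: bool
    fc_ok: bool
    conc_ok: bool
    validated: bool
    record: CandidateRecord | None = None
    bonferroni_pass: bool | None = None


def _case_grade(contrast: str) -> str:
    return contrast.split(" vs ")[0]


def _ref_grade(contrast: str) -> str:
    return contrast.split(" vs ")[1]


def validate_candidates(
    stage1_records: Sequence[CandidateRecord],
    norm_stage2: NormalizedMatrix,
    samples_stage2: Sequence[SampleMeta],
    config: ScreenConfig,
    stage1_sample_ids: Sequence[str] | None = None,
) -> list[ValidationDecision]:
    """Independently re-test every screen-passing candidate on Stage II.

    When ``stage1_sample_ids`` is given, disjointness of the two stages is
    asserted — the methodological independence of the validation depends on
    it.  Only records with ``passes_screen`` enter; each is recomputed on
    the Stage-II samples matching its grade and day set.
    """
    if stage1_sample_ids is not None:
        overlap = set(stage1_sample_ids) & {s.sample_id for s in samples_stage2}
        if overlap:
            raise ValueError(
                f"Stage I and Stage II sample sets overlap: {sorted(overlap)}"
            )

    decisions: list[ValidationDecision] = []
    for rec in stage1_records:
        if not rec.passes_screen:
            continue
        case_grade = _case_grade(rec.contrast)
        ref_grade = _ref_grade(rec.contrast)
        days = _DAY_SET_DAYS[rec.day_set]
        case_ids = [
            s.sample_id
            for s in samples_stage2
            if s.hars_grade == case_grade and s.day in days
        ]
        ref_ids = [
            s.sample_id for s in samples_stage2 if s.hars_grade == ref_grade
        ]
        if not case_ids:
            logger.info(
                "validation: %s %s %s has no Stage-II case samples; not validatable",
                rec.mirna_id,
                rec.contrast,
                rec.day_set,
            )
            decisions.append(
                ValidationDecision(
                    mirna_id=rec.mirna_id,
                    contrast=rec.contrast,
                    day_set=rec.day_set,
                    validatable=False,
                    direction_match=False,
                    p_ok=False,
                    fc_ok=False,
                    conc_ok=False,
                    validated=False,
                )
            )
            continue

        fc2 = group_fold_change(
            norm_stage2, case_ids, ref_ids, rec.mirna_id, fc_min=config.fc_min
        )
        rec2 = None
        if fc2 is not None:
            rec2 = _build_record(
                norm_stage2,
                rec.mirna_id,
                rec.contrast,
                rec.day_set,
                case_ids,
                ref_ids,
                fc2,
                config,
                stage="II",
            )
        if fc2 is None or rec2 is None:
            decisions.append(
                ValidationDecision(
                    mirna_id=rec.mirna_id,
                    contrast=rec.contrast,
                    day_set=rec.day_set,
                    validatable=True,
                    direction_match=False,
                    p_ok=False,
                    fc_ok=False,
                    conc_ok=False,
                    validated=False,
                )
            )
            continue

        direction_match = (
            fc2.direction == rec.fc.direction and rec.fc.direction != "flat"
        )
        p_ok = rec2.comparison is not None and rec2.comparison.t_p < config.alpha
        fc_ok = abs(fc2.log2) >= float(np.log2(config.fc_min))
        conc_ok = rec2.fit.concordance >= config.conc_min
        validated = bool(direction_match and p_ok and fc_ok and conc_ok)
        rec2.passes_validation = validated
        decisions.append(
            ValidationDecision(
                mirna_id=rec.mirna_id,
                contrast=rec.contrast,
                day_set=rec.day_set,
                validatable=True,
                direction_match=direction_match,
                p_ok=bool(p_ok),
                fc_ok=bool(fc_ok),
                conc_ok=bool(conc_ok),
                validated=validated,
                record=rec2,
            )
        )
    return decisions


def apply_bonferroni(
    decisions: Sequence[ValidationDecision], alpha: float = 0.05
) -> dict[str, float]:
    """Flag Bonferroni survivors among validated decisions, per contrast.

    The family of a contrast is its set of distinct *validated* miRNAs; each
    validated decision is flagged by strict ``p < alpha/m`` on the reported
    (Wald or fallback) p of its Stage-II fit.  Returns the per-contrast
    thresholds.  An empty family is a warned no-op.
    """
    thresholds: dict[str, float] = {}
    contrasts = sorted({d.contrast for d in decisions})
    for contrast in contrasts:
        validated = [d for d in decisions if d.contrast == contrast and d.validated]
        family = sorted({d.mirna_id for d in validated})
        if not family:
            logger.warning(
                "apply_bonferroni: no validated candidates for %s", contrast
            )
            continue
        threshold = alpha / len(family)
        thresholds[contrast] = threshold
        for d in validated:
            assert d.record is not None
            d.bonferroni_pass = d.record.fit.p < threshold
            d.record.bonferroni_pass = d.bonferroni_pass
    return thresholds


def combined_analysis(
    norm_all: NormalizedMatrix,
    samples_all: Sequence[SampleMeta],
    candidates: Sequence[CandidateRecord],
    config: ScreenConfig,
) -> list[CandidateRecord]:
    """Recompute candidate statistics on the pooled Stage I + II samples.

    Each input candidate (miRNA, contrast, day set) is re-evaluated against
    the full H0 reference and full case day cells; the returned records are
    flagged ``stage="combined"``.  Candidates not evaluable on the pooled
    set (no detected values in a group) are skipped with a log entry.
    """
    out: list[CandidateRecord] = []
    for rec in candidates:
        case_grade = _case_grade(rec.contrast)
        ref_grade = _ref_grade(rec.contrast)
        days = _DAY_SET_DAYS[rec.day_set]
        case_ids = [
            s.sample_id
            for s in samples_all
            if s.hars_grade == case_grade and s.day in days
        ]
        ref_ids = [s.sample_id for s in samples_all if s.hars_grade == ref_grade]
        fc = group_fold_change(
            norm_all, case_ids, ref_ids, rec.mirna_id, fc_min=config.fc_min
        )
        if fc is None:
            logger.info(
                "combined: %s %s %s not evaluable on pooled samples",
                rec.mirna_id,
                rec.contrast,
                rec.day_set,
            )
            continue
        rec_c = _build_record(
            norm_all,
            rec.mirna_id,
            rec.contrast,
            rec.day_set,
            case_ids,
            ref_ids,
            fc,
            config,
            stage="combined",
        )
        if rec_c is not None:
            out.append(rec_c)
    return out
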