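"""Stage-I eligibility funnel: detection filter, contrasts, candidate screen.

A miRNA enters a contrast (H1-2 vs H0 or H2-3 vs H0) only if it is detected
in at least ``det_frac`` (default 75%) of the samples of *every* group×day
cell participating in the contrast — the H0 cell and each post-exposure day
cell of the case grade.  Cell-wise enforcement is the stricter, internally
consistent reading of the per-group detection rule.

A surviving miRNA becomes a candidate for a day set when

    (|log2 FC| >= log2 fc_min)  AND  (t-test p < alpha  OR  concordance >= conc_min)

— note the disjunction between the significance and concordance gates at
screening; validation later requires the conjunction of all criteria.  No
multiple-testing correction is applied at this exploratory stage.

Day handling: each candidate is assessed on day 1 and day 2 separately; when
the two single-day fold changes share a direction the two case days are
merged into one pooled category and analyzed together as the ``merged`` day
set.  Samples from the same animal on days 1 and 2 are treated as
independent observations (a documented limitation; no mixed-effects
correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_io import SampleMeta
from .normalization import (
    DEFAULT_CT_MAX,
    DEFAULT_FC_MIN,
    FoldChange,
    NormalizedMatrix,
    group_fold_change,
)
from .stats_models import GroupComparison, LogisticFit, fit_logistic, students_t_test

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "CandidateRecord",
    "detection_filter",
    "merge_days",
    "screen_contrast",
    "screen_all",
    "flag_bonferroni",
]

DAY_SET_ORDER = ("day1", "day2", "merged")


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable thresholds of the eligibility funnel.

    * ``ct_max`` — upper limit of the linear-dynamic range (cycles).
    * ``det_frac`` — minimum detected fraction per group×day cell.
    * ``fc_min`` — differential-expression bound on the linear FC scale.
    * ``alpha`` — nominal significance level of the t-test gate.
    * ``conc_min`` — minimum concordance for the alternative gate.
    * ``contrasts`` — (case grade, reference grade) pairs; reference is H0.
    """

    ct_max: float = DEFAULT_CT_MAX
    det_frac: float = 0.75
    fc_min: float = DEFAULT_FC_MIN
    alpha: float = 0.05
    conc_min: float = 0.75
    contrasts: tuple[tuple[str, str], ...] = (("H1-2", "H0"), ("H2-3", "H0"))
    days: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if not (0 < self.det_frac <= 1):
            raise ValueError("det_frac must be in (0, 1]")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.5 <= self.conc_min <= 1):
            raise ValueError("conc_min must be in [0.5, 1]")


@dataclass
class CandidateRecord:
    """Per-miRNA, per-contrast, per-day-set statistics and pass flags.

    ``comparison`` is None when a group is too small for a t-test (fewer
    than two detected values); the screen then rests on the concordance
    gate alone.  ``passes_validation`` and ``bonferroni_pass`` stay None
    until the corresponding later stage fills them.
    """

    mirna_id: str
    contrast: str
    day_set: str
    fc: FoldChange
    comparison: GroupComparison | None
    fit: LogisticFit
    passes_screen: bool
    stage: str = "I"
    passes_validation: bool | None = None
    bonferroni_pass: bool | None = None


def _cells_for_contrast(
    samples: Sequence[SampleMeta], case_grade: str, ref_grade: str, days: Sequence[int]
) -> dict[str, list[str]]:
    """Group×day cells entering a contrast, as name -> sample-id list."""
    cells: dict[str, list[str]] = {
        f"{ref_grade}/day0": [
            s.sample_id for s in samples if s.hars_grade == ref_grade
        ]
    }
    for d in days:
        cells[f"{case_grade}/day{d}"] = [
            s.sample_id
            for s in samples
            if s.hars_grade == case_grade and s.day == d
        ]
    return cells


def detection_filter(
    mask: np.ndarray,
    norm_or_ct,
    cells: Mapping[str, Sequence[str]],
    det_frac: float = 0.75,
) -> set[str]:
    """miRNAs detected in at least ``det_frac`` of samples of every cell.

    ``norm_or_ct`` supplies id -> index lookups (a CTMatrix or
    NormalizedMatrix).  The bound is inclusive: 3 of 4 detected passes a
    75% requirement.  An empty cell raises, naming the cell — the contrast
    cannot be evaluated at all then.
    """
    for name, ids in cells.items():
        if len(ids) == 0:
            raise ValueError(f"detection filter: cell {name!r} has no samples")
    kept: set[str] = set()
    col_idx = {
        name: [norm_or_ct.sample_index(s) for s in ids] for name, ids in cells.items()
    }
    for mid in norm_or_ct.mirna_ids:
        i = norm_or_ct.mirna_index(mid)
        ok = True
        for cols in col_idx.values():
            frac = float(np.mean(mask[i, cols]))
            if frac < det_frac:
                ok = False
                break
        if ok:
            kept.add(mid)
    return kept


def merge_days(fc_day1: FoldChange | None, fc_day2: FoldChange | None) -> bool:
    """True iff both day fold-changes are evaluable and share a non-flat direction."""
    if fc_day1 is None or fc_day2 is None:
        return False
    return fc_day1.direction == fc_day2.direction and fc_day1.direction != "flat"


def _passes_screen(
    fc: FoldChange,
    comparison: GroupComparison | None,
    fit: LogisticFit,
    config: ScreenConfig,
) -> bool:
    fc_gate = abs(fc.log2) >= np.log2(config.fc_min)
    t_gate = comparison is not None and comparison.t_p < config.alpha
    conc_gate = fit.concordance >= config.conc_min
    return bool(fc_gate and (t_gate or conc_gate))


def _build_record(
    norm: NormalizedMatrix,
    mirna_id: str,
    contrast: str,
    day_set: str,
    case_ids: Sequence[str],
    ref_ids: Sequence[str],
    fc: FoldChange,
    config: ScreenConfig,
    stage: str = "I",
) -> CandidateRecord | None:
    case = norm.values_for(mirna_id, case_ids)
    ref = norm.values_for(mirna_id, ref_ids)
    if case.size == 0 or ref.size == 0:
        return None
    comparison: GroupComparison | None = None
    if case.size >= 2 and ref.size >= 2:
        comparison = students_t_test(case, ref)
    x = np.concatenate([case, ref])
    y = np.concatenate([np.ones(case.size, dtype=int), np.zeros(ref.size, dtype=int)])
    fit = fit_logistic(x, y)
    return CandidateRecord(
        mirna_id=mirna_id,
        contrast=contrast,
        day_set=day_set,
        fc=fc,
        comparison=comparison,
        fit=fit,
        passes_screen=_passes_screen(fc, comparison, fit, config),
        stage=stage,
    )


def screen_contrast(
    norm: NormalizedMatrix,
    samples: Sequence[SampleMeta],
    config: ScreenConfig,
    case_grade: str,
    ref_grade: str = "H0",
) -> list[CandidateRecord]:
    """Run the Stage-I screen of one contrast over all eligible miRNAs.

    For each miRNA surviving the detection filter, fold change, t-test and
    logistic fit are computed per day and, when both day fold-changes agree
    in direction, for the merged (pooled days) case group.  Records are
    ordered by miRNA id, then day1/day2/merged.  miRNAs whose fold change is
    not evaluable on a day yield no record for that day set (logged).
    """
    cells = _cells_for_contrast(samples, case_grade, ref_grade, config.days)
    ref_ids = cells[f"{ref_grade}/day0"]
    survivors = detection_filter(norm.mask, norm, cells, config.det_frac)
    contrast = f"{case_grade} vs {ref_grade}"

    records: list[CandidateRecord] = []
    for mid in sorted(survivors):
        day_fcs: dict[int, FoldChange | None] = {}
        day_case_ids: dict[int, list[str]] = {}
        for d in config.days:
            case_ids = cells[f"{case_grade}/day{d}"]
            day_case_ids[d] = list(case_ids)
            day_fcs[d] = group_fold_change(
                norm, case_ids, ref_ids, mid, fc_min=config.fc_min
            )
        for d in config.days:
            fc = day_fcs[d]
            if fc is None:
                logger.info(
                    "screen %s: %s day%d not evaluable (no detected values)",
                    contrast,
                    mid,
                    d,
                )
                continue
            rec = _build_record(
                norm, mid, contrast, f"day{d}", day_case_ids[d], ref_ids, fc, config
            )
            if rec is not None:
                records.append(rec)
        if len(config.days) == 2 and merge_days(
            day_fcs[config.days[0]], day_fcs[config.days[1]]
        ):
            merged_ids = day_case_ids[config.days[0]] + day_case_ids[config.days[1]]
            fc = group_fold_change(norm, merged_ids, ref_ids, mid, fc_min=config.fc_min)
            if fc is not None:
                rec = _build_record(
                    norm, mid, contrast, "merged", merged_ids, ref_ids, fc, config
                )
                if rec is not None:
                    records.append(rec)

    order = {ds: k for k, ds in enumerate(DAY_SET_ORDER)}
    records.sort(key=lambda r: (r.mirna_id, order[r.day_set]))
    return records


def screen_all(
    norm: NormalizedMatrix,
    samples: Sequence[SampleMeta],
    config: ScreenConfig,
) -> list[CandidateRecord]:
    """Screen every configured contrast; concatenated, per-contrast ordered."""
    records: list[CandidateRecord] = []
    for case_grade, ref_grade in config.contrasts:
        records.extend(screen_contrast(norm, samples, config, case_grade, ref_grade))
    return records


def flag_bonferroni(
    records: Sequence[CandidateRecord], alpha: float = 0.05
) -> float | None:
    """Bonferroni-flag a family of screen-passing records of one contrast.

    The family size is the number of *distinct miRNAs* passing the screen
    (hypotheses are counted per miRNA, matching the per-figure convention:
    20 candidates give a 0.05/20 = 0.0025 threshold).  Each passing record
    is flagged by strict ``p < alpha/m`` on its reported p.  Returns the
    threshold, or None for an empty family (no-op, warned).
    """
    passing = [r for r in records if r.passes_screen]
    family = sorted({r.mirna_id for r in passing})
    if not family:
        logger.warning("flag_bonferroni: empty family, nothing to flag")
        return None
    threshold = alpha / len(family)
    for r in passing:
        r.bonferroni_pass = r.fit.p < threshold
    return threshold
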