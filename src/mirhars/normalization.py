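"""Detection calls, per-card median ΔCT normalization and fold changes.

A qPCR reaction is *detected* (within the linear-dynamic range of the assay)
when its threshold cycle satisfies CT <= ct_max (default 30, inclusive).
Normalization subtracts, from every well of a card run, the median CT of the
detected wells on that same card run — the ΔCT approach with the card median
as reference.  This removes per-card level shifts exactly and was preferred
over a housekeeping-miRNA reference; housekeeping normalization is a
non-goal here.

Fold changes follow the ΔΔCT convention: lower CT means more transcript, so

    log2 FC = mean ΔCT(reference) − mean ΔCT(case),    FC = 2 ** log2FC.

A case group whose ΔCT lies above the reference therefore yields FC < 1,
i.e. down-regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import CTMatrix

__all__ = [
    "detect_calls",
    "NormalizedMatrix",
    "median_normalize",
    "FoldChange",
    "group_fold_change",
    "write_normalized",
]

#: Default upper limit of the linear-dynamic range (threshold cycles).
DEFAULT_CT_MAX = 30.0

#: Default fold-change bound: |FC| >= 2 (or <= 0.5) counts as differential.
DEFAULT_FC_MIN = 2.0


def detect_calls(ctm: CTMatrix, ct_max: float = DEFAULT_CT_MAX) -> np.ndarray:
    """Boolean detection mask aligned to ``ctm.ct``.

    A cell is True iff its CT is present (finite) and CT <= ct_max.  The
    bound is inclusive: CT exactly at the limit is still within the dynamic
    range.
    """
    if not math.isfinite(ct_max):
        raise ValueError("ct_max must be finite")
    with np.errstate(invalid="ignore"):
        return np.isfinite(ctm.ct) & (ctm.ct <= ct_max)


@dataclass
class NormalizedMatrix:
    """Per-card median-centered ΔCT values plus the detection mask.

    ``dct[i, j]`` is CT minus the median detected CT of the card run that
    produced the well; NaN where the well was undetected.  ``card_medians``
    records the subtracted median per card run id.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    dct: np.ndarray
    mask: np.ndarray
    card_medians: dict[str, float]

    def __post_init__(self) -> None:
        self._mirna_index = {m: i for i, m in enumerate(self.mirna_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    def mirna_index(self, mirna_id: str) -> int:
        return self._mirna_index[mirna_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def values_for(
        self, mirna_id: str, sample_ids: Sequence[str], detected_only: bool = True
    ) -> np.ndarray:
        """ΔCT values of one miRNA over the given samples.

        With ``detected_only`` (default) undetected cells are dropped
        (complete-case analysis); otherwise NaNs are returned in place.
        """
        i = self._mirna_index[mirna_id]
        cols = [self._sample_index[s] for s in sample_ids]
        vals = self.dct[i, cols]
        if detected_only:
            det = self.mask[i, cols]
            return vals[det]
        return vals


def median_normalize(
    ctm: CTMatrix,
    mask: np.ndarray,
    impute_at: float | None = None,
) -> NormalizedMatrix:
    """Subtract the per-card-run median of detected CTs from every well.

    The median is computed over *detected* wells only — censored CTs are not
    measurements (an all-wells switch would be the main alternative; the
    detected-only reading is exposed as the fixed behaviour and documented).
    Even-count medians use the mean of the two central values.

    After normalization the median of detected ΔCT values on every card run
    is zero to within floating-point error, and adding any constant to all
    wells of one card run leaves ΔCT unchanged.

    ``impute_at`` optionally fills *undetected* cells with
    ``impute_at − card median`` (a censor-at-limit value) instead of NaN;
    the mask still marks them undetected so complete-case consumers ignore
    them.  Off by default: no imputation rule is part of the core method.

    Raises :class:`ValueError` naming the card run if a card has no detected
    wells at all.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ctm.ct.shape:
        raise ValueError("mask shape does not match CT matrix")

    dct = np.full_like(ctm.ct, np.nan)
    card_medians: dict[str, float] = {}

    # Group rows by card type once; each (sample, card type) pair is one run.
    rows_by_type: dict[str, np.ndarray] = {}
    for ctype in sorted({ctm.card_of[m] for m in ctm.mirna_ids}):
        rows_by_type[ctype] = np.array(
            [i for i, m in enumerate(ctm.mirna_ids) if ctm.card_of[m] == ctype]
        )

    for j, sid in enumerate(ctm.sample_ids):
        for ctype, rows in rows_by_type.items():
            inst = ctm.card_instance.get((sid, ctype))
            if inst is None:
                continue
            col_mask = mask[rows, j]
            detected = ctm.ct[rows, j][col_mask]
            if detected.size == 0:
                raise ValueError(
                    f"card run {inst!r} (sample {sid!r}, card {ctype}) has no "
                    "detected wells; cannot normalize"
                )
            med = float(np.median(detected))
            card_medians[inst] = med
            vals = ctm.ct[rows, j] - med
            if impute_at is None:
                vals = np.where(col_mask, vals, np.nan)
            else:
                vals = np.where(col_mask, vals, impute_at - med)
            dct[rows, j] = vals

    return NormalizedMatrix(
        mirna_ids=list(ctm.mirna_ids),
        sample_ids=list(ctm.sample_ids),
        dct=dct,
        mask=mask,
        card_medians=card_medians,
    )


@dataclass(frozen=True)
class FoldChange:
    """Linear-scale expression ratio of case over reference.

    ``direction`` is ``up`` when value >= fc_min, ``down`` when
    value <= 1/fc_min, else ``flat`` (fc_min defaults to 2: only two-fold
    ratios, >=2 or <=0.5, count as differential expression).
    """

    value: float
    log2: float
    direction: str

    @classmethod
    def from_log2(cls, log2: float, fc_min: float = DEFAULT_FC_MIN) -> "FoldChange":
        if fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        value = 2.0 ** log2
        if value >= fc_min:
            direction = "up"
        elif value <= 1.0 / fc_min:
            direction = "down"
        else:
            direction = "flat"
        return cls(value=value, log2=log2, direction=direction)


def group_fold_change(
    norm: NormalizedMatrix,
    case_samples: Sequence[str],
    ref_samples: Sequence[str],
    mirna_id: str,
    fc_min: float = DEFAULT_FC_MIN,
) -> FoldChange | None:
    """Group fold change of one miRNA, case vs reference, on the ΔΔCT scale.

    Means are taken over detected values only (complete case).  Returns
    ``None`` ("not evaluable") when either group has no detected value —
    deliberately not an exception, since undetectable miRNAs are routine.
    """
    case = norm.values_for(mirna_id, case_samples)
    ref = norm.values_for(mirna_id, ref_samples)
    if case.size == 0 or ref.size == 0:
        return None
    log2 = float(np.mean(ref) - np.mean(case))
    return FoldChange.from_log2(log2, fc_min=fc_min)


def write_normalized(norm: NormalizedMatrix, path: str | Path) -> None:
    """Export ΔCT values as TSV: sample_id, mirna_id, dct, detected."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tmirna_id\tdct\tdetected\n")
        for i, mid in enumerate(norm.mirna_ids):
            for j, sid in enumerate(norm.sample_ids):
                det = bool(norm.mask[i, j])
                v = norm.dct[i, j]
                raw = "" if math.isnan(v) else format(v, ".6f")
                fh.write(f"{sid}\t{mid}\t{raw}\t{'true' if det else 'false'}\n")
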