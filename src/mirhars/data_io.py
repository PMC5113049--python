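"""Reading and writing of sample metadata, raw CT tables and candidate tables.

The canonical on-disk formats are tab-separated UTF-8 text with a mandatory
header row:

* ``samples.tsv`` — one row per blood sample:
  ``sample_id  animal_id  day  hars  stage  dose_gy  rin  a260_280``
* ``ct_long.tsv`` — one row per well in long ("tidy") layout:
  ``sample_id  card_instance  card_type  mirna_id  ct``
  where ``ct`` is a threshold-cycle value or ``Undetermined`` (case-insensitive;
  an empty cell means the same) for reactions that never crossed threshold.
* ``candidates.tsv`` — the serialized per-miRNA statistics (see
  :func:`write_candidates`).

Long TSV was chosen over vendor 384-well plate exports deliberately: it is
instrument-agnostic and diff-friendly.  A plate-layout importer is out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .stage1 import CandidateRecord

__all__ = [
    "HARS_GRADES",
    "STAGES",
    "CARD_TYPES",
    "SampleMeta",
    "QCThresholds",
    "CTMatrix",
    "read_samples",
    "write_samples",
    "qc_filter_samples",
    "read_ct_long",
    "write_ct_long",
    "write_candidates",
    "CANDIDATE_COLUMNS",
]

#: HARS severity grades used in this design: H0 (unexposed reference),
#: mild (H1-2) and more severe (H2-3) hematologic acute radiation syndrome.
HARS_GRADES = ("H0", "H1-2", "H2-3")
STAGES = ("I", "II")
CARD_TYPES = ("A", "B")

SAMPLE_COLUMNS = (
    "sample_id",
    "animal_id",
    "day",
    "hars",
    "stage",
    "dose_gy",
    "rin",
    "a260_280",
)

CT_COLUMNS = ("sample_id", "card_instance", "card_type", "mirna_id", "ct")


@dataclass(frozen=True)
class SampleMeta:
    """Identity, design cell and RNA quality metrics of one blood sample.

    ``day`` is days post-exposure (0 = pre-exposure draw, which by design is
    the H0 reference).  ``equivalent_dose_gy`` is the whole-body equivalent
    dose in Gy; heterogeneous (partial-body) exposures are summarized on this
    scale.  ``rin`` is the RNA integrity number and ``a260_280`` the
    spectrophotometric absorbance ratio; either may be NaN when unmeasured.
    """

    sample_id: str
    animal_id: str
    day: int
    hars_grade: str
    stage: str
    equivalent_dose_gy: float
    rin: float
    a260_280: float

    def __post_init__(self) -> None:
        if self.hars_grade not in HARS_GRADES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown HARS grade {self.hars_grade!r}; "
                f"expected one of {HARS_GRADES}"
            )
        if self.stage not in STAGES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown stage {self.stage!r}; "
                f"expected one of {STAGES}"
            )
        if self.day not in (0, 1, 2):
            raise ValueError(
                f"sample {self.sample_id!r}: day must be 0, 1 or 2, got {self.day}"
            )
        # Pre-exposure draws define the unexposed reference and vice versa.
        if (self.day == 0) != (self.hars_grade == "H0"):
            raise ValueError(
                f"sample {self.sample_id!r}: day 0 if and only if grade H0 "
                f"(got day={self.day}, grade={self.hars_grade})"
            )
        if not (self.equivalent_dose_gy >= 0 or math.isnan(self.equivalent_dose_gy)):
            raise ValueError(
                f"sample {self.sample_id!r}: negative dose {self.equivalent_dose_gy}"
            )


@dataclass(frozen=True)
class QCThresholds:
    """Sample-level RNA quality gates.

    Defaults are the qRT-PCR acceptance bounds: absorbance ratio
    A260/A280 >= 2.0 and RIN >= 7.3 (the stricter 7.5 bound applies to
    microarray work only and is not the default here).  Both bounds are
    inclusive.
    """

    min_a260_280: float = 2.0
    min_rin: float = 7.3

    def __post_init__(self) -> None:
        if self.min_a260_280 <= 0 or self.min_rin <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class CTMatrix:
    """Dense raw threshold-cycle matrix, miRNAs x samples.

    ``ct[i, j]`` is the CT of miRNA ``mirna_ids[i]`` in sample
    ``sample_ids[j]``; NaN marks a missing / Undetermined reaction.  Each
    miRNA is assayed on exactly one low-density-array card type (A or B);
    ``card_instance`` maps a (sample, card type) pair to the physical card
    run identifier, which is the normalization unit.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    ct: np.ndarray
    card_of: dict[str, str]
    card_instance: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValueError(
                f"ct shape {self.ct.shape} does not match "
                f"({len(self.mirna_ids)}, {len(self.sample_ids)})"
            )
        for m in self.mirna_ids:
            if self.card_of.get(m) not in CARD_TYPES:
                raise ValueError(f"miRNA {m!r} has no valid card type assignment")
        self._mirna_index = {m: i for i, m in enumerate(self.mirna_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    def mirna_index(self, mirna_id: str) -> int:
        return self._mirna_index[mirna_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]


def read_samples(path: str | Path) -> list[SampleMeta]:
    """Read a sample-metadata TSV into a list of :class:`SampleMeta`.

    Row order of the file is preserved.  Unknown HARS labels, unknown stages,
    impossible days and duplicated sample ids raise :class:`ValueError`
    naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    samples: list[SampleMeta] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        sid = row.sample_id
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r} at row {idx + 2}")
        seen.add(sid)
        try:
            sm = SampleMeta(
                sample_id=sid,
                animal_id=row.animal_id,
                day=int(row.day),
                hars_grade=row.hars,
                stage=row.stage,
                equivalent_dose_gy=float(row.dose_gy) if row.dose_gy else math.nan,
                rin=float(row.rin) if row.rin else math.nan,
                a260_280=float(row.a260_280) if row.a260_280 else math.nan,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
        samples.append(sm)
    return samples


def write_samples(samples: Sequence[SampleMeta], path: str | Path) -> None:
    """Write metadata back out in the canonical TSV layout (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SAMPLE_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                "\t".join(
                    [
                        s.sample_id,
                        s.animal_id,
                        str(s.day),
                        s.hars_grade,
                        s.stage,
                        _fmt_float(s.equivalent_dose_gy),
                        _fmt_float(s.rin),
                        _fmt_float(s.a260_280),
                    ]
                )
                + "\n"
            )


def _fmt_float(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))  # shortest representation that round-trips exactly


def qc_filter_samples(
    samples: Sequence[SampleMeta],
    thresholds: QCThresholds = QCThresholds(),
    exclude_missing: bool = True,
) -> tuple[list[SampleMeta], list[tuple[SampleMeta, str]]]:
    """Partition samples into (kept, excluded-with-reason) by RNA quality.

    A sample is kept when ``rin >= min_rin`` and ``a260_280 >= min_a260_280``
    (inclusive bounds).  A missing metric excludes the sample by default —
    conservative for a screening design — unless ``exclude_missing=False``,
    in which case a missing metric counts as passing.

    The two returned lists always partition the input: no sample is dropped
    silently.
    """
    kept: list[SampleMeta] = []
    excluded: list[tuple[SampleMeta, str]] = []
    for s in samples:
        reasons: list[str] = []
        for name, value, bound in (
            ("rin", s.rin, thresholds.min_rin),
            ("a260_280", s.a260_280, thresholds.min_a260_280),
        ):
            if math.isnan(value):
                if exclude_missing:
                    reasons.append(f"missing:{name}")
            elif value < bound:
                reasons.append(name)
        if reasons:
            excluded.append((s, ",".join(reasons)))
        else:
            kept.append(s)
    return kept, excluded


def _parse_ct(raw: str) -> float:
    raw = raw.strip()
    if raw == "" or raw.lower() == "undetermined":
        return math.nan
    return float(raw)


def read_ct_long(path: str | Path, samples: Sequence[SampleMeta]) -> CTMatrix:
    """Read a long-format CT table into a dense :class:`CTMatrix`.

    miRNA row order follows first appearance in the file; sample column order
    follows the metadata.  Cells absent from the file are missing (NaN), as
    are ``Undetermined`` wells.  A sample id not present in the metadata, a
    miRNA listed on both card types, or the same (sample, miRNA) cell listed
    twice with conflicting CT values all raise :class:`ValueError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    known = {s.sample_id for s in samples}
    sample_ids = [s.sample_id for s in samples]

    mirna_ids: list[str] = []
    card_of: dict[str, str] = {}
    card_instance: dict[tuple[str, str], str] = {}
    cells: dict[tuple[str, str], float] = {}

    for idx, row in enumerate(df.itertuples(index=False)):
        sid, inst, ctype, mid, raw = (
            row.sample_id,
            row.card_instance,
            row.card_type,
            row.mirna_id,
            row.ct,
        )
        if sid not in known:
            raise ValueError(
                f"{path}: row {idx + 2}: sample_id {sid!r} not in metadata"
            )
        if ctype not in CARD_TYPES:
            raise ValueError(
                f"{path}: row {idx + 2}: card_type {ctype!r} must be one of {CARD_TYPES}"
            )
        prev_type = card_of.get(mid)
        if prev_type is None:
            card_of[mid] = ctype
            mirna_ids.append(mid)
        elif prev_type != ctype:
            raise ValueError(
                f"{path}: miRNA {mid!r} listed on both card types "
                f"({prev_type} and {ctype})"
            )
        key = (sid, ctype)
        prev_inst = card_instance.get(key)
        if prev_inst is None:
            card_instance[key] = inst
        elif prev_inst != inst:
            raise ValueError(
                f"{path}: sample {sid!r} card {ctype} has two run ids "
                f"({prev_inst!r} and {inst!r})"
            )
        value = _parse_ct(raw)
        cell = (sid, mid)
        if cell in cells:
            prev = cells[cell]
            same = (math.isnan(prev) and math.isnan(value)) or prev == value
            if not same:
                raise ValueError(
                    f"{path}: duplicate cell (sample {sid!r}, miRNA {mid!r}) "
                    f"with conflicting CT values {prev} and {value}"
                )
        cells[cell] = value

    ct = np.full((len(mirna_ids), len(sample_ids)), np.nan)
    mi = {m: i for i, m in enumerate(mirna_ids)}
    sj = {s: j for j, s in enumerate(sample_ids)}
    for (sid, mid), value in cells.items():
        ct[mi[mid], sj[sid]] = value
    return CTMatrix(
        mirna_ids=mirna_ids,
        sample_ids=sample_ids,
        ct=ct,
        card_of=card_of,
        card_instance=card_instance,
    )


def write_ct_long(ctm: CTMatrix, path: str | Path) -> None:
    """Write a :class:`CTMatrix` in the canonical long TSV layout.

    NaN cells whose (sample, card) pair has a card run id are emitted as
    ``Undetermined``; cells on cards that were never run for a sample are
    omitted entirely, so read -> write -> read is the identity.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CT_COLUMNS) + "\n")
        for i, mid in enumerate(ctm.mirna_ids):
            ctype = ctm.card_of[mid]
            for j, sid in enumerate(ctm.sample_ids):
                inst = ctm.card_instance.get((sid, ctype))
                if inst is None:
                    continue
                v = ctm.ct[i, j]
                raw = "Undetermined" if math.isnan(v) else repr(float(v))
                fh.write(f"{sid}\t{inst}\t{ctype}\t{mid}\t{raw}\n")


# Fixed column order of candidates.tsv.  Fold changes render at one decimal
# (the display convention of the summary tables); all other floats at four.
CANDIDATE_COLUMNS = (
    "mirna_id",
    "contrast",
    "day_set",
    "stage",
    "n_case",
    "n_ref",
    "mean_case",
    "mean_ref",
    "sd_case",
    "sd_ref",
    "min",
    "max",
    "fc",
    "log2_fc",
    "direction",
    "t_stat",
    "t_p",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "p",
    "p_source",
    "concordance",
    "separated",
    "passes_screen",
    "passes_validation",
    "bonferroni_pass",
)


def _cell(value, fmt: str | None = None) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if fmt is not None:
        return format(value, fmt)
    return str(value)


def write_candidates(records: Iterable["CandidateRecord"], path: str | Path) -> None:
    """Serialize candidate records to TSV with a fixed, documented schema."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for r in records:
            cmp_ = r.comparison
            fit = r.fit
            row = [
                _cell(r.mirna_id),
                _cell(r.contrast),
                _cell(r.day_set),
                _cell(r.stage),
                _cell(cmp_.n_case if cmp_ else None),
                _cell(cmp_.n_ref if cmp_ else None),
                _cell(cmp_.mean_case if cmp_ else None, ".4f"),
                _cell(cmp_.mean_ref if cmp_ else None, ".4f"),
                _cell(cmp_.sd_case if cmp_ else None, ".4f"),
                _cell(cmp_.sd_ref if cmp_ else None, ".4f"),
                _cell(cmp_.minimum if cmp_ else None, ".4f"),
                _cell(cmp_.maximum if cmp_ else None, ".4f"),
                _cell(r.fc.value if r.fc else None, ".1f"),
                _cell(r.fc.log2 if r.fc else None, ".4f"),
                _cell(r.fc.direction if r.fc else None),
                _cell(cmp_.t_stat if cmp_ else None, ".4f"),
                _cell(cmp_.t_p if cmp_ else None, ".4f"),
                _cell(fit.or_value if fit else None, ".4f"),
                _cell(fit.ci_low if fit else None, ".4f"),
                _cell(fit.ci_high if fit else None, ".4f"),
                _cell(fit.p if fit else None, ".4f"),
                _cell(fit.p_source if fit else None),
                _cell(fit.concordance if fit else None, ".4f"),
                _cell(fit.separated if fit else None),
                _cell(r.passes_screen),
                _cell(r.passes_validation),
                _cell(r.bonferroni_pass),
            ]
            fh.write("\t".join(row) + "\n")
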