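"""Synthetic qPCR datasets with the structure the analysis assumes.

The generator emulates the two-card low-density-array design: 667 miRNA
species split over card types A and B, blood samples laid out on the
two-stage screening/validation grid, per-card-run level shifts, well-level
noise, and right-censoring of reactions beyond the dynamic range
(CT > ct_max is emitted as ``Undetermined``).

The default design grid reproduces the reference study's sample table:

    Stage I  (screen):    H0 day0 n=5;  H1-2 days 1,2 n=4+4;  H2-3 days 1,2 n=5+5
    Stage II (validate):  H0 day0 n=11; H1-2 days 1,2 n=0+0;  H2-3 days 1,2 n=7+8

giving 23 screening and 26 validation samples — 49 in all, from 17 animals
sampled at up to three time points (51 draws would be complete; two are
missing, as in the reference design).

Planted effects live on the CT scale (additive cycles) so the ΔΔCT → FC
mapping is exact: a planted expression change of ``log2fc`` adds
``-log2fc`` cycles to the case samples' CT (down-regulation raises CT).
Planted markers are assigned baselines in the lower half of the dynamic
range unless pinned explicitly, emulating the fact that validated markers
were by construction quantifiable in most samples; null miRNAs draw
baselines across the full range and may be censored.

What the generator does *not* emulate: amplification-efficiency variation
between assays, correlated within-animal measurements across days, and
miRNA–miRNA expression correlation.  Recovery results on synthetic data
therefore show that the funnel recovers planted marginal effects at the
design's sample sizes, not that real blood miRNAs behave this simply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_io import CTMatrix, SampleMeta
from .stage1 import CandidateRecord
from .stage2 import ValidationDecision

__all__ = [
    "DesignCell",
    "TABLE_DESIGN",
    "TruthRecord",
    "SyntheticConfig",
    "default_planted_panel",
    "generate_dataset",
    "write_truth",
    "RecoveryReport",
    "evaluate_recovery",
    "replicate_recovery",
    "design_summary",
]


@dataclass(frozen=True)
class DesignCell:
    """One group×day×stage cell of the sampling design."""

    hars_grade: str
    day: int
    stage: str
    n_samples: int


#: The reference two-stage design (49 samples, 23 screening + 26 validation).
TABLE_DESIGN: tuple[DesignCell, ...] = (
    DesignCell("H0", 0, "I", 5),
    DesignCell("H1-2", 1, "I", 4),
    DesignCell("H1-2", 2, "I", 4),
    DesignCell("H2-3", 1, "I", 5),
    DesignCell("H2-3", 2, "I", 5),
    DesignCell("H0", 0, "II", 11),
    DesignCell("H1-2", 1, "II", 0),
    DesignCell("H1-2", 2, "II", 0),
    DesignCell("H2-3", 1, "II", 7),
    DesignCell("H2-3", 2, "II", 8),
)

_PATTERN_DAYS = {"day1_only": (1,), "day2_only": (2,), "sustained": (1, 2)}


@dataclass(frozen=True)
class TruthRecord:
    """A planted group×day expression effect.

    ``log2fc`` is on the expression scale: negative = down-regulated in the
    case grade (implemented as +|log2fc| cycles on case CT).  ``baseline_ct``
    pins the marker's baseline; None lets the generator assign one from the
    lower half of the dynamic range.
    """

    mirna_id: str
    contrast: str  # case grade: "H1-2" or "H2-3"
    day_pattern: str  # day1_only | day2_only | sustained
    log2fc: float
    baseline_ct: float | None = None

    def __post_init__(self) -> None:
        if self.day_pattern not in _PATTERN_DAYS:
            raise ValueError(f"unknown day_pattern {self.day_pattern!r}")
        if self.log2fc == 0:
            raise ValueError("planted effects must have |log2fc| > 0")

    @property
    def days(self) -> tuple[int, ...]:
        return _PATTERN_DAYS[self.day_pattern]

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the reference study conditions.

    * ``n_mirnas`` 667, split A/B cards (first half A, rest B).
    * ``baseline_ct_range`` (18, 29) cycles — spans the usable range below
      the censoring limit, so high-baseline species are partially censored
      as on real cards.
    * ``noise_sd`` 0.5 cycles of well-level technical+biological noise.
    * ``card_shift_sd`` 1.0 cycles of per-card-run level shift (the
      artifact median normalization exists to remove).
    * ``ct_max`` 30: deterministic right-censoring; values beyond it leave
      the dynamic range and are emitted as Undetermined.  An optional
      stochastic dropout mode instead censors with probability rising
      smoothly over the last cycles before the limit.
    * ``seed`` is mandatory; identical seeds give bit-identical datasets.
    """

    seed: int
    n_mirnas: int = 667
    design: tuple[DesignCell, ...] = TABLE_DESIGN
    baseline_ct_range: tuple[float, float] = (18.0, 29.0)
    noise_sd: float = 0.5
    card_shift_sd: float = 1.0
    ct_max: float = 30.0
    planted: tuple[TruthRecord, ...] = ()
    stochastic_dropout: bool = False
    planted_baseline_range: tuple[float, float] = (19.0, 24.0)

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.card_shift_sd < 0:
            raise ValueError("card_shift_sd must be non-negative")
        if any(c.n_samples < 0 for c in self.design):
            raise ValueError("design cell sizes must be non-negative")


def mirna_name(i: int) -> str:
    return f"syn-mir-{i:04d}"


def default_planted_panel(n_mirnas: int = 667) -> tuple[TruthRecord, ...]:
    """The standard regression-test scenario of planted effects.

    Mirrors the composition of the reference candidate table: for the mild
    (H1-2) contrast nine day-1-only, two day-2-only and nine sustained
    effects, mostly 2–4-fold up-regulated with one down-regulated marker;
    for the severe (H2-3) contrast thirteen day-2-only 2–5-fold
    down-regulated effects and two sustained ones, among them a single
    10-fold down marker (the strongest-candidate analogue).

    Planted ids are spread evenly over the miRNA panel so both card types
    carry effects.
    """
    fcs_h12_d1 = [2.8, 2.4, 2.6, 2.7, 2.8, 2.0, 0.3, 3.9, 2.5]
    fcs_h12_d2 = [2.2, 2.8]
    fcs_h12_sus = [2.2, 2.35, 2.25, 3.0, 2.25, 4.1, 0.4, 2.65, 2.7]
    fcs_h23_d2 = [0.4, 0.4, 0.4, 0.5, 0.5, 0.2, 0.3, 0.4, 0.4, 0.3, 0.4, 0.3, 0.5]
    fcs_h23_sus = [0.3, 0.1]

    specs: list[tuple[str, str, float]] = []
    specs += [("H1-2", "day1_only", fc) for fc in fcs_h12_d1]
    specs += [("H1-2", "day2_only", fc) for fc in fcs_h12_d2]
    specs += [("H1-2", "sustained", fc) for fc in fcs_h12_sus]
    specs += [("H2-3", "day2_only", fc) for fc in fcs_h23_d2]
    specs += [("H2-3", "sustained", fc) for fc in fcs_h23_sus]
    if len(specs) > n_mirnas:
        # Miniature panels keep an evenly spaced subset of the effects so
        # the composition (patterns, directions) stays representative.
        pick = sorted({round(i * (len(specs) - 1) / (n_mirnas - 1)) for i in range(n_mirnas)}) if n_mirnas > 1 else [0]
        specs = [specs[i] for i in pick]

    panel = []
    for k, (grade, pattern, fc) in enumerate(specs):
        idx = round(k * n_mirnas / len(specs)) % n_mirnas
        panel.append(
            TruthRecord(
                mirna_id=mirna_name(idx),
                contrast=grade,
                day_pattern=pattern,
                log2fc=math.log2(fc),
            )
        )
    return tuple(panel)


def _build_samples(config: SyntheticConfig, rng: np.random.Generator) -> list[SampleMeta]:
    """Lay samples onto animals following the design grid.

    Each case grade gets as many animals as its busiest day needs (summed
    over stages); design cells of the same grade and day then consume
    animals in order, so Stage-I and Stage-II case samples come from
    disjoint animals while each Stage-I animal contributes both of its
    post-exposure days.  H0 day-0 draws cycle through the full animal pool,
    as many as the design requests (in the reference grid: 16 of the 17
    animals, leaving the design two samples short of the complete
    17 x 3 = 51).  Dose is 0 Gy for H0 draws and 2.5 or 5 Gy per exposed
    animal.
    """
    grades = ("H1-2", "H2-3")
    tags = {"H1-2": "m", "H2-3": "s"}
    animals_by_grade: dict[str, list[str]] = {}
    for grade in grades:
        per_day: dict[int, int] = {}
        for c in config.design:
            if c.hars_grade == grade:
                per_day[c.day] = per_day.get(c.day, 0) + c.n_samples
        n_animals = max(per_day.values(), default=0)
        animals_by_grade[grade] = [
            f"an-{tags[grade]}{i:02d}" for i in range(1, n_animals + 1)
        ]
    all_animals = [a for grade in grades for a in animals_by_grade[grade]]

    doses = {a: float(rng.choice([2.5, 5.0])) for a in all_animals}

    samples: list[SampleMeta] = []
    h0_cursor = 0
    case_cursor: dict[tuple[str, int], int] = {}

    for cell in config.design:
        for _ in range(cell.n_samples):
            if cell.hars_grade == "H0":
                animal = all_animals[h0_cursor % len(all_animals)]
                h0_cursor += 1
                dose = 0.0
            else:
                key = (cell.hars_grade, cell.day)
                idx = case_cursor.get(key, 0)
                case_cursor[key] = idx + 1
                pool = animals_by_grade[cell.hars_grade]
                animal = pool[idx % len(pool)]
                dose = doses[animal]
            rin = float(np.clip(rng.normal(8.6, 0.6), 7.3, 9.5))
            ratio = float(np.clip(rng.normal(2.05, 0.03), 2.0, None))
            sid = f"{animal}-st{cell.stage}-d{cell.day}-{cell.hars_grade}"
            base, k = sid, 1
            existing = {s.sample_id for s in samples}
            while sid in existing:
                k += 1
                sid = f"{base}-{k}"
            samples.append(
                SampleMeta(
                    sample_id=sid,
                    animal_id=animal,
                    day=cell.day,
                    hars_grade=cell.hars_grade,
                    stage=cell.stage,
                    equivalent_dose_gy=dose,
                    rin=rin,
                    a260_280=ratio,
                )
            )
    return samples


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[SampleMeta], CTMatrix, list[TruthRecord]]:
    """Generate (sample metadata, raw CT matrix, ground truth).

    CT of miRNA *i* in sample *j* is

        baseline_i + card_shift(sample j, card of i) + planted effect + noise

    with the planted effect equal to ``-log2fc`` cycles on case samples of
    the matching grade and day(s).  Values beyond ``ct_max`` are censored
    (missing, written as Undetermined).  Fully reproducible from the seed.
    Raises when a planted miRNA id is not in the panel.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mirnas
    mirnas = [mirna_name(i) for i in range(n)]
    known = set(mirnas)
    for t in config.planted:
        if t.mirna_id not in known:
            raise ValueError(f"planted miRNA {t.mirna_id!r} not among the {n} panel ids")
    card_of = {m: ("A" if i < (n + 1) // 2 else "B") for i, m in enumerate(mirnas)}

    lo, hi = config.baseline_ct_range
    baselines = rng.uniform(lo, hi, size=n)
    # Planted markers stay quantifiable: pin their baselines low unless set.
    plo, phi = config.planted_baseline_range
    truths: list[TruthRecord] = []
    mi = {m: i for i, m in enumerate(mirnas)}
    for t in config.planted:
        b = t.baseline_ct if t.baseline_ct is not None else float(rng.uniform(plo, phi))
        baselines[mi[t.mirna_id]] = b
        truths.append(replace(t, baseline_ct=b))

    samples = _build_samples(config, rng)
    n_samples = len(samples)

    # Per-(sample, card type) level shift; scaling card_shift_sd rescales the
    # same draws, so normalization-immunity checks can compare seeds directly.
    card_types = sorted(set(card_of.values()))
    shift = {
        (s.sample_id, ct): config.card_shift_sd * float(rng.standard_normal())
        for s in samples
        for ct in card_types
    }
    noise = config.noise_sd * rng.standard_normal((n, n_samples))

    effect = np.zeros((n, n_samples))
    for t in truths:
        i = mi[t.mirna_id]
        for j, s in enumerate(samples):
            if s.hars_grade == t.contrast and s.day in t.days:
                effect[i, j] += -t.log2fc

    ct = np.empty((n, n_samples))
    for j, s in enumerate(samples):
        col_shift = np.array([shift[(s.sample_id, card_of[m])] for m in mirnas])
        ct[:, j] = baselines + col_shift + effect[:, j] + noise[:, j]

    if config.stochastic_dropout:
        # Detection probability decays over the last ~3 cycles to the limit.
        p_drop = 1.0 / (1.0 + np.exp(-(ct - config.ct_max) / 0.75))
        drop = rng.random(ct.shape) < p_drop
    else:
        drop = ct > config.ct_max
    ct = np.where(drop, np.nan, ct)

    card_instance = {
        (s.sample_id, ctype): f"{s.sample_id}:card{ctype}"
        for s in samples
        for ctype in card_types
    }
    matrix = CTMatrix(
        mirna_ids=mirnas,
        sample_ids=[s.sample_id for s in samples],
        ct=ct,
        card_of=card_of,
        card_instance=card_instance,
    )
    return samples, matrix, truths


def write_truth(truths: Sequence[TruthRecord], path) -> None:
    """Serialize the planted ground truth as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tcontrast\tday_pattern\tlog2fc\tbaseline_ct\n")
        for t in truths:
            b = "" if t.baseline_ct is None else format(t.baseline_ct, ".6f")
            fh.write(
                f"{t.mirna_id}\t{t.contrast}\t{t.day_pattern}\t"
                f"{format(t.log2fc, '.6f')}\t{b}\n"
            )


def design_summary(samples: Sequence[SampleMeta]) -> dict[str, int]:
    """Headline counts of a sample table: per-stage sizes and completeness."""
    animals = {s.animal_id for s in samples}
    return {
        "n_samples": len(samples),
        "n_stage1": sum(1 for s in samples if s.stage == "I"),
        "n_stage2": sum(1 for s in samples if s.stage == "II"),
        "n_animals": len(animals),
        "n_expected": len(animals) * 3,
    }


def replicate_recovery(
    seed: int,
    n_mirnas: int = 100,
    planted: tuple[TruthRecord, ...] = (),
) -> RecoveryReport:
    """One full screen+validate replicate on a fresh synthetic dataset.

    Generates a dataset under the default study conditions (reference
    design, noise sd 0.5, card shifts, censoring at CT 30), runs
    normalization, the Stage-I screen of both contrasts and the Stage-II
    validation, and scores the outcome against the planted truth.  The
    building block of the Monte-Carlo power/false-positive experiments.
    """
    from .normalization import detect_calls, median_normalize
    from .stage1 import ScreenConfig, screen_all
    from .stage2 import validate_candidates

    cfg = SyntheticConfig(seed=seed, n_mirnas=n_mirnas, planted=planted)
    samples, ctm, truths = generate_dataset(cfg)
    norm = median_normalize(ctm, detect_calls(ctm, cfg.ct_max))
    screen_cfg = ScreenConfig(ct_max=cfg.ct_max)
    samples1 = [s for s in samples if s.stage == "I"]
    samples2 = [s for s in samples if s.stage == "II"]
    records = screen_all(norm, samples1, screen_cfg)
    decisions = validate_candidates(
        records,
        norm,
        samples2,
        screen_cfg,
        stage1_sample_ids=[s.sample_id for s in samples1],
    )
    return evaluate_recovery(truths, records, decisions, n_mirnas)


_CONSISTENT_DAY_SETS = {
    "day1_only": {"day1"},
    "day2_only": {"day2"},
    "sustained": {"day1", "day2", "merged"},
}


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the planted truth.

    A planted effect counts *recovered* when it passed the screen with the
    planted direction on a day set consistent with its day pattern and —
    where its contrast had Stage-II samples — also validated there.
    ``false_positive_validated`` counts validated miRNAs that were never
    planted; the fraction is per miRNA on the panel.
    """

    n_planted: int
    n_screened: int
    n_recovered: int
    sensitivity: float
    false_positive_validated: int
    false_positive_fraction: float
    per_pattern: dict[str, tuple[int, int]]
    per_truth: list[dict]


def evaluate_recovery(
    truths: Sequence[TruthRecord],
    records: Sequence[CandidateRecord],
    decisions: Sequence[ValidationDecision],
    n_mirnas: int,
) -> RecoveryReport:
    """Score screening/validation outcomes against the planted truth."""
    planted_ids = {t.mirna_id for t in truths}
    n_screened = 0
    n_recovered = 0
    per_pattern: dict[str, list[int]] = {}
    per_truth: list[dict] = []

    for t in truths:
        contrast = f"{t.contrast} vs H0"
        ok_sets = _CONSISTENT_DAY_SETS[t.day_pattern]
        screened = any(
            r.passes_screen
            and r.mirna_id == t.mirna_id
            and r.contrast == contrast
            and r.day_set in ok_sets
            and r.fc.direction == t.direction
            for r in records
        )
        contrast_decisions = [d for d in decisions if d.contrast == contrast]
        has_validation_arm = any(d.validatable for d in contrast_decisions)
        if has_validation_arm:
            validated = any(
                d.validated
                and d.mirna_id == t.mirna_id
                and d.day_set in ok_sets
                and d.record is not None
                and d.record.fc.direction == t.direction
                for d in contrast_decisions
            )
            recovered = screened and validated
        else:
            validated = None
            recovered = screened
        n_screened += screened
        n_recovered += recovered
        bucket = per_pattern.setdefault(t.day_pattern, [0, 0])
        bucket[0] += recovered
        bucket[1] += 1
        per_truth.append(
            {
                "mirna_id": t.mirna_id,
                "contrast": t.contrast,
                "day_pattern": t.day_pattern,
                "log2fc": t.log2fc,
                "screened": screened,
                "validated": validated,
                "recovered": recovered,
            }
        )

    fp_ids = {
        d.mirna_id for d in decisions if d.validated and d.mirna_id not in planted_ids
    }
    return RecoveryReport(
        n_planted=len(truths),
        n_screened=n_screened,
        n_recovered=n_recovered,
        sensitivity=(n_recovered / len(truths)) if truths else float("nan"),
        false_positive_validated=len(fp_ids),
        false_positive_fraction=len(fp_ids) / n_mirnas if n_mirnas else float("nan"),
        per_pattern={k: (v[0], v[1]) for k, v in per_pattern.items()},
        per_truth=per_truth,
    )
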