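"""Stage-II validation conjunction, Bonferroni families, combined analysis."""

import math

import numpy as np
import pytest

from mirhars.normalization import FoldChange, NormalizedMatrix, detect_calls, median_normalize
from mirhars.stage1 import CandidateRecord, ScreenConfig
from mirhars.stage2 import (
    ValidationDecision,
    apply_bonferroni,
    combined_analysis,
    validate_candidates,
)
from mirhars.stats_models import LogisticFit
from mirhars.synthetic import SyntheticConfig, TruthRecord, generate_dataset
from mirhars.data_io import SampleMeta

from conftest import brute_force_concordance


def _full_run(seed, planted, n_mirnas=40):
    cfg = SyntheticConfig(seed=seed, n_mirnas=n_mirnas, planted=planted)
    samples, ctm, truths = generate_dataset(cfg)
    norm = median_normalize(ctm, detect_calls(ctm))
    sc = ScreenConfig()
    s1 = [s for s in samples if s.stage == "I"]
    s2 = [s for s in samples if s.stage == "II"]
    from mirhars.stage1 import screen_all

    records = screen_all(norm, s1, sc)
    decisions = validate_candidates(
        records, norm, s2, sc, stage1_sample_ids=[s.sample_id for s in s1]
    )
    return samples, norm, sc, records, decisions


class TestValidateCandidates:
    def test_planted_tenfold_down_validates_on_both_days(self):
        planted = (TruthRecord("syn-mir-0007", "H2-3", "sustained", -math.log2(10)),)
        _, _, _, records, decisions = _full_run(seed=2, planted=planted)
        for day_set in ("day1", "day2"):
            hits = [
                d
                for d in decisions
                if d.mirna_id == "syn-mir-0007" and d.day_set == day_set
            ]
            assert hits and hits[0].validated
            assert hits[0].record.fc.direction == "down"

    def test_h12_candidates_not_validatable_without_stage2_samples(self):
        planted = (TruthRecord("syn-mir-0005", "H1-2", "sustained", 2.0),)
        _, _, _, records, decisions = _full_run(seed=5, planted=planted)
        h12 = [d for d in decisions if d.contrast == "H1-2 vs H0"]
        assert h12  # the planted candidate passed the screen
        assert all(not d.validatable and not d.validated for d in h12)
        # ... and they never enter a Bonferroni family
        thresholds = apply_bonferroni(decisions)
        assert "H1-2 vs H0" not in thresholds

    def test_direction_flip_fails_validation(self):
        # Hand-built stage-II matrix where the candidate's expression is
        # *down* although the stage-I record said up.
        samples2 = [
            SampleMeta(f"v{i}", f"av{i}", 0, "H0", "II", 0.0, 8.5, 2.1)
            for i in range(3)
        ] + [
            SampleMeta(f"w{i}", f"aw{i}", 1, "H2-3", "II", 5.0, 8.5, 2.1)
            for i in range(3)
        ]
        dct = np.array([[0.0, 0.1, -0.1, 2.0, 2.1, 1.9]])  # case above ref: down
        norm2 = NormalizedMatrix(
            mirna_ids=["m0"],
            sample_ids=[s.sample_id for s in samples2],
            dct=dct,
            mask=np.ones_like(dct, dtype=bool),
            card_medians={},
        )
        stage1_rec = CandidateRecord(
            mirna_id="m0",
            contrast="H2-3 vs H0",
            day_set="day1",
            fc=FoldChange.from_log2(1.5),  # screen said ~2.8-fold up
            comparison=None,
            fit=LogisticFit(
                beta0=0.0, beta1=1.0, or_value=2.7, ci_low=1.1, ci_high=6.0,
                wald_p=0.01, p=0.01, p_source="wald", concordance=0.9,
                separated=False, n_iter=3, converged=True,
            ),
            passes_screen=True,
        )
        decisions = validate_candidates([stage1_rec], norm2, samples2, ScreenConfig())
        assert len(decisions) == 1
        d = decisions[0]
        assert not d.direction_match and not d.validated
        # the other gates can hold; the conjunction still fails
        assert d.fc_ok

    def test_stage_overlap_rejected(self):
        planted = (TruthRecord("syn-mir-0007", "H2-3", "sustained", -2.0),)
        cfg = SyntheticConfig(seed=2, n_mirnas=20, planted=planted)
        samples, ctm, _ = generate_dataset(cfg)
        norm = median_normalize(ctm, detect_calls(ctm))
        s2 = [s for s in samples if s.stage == "II"]
        with pytest.raises(ValueError, match="overlap"):
            validate_candidates([], norm, s2, ScreenConfig(),
                                stage1_sample_ids=[s2[0].sample_id])

    def test_validated_implies_screened(self, screened_run):
        passing = {
            (r.mirna_id, r.contrast, r.day_set)
            for r in screened_run["records"]
            if r.passes_screen
        }
        for d in screened_run["decisions"]:
            if d.validated:
                assert (d.mirna_id, d.contrast, d.day_set) in passing


def _decision(mirna, p, validated=True, contrast="H2-3 vs H0"):
    fit = LogisticFit(
        beta0=0.0, beta1=-1.0, or_value=0.4, ci_low=0.2, ci_high=0.9,
        wald_p=p, p=p, p_source="wald", concordance=0.9,
        separated=False, n_iter=3, converged=True,
    )
    rec = CandidateRecord(
        mirna_id=mirna, contrast=contrast, day_set="day2",
        fc=FoldChange.from_log2(-1.5), comparison=None, fit=fit,
        passes_screen=True, stage="II", passes_validation=validated,
    )
    return ValidationDecision(
        mirna_id=mirna, contrast=contrast, day_set="day2", validatable=True,
        direction_match=True, p_ok=True, fc_ok=True, conc_ok=True,
        validated=validated, record=rec,
    )


class TestApplyBonferroni:
    def test_family_of_15_threshold(self):
        decisions = [_decision(f"m{i}", 0.003) for i in range(15)]
        thr = apply_bonferroni(decisions)["H2-3 vs H0"]
        assert thr == pytest.approx(0.05 / 15)
        assert all(d.bonferroni_pass for d in decisions)  # 0.003 < 0.00333

    def test_family_of_20_strict_inequality(self):
        decisions = [_decision(f"m{i}", 0.0025) for i in range(20)]
        apply_bonferroni(decisions)
        assert all(d.bonferroni_pass is False for d in decisions)

    def test_family_of_one(self):
        decisions = [_decision("m0", 0.049)]
        apply_bonferroni(decisions)
        assert decisions[0].bonferroni_pass

    def test_survivors_subset_of_nominal(self, screened_run):
        decisions = screened_run["decisions"]
        apply_bonferroni(decisions)
        alpha = screened_run["screen_config"].alpha
        for d in decisions:
            if d.bonferroni_pass:
                assert d.validated and d.record.fit.p < alpha


class TestCombinedAnalysis:
    def test_pooled_reference_size(self, screened_run):
        # Pooling stages grows the H0 reference from 5 to 16 samples.
        samples = screened_run["samples"]
        h0_1 = [s for s in samples if s.hars_grade == "H0" and s.stage == "I"]
        h0_all = [s for s in samples if s.hars_grade == "H0"]
        assert (len(h0_1), len(h0_all)) == (5, 16)

    def test_validated_candidates_stay_significant_when_pooled(self):
        planted = (TruthRecord("syn-mir-0003", "H2-3", "sustained", -math.log2(10)),)
        samples, norm, sc, records, decisions = _full_run(seed=3, planted=planted)
        validated = [
            r
            for r in records
            if (r.mirna_id, r.contrast, r.day_set)
            in {(d.mirna_id, d.contrast, d.day_set) for d in decisions if d.validated}
        ]
        assert any(r.mirna_id == "syn-mir-0003" for r in validated)
        combined = combined_analysis(norm, samples, validated, sc)
        ours = [r for r in combined if r.mirna_id == "syn-mir-0003"]
        assert ours
        for r in ours:
            assert r.stage == "combined"
            assert r.fit.p < 0.05
            assert r.fc.direction == "down"

    def test_pooled_concordance_equals_brute_force(self):
        planted = (TruthRecord("syn-mir-0003", "H2-3", "sustained", -2.0),)
        samples, norm, sc, records, decisions = _full_run(seed=6, planted=planted)
        cand = [r for r in records if r.mirna_id == "syn-mir-0003" and r.passes_screen]
        combined = combined_analysis(norm, samples, cand[:1], sc)
        assert combined
        r = combined[0]
        days = {"day1": (1,), "day2": (2,), "merged": (1, 2)}[r.day_set]
        case_ids = [
            s.sample_id for s in samples if s.hars_grade == "H2-3" and s.day in days
        ]
        ref_ids = [s.sample_id for s in samples if s.hars_grade == "H0"]
        case = norm.values_for("syn-mir-0003", case_ids)
        ref = norm.values_for("syn-mir-0003", ref_ids)
        x = np.concatenate([case, ref])
        y = np.array([1] * case.size + [0] * ref.size)
        # fitted scores are monotone in x (sign aside); the c-statistic of
        # the fit must equal brute-force pair counting on x or its negation
        bf = brute_force_concordance(x, y)
        assert r.fit.concordance == pytest.approx(max(bf, 1 - bf), abs=1e-12)
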