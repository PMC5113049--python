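"""Shared fixtures: small synthetic datasets standing in for the undeposited
study data.  Everything is generated programmatically from fixed seeds."""

from __future__ import annotations

import numpy as np
import pytest

from mirhars.normalization import detect_calls, median_normalize
from mirhars.stage1 import ScreenConfig, screen_all
from mirhars.stage2 import validate_candidates
from mirhars.synthetic import (
    SyntheticConfig,
    default_planted_panel,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """60-miRNA dataset on the full two-stage design with planted effects."""
    cfg = SyntheticConfig(seed=101, n_mirnas=60, planted=default_planted_panel(60))
    samples, ctm, truths = generate_dataset(cfg)
    return cfg, samples, ctm, truths


@pytest.fixture(scope="session")
def screened_run(small_dataset):
    """The small dataset taken through normalization, screen and validation."""
    cfg, samples, ctm, truths = small_dataset
    mask = detect_calls(ctm)
    norm = median_normalize(ctm, mask)
    screen_cfg = ScreenConfig()
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
    return {
        "config": cfg,
        "screen_config": screen_cfg,
        "samples": samples,
        "samples1": samples1,
        "samples2": samples2,
        "norm": norm,
        "truths": truths,
        "records": records,
        "decisions": decisions,
    }


def brute_force_concordance(scores, y) -> float:
    """O(n^2) pair-counting oracle for the c-statistic."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    cases = scores[y == 1]
    ctrls = scores[y == 0]
    num = 0.0
    for c in cases:
        for r in ctrls:
            if c > r:
                num += 1.0
            elif c == r:
                num += 0.5
    return num / (len(cases) * len(ctrls))
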