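"""Shared fixtures and in-memory cohort helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pneumotex import (DEFAULT_STAGE_SPECS, apply_mask, enhance, entropy_vector,
                       generate_image, segment_lung_fields)
from pneumotex.synthetic import _derive_seeds


def image_features(stage: str, seed: int, size: int = 256) -> np.ndarray:
    """T-vector of one synthetic image via the standard processing path:
    equalize -> segment -> mask the original intensities -> wavelet entropy."""
    img = generate_image(DEFAULT_STAGE_SPECS[stage], size, size, seed)
    mask = segment_lung_fields(enhance(img))
    fv = entropy_vector(apply_mask(img, mask), mask=mask)
    return fv.log_features


def cohort_features(seed: int, n_normal: int,
                    stage_counts: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) feature matrix of an in-memory cohort; per-image seeds are
    derived from the master seed exactly as in ``generate_cohort``."""
    plan = [("normal", 0)] * n_normal
    for stage in ("I", "II", "III"):
        plan += [(stage, 1)] * stage_counts.get(stage, 0)
    seeds = _derive_seeds(seed, len(plan))
    X = np.array([image_features(stage, int(s)) for (stage, _), s in zip(plan, seeds)])
    y = np.array([label for _, label in plan])
    return X, y


@pytest.fixture(scope="session")
def strong_cohort():
    """One 30+30 cohort with strong stage-III-like signal (session-cached)."""
    return cohort_features(seed=11, n_normal=30, stage_counts={"III": 30})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def staging_frame() -> pd.DataFrame:
    """Hand-entered 60-case staging table of a patient cohort.

    Gold standard: 40 stage-I, 12 stage-II, 8 stage-III cases.  Modality A
    (radiography) stages 32 of the stage-I cases correctly, leaves 7
    undetermined and overcalls 1 as stage III; it overcalls one stage-II case
    as III.  Modality B (CT) overcalls 2 stage-I cases as stage III and is
    otherwise correct.  The two modalities agree on 32 + 11 + 8 = 51 cases.
    """
    rows = []

    def add(n, gold, a, b):
        for _ in range(n):
            rows.append({"case_id": f"c{len(rows):03d}", "gold": gold,
                         "stage_a": a, "stage_b": b})

    add(32, "I", "I", "I")
    add(5, "I", "ND", "I")
    add(2, "I", "ND", "III")
    add(1, "I", "III", "I")
    add(11, "II", "II", "II")
    add(1, "II", "III", "II")
    add(8, "III", "III", "III")
    return pd.DataFrame(rows)
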