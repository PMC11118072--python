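"""Shared fixtures: small synthetic batches and the default-condition cohort."""

from __future__ import annotations

import numpy as np
import pytest

from myowrite import (
    SyntheticConfig,
    WordRecognitionModel,
    bandpass,
    build_feature_matrix,
    detect_segments,
    generate_dataset,
)
from myowrite.features import FEATURE_SETS


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast 4-class protocol for unit-level pipeline tests."""
    return SyntheticConfig(
        n_classes=4, reps_per_class=4, word_duration=1.0,
        rest_duration=1.5, lead_in=1.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_recordings(small_config):
    """Band-passed recordings of the small protocol, with truth segments."""
    return [bandpass(r) for r in generate_dataset(small_config, "S1")]


@pytest.fixture(scope="session")
def rng_windows() -> np.ndarray:
    """50 random 150-sample windows: white noise, band-limited and mixed."""
    from scipy import signal

    rng = np.random.default_rng(1234)
    sos = signal.butter(4, (35, 450), btype="bandpass", fs=1000, output="sos")
    rows = []
    for i in range(50):
        white = rng.standard_normal(600)
        if i % 3 == 0:
            w = white[:150]
        elif i % 3 == 1:
            w = signal.sosfiltfilt(sos, white)[200:350]
        else:
            t = np.arange(150) / 1000.0
            w = signal.sosfiltfilt(sos, white)[200:350] + 0.5 * np.sin(
                2 * np.pi * 120 * t
            )
        rows.append(w * rng.uniform(0.05, 2.0))
    return np.stack(rows)


@pytest.fixture(scope="session")
def default_cohort():
    """Three simulated subjects at the default study conditions.

    For each of three seeds: generate the 30-word dataset, band-pass,
    segment by threshold, extract the full feature matrix once, and fit
    every (feature set, classifier) cell with and without majority voting.
    Shared by the end-to-end recovery, ordering and smoothing tests.
    """
    named = ["Hudgins", "Du", "Phinyomark1", "Phinyomark2", "TDAR"]
    per_seed = []
    for seed in (1, 2, 3):
        cfg = SyntheticConfig(seed=seed)
        recs = [bandpass(r) for r in generate_dataset(cfg, f"S{seed}")]
        segs = [detect_segments(r) for r in recs]
        fm_all = build_feature_matrix(recs, segs, "ALL")
        cells = {}
        for set_name in ["ALL"] + named:
            fm = fm_all if set_name == "ALL" else fm_all.select(set_name)
            for kind in ("KNN", "SVM", "LDA"):
                res = WordRecognitionModel(fm, classifier=kind).fit(seed=seed)
                cells[(set_name, kind)] = (res.accuracy, res.accuracy_mv)
        per_seed.append(
            {"seed": seed, "cells": cells, "n_windows": fm_all.n_windows}
        )
    return per_seed


NAMED_SETS = ["Hudgins", "Du", "Phinyomark1", "Phinyomark2", "TDAR"]
assert set(NAMED_SETS) < set(FEATURE_SETS)
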