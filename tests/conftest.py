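"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lymphomir as lm


def make_cohort(
    seed: int = 7,
    n_mirnas: int = 40,
    n_low_detection: int = 10,
    effects=None,
    **kwargs,
):
    """Small cohort with the default class sizes (19, 49, 20)."""
    if effects is None:
        effects = lm.sample_effects(
            6, shift_range=(1.5, 2.0), seed=seed, n_mirnas=n_mirnas
        )
    cfg = lm.CohortConfig(
        n_mirnas=n_mirnas,
        n_low_detection=n_low_detection,
        effects=effects,
        seed=seed,
        **kwargs,
    )
    return lm.simulate_cohort(cfg)


def normalize_chain(matrix):
    adjusted = lm.spikein_normalize(matrix)
    filtered, removed = lm.filter_low_detection(adjusted)
    return lm.global_mean_normalize(filtered), removed


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort()


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    matrix, ann, truth = small_cohort
    nm, removed = normalize_chain(matrix)
    return nm, ann, truth, removed


@pytest.fixture()
def tiny_ct_csv(tmp_path):
    path = tmp_path / "ct.csv"
    path.write_text(
        "mirna_id,S1,S2\n"
        "MIR_A,20.5,\n"
        "MIR_B,44.0,30.0\n"
        "SPIKE_1,21.0,21.5\n"
    )
    return path
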