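"""Shared fixtures. Heavy model fits are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from multiscreen.dose_model import ModelConfig, fit
from multiscreen.metrics import debatch_pipeline
from multiscreen.screen_data import ScreenDataset
from multiscreen.simulate import SyntheticConfig, simulate_screen


@pytest.fixture(scope="session")
def default_screen():
    """The default synthetic multi-study screen plus its ground truth."""
    cfg = SyntheticConfig()
    ds, truth = simulate_screen(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def small_screen():
    cfg = SyntheticConfig(
        n_studies=3, samples_per_study=10, n_drugs=30, doses_per_curve=5,
        n_single_dose_studies=0,
    )
    ds, truth = simulate_screen(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def fitted_default(default_screen):
    """Dose model fitted on the default screen with 10% of curves held out.

    Returns (model, heldout record frame, truth, full dataset)."""
    _, ds, truth = default_screen
    rng = np.random.default_rng(0)
    keys = sorted(set(map(tuple, ds.records[["study_id", "sample_id", "drug_id"]].to_numpy())))
    perm = rng.permutation(len(keys))
    held = set(keys[i] for i in perm[: len(keys) // 10])
    mask = np.array(
        [tuple(k) in held for k in ds.records[["study_id", "sample_id", "drug_id"]].to_numpy()]
    )
    train = ScreenDataset(ds.records[~mask], samples=ds.samples, drugs=ds.drugs)
    model = fit(train, ModelConfig(seed=0, n_iters=600))
    return model, ds.records[mask], truth, ds


@pytest.fixture(scope="session")
def zscores_default(fitted_default):
    model, _, _, _ = fitted_default
    z, nulls, summaries = debatch_pipeline(model, S=30, seed=5)
    return z, nulls, summaries


@pytest.fixture(scope="session")
def trained_fm(default_screen):
    """Desk-preset foundation model trained with study_0 held out."""
    from multiscreen.fm import FMConfig, train_fm

    _, ds, _ = default_screen
    return train_fm(ds, FMConfig.desk(seed=0, n_steps=300), exclude_studies=["study_0"])
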