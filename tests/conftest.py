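"""Shared fixtures: one clean synthetic plate per assay (session scope)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenoplate import assays, simulate

SEED = 12345
SMALL_SIDE = 900  # salt/arsenic test plates; defaults stay at full size


def _plate_bundle(assay: str, side: int, seed: int, **effects):
    layout = simulate.default_layout(assay, line="Col-0", side=side)
    spec = simulate.LineEffectSpec("Col-0", **effects)
    images, truth = simulate.generate_plate(assay, layout, spec, seed=seed)
    records = pd.DataFrame(assays.segment_plate(images, layout))
    return images, layout, truth, records


@pytest.fixture(scope="session")
def salt_plate():
    return _plate_bundle("salt", SMALL_SIDE, SEED, survival_prob=0.7)


@pytest.fixture(scope="session")
def arsenic_plate():
    return _plate_bundle("arsenic", SMALL_SIDE, SEED + 1, germination_prob=0.6)


@pytest.fixture(scope="session")
def freezing_plate():
    return _plate_bundle("freezing", simulate.IMAGE_SIDE, SEED + 2, damage_mean=0.4)


@pytest.fixture(scope="session")
def phosphate_plate():
    return _plate_bundle("phosphate", simulate.IMAGE_SIDE, SEED + 3)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def screen_data():
    """Transcribed per-line screen tables (results, meta)."""
    from phenoplate import triage

    return triage.load_reported_screen()
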