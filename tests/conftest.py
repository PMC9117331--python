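"""Shared fixtures.

The expensive artifacts (a paper-regime screen and a 12-clone barcode image
run) are session-scoped so the parameter-recovery, metric, and acceptance
tests all reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from signalome.barcodes import profile_image_set, train_barcode_classifier
from signalome.panels import BarcodePanel, default_panel
from signalome.scoring import score_screen
from signalome.simulate import (
    NoiseParams,
    generate_barcode_images,
    generate_screen,
    three_group_design,
)

ACCEPTANCE_SEED = 1729


@pytest.fixture(scope="session")
def full_screen():
    """Paper-regime screen: 100 drugs, 12 pathways, 5 timepoints, ~656
    cells per reporter per condition, plus its score matrix."""
    design = three_group_design(n_drugs=100, seed=ACCEPTANCE_SEED)
    cells, truth = generate_screen(design)
    matrix = score_screen(cells, design.modes)
    return design, cells, truth, matrix


@pytest.fixture(scope="session")
def small_screen():
    """A fast screen for unit-level checks."""
    design = three_group_design(n_drugs=24, cells_per_well=150, seed=11)
    cells, truth = generate_screen(design)
    matrix = score_screen(cells, design.modes)
    return design, cells, truth, matrix


@pytest.fixture(scope="session")
def barcode_run():
    """12-clone image set at default noise, profiled and classified."""
    iset = generate_barcode_images(default_panel(), 220, seed=ACCEPTANCE_SEED)
    features, labels = profile_image_set(iset)
    model, summary = train_barcode_classifier(features, labels, seed=ACCEPTANCE_SEED)
    return iset, features, labels, model, summary


@pytest.fixture(scope="session")
def clean_images():
    """Small noise-free image set (one clone per localization pattern)."""
    panel = BarcodePanel(
        ("CFP", "GFP"),
        ("whole_cell", "nuclear", "cytoplasmic", "peroxisome", "er"),
        barcodes=(
            ("CFP", "whole_cell"),
            ("CFP", "nuclear"),
            ("GFP", "cytoplasmic"),
            ("GFP", "peroxisome"),
            ("CFP", "er"),
        ),
    )
    return generate_barcode_images(
        panel, 6, image_shape=(192, 192), noise=NoiseParams.none(), seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
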