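"""Shared fixtures: tiny synthetic datasets sized for fast unit tests."""

import numpy as np
import pytest

from convscreen import (
    CVConfig,
    GeneSpec,
    LabeledAlignment,
    SyntheticSpec,
    default_screen_spec,
    generate_dataset,
    make_signal_columns,
)


def tiny_spec() -> SyntheticSpec:
    """A small panel: one high-penetrance signal gene plus one noise gene."""
    return SyntheticSpec(
        n_class0=12,
        n_class1=16,
        n_lineages=4,
        genes=[
            GeneSpec("sigA", 40, make_signal_columns(3, 0.95, 4, 0.0)),
            GeneSpec("noiseB", 30),
        ],
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    alignments, truth = generate_dataset(tiny_spec(), seed=11)
    return alignments, truth


@pytest.fixture(scope="session")
def fast_config():
    return CVConfig(n_iterations=25, master_seed=11)


@pytest.fixture
def toy_alignment():
    """Hand-built labeled alignment with known column structure."""
    return LabeledAlignment(
        gene_name="toy",
        sample_ids=["s1", "s2", "s3", "s4"],
        rows=["MAKT", "MAST", "M-SA", "MASA"],
        labels={"s1": "C3", "s2": "C3", "s3": "C4", "s4": "C4"},
        groups={s: {"subtype": g} for s, g in
                zip(["s1", "s2", "s3", "s4"], ["C3", "C3", "NAD-ME", "NADP-ME"])},
        reference_id="s3",
    )


@pytest.fixture
def random_xy():
    """A seeded separable-ish random design for CV engine tests."""
    rng = np.random.default_rng(5)
    n, p = 60, 8
    X = rng.integers(0, 3, size=(n, p)).astype(float)
    y = rng.integers(0, 2, size=n).astype(np.int8)
    y[:4] = 1
    y[-4:] = 0
    # plant a weak signal in column 0 so accuracy is above chance
    X[:, 0] = y * 1.0 + (rng.random(n) < 0.2)
    return X, y


@pytest.fixture(scope="session")
def default_spec():
    return default_screen_spec()
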