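from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py importable

from phosphoage.io_formats import DatedTree, OrthologAlignment
from phosphoage.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def default_tree() -> DatedTree:
    return DatedTree.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_alignment(
    sequences: dict[str, str],
    focal: str | None = None,
    family_id: str = "fam",
) -> OrthologAlignment:
    focal = focal or next(iter(sequences))
    return OrthologAlignment(
        family_id=family_id, sequences=sequences, focal_species=focal
    )


@pytest.fixture()
def small_config() -> GeneratorConfig:
    """A fast generator configuration for unit-level end-to-end checks."""
    return GeneratorConfig(
        n_families=8,
        n_phospho_sites=80,
        n_control_sites=120,
        background_columns=12,
    )
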