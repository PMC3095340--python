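"""Shared fixtures: hand-buildable reads and small simulation configs."""

from __future__ import annotations

import numpy as np
import pytest

from supersage import LINKERS, SequencingRead, SimConfig, revcomp

BASES = "ACGT"


def random_tag(rng: np.random.Generator) -> str:
    return "CATG" + "".join(rng.choice(list(BASES), 22))


def make_read(
    library: str,
    tag_a: str,
    tag_b: str,
    read_id: str = "r0",
    left: str | None = None,
    right: str | None = None,
) -> SequencingRead:
    """Assemble a well-formed ditag read (linker overrides for corruption)."""
    cat_left, cat_right = LINKERS[library]
    left = cat_left if left is None else left
    right = cat_right if right is None else right
    return SequencingRead(read_id, left + tag_a + revcomp(tag_b) + right)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def clean_sim_config() -> SimConfig:
    """Small collision-free simulation without artifacts.

    Low/mid-only abundance keeps per-tag shares below ~0.1%, so chance
    re-occurrence of a ditag is rare and count conservation is exact.
    """
    return SimConfig(
        n_transcripts=1500,
        depth_W=4000,
        depth_F=2240,
        abundance_mixture=(0.3, 0.7, 0.0, 0.0),
        de_fraction=0.1,
        error_rate=0.0,
        twin_ditag_rate=0.0,
        incomplete_read_rate=0.0,
        seed=5,
    )


@pytest.fixture
def noisy_sim_config() -> SimConfig:
    """Small simulation with all artifact channels switched on."""
    return SimConfig(
        n_transcripts=1500,
        depth_W=4000,
        depth_F=2240,
        abundance_mixture=(0.3, 0.7, 0.0, 0.0),
        de_fraction=0.1,
        error_rate=0.002,
        twin_ditag_rate=0.08,
        incomplete_read_rate=0.08,
        seed=5,
    )
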