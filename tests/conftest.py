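"""Shared fixtures: synthetic scenes and pipeline runs reused across tests.

Scenes are generated once per session; the heavier end-to-end pipeline runs
are cached so acceptance-style checks and unit checks share the work.
"""

from __future__ import annotations

import numpy as np
import pytest

from rowweed import FieldSpec, generate_field, run_weed_mapping


@pytest.fixture(scope="session")
def scene37():
    """A 6 x 6 m field with rows at 37 degrees, default weeds, 1.5 cm GSD."""
    return generate_field(FieldSpec(row_angle_deg=37.0, random_seed=3), gsd_m=0.015)


@pytest.fixture(scope="session")
def scene0_weedfree():
    """A weed-free field with rows at 0 degrees, 1.5 cm GSD."""
    return generate_field(
        FieldSpec(row_angle_deg=0.0, weed_density_per_m2=0.0, random_seed=21), gsd_m=0.015
    )


@pytest.fixture(scope="session")
def classmap37(scene37):
    return run_weed_mapping(scene37.image)


@pytest.fixture(scope="session")
def classmap0_weedfree(scene0_weedfree):
    return run_weed_mapping(scene0_weedfree.image)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
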