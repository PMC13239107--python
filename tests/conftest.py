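"""Shared fixtures: radiation-quality tables and small machine models.

The quality tables (per-species LQ coefficients vs energy for both models)
are the expensive ingredient; they are built once per session and reused by
every machine the tests generate.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mkmplan import base_data as bd
from mkmplan.rbe_models import ModelParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def hsg_models():
    return {"mmkm": ModelParams.mmkm_hsg(), "mcf_mkm": ModelParams.mcf_hsg()}


@pytest.fixture(scope="session")
def quality_tables(hsg_models):
    return bd.build_quality_tables(hsg_models)


@pytest.fixture(scope="session")
def tiny_machine(quality_tables):
    """Three shallow beams: enough for engine-level unit tests."""
    return bd.generate_mini_machine(
        ranges_cm=[4.0, 5.0, 6.0], tables=quality_tables
    )


@pytest.fixture(scope="session")
def layered_machine(quality_tables):
    """Layers at 3 mm range spacing across a shallow target window."""
    return bd.generate_mini_machine(
        ranges_cm=np.arange(3.1, 6.35, 0.3), tables=quality_tables
    )


@pytest.fixture(scope="session")
def planning_machine(quality_tables):
    """Machine covering a shallow cubic target and the 21 cm reference SOBP."""
    ranges = np.concatenate([np.arange(3.4, 8.8, 0.3), np.arange(14.6, 21.6, 0.25)])
    return bd.generate_mini_machine(ranges_cm=ranges, tables=quality_tables)
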