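from __future__ import annotations

import copy

import numpy as np
import pytest

from foldrank import StructureModel, make_reference_chain


@pytest.fixture(scope="session")
def helix30() -> StructureModel:
    return make_reference_chain(30, style="helix", rng_seed=11)


@pytest.fixture(scope="session")
def walk40() -> StructureModel:
    return make_reference_chain(40, style="random_walk", rng_seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def perturb(model: StructureModel, sigma: float, rng: np.random.Generator,
            model_id: str | None = None) -> StructureModel:
    """Noisy copy of a model (helper, not a fixture)."""
    out = copy.deepcopy(model)
    out.ca_coords = out.ca_coords + sigma * rng.standard_normal(out.ca_coords.shape)
    if model_id:
        out.model_id = model_id
    return out


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 90.12           C
ATOM      3  C   ALA A   1      10.751   6.861  -4.190  1.00  0.00           C
ATOM      4  CA AGLY A   2      12.345   8.910  -2.200  0.40 80.00           C
ATOM      5  CA BGLY A   2      12.500   9.000  -2.100  0.60 70.00           C
ATOM      6  CA  SER A   3      14.021  10.500   1.234  1.00 60.55           C
TER
END
"""
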