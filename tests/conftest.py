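import numpy as np
import pytest

from sdscam.structmetrics.model import StructureModel
from sdscam.synthcells import CellFieldImage

#: small frame used by image tests so the suite stays fast; the reference
#: 2160x2560 frame is exercised by the acceptance tests
SMALL_FRAME = (720, 860)


def make_image(red: np.ndarray, green: np.ndarray, cell_radius: float = 1.0) -> CellFieldImage:
    return CellFieldImage(
        red.astype(np.float32), green.astype(np.float32), cell_radius,
        {"mode": "handmade"},
    )


def single_atom_model(
    element: str = "C",
    coords=(0.0, 0.0, 0.0),
    res_name: str = "ALA",
    atom_name: str = "CA",
    chain: str = "A",
    res_id: int = 1,
) -> StructureModel:
    return StructureModel.from_arrays(
        [chain], [res_id], [res_name], [atom_name], [element],
        np.array([coords], dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230502)
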