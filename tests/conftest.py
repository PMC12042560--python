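import numpy as np
import pandas as pd
import pytest

from qmoaks import (
    FieldParams,
    NormativeModel,
    RegionAtlas,
    ThicknessMap,
    REGION_CODES,
    make_grid_atlas,
)


@pytest.fixture
def tiny_atlas() -> RegionAtlas:
    """Ten landmarks, one per subregion."""
    return RegionAtlas(
        landmark_ids=np.arange(10),
        regions=np.asarray(REGION_CODES, dtype=object),
        area_weights=np.ones(10),
    )


@pytest.fixture
def grid_atlas() -> RegionAtlas:
    """4x4 grid per subregion (160 landmarks)."""
    return make_grid_atlas((4, 4))


@pytest.fixture
def field_params() -> FieldParams:
    return FieldParams(grid_shape=(4, 4))


def flat_model(n_landmarks: int, mean: float = 2.0, **kwargs) -> NormativeModel:
    """Normative model with a constant mean everywhere."""
    return NormativeModel(
        normative_mean=np.full(n_landmarks, mean), n_controls=2, **kwargs
    )


def constant_map(n_landmarks: int, value: float, knee="k1", visit=0) -> ThicknessMap:
    return ThicknessMap(knee_id=knee, visit_month=visit, thickness=np.full(n_landmarks, value))


def single_region_atlas(n: int, region: str = "cMF", weights=None) -> RegionAtlas:
    return RegionAtlas(
        landmark_ids=np.arange(n),
        regions=np.asarray([region] * n, dtype=object),
        area_weights=np.ones(n) if weights is None else np.asarray(weights, float),
    )


@pytest.fixture
def atlas_csv(tmp_path):
    path = tmp_path / "atlas.csv"
    pd.DataFrame(
        {"landmark_id": range(10), "region": list(REGION_CODES), "area_weight": 1.0}
    ).to_csv(path, index=False)
    return path
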