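import pandas as pd
import pytest

from rockveg.pipeline import PipelineConfig, run_pipeline
from rockveg.synth import SceneParams, gen_scene, sample_point_cloud


@pytest.fixture(scope="session")
def small_scene():
    """A compact outcrop scene: 160 m extent, 60 m rock dome."""
    params = SceneParams(extent=160.0, rock_radius=60.0, soil_tau=15.0)
    return gen_scene(seed=11, params=params)


@pytest.fixture(scope="session")
def small_cloud(small_scene):
    return sample_point_cloud(small_scene, seed=12)


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """Full pipeline artifacts on a small synthetic scene (session-cached)."""
    out = tmp_path_factory.mktemp("pipe")
    cfg = PipelineConfig(seed=3, scene_extent=200.0, k_init=10)
    art = run_pipeline(
        cfg,
        ["synth", "ingest", "profile", "classify", "polygonize", "model", "project"],
        out,
    )
    art["out_dir"] = out
    art["config"] = cfg
    return art


@pytest.fixture()
def toy_points():
    """Five hand-written valid point records."""
    return pd.DataFrame(
        {
            "x": [0.5, 1.5, 2.5, 3.5, 4.5],
            "y": [0.5, 0.5, 0.5, 0.5, 0.5],
            "z": [10.0, 11.0, 12.0, 13.0, 14.0],
            "return_number": [1, 1, 2, 1, 1],
            "intensity": [50.0, 55.0, 40.0, 60.0, 52.0],
            "scan_angle": [1.0, 2.0, 3.0, -2.0, 0.0],
            "run_id": ["A", "A", "A", "B", "B"],
            "is_ground": [True, False, False, False, True],
        }
    )
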