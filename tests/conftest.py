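import numpy as np
import pytest

import plaquefir as pf
from plaquefir.cli_pipeline import RunConfig, analyze_scene


@pytest.fixture(scope="session")
def axis():
    return pf.default_axis()


@pytest.fixture(scope="session")
def small_cube(axis):
    """Random 8x8x64 cube for I/O round-trip tests."""
    rng = np.random.default_rng(42)
    sub = pf.WavenumberAxis(axis.values[:64])
    data = rng.random((8, 8, 64)).astype(np.float32)
    return pf.HyperCube(data, sub, 1.1)


@pytest.fixture(scope="session")
def cored_scene():
    """One classic cored plaque, default conditions, fixed seed."""
    cfg = pf.single_plaque_config("classic_cored", rows=64, cols=64, seed=1)
    cube, truth = pf.simulate_scene(cfg)
    return cfg, cube, truth


@pytest.fixture(scope="session")
def cored_analysis():
    """Full-pipeline analysis of a single cored-plaque scene."""
    cfg = RunConfig(
        scene=pf.single_plaque_config("classic_cored", rows=64, cols=64, seed=1),
        n_control_patches=2,
        control_patch_um=12,
        make_figures=False,
    )
    df, report, art = analyze_scene(cfg)
    return cfg, df, report, art


@pytest.fixture(scope="session")
def diffuse_analysis():
    cfg = RunConfig(
        scene=pf.single_plaque_config("diffuse", rows=64, cols=64, seed=2),
        n_control_patches=2,
        control_patch_um=12,
        make_figures=False,
    )
    df, report, art = analyze_scene(cfg)
    return cfg, df, report, art
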