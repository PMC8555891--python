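import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from freywave.phantom import (
    PhantomGrid, TissueSpec, tissue_property_table, build_layered_head,
)
from freywave.cli_pipeline import ExposureScenario, run_pipeline

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table_1ghz():
    return tissue_property_table(1e9)


@pytest.fixture(scope="session")
def brain_tissue(table_1ghz):
    """Homogeneous gray-matter spec (c_bulk = 1450 m/s)."""
    return table_1ghz[4]


@pytest.fixture()
def vacuum_phantom(table_1ghz):
    labels = np.zeros((12, 12, 12), dtype=np.int16)
    return PhantomGrid(spacing=5e-3, labels=labels, tissue_table=table_1ghz,
                       head_length=0.0, probes={})


def make_sphere_phantom(radius, spacing, tissue, margin=2):
    """Voxelised homogeneous sphere in air (label 1)."""
    n = int(2 * radius / spacing) + 1 + 2 * margin
    idx = np.arange(n) - (n - 1) / 2.0
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2) * spacing
    labels = (r <= radius).astype(np.int16)
    ph = PhantomGrid(spacing=spacing, labels=labels, tissue_table={1: tissue},
                     head_length=2 * radius, probes={})
    return ph, r


@pytest.fixture(scope="session")
def smoke_scenario():
    """Desk-scale pipeline scenario: small spherical head, coarse grids."""
    return ExposureScenario(
        frequency=1e9, pin=1e6, tau_d=5e-6, direction="+y",
        phantom_shape="sphere", head_length=0.10,
        em_spacing=3e-3, wave_spacing=3e-3, wave_duration=3e-4,
    )


@pytest.fixture(scope="session")
def smoke_run(smoke_scenario, tmp_path_factory):
    """One full reference pipeline run with written artifacts."""
    outdir = tmp_path_factory.mktemp("smoke_ref")
    result = run_pipeline(smoke_scenario, outdir=outdir)
    return result, outdir


@pytest.fixture(scope="session")
def smoke_run_double_pin(smoke_scenario):
    """Independent full run at twice the incident power density."""
    import dataclasses

    sc2 = dataclasses.replace(smoke_scenario, pin=2 * smoke_scenario.pin)
    return run_pipeline(sc2)
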