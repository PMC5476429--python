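import numpy as np
import pytest

from fibsem_phys import detection, materials, scatter_mc


@pytest.fixture(scope="session")
def mask45() -> detection.AcceptanceMask:
    """The standard detector: 45-degree acceptance, +600 V sample bias."""
    return detection.AcceptanceMask(max_polar_angle=45.0, bias_voltage=600.0)


def _bulk_set(name: str, n: int, seed: int) -> scatter_mc.BackscatterSet:
    return scatter_mc.simulate(
        scatter_mc.SampleGeometry.bulk(materials.get_material(name)),
        scatter_mc.BeamConfig(1.2, n, seed))


@pytest.fixture(scope="session")
def gold_set() -> scatter_mc.BackscatterSet:
    """Gold at 1.2 keV, 30k trajectories (shared across tests)."""
    return _bulk_set("gold", 30_000, seed=11)


@pytest.fixture(scope="session")
def epoxy_set() -> scatter_mc.BackscatterSet:
    return _bulk_set("epoxy", 30_000, seed=12)


@pytest.fixture(scope="session")
def ptt_set() -> scatter_mc.BackscatterSet:
    return _bulk_set("pt_tetrakis", 30_000, seed=13)


@pytest.fixture(scope="session")
def cosine_law_set() -> scatter_mc.BackscatterSet:
    """Analytic fixture: exit angles following the cosine emission law.

    For p(theta) ~ cos(theta) sin(theta), cos^2(theta) is uniform, so a
    deterministic uniform grid of u gives theta = arccos(sqrt(u)) with
    exactly half the exits within 45 degrees.
    """
    n = 10_000
    u = (np.arange(n) + 0.5) / n
    theta = np.degrees(np.arccos(np.sqrt(u)))
    beam = scatter_mc.BeamConfig(1.2, n, 0)
    geom = scatter_mc.SampleGeometry.bulk(materials.get_material("gold"))
    return scatter_mc.BackscatterSet(
        exit_energy=np.full(n, 1.0), exit_angle=theta,
        exit_x=np.zeros(n), exit_y=np.zeros(n), max_depth=np.ones(n),
        n_primary=n, beam=beam, geometry=geom)
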