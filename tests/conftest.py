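import numpy as np
import pytest

from lisawave import ElasticMaterial
from lisawave.engine import default_time_step, run
from lisawave.grid import ExcitationSpec, PhantomGrid
from lisawave.measurement import extract_line_profile
from lisawave.rescaling import scale_material


@pytest.fixture(scope="session")
def gel_90k():
    """The 90 kPa phantom gel (nearly incompressible, water density)."""
    return ElasticMaterial(90e3, 0.495, 1000.0)


@pytest.fixture(scope="session")
def gel_30k():
    return ElasticMaterial(30e3, 0.495, 1000.0)


def simulate_bulk_column(
    material,
    n_cycles: float = 3.0,
    frequency: float = 150.0,
    spacing: float = 0.5e-3,
    n_cells: int = 240,
):
    """Plane shear wave down a laterally periodic column.

    The x displacement is prescribed uniformly on the top face, so a
    pure bulk shear wave of wavelength V_T/f travels down axis 1 with
    no guiding effects; the returned profile samples u(y) from the top.
    """
    grid = PhantomGrid(
        spacings=(spacing, spacing),
        cell_material=np.zeros((4, n_cells), dtype=np.int64),
        periodic=(True, False),
    )
    dt = default_time_step(material, grid.spacings)
    n_steps = int(round(n_cycles / frequency / dt))
    top = grid.node_shape[1] - 1
    nodes = tuple((i, top) for i in range(grid.node_shape[0]))
    excitation = ExcitationSpec(
        nodes=nodes, component=0, amplitude=1e-6, frequency=frequency
    )
    _, records = run(grid, material, excitation, [], dt, n_steps, snapshot_steps=[n_steps])
    return extract_line_profile(
        records.snapshots[n_steps], grid, (0, top), axis=1, component="x", direction=-1
    )


@pytest.fixture(scope="session")
def bulk_shear_profile(gel_30k):
    """Engine-produced bulk shear profile, wavelength ~21.1 mm."""
    return simulate_bulk_column(gel_30k)


@pytest.fixture(scope="session")
def bulk_shear_profile_scaled(gel_30k):
    """Same column with the density scaled by S = 3 (wavelength / sqrt 3)."""
    return simulate_bulk_column(scale_material(gel_30k, 3.0))
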