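import numpy as np
import pytest

import oligoquant as oq


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """Five disjoint elliptical nuclei with tracer/target/DAPI channels."""
    nuclei = oq.random_nuclei(5, (512, 512), diameter_range=(30, 60),
                              rng=np.random.default_rng(1))
    spec = oq.SceneSpec(
        image_shape=(512, 512),
        nuclei=nuclei,
        cytosol_margin=10,
        compartment_concentrations={
            "dapi": {"nucleus": 4e-7, "cytosol": 5e-8},
            "tracer": {"nucleus": 1e-7, "cytosol": 1e-7},
            "target": {"nucleus": 1e-7},
        },
        injected_cell_ids=frozenset({1, 3}),
        knockdown_factor=0.5,
        counts_per_molar=5e8,
        background_counts=0.5,
        bit_depth=8,
        seed=42,
    )
    return oq.generate_scene(spec)


@pytest.fixture(scope="session")
def gymnosis_field():
    """Cells with 52 planted vesicles each at 19.8 uM plus 296 nM nuclei."""
    from oligoquant.pipeline import gymnosis_scene
    return gymnosis_scene(seed=11, n_cells=4)
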