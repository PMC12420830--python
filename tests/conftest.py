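import numpy as np
import pandas as pd
import pytest

from spotcta import (
    assign_cells_to_spots,
    compose_spots,
    estimate_stain_vectors,
    rgb_to_od,
    segment_nuclei,
)
from spotcta.synthetic import (
    CloneSpec,
    GridParams,
    SceneParams,
    Segment,
    generate_he_scene,
    generate_spot_grid,
)


@pytest.fixture(scope="session")
def scene():
    """Mid-size H&E scene: 150 well-separated cells, 50 per class."""
    params = SceneParams(
        width_px=1300,
        height_px=1300,
        counts={"tumor": 50, "immune": 50, "stroma": 50},
        seed=7,
    )
    return generate_he_scene(params)


@pytest.fixture(scope="session")
def scene_stains(scene):
    return estimate_stain_vectors(scene.image)


@pytest.fixture(scope="session")
def scene_od(scene, scene_stains):
    return rgb_to_od(
        scene.image, scene_stains.background_rgb, pixel_size_um=scene.params.pixel_size_um
    )


@pytest.fixture(scope="session")
def scene_nuclei(scene_od, scene_stains):
    return segment_nuclei(scene_od, scene_stains)


@pytest.fixture(scope="session")
def grid():
    return generate_spot_grid(GridParams(rows=6, cols=6))


def random_composition(n_spots=40, n_cells=400, seed=0):
    """Random cells on the default grid -> composition with ground truth."""
    rng = np.random.default_rng(seed)
    g = generate_spot_grid(GridParams(rows=6, cols=6))
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "centroid_x_px": rng.uniform(0, 1400, n_cells),
            "centroid_y_px": rng.uniform(0, 1200, n_cells),
        }
    )
    assignment = assign_cells_to_spots(cells, g)
    labels = pd.Series(
        rng.choice(["tumor", "immune", "stroma"], n_cells), index=cells["cell_id"]
    )
    comp = compose_spots(assignment, labels, barcodes=list(g.table["barcode"]))
    return comp, assignment, labels


@pytest.fixture(scope="session")
def composition():
    return random_composition(seed=0)[0]


@pytest.fixture(scope="session")
def gene_order_4chrom():
    """600 genes on 4 chromosomes of 150 genes each."""
    return pd.DataFrame(
        {
            "gene": [f"G{i}" for i in range(600)],
            "chrom": [str(c + 1) for c in np.repeat(range(4), 150)],
            "start": list(range(150)) * 4,
            "stop": [i + 1 for i in range(150)] * 4,
        }
    )


@pytest.fixture(scope="session")
def two_clone_fixture(gene_order_4chrom):
    """Two clones with disjoint 150-gene alterations plus reference spots."""
    clone_a = CloneSpec("A", [Segment("2", 0, 150, 1.0)], [f"qa{i}" for i in range(100)])
    clone_b = CloneSpec("B", [Segment("4", 0, 150, -1.0)], [f"qb{i}" for i in range(100)])
    refs = [f"r{i}" for i in range(100)]
    return gene_order_4chrom, [clone_a, clone_b], refs
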