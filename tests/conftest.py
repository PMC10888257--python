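import numpy as np
import pytest
from scipy.spatial import cKDTree

from beadmosaic import (
    SimConfig,
    simulate_bead_image_set,
    register_rounds,
    segment_beads,
    propagate_mask,
    extract_bead_table,
    normalize_intensities,
)


@pytest.fixture(scope="session")
def mixed_field():
    """A simulated field containing all four bead classes.

    Seeding rate 0.3 with VAF 0.1 yields empties, wild-type, mutant, and a
    few mixed beads in one 1200-bead field; noise 20 vs signal 900 gives a
    45-sigma class separation.
    """
    cfg = SimConfig(seed=2, image_size=(768, 768), n_beads=1200,
                    true_vaf=0.1, seeding_rate=0.3)
    image_set, truth = simulate_bead_image_set(cfg)
    return cfg, image_set, truth


@pytest.fixture(scope="session")
def mixed_field_table(mixed_field):
    """The mixed field taken through registration -> extraction, plus the
    true class of every extracted bead (matched by centroid)."""
    cfg, image_set, truth = mixed_field
    reg = register_rounds(image_set[("scan1", "brightfield")],
                          image_set[("dyeswitch", "brightfield")])
    mask1 = segment_beads(image_set[("scan1", "brightfield")],
                          bead_radius=cfg.bead_radius)
    mask2 = segment_beads(image_set[("dyeswitch", "brightfield")],
                          bead_radius=cfg.bead_radius)
    _, matched = propagate_mask(mask1, reg, mask2)
    table = extract_bead_table(image_set, mask1, reg, matched)
    dist, idx = cKDTree(truth.bead_centers).query(table[["y", "x"]].to_numpy())
    assert dist.max() < 1.5, "extracted centroids should match simulated beads"
    return cfg, table, truth.bead_classes[idx]


@pytest.fixture(scope="session")
def normalized_table(mixed_field_table):
    cfg, table, true_classes = mixed_field_table
    return cfg, normalize_intensities(table), true_classes
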