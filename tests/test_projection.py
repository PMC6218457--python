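import numpy as np
import pandas as pd
import pytest

from projectome import errors
from projectome.atlas import LabelVolume, MidlinePlane, RegionOntology, Side
from projectome.morphometry import count_tips
from projectome.projection import (
    compute_profile,
    hemisphere_split,
    projection_matrix,
    projection_strengths,
    segment_region_lengths,
    side_lengths,
    tips_per_region,
)
from projectome.swc import Morphology, MorphNode, StructureClass
from treegen import make_morph, random_tree, y_tree


def two_region_volume():
    """Regions 1 | 2 split at x = 10 μm; 20×20×20 μm extent."""
    labels = np.zeros((2, 2, 2), dtype=np.int32)
    labels[0], labels[1] = 1, 2
    return LabelVolume(labels, voxel_size=(10.0, 10.0, 10.0))


def test_axon_wholly_inside_one_region():
    vol = two_region_volume()
    m = make_morph([(1, 1, 1, 1, 1, -1), (2, 2, 8, 8, 8, 1)])
    lengths = segment_region_lengths(m, vol, step=1.0)
    assert set(lengths) == {1}
    assert lengths[1] == pytest.approx(np.linalg.norm([7, 7, 7]))


def test_boundary_crossing_split_matches_analytic_clipping():
    vol = two_region_volume()
    m = make_morph([(1, 1, 0, 5, 5, -1), (2, 2, 20, 5, 5, 1)])
    step = 1.0
    lengths = segment_region_lengths(m, vol, step=step)
    # analytic clipping: exactly 10 μm on either side of the x=10 boundary
    assert lengths[1] == pytest.approx(10.0, abs=step)
    assert lengths[2] == pytest.approx(10.0, abs=step)
    assert lengths[1] + lengths[2] == pytest.approx(20.0, rel=1e-12)


def test_cable_outside_volume_goes_to_background():
    vol = two_region_volume()
    m = make_morph([(1, 1, -50, -50, -50, -1), (2, 2, -30, -50, -50, 1)])
    lengths = segment_region_lengths(m, vol, step=2.0)
    assert set(lengths) == {0}
    assert lengths[0] == pytest.approx(20.0)


def test_conservation_on_random_morphologies(atlas_bundle):
    vol = atlas_bundle.volume
    for seed in range(10):
        m = random_tree(seed, 200)
        try:
            lengths = segment_region_lengths(m, vol, step=37.0)
        except errors.EmptyAxon:
            continue
        from projectome.morphometry import cable_length

        total = cable_length(m, StructureClass.AXON)
        assert sum(lengths.values()) == pytest.approx(total, rel=1e-6)


def test_refinement_stability_under_step_halving():
    vol = two_region_volume()
    rng = np.random.default_rng(0)
    nodes = [MorphNode(1, 1, 10.0, 10.0, 10.0, 1.0, -1)]
    for i in range(2, 60):
        x, y, z = rng.uniform(0, 20, 3)
        nodes.append(MorphNode(i, 2, x, y, z, 1.0, int(rng.integers(1, i))))
    m = Morphology(nodes)
    a = segment_region_lengths(m, vol, step=2.0)
    b = segment_region_lengths(m, vol, step=1.0)
    total = sum(a.values())
    for rid in set(a) | set(b):
        assert abs(a.get(rid, 0) - b.get(rid, 0)) / total < 0.01


def test_empty_axon_raises():
    m = make_morph([(1, 1, 0, 0, 0, -1), (2, 3, 5, 0, 0, 1)])
    with pytest.raises(errors.EmptyAxon):
        segment_region_lengths(m, two_region_volume(), step=1.0)


def test_hemisphere_split_all_ipsilateral():
    vol = two_region_volume()
    mid = MidlinePlane("x", 10.0)
    m = make_morph([(1, 1, 2, 5, 5, -1), (2, 2, 8, 5, 5, 1)])
    split = hemisphere_split(m, vol, mid, step=0.5)
    assert split.ipsi_fraction == pytest.approx(1.0)
    assert split.contra_length == 0.0


def test_hemisphere_split_constructed_30_70():
    vol = two_region_volume()
    mid = MidlinePlane("x", 10.0)
    # soma left; 30 μm of axon left of the plane, 70 μm right (y-runs)
    m = make_morph(
        [
            (1, 1, 5, 5, 5, -1),
            (2, 2, 5, 5 + 30, 5, 1),  # 30 μm at x=5 (left)
            (3, 2, 15, 5 + 30, 5, 2),  # 10 μm crossing: 5 left, 5 right
            (4, 2, 15, 5 + 30 + 65, 5, 3),  # 65 μm at x=15 (right)
        ]
    )
    split = hemisphere_split(m, vol, mid, step=0.1)
    assert split.ipsi_length == pytest.approx(35.0, abs=0.2)
    assert split.contra_length == pytest.approx(70.0, abs=0.2)
    assert split.ipsi_length + split.contra_length + split.on_midline_length == pytest.approx(
        split.total_axon_length, rel=1e-6
    )


def _mirror(m: Morphology, mid: MidlinePlane) -> Morphology:
    axis = mid.axis_index
    out = []
    for n in m.nodes:
        pos = [n.x, n.y, n.z]
        pos[axis] = 2 * mid.coordinate - pos[axis]
        out.append(MorphNode(n.node_id, n.type_code, *pos, n.radius, n.parent_id))
    return Morphology(out, name=m.name)


def test_mirroring_swaps_left_right_exactly_and_preserves_ipsi_contra(atlas_bundle):
    mid = atlas_bundle.midline
    m = random_tree(5, 300)
    mirrored = _mirror(m, mid)
    s = side_lengths(m, mid, step=25.0)
    sm = side_lengths(mirrored, mid, step=25.0)
    assert sm[Side.LEFT] == s[Side.RIGHT]
    assert sm[Side.RIGHT] == s[Side.LEFT]
    assert sm[Side.ON_MIDLINE] == s[Side.ON_MIDLINE]
    # ipsi/contra follow the soma, which mirrors too
    vol = atlas_bundle.volume
    a = hemisphere_split(m, vol, mid, step=25.0)
    b = hemisphere_split(mirrored, vol, mid, step=25.0)
    assert b.ipsi_length == a.ipsi_length
    assert b.contra_length == a.contra_length


def test_tips_per_region_cross_module_conservation(atlas_bundle):
    for seed in (0, 1, 2):
        m = random_tree(seed, 150)
        counts = tips_per_region(m, atlas_bundle.volume)
        assert sum(counts.values()) == count_tips(m, StructureClass.AXON)


def test_tips_assigned_to_their_regions():
    vol = two_region_volume()
    m = make_morph(
        [(1, 1, 5, 5, 5, -1), (2, 2, 9, 5, 5, 1), (3, 2, 4, 8, 8, 2), (4, 2, 16, 2, 2, 2)]
    )
    assert tips_per_region(m, vol) == {1: 1, 2: 1}


@pytest.fixture
def tiny_ontology():
    return RegionOntology(
        pd.DataFrame(
            [
                {"region_id": 1, "acronym": "brain", "name": "", "parent_id": -1},
                {"region_id": 2, "acronym": "MO", "name": "", "parent_id": 1},
                {"region_id": 3, "acronym": "MO5", "name": "", "parent_id": 2, "layer": "5"},
                {"region_id": 4, "acronym": "CP", "name": "", "parent_id": 1},
            ]
        )
    )


def test_strengths_aggregate_up_ontology(tiny_ontology):
    labels = np.zeros((2, 1, 1), dtype=np.int32)
    labels[0], labels[1] = 3, 4  # MO5 | CP
    vol = LabelVolume(labels, voxel_size=(10, 10, 10))
    mid = MidlinePlane("x", 10.0)
    m = make_morph([(1, 1, 2, 5, 5, -1), (2, 2, 8, 5, 5, 1)])  # all cable in MO5
    prof = compute_profile(m, vol, mid, step=0.5)
    s = projection_strengths(prof, tiny_ontology, ["MO"])
    assert s[tiny_ontology.id_of("MO")] == pytest.approx(1.0)


def test_even_split_and_matrix_row_sums(tiny_ontology):
    labels = np.zeros((2, 1, 1), dtype=np.int32)
    labels[0], labels[1] = 3, 4
    vol = LabelVolume(labels, voxel_size=(10, 10, 10))
    mid = MidlinePlane("x", 10.0)
    m = make_morph([(1, 1, 0, 5, 5, -1), (2, 2, 20, 5, 5, 1)])
    prof = compute_profile(m, vol, mid, step=0.1)
    s = projection_strengths(prof, tiny_ontology, ["MO", "CP"])
    assert s[tiny_ontology.id_of("MO")] == pytest.approx(0.5, abs=0.01)
    assert s[tiny_ontology.id_of("CP")] == pytest.approx(0.5, abs=0.01)

    mat = projection_matrix([prof, prof], tiny_ontology, ["MO", "CP"])
    assert list(mat.columns) == ["MO", "CP", "background"]
    assert np.allclose(mat.sum(axis=1), 1.0)


def test_single_region_matrix_is_unit(tiny_ontology):
    labels = np.full((1, 1, 1), 4, dtype=np.int32)
    vol = LabelVolume(labels, voxel_size=(10, 10, 10))
    m = make_morph([(1, 1, 2, 5, 5, -1), (2, 2, 8, 5, 5, 1)])
    prof = compute_profile(m, vol, MidlinePlane("x", 5.0), step=0.5)
    mat = projection_matrix([prof], tiny_ontology, ["CP"])
    assert mat.loc[m.name, "CP"] == pytest.approx(1.0)
    assert mat.loc[m.name, "background"] == pytest.approx(0.0)


def test_zero_length_strengths_raise(tiny_ontology):
    from projectome.projection import ProjectionProfile

    prof = ProjectionProfile("x", 0, Side.LEFT, {}, {}, 0.0)
    with pytest.raises(errors.ZeroLength):
        projection_strengths(prof, tiny_ontology, ["CP"])
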