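import numpy as np
import pytest

from projectome import errors
from projectome.atlas import Side, hemisphere_of
from projectome.classify import classify_it
from projectome.morphometry import (
    count_branches,
    count_branchpoints,
    count_tips,
    summarize_neuron,
)
from projectome.projection import compute_profile
from projectome.swc import StructureClass, swc_string
from projectome.synthetic import (
    AtlasSpec,
    NeuronSpec,
    RegionBoxSpec,
    default_atlas_spec,
    make_atlas,
    simulate_neuron,
    simulate_population,
)


def test_single_bilateral_box_gives_three_ids():
    spec = AtlasSpec(
        shape=(10, 4, 4),
        voxel_size=(10.0, 10.0, 10.0),
        origin=(0.0, 0.0, 0.0),
        midline_axis="x",
        midline_coordinate=50.0,
        boxes=[
            RegionBoxSpec("R-L", "R", ((10, 40), (0, 40), (0, 40)), "left"),
            RegionBoxSpec("R-R", "R", ((60, 90), (0, 40), (0, 40)), "right"),
        ],
    )
    a = make_atlas(spec)
    assert set(np.unique(a.volume.labels)) == {0, a.ontology.id_of("R-L"), a.ontology.id_of("R-R")}
    # mirror pair shares an area parent
    assert a.ontology.parent(a.ontology.id_of("R-L")) == a.ontology.id_of("R")
    assert a.ontology.parent(a.ontology.id_of("R-R")) == a.ontology.id_of("R")


def test_default_atlas_is_mirror_symmetric_up_to_id_swap(atlas_bundle):
    a = atlas_bundle
    labels = a.volume.labels
    reflected = labels[::-1, :, :]
    # build the left<->right id swap from acronyms
    swap = {}
    for rid in a.ontology.region_ids():
        acr = a.ontology.acronym(rid)
        if acr.endswith("-L"):
            swap[rid] = a.ontology.id_of(acr[:-2] + "-R")
        elif acr.endswith("-R"):
            swap[rid] = a.ontology.id_of(acr[:-2] + "-L")
        else:
            swap[rid] = rid
    swap[0] = 0
    lut = np.zeros(max(swap) + 1, dtype=labels.dtype)
    for k, v in swap.items():
        lut[k] = v
    assert np.array_equal(lut[reflected], labels)


def test_cc_band_straddles_midline(atlas_bundle):
    a = atlas_bundle
    cc_id = a.ontology.id_of("cc")
    xs, _, _ = np.nonzero(a.volume.labels == cc_id)
    x_left = a.volume.origin[0] + xs.min() * a.volume.voxel_size[0]
    x_right = a.volume.origin[0] + (xs.max() + 1) * a.volume.voxel_size[0]
    assert x_left < a.midline.coordinate < x_right


def test_out_of_bounds_box_rejected():
    spec = default_atlas_spec()
    spec.boxes.append(RegionBoxSpec("bad", "", ((0, 20000), (0, 100), (0, 100)), "left"))
    with pytest.raises(errors.BoxOutOfBounds):
        make_atlas(spec)


def test_overlapping_layer_slabs_rejected():
    spec = default_atlas_spec()
    spec.boxes.append(
        RegionBoxSpec("MOsX-L", "MOs-L", ((3000, 4600), (5500, 7500), (700, 900)), "left", "1")
    )
    with pytest.raises(errors.OverlappingLayerSlabs):
        make_atlas(spec)


def _basic_spec(atlas, **kw):
    defaults = dict(
        name="n1",
        soma=(3800.0, 6500.0, 1700.0),  # MOs5-L
        it_class="APN",
        target_weights={"CP-L": 1.0},
        total_axon_mm=50.0,
        dendrite_mm=6.0,
        branch_rate_per_mm=6.0,
        seed=11,
    )
    defaults.update(kw)
    return NeuronSpec(**defaults)


def test_same_seed_gives_byte_identical_swc(atlas_bundle):
    spec = _basic_spec(atlas_bundle)
    m1, _ = simulate_neuron(spec, atlas_bundle)
    m2, _ = simulate_neuron(spec, atlas_bundle)
    assert swc_string(m1) == swc_string(m2)


def test_single_target_realizes_at_least_90_percent(atlas_bundle):
    m, gt = simulate_neuron(_basic_spec(atlas_bundle), atlas_bundle)
    cp = atlas_bundle.ontology.id_of("CP-L")
    assert gt.region_fractions[cp] >= 0.9  # routing overhead < 10%


def test_cpn_round_trips_through_classifier(atlas_bundle):
    a = atlas_bundle
    spec = _basic_spec(
        a,
        it_class="CPN",
        target_weights={"CP-L": 0.4, "CP-R": 0.3, "MOs5-R": 0.3},
        seed=5,
    )
    m, gt = simulate_neuron(spec, a)
    assert gt.it_class == "CPN"
    assert gt.crossed_via_cc
    rec = classify_it(m, a.volume, a.midline, a.ontology, a.ontology.id_of("cc"))
    assert rec.it_subclass == "CPN"
    assert rec.crossed_via_cc


def test_cpn_without_contralateral_target_rejected(atlas_bundle):
    with pytest.raises(ValueError):
        simulate_neuron(
            _basic_spec(atlas_bundle, it_class="CPN", target_weights={"CP-L": 1.0}),
            atlas_bundle,
        )


def test_ground_truth_closure_with_projection_module(atlas_bundle):
    a = atlas_bundle
    spec = _basic_spec(
        a, target_weights={"CP-L": 0.5, "SS-L": 0.3, "AI-L": 0.2}, seed=23
    )
    m, gt = simulate_neuron(spec, a)
    prof = compute_profile(m, a.volume, a.midline)
    s = prof.strengths()
    for rid, frac in gt.region_fractions.items():
        assert s.get(rid, 0.0) == pytest.approx(frac, abs=0.01)
    assert prof.total_axon_length == pytest.approx(gt.total_axon_um, rel=1e-9)


def test_weight_recovery_within_tolerance(atlas_bundle):
    """Requested weights {CP: 0.7, MOs5: 0.3} recovered within 0.05 at 100 mm."""
    a = atlas_bundle
    spec = _basic_spec(
        a, target_weights={"CP-L": 0.7, "MOs5-L": 0.3}, total_axon_mm=100.0, seed=9
    )
    m, gt = simulate_neuron(spec, a)
    prof = compute_profile(m, a.volume, a.midline)
    s = prof.strengths()
    assert s[a.ontology.id_of("CP-L")] == pytest.approx(0.7, abs=0.05)
    assert s[a.ontology.id_of("MOs5-L")] == pytest.approx(0.3, abs=0.05)


def test_population_basics(atlas_bundle):
    pop = simulate_population(1, "pl_l23", seed=0, atlas=atlas_bundle)
    assert len(pop) == 1
    two_a = simulate_population(2, "orbm_l23", seed=1, atlas=atlas_bundle)
    two_b = simulate_population(2, "orbm_l23", seed=2, atlas=atlas_bundle)
    assert swc_string(two_a[0][0]) != swc_string(two_b[0][0])
    with pytest.raises(KeyError):
        simulate_population(2, "nope", seed=0, atlas=atlas_bundle)


def test_population_is_reproducible(atlas_bundle):
    a = simulate_population(2, "mos_l23", seed=7, atlas=atlas_bundle)
    b = simulate_population(2, "mos_l23", seed=7, atlas=atlas_bundle)
    assert [swc_string(m) for m, _ in a] == [swc_string(m) for m, _ in b]


def test_layer5_population_matches_printed_regime(atlas_bundle):
    """Six layer-5 somata: totals in the printed range, sum > 1,600 mm,
    topology identity exact, somata in the layer-5 slab, all callosal."""
    pop = simulate_population(6, "mos_l5", seed=1, atlas=atlas_bundle)
    total = 0.0
    for m, gt in pop:
        rec = summarize_neuron(m)
        assert 180.04 <= rec.axonal_length_mm <= 318.43
        total += rec.axonal_length_mm
        assert rec.axonal_branches == rec.axonal_tips + count_branchpoints(
            m, StructureClass.AXON
        )
        assert gt.it_class == "CPN"
        assert atlas_bundle.ontology.acronym(
            __import__("projectome").atlas.region_at(atlas_bundle.volume, m.root.position)
        ) == "MOs5-L"
    assert total > 1600.0


def test_l23_population_class_mix(atlas_bundle):
    pop = simulate_population(17, "mos_l23", seed=4, atlas=atlas_bundle)
    classes = [gt.it_class for _, gt in pop]
    assert classes.count("CPN") == 10
    assert classes.count("APN") == 7
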