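import numpy as np
import pandas as pd
import pytest

from projectome import errors
from projectome.classify import assign_soma_location, categorize_profiles, classify_it
from projectome.swc import Morphology, MorphNode
from treegen import make_morph


def test_soma_location_with_layer(atlas_bundle):
    a = atlas_bundle
    soma = (3800.0, 6500.0, 1000.0)  # inside MOs2/3-L
    m = make_morph([(1, 1, *soma, -1), (2, 2, soma[0] + 50, soma[1], soma[2], 1)])
    rid, layer = assign_soma_location(m, a.volume, a.ontology)
    assert a.ontology.acronym(rid) == "MOs2/3-L"
    assert layer == "2/3"


def test_soma_in_unlayered_region(atlas_bundle):
    a = atlas_bundle
    soma = (3000.0, 5500.0, 3500.0)  # CP-L
    m = make_morph([(1, 1, *soma, -1), (2, 2, soma[0] + 50, soma[1], soma[2], 1)])
    rid, layer = assign_soma_location(m, a.volume, a.ontology)
    assert a.ontology.acronym(rid) == "CP-L"
    assert layer == "unknown"


def test_soma_outside_volume_raises(atlas_bundle):
    a = atlas_bundle
    m = make_morph([(1, 1, 50, 50, 5900, -1), (2, 2, 100, 50, 5900, 1)])  # background
    with pytest.raises(errors.SomaOutsideVolume):
        assign_soma_location(m, a.volume, a.ontology)


def _neuron_with_contra(atlas_bundle, contra_mm: float, via_cc: bool) -> Morphology:
    """Soma in MOs2/3-L; a straight contralateral run of the given length.

    When ``via_cc`` the crossing passes through the corpus-callosum band
    (y=5000, z=2200), otherwise above it (z=1000).
    """
    soma = np.array([3800.0, 5800.0, 1200.0])
    y, z = (5000.0, 2200.0) if via_cc else (5800.0, 1000.0)
    nodes = [
        MorphNode(1, 1, *soma, 5.0, -1),
        MorphNode(2, 2, 4900.0, y, z, 1.0, 1),  # ipsi approach
        MorphNode(3, 2, 5100.0, y, z, 1.0, 2),  # crossing
    ]
    # extend contralaterally by contra_mm (μm = mm * 1000), minus the 100 μm already across
    extra = contra_mm * 1000.0 - 100.0
    nodes.append(MorphNode(4, 2, 5100.0 + extra, y, z, 1.0, 3))
    return Morphology(nodes, name="constructed")


def test_all_ipsilateral_axon_is_apn(atlas_bundle):
    a = atlas_bundle
    soma = (3800.0, 5800.0, 1200.0)
    m = make_morph([(1, 1, *soma, -1), (2, 2, 3000.0, 5000.0, 3000.0, 1)])
    rec = classify_it(m, a.volume, a.midline, a.ontology, a.ontology.id_of("cc"))
    assert rec.it_subclass == "APN"
    assert rec.contra_axon_mm == 0.0
    assert not rec.crossed_via_cc


def test_contralateral_5mm_via_cc_is_cpn(atlas_bundle):
    a = atlas_bundle
    m = _neuron_with_contra(a, contra_mm=5.0, via_cc=True)
    rec = classify_it(m, a.volume, a.midline, a.ontology, a.ontology.id_of("cc"))
    assert rec.it_subclass == "CPN"
    assert rec.crossed_via_cc
    assert rec.contra_axon_mm == pytest.approx(5.0, abs=0.2)


def test_subthreshold_contra_is_apn(atlas_bundle):
    a = atlas_bundle
    m = _neuron_with_contra(a, contra_mm=0.5, via_cc=True)
    rec = classify_it(
        m, a.volume, a.midline, a.ontology, a.ontology.id_of("cc"), min_contra_mm=1.0
    )
    assert rec.it_subclass == "APN"
    assert rec.crossed_via_cc  # geometric fact reported separately from the class


def test_crossing_outside_cc_detected(atlas_bundle):
    a = atlas_bundle
    m = _neuron_with_contra(a, contra_mm=5.0, via_cc=False)
    rec = classify_it(m, a.volume, a.midline, a.ontology, a.ontology.id_of("cc"))
    assert rec.it_subclass == "CPN"
    assert not rec.crossed_via_cc


def test_translation_along_midline_plane_invariance(atlas_bundle):
    a = atlas_bundle
    m = _neuron_with_contra(a, contra_mm=3.0, via_cc=True)
    shifted = Morphology(
        [
            MorphNode(n.node_id, n.type_code, n.x, n.y + 400.0, n.z, n.radius, n.parent_id)
            for n in m.nodes
        ],
        name=m.name,
    )
    r1 = classify_it(m, a.volume, a.midline, a.ontology, a.ontology.id_of("cc"))
    r2 = classify_it(shifted, a.volume, a.midline, a.ontology, a.ontology.id_of("cc"))
    assert r1.it_subclass == r2.it_subclass
    assert r1.contra_axon_mm == pytest.approx(r2.contra_axon_mm, rel=1e-9)


def _matrix(rows):
    return pd.DataFrame(rows).set_index("name")


def test_identical_target_sets_share_category():
    mat = _matrix(
        [
            {"name": "n1", "A": 0.5, "B": 0.5, "C": 0.0},
            {"name": "n2", "A": 0.6, "B": 0.4, "C": 0.0},
        ]
    )
    cats = categorize_profiles(mat, theta=0.05)
    assert cats["n1"] == cats["n2"]


def test_disjoint_target_sets_split():
    mat = _matrix(
        [
            {"name": "n1", "A": 0.5, "B": 0.5, "C": 0.0, "D": 0.0},
            {"name": "n2", "A": 0.0, "B": 0.0, "C": 0.5, "D": 0.5},
        ]
    )
    cats = categorize_profiles(mat, theta=0.05)
    assert cats["n1"] != cats["n2"]


def test_jaccard_two_thirds_merges():
    # {A,B} vs {A,B,C}: Jaccard 2/3 >= 0.5
    mat = _matrix(
        [
            {"name": "n1", "A": 0.5, "B": 0.5, "C": 0.0},
            {"name": "n2", "A": 0.4, "B": 0.3, "C": 0.3},
        ]
    )
    cats = categorize_profiles(mat, theta=0.05, jaccard_cutoff=0.5)
    assert cats["n1"] == cats["n2"]


def test_categorization_permutation_equivariant():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(12):
        w = rng.dirichlet(np.ones(5) * 0.7)
        rows.append({"name": f"n{i}", **{k: v for k, v in zip("ABCDE", w)}})
    mat = _matrix(rows)
    cats = categorize_profiles(mat)
    perm = rng.permutation(len(rows))
    cats_p = categorize_profiles(mat.iloc[perm])
    # same partition: category ids may be renumbered, membership may not
    def partition(c):
        groups = {}
        for name, cid in c.items():
            groups.setdefault(cid, set()).add(name)
        return {frozenset(v) for v in groups.values()}

    assert partition(cats) == partition(cats_p)


def test_categorization_matches_scipy_single_linkage():
    """Independent oracle: scipy single-linkage on Jaccard distances, cut at 0.5."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    rng = np.random.default_rng(7)
    rows = []
    for i in range(15):
        w = rng.dirichlet(np.ones(6) * 0.5)
        rows.append({"name": f"n{i}", **{k: v for k, v in zip("ABCDEF", w)}})
    mat = _matrix(rows)
    theta = 0.05
    binary = (mat.to_numpy() >= theta).astype(bool)
    dist = pdist(binary, metric="jaccard")  # 1 - similarity
    labels = fcluster(linkage(dist, method="single"), t=0.5, criterion="distance")
    cats = categorize_profiles(mat, theta=theta, jaccard_cutoff=0.5)

    ours = {}
    for name, cid in cats.items():
        ours.setdefault(cid, set()).add(name)
    theirs = {}
    for name, cid in zip(mat.index, labels):
        theirs.setdefault(cid, set()).add(name)
    assert {frozenset(v) for v in ours.values()} == {frozenset(v) for v in theirs.values()}


def test_empty_matrix_raises():
    with pytest.raises(errors.EmptyMatrix):
        categorize_profiles(pd.DataFrame(columns=["A"]))
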