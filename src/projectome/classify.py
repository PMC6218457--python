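"""Soma localization and IT-subclass / profile-category assignment.

Intratelencephalic (IT) cortical neurons split into callosal projection
neurons (CPNs), whose axons cross the midline through the corpus callosum
and arborize contralaterally, and associative projection neurons (APNs),
which stay within the ipsilateral hemisphere.  The operational CPN rule
here is a contralateral axonal cable length at or above a configurable
threshold (default 1.0 mm); whether the axon actually passes through the
corpus-callosum label is recorded separately as ``crossed_via_cc`` rather
than made part of the definition, so a stray sub-threshold crossing does
not flip the class.

Projection-profile categories replace a qualitative by-eye grouping with
a deterministic rule: binarize each neuron's region-strength row at a
threshold theta (a region is a target iff its fraction >= theta), then
single-linkage-merge neurons whose target sets have Jaccard similarity at
or above a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .atlas import LabelVolume, MidlinePlane, RegionOntology, Side, hemisphere_of, region_at, region_at_points
from .errors import EmptyAxon, EmptyMatrix, SomaOutsideVolume
from .projection import axon_pieces, hemisphere_split, _default_step
from .swc import Morphology

__all__ = [
    "NeuronClassRecord",
    "assign_soma_location",
    "classify_it",
    "categorize_profiles",
]

DEFAULT_MIN_CONTRA_MM = 1.0
DEFAULT_THETA = 0.05
DEFAULT_JACCARD_CUTOFF = 0.5


@dataclass(frozen=True)
class NeuronClassRecord:
    name: str
    soma_region: int
    soma_layer: str  # '1', '2/3', '5' or 'unknown'
    it_subclass: str  # 'CPN' or 'APN'
    contra_axon_mm: float
    crossed_via_cc: bool
    ap_extension_um: float = float("nan")  # signed contralateral-centroid shift, descriptive only


def assign_soma_location(
    m: Morphology, vol: LabelVolume, ont: RegionOntology
) -> Tuple[int, str]:
    """(region id, layer tag) at the soma position.

    The layer is the region's own layer tag or that of its nearest
    layer-typed ancestor, else 'unknown'.  Raises
    :class:`SomaOutsideVolume` if the soma voxel is background.
    """
    rid = region_at(vol, m.root.position)
    if rid == 0:
        raise SomaOutsideVolume(m.root.position)
    return rid, ont.layer_of(rid)


def classify_it(
    m: Morphology,
    vol: LabelVolume,
    mid: MidlinePlane,
    ont: RegionOntology,
    cc_region: Optional[int],
    min_contra_mm: float = DEFAULT_MIN_CONTRA_MM,
    step: Optional[float] = None,
    ap_axis: str = "y",
) -> NeuronClassRecord:
    """Classify one neuron as CPN or APN.

    CPN iff the contralateral axonal cable length is at least
    ``min_contra_mm``.  ``crossed_via_cc`` is set iff any axonal
    subsegment midpoint falls in ``cc_region`` (or one of its
    descendants).  ``ap_extension_um`` is the signed displacement of the
    contralateral axonal-cable centroid from the soma along ``ap_axis``
    (NaN when there is no contralateral cable) — descriptive output only.
    """
    step = _default_step(vol, step)
    split = hemisphere_split(m, vol, mid, step)
    contra_mm = split.contra_length / 1000.0

    mids, lens = axon_pieces(m, step)
    regions = region_at_points(vol, mids)
    if cc_region is None:
        crossed = False
    else:
        cc_ids = {cc_region} | {
            rid for rid in ont.region_ids() if cc_region in ont.ancestors(rid)
        }
        crossed = bool(np.isin(regions, list(cc_ids)).any())

    soma_region, soma_layer = assign_soma_location(m, vol, ont)

    soma_side = hemisphere_of(m.root.position, mid)
    coord = mids[:, mid.axis_index]
    if soma_side is Side.RIGHT:
        contra_mask = coord < mid.coordinate
    else:
        contra_mask = coord > mid.coordinate
    ap_idx = {"x": 0, "y": 1, "z": 2}[ap_axis]
    if contra_mask.any():
        centroid = float(np.average(mids[contra_mask, ap_idx], weights=lens[contra_mask]))
        ap_ext = centroid - m.root.position[ap_idx]
    else:
        ap_ext = float("nan")

    return NeuronClassRecord(
        name=m.name,
        soma_region=soma_region,
        soma_layer=soma_layer,
        it_subclass="CPN" if contra_mm >= min_contra_mm else "APN",
        contra_axon_mm=contra_mm,
        crossed_via_cc=crossed,
        ap_extension_um=ap_ext,
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def categorize_profiles(
    matrix: pd.DataFrame,
    theta: float = DEFAULT_THETA,
    jaccard_cutoff: float = DEFAULT_JACCARD_CUTOFF,
) -> Dict[str, int]:
    """Group neurons by thresholded target-set similarity.

    ``matrix`` is a neurons × regions strength DataFrame (rows sum to 1;
    a 'background' column, if present, is ignored for target sets).
    Returns neuron name -> category id; ids are numbered 1.. in order of
    each category's first member, so the grouping is deterministic and
    permutation-equivariant.
    """
    if matrix.shape[0] == 0:
        raise EmptyMatrix("no neuron rows to categorize")
    cols = [c for c in matrix.columns if c != "background"]
    names = list(matrix.index)
    targets = [
        frozenset(c for c in cols if matrix.loc[name, c] >= theta) for name in names
    ]
    # single linkage via union-find over all >=cutoff pairs
    parent = list(range(len(names)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if _jaccard(targets[i], targets[j]) >= jaccard_cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    category: Dict[str, int] = {}
    root_to_cat: Dict[int, int] = {}
    for i, name in enumerate(names):
        r = find(i)
        if r not in root_to_cat:
            root_to_cat[r] = len(root_to_cat) + 1
        category[name] = root_to_cat[r]
    return category
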