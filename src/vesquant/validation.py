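"""Scoring measured graphs against generator ground truth.

Used by the test-suite and the reproduction script to quantify how well the
image pipeline (binarize -> skeletonize -> graph -> generations) recovers
the known geometry of synthetic eyes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .generations import GenerationMap
from .synthgen import GroundTruth
from .vesselgraph import VesselGraph

__all__ = ["true_generation_of_edges", "generation_label_accuracy"]


def true_generation_of_edges(graph: VesselGraph, gt: GroundTruth
                             ) -> dict[int, int]:
    """Majority-vote true generation per measured edge.

    The ground-truth centerlines are rasterized with their generation
    labels; every measured polyline pixel reads the label of the nearest
    ground-truth centerline pixel, and the edge takes the majority label.
    """
    label_img = gt.centerline_label_image("generation")
    _, (ir, ic) = ndi.distance_transform_edt(label_img == 0,
                                             return_indices=True)
    nearest = label_img[ir, ic]
    out = {}
    for eid, e in graph.edges.items():
        pix = np.asarray(e.polyline, dtype=int)
        labels = nearest[pix[:, 0], pix[:, 1]]
        vals, counts = np.unique(labels[labels > 0], return_counts=True)
        out[eid] = int(vals[np.argmax(counts)]) if len(vals) else 0
    return out


def generation_label_accuracy(graph: VesselGraph, gm: GenerationMap,
                              gt: GroundTruth,
                              length_weighted: bool = False) -> float:
    """Fraction of measured edges whose assigned generation matches the
    ground truth (optionally arc-length weighted)."""
    truth = true_generation_of_edges(graph, gt)
    if not graph.edges:
        return float("nan")
    hits, weights = [], []
    for eid, e in graph.edges.items():
        hits.append(1.0 if gm.generation.get(eid) == truth[eid] else 0.0)
        weights.append(e.arc_length if length_weighted else 1.0)
    return float(np.average(hits, weights=weights))
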