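"""Vessel morphometry endpoints: tortuosity, length density, area density.

All quantities are in pixel units.

* **Tv** (tortuosity, distance method): per segment, centerline arc length
  divided by the straight distance between its two endpoints (>= 1, 1 =
  straight).  Per-eye and per-group values are arc-length-weighted means
  over segments (switchable to unweighted); self-loop segments with zero
  chord are excluded and counted.
* **Lv** (vessel length density): summed centerline arc length / ROI area.
* **Av** (vessel area density): vessel pixel area / ROI area.  Per-group
  area attribution assigns every vessel pixel to the generation group of
  its nearest skeleton pixel, so group areas partition the total.

Empty generation groups yield missing values (NaN), never zero: a tree
with no G>=6 vessels has *undefined* micro tortuosity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .generations import GenerationMap, generation_group
from .vesselgraph import Edge, VesselGraph

logger = logging.getLogger(__name__)

__all__ = [
    "MorphometryRecord",
    "tortuosity",
    "aggregate_tortuosity",
    "vessel_area_density",
    "vessel_length_density",
    "measure_eye",
]

_GROUPS = ("large", "medium", "micro")


class EmptyROIError(ValueError):
    """Density requested over an empty ROI."""


def tortuosity(edge: Edge) -> float:
    """Distance-method tortuosity of one segment: arc / chord.

    Raises ``ValueError`` for zero-chord (self-loop) edges, which callers
    exclude from aggregation with a logged count.
    """
    if edge.arc_length <= 0:
        raise ValueError(f"edge {edge.edge_id} has non-positive arc length")
    if edge.chord_length <= 0:
        raise ValueError(f"edge {edge.edge_id} is a closed loop (chord 0); "
                         "excluded from tortuosity")
    return float(edge.arc_length / edge.chord_length)


def _eligible(edges: list[Edge]) -> tuple[list[Edge], int]:
    ok = [e for e in edges if e.chord_length > 0 and e.arc_length > 0]
    return ok, len(edges) - len(ok)


def aggregate_tortuosity(graph: VesselGraph, gm: GenerationMap | None = None,
                         scope: str = "total", weighted: bool = True) -> float:
    """Arc-length-weighted mean tortuosity over a scope.

    ``scope`` is ``"total"`` or one of ``"large"/"medium"/"micro"`` (the
    latter require ``gm``).  Returns NaN for an empty scope.
    """
    edges = list(graph.edges.values())
    if scope != "total":
        if gm is None:
            raise ValueError("group scopes require a GenerationMap")
        edges = [e for e in edges
                 if generation_group(gm.generation[e.edge_id]) == scope]
    edges, n_excluded = _eligible(edges)
    if n_excluded:
        logger.info("aggregate_tortuosity: excluded %d zero-chord loop "
                    "edge(s) from scope %s", n_excluded, scope)
    if not edges:
        return float("nan")
    t = np.array([tortuosity(e) for e in edges])
    if not weighted:
        return float(t.mean())
    w = np.array([e.arc_length for e in edges])
    return float(np.sum(w * t) / np.sum(w))


def vessel_area_density(mask: np.ndarray, roi: np.ndarray,
                        scope_mask: np.ndarray | None = None) -> float:
    """Vessel pixels inside the ROI divided by ROI pixels.

    ``scope_mask`` restricts the numerator to the pixels claimed by one
    generation group (see :func:`group_pixel_map`).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise EmptyROIError("empty ROI")
    mask = np.asarray(mask, dtype=bool)
    outside = int((mask & ~roi).sum())
    if outside:
        warnings.warn(f"{outside} vessel pixels fall outside the ROI and are "
                      "excluded from the area density", stacklevel=2)
    num = mask & roi
    if scope_mask is not None:
        num = num & scope_mask
    return float(num.sum() / roi.sum())


def vessel_length_density(graph: VesselGraph, roi: np.ndarray,
                          gm: GenerationMap | None = None,
                          scope: str = "total") -> float:
    """Summed centerline arc length of in-scope edges / ROI pixel count."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise EmptyROIError("empty ROI")
    edges = list(graph.edges.values())
    if scope != "total":
        if gm is None:
            raise ValueError("group scopes require a GenerationMap")
        edges = [e for e in edges
                 if generation_group(gm.generation[e.edge_id]) == scope]
    if not edges:
        return float("nan")
    return float(sum(e.arc_length for e in edges) / roi.sum())


def group_pixel_map(mask: np.ndarray, graph: VesselGraph,
                    gm: GenerationMap) -> np.ndarray:
    """Assign every vessel pixel to a generation group via its nearest
    skeleton pixel (Euclidean); returns an int image (0 background,
    1 large, 2 medium, 3 micro).  Groups partition the vessel area."""
    mask = np.asarray(mask, dtype=bool)
    group_code = {"large": 1, "medium": 2, "micro": 3}
    skel_label = np.zeros(mask.shape, dtype=np.int8)
    for e in graph.edges.values():
        code = group_code[generation_group(gm.generation[e.edge_id])]
        pix = np.asarray(e.polyline, dtype=int)
        skel_label[pix[:, 0], pix[:, 1]] = code
    if not (skel_label > 0).any():
        return np.zeros(mask.shape, dtype=np.int8)
    _, (ir, ic) = ndi.distance_transform_edt(skel_label == 0,
                                             return_indices=True)
    out = skel_label[ir, ic]
    out[~mask] = 0
    return out


@dataclass
class MorphometryRecord:
    """Per-eye morphometry: total and per-group Av, Lv, Tv (pixel units)."""

    eye_id: str
    mode: str
    roi_area: float
    vessel_area: float
    Av_total: float
    Lv_total: float
    Tv_total: float
    groups: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_tidy_rows(self) -> list[dict]:
        rows = []
        for metric in ("Av", "Lv", "Tv"):
            rows.append({"eye_id": self.eye_id, "metric": metric,
                         "scope": "total",
                         "value": getattr(self, f"{metric}_total")})
            for grp in _GROUPS:
                rows.append({"eye_id": self.eye_id, "metric": metric,
                             "scope": grp,
                             "value": self.groups.get(grp, {}).get(metric,
                                                                   float("nan"))})
        return rows


def measure_eye(mask: np.ndarray, roi: np.ndarray, graph: VesselGraph,
                gm: GenerationMap, eye_id: str = "eye",
                weighted_tv: bool = True) -> MorphometryRecord:
    """Compute the full per-eye record; group and total values are mutually
    consistent (group lengths sum to the total; group areas partition the
    vessel area)."""
    roi = np.asarray(roi, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not roi.any():
        raise EmptyROIError("empty ROI")

    av_total = vessel_area_density(mask, roi)
    lv_total = vessel_length_density(graph, roi)
    tv_total = aggregate_tortuosity(graph, gm, "total", weighted=weighted_tv)

    gmap = group_pixel_map(mask, graph, gm)
    code = {"large": 1, "medium": 2, "micro": 3}
    groups: dict[str, dict[str, float]] = {}
    present = {generation_group(g) for g in gm.generation.values()}
    for grp in _GROUPS:
        if grp not in present:
            groups[grp] = {"Av": float("nan"), "Lv": float("nan"),
                           "Tv": float("nan")}
            continue
        groups[grp] = {
            "Av": vessel_area_density(mask, roi,
                                      scope_mask=(gmap == code[grp])),
            "Lv": vessel_length_density(graph, roi, gm, grp),
            "Tv": aggregate_tortuosity(graph, gm, grp, weighted=weighted_tv),
        }
    return MorphometryRecord(
        eye_id=eye_id, mode=gm.mode,
        roi_area=float(roi.sum()),
        vessel_area=float((mask & roi).sum()),
        Av_total=av_total, Lv_total=lv_total, Tv_total=tv_total,
        groups=groups,
    )
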