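"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from vesquant import segmentation, synthgen, vesselgraph


@pytest.fixture(scope="session")
def tree5():
    """Default depth-5 noiseless tree: (image, mask, ground truth)."""
    spec = synthgen.TreeSpec(n_generations=5, seed=1)
    return synthgen.generate_tree(spec)


@pytest.fixture(scope="session")
def tree5_graph(tree5):
    """Pruned measured graph of the depth-5 tree."""
    _, mask, _ = tree5
    skel = vesselgraph.skeletonize_map(mask)
    return vesselgraph.prune_spurs(vesselgraph.build_graph(skel))


@pytest.fixture(scope="session")
def grid4x4():
    """4x4 lattice mesh, jitter 0, all cycles retained."""
    spec = synthgen.NetworkSpec(lattice_pitch=40, jitter=0, radius_sd=0,
                                loop_fraction=1.0, canvas=(134, 134), seed=0)
    return synthgen.generate_network(spec), spec


def graph_from_mask(mask: np.ndarray) -> vesselgraph.VesselGraph:
    """Convenience: skeleton graph of a binary mask without pruning."""
    return vesselgraph.build_graph(vesselgraph.skeletonize_map(mask))


def make_edge(edge_id: int, u: int, v: int, vertices,
              radius: float = 2.0) -> vesselgraph.Edge:
    """Edge built from explicit vertices; arc is the exact polyline length
    (no resampling), as for analytically specified paths."""
    poly = np.asarray(vertices, dtype=float)
    arc = vesselgraph.polyline_length(poly)
    chord = float(np.hypot(*(poly[-1] - poly[0])))
    prof = np.full(len(poly), float(radius))
    return vesselgraph.Edge(edge_id, u, v, poly, arc, arc, chord, prof)


def sinusoid_arc_oracle(length: float, amp: float, wavelength: float) -> float:
    """Independent quadrature of the sinusoid arc-length integral
    int_0^L sqrt(1 + (2 pi A / lambda)^2 cos^2(2 pi s / lambda)) ds."""
    import math

    from scipy.integrate import quad
    k = 2 * math.pi / wavelength
    val, _ = quad(lambda s: math.sqrt(1 + (amp * k * math.cos(k * s)) ** 2),
                  0, length, limit=400)
    return val


def tree_tortuosity_oracle(spec) -> float:
    """Closed-form (quadrature) arc-length-weighted tortuosity of a complete
    tree built from a TreeSpec, independent of the generator's sampling."""
    import math
    total_w, total_wt = 0.0, 0.0
    for g in range(1, spec.n_generations + 1):
        length = spec.length0 * spec.length_ratio ** (g - 1)
        arc = sinusoid_arc_oracle(length, spec.tortuosity_amp,
                                  spec.tortuosity_wavelength)
        end_off = spec.tortuosity_amp * math.sin(
            2 * math.pi * length / spec.tortuosity_wavelength)
        chord = math.hypot(length, end_off)
        n = 2 ** (g - 1)
        total_w += n * arc
        total_wt += n * arc * (arc / chord)
    return total_wt / total_w


def line_mask(h: int, w: int, points) -> np.ndarray:
    m = np.zeros((h, w), dtype=bool)
    for r, c in points:
        m[r, c] = True
    return m


def handcrafted_mask_cases():
    """Ten <=20x20 skeleton masks with manually enumerated
    (nodes, edges, cycle rank) inventories."""
    cases = []
    # 1: single pixel -> 1 isolated node, 0 edges
    cases.append((line_mask(5, 5, [(2, 2)]), 1, 0, 0))
    # 2: straight horizontal 10-px line -> 2 endpoints, 1 edge
    cases.append((line_mask(5, 12, [(2, c) for c in range(1, 11)]), 2, 1, 0))
    # 3: straight diagonal 8-px line
    cases.append((line_mask(10, 10, [(i, i) for i in range(1, 9)]), 2, 1, 0))
    # 4: plus sign, two crossing 9-px lines -> 1 junction + 4 endpoints
    plus = [(4, c) for c in range(9)] + [(r, 4) for r in range(9)]
    cases.append((line_mask(9, 9, plus), 5, 4, 0))
    # 5: Y shape -> 1 junction + 3 endpoints, 3 edges
    y = [(r, 7) for r in range(8, 15)] + \
        [(8 - k, 7 - k) for k in range(1, 7)] + \
        [(8 - k, 7 + k) for k in range(1, 7)]
    cases.append((line_mask(15, 15, y), 4, 3, 0))
    # 6: T shape -> 1 junction + 3 endpoints, 3 edges
    t = [(2, c) for c in range(1, 12)] + [(r, 6) for r in range(3, 12)]
    cases.append((line_mask(13, 13, t), 4, 3, 0))
    # 7: L path, corner is degree-2 -> 2 endpoints, 1 edge
    ell = [(r, 2) for r in range(2, 9)] + [(8, c) for c in range(3, 9)]
    cases.append((line_mask(10, 10, ell), 2, 1, 0))
    # 8: hollow square ring -> pure cycle: 1 anchor node, 1 self-loop
    ring = [(2, c) for c in range(2, 9)] + [(8, c) for c in range(2, 9)] + \
           [(r, 2) for r in range(3, 8)] + [(r, 8) for r in range(3, 8)]
    cases.append((line_mask(11, 11, ring), 1, 1, 1))
    # 9: two disjoint vertical lines -> 4 endpoints, 2 edges
    two = [(r, 3) for r in range(2, 10)] + [(r, 12) for r in range(2, 10)]
    cases.append((line_mask(12, 16, two), 4, 2, 0))
    # 10: H shape -> 2 junctions + 4 endpoints, 5 edges
    hsh = [(r, 2) for r in range(1, 12)] + [(r, 9) for r in range(1, 12)] + \
          [(6, c) for c in range(3, 9)]
    cases.append((line_mask(13, 13, hsh), 6, 5, 0))
    return cases


def make_graph(edges_spec) -> vesselgraph.VesselGraph:
    """Build a VesselGraph from (u, v, vertices, radius) tuples, creating
    endpoint/junction nodes from the implied degrees."""
    g = vesselgraph.VesselGraph()
    edges = []
    for eid, (u, v, verts, radius) in enumerate(edges_spec):
        edges.append(make_edge(eid, u, v, verts, radius))
    deg: dict[int, int] = {}
    pos: dict[int, tuple[float, float]] = {}
    for e in edges:
        for nid, end in ((e.u, e.polyline[0]), (e.v, e.polyline[-1])):
            deg[nid] = deg.get(nid, 0) + 1
            pos[nid] = (float(end[0]), float(end[1]))
    for nid in sorted(deg):
        kind = "endpoint" if deg[nid] == 1 else "junction"
        g.nodes[nid] = vesselgraph.Node(nid, pos[nid], kind,
                                        [tuple(map(int, pos[nid]))],
                                        radius=max(e.mean_radius for e in edges
                                                   if nid in (e.u, e.v)))
    for e in edges:
        g.edges[e.edge_id] = e
    return g
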