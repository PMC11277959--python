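"""Synthetic retinal vasculature with known ground truth.

Two geometries are emulated:

* open branching trees with tapering radii and sinusoidally tortuous
  segments, the morphology seen on fluorescein angiograms of the
  arterial/venous trees (``generate_tree``);
* closed capillary meshes built on a jittered lattice with cycles, the
  morphology of the OCTA superficial vascular plexus (``generate_network``).

Every generated image carries a :class:`GroundTruth` holding the exact
centerline geometry, per-segment branching generation, arc and chord
lengths and radii, so measured morphometry can be validated against known
values.  ``generate_cohort`` assembles whole labeled cohorts
(control / diabetic without retinopathy / diabetic with retinopathy style
group structure) with controlled between-group effect multipliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TreeSpec",
    "NetworkSpec",
    "GroupSpec",
    "CohortSpec",
    "Segment",
    "GroundTruth",
    "SpecValidationError",
    "CanvasOverflowError",
    "generate_tree",
    "generate_network",
    "generate_cohort",
]

# centerline sampling step (px along the parameter axis); <=0.5 px guarantees
# 8-connected, width-faithful rasterization
_DS = 0.25


class SpecValidationError(ValueError):
    """A generator spec violates its invariants."""


class CanvasOverflowError(ValueError):
    """A segment (including its radius) would leave the canvas."""


class OverlapError(ValueError):
    """Two unrelated segments (not parent/daughter/sibling) would overlap
    when rasterized, which would corrupt the tree topology of the mask."""


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of a synthetic bifurcating vascular tree.

    Radii taper geometrically: a segment at generation ``g`` has radius
    ``root_radius * radius_ratio**(g-1)``, modulated by ``asymmetry``
    (one daughter scaled by ``1+asymmetry``, the other by ``1-asymmetry``).
    Tortuosity is a sinusoidal perpendicular displacement of amplitude
    ``tortuosity_amp`` and wavelength ``tortuosity_wavelength``, chosen so
    the true arc length has a closed quadrature form.

    The default 90-degree branch angle with length ratio ~0.70 lays the
    complete binary tree out as an H-tree, the planar embedding that keeps
    all 2**g - 1 segments disjoint down to deep generations; shallower
    trees tolerate any angle, but deep complete trees with moderate
    constant angles inevitably self-intersect, and the generator checks
    and refuses overlapping geometry.
    """

    n_generations: int = 5
    root_radius: float = 6.0
    radius_ratio: float = 0.8
    length0: float = 120.0
    length_ratio: float = 0.70
    branch_angle: float = 90.0          # degrees off the parent direction
    tortuosity_amp: float = 1.5         # px
    tortuosity_wavelength: float = 30.0  # px
    asymmetry: float = 0.0              # in [0, 1)
    canvas: tuple[int, int] = (360, 400)
    seed: int = 0
    vessel_level: int = 200
    background_level: int = 30
    noise_sigma: float = 0.0

    def validate(self) -> None:
        if self.n_generations < 1:
            raise SpecValidationError("n_generations must be >= 1")
        if self.root_radius < 1:
            raise SpecValidationError("root_radius must be >= 1 px")
        if not (0 < self.radius_ratio <= 1):
            raise SpecValidationError("radius_ratio must be in (0, 1]")
        if not (0 < self.length_ratio <= 1):
            raise SpecValidationError("length_ratio must be in (0, 1]")
        if self.tortuosity_amp > 0 and self.tortuosity_wavelength <= 0:
            raise SpecValidationError(
                "tortuosity_wavelength must be > 0 when tortuosity_amp > 0")
        if not (0 <= self.asymmetry < 1):
            raise SpecValidationError("asymmetry must be in [0, 1)")
        if self.length0 <= 0:
            raise SpecValidationError("length0 must be > 0")
        if min(self.canvas) < 16:
            raise SpecValidationError("canvas too small")


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of a synthetic closed capillary mesh on a jittered lattice."""

    lattice_pitch: float = 40.0
    jitter: float = 4.0
    radius_mean: float = 3.0
    radius_sd: float = 0.6
    loop_fraction: float = 1.0          # fraction of lattice cycles retained
    canvas: tuple[int, int] = (320, 320)
    seed: int = 0
    vessel_level: int = 200
    background_level: int = 30
    noise_sigma: float = 0.0

    def validate(self) -> None:
        if self.lattice_pitch <= 2 * self.radius_mean:
            raise SpecValidationError("lattice_pitch must exceed 2*radius_mean")
        if not (0 < self.loop_fraction <= 1):
            raise SpecValidationError("loop_fraction must be in (0, 1]")
        if self.radius_mean < 1:
            raise SpecValidationError("radius_mean must be >= 1 px")
        if self.radius_sd < 0:
            raise SpecValidationError("radius_sd must be >= 0")
        nr, nc = self.grid_shape
        if nr < 2 or nc < 2 or (nr - 1) * (nc - 1) < 1:
            raise SpecValidationError(
                "canvas/pitch admit no lattice cycle; enlarge canvas or shrink pitch")

    @property
    def margin(self) -> float:
        return max(6.0, self.radius_mean + 3 * self.radius_sd + self.jitter + 2)

    @property
    def grid_shape(self) -> tuple[int, int]:
        h, w = self.canvas
        nr = int((h - 1 - 2 * self.margin) // self.lattice_pitch) + 1
        nc = int((w - 1 - 2 * self.margin) // self.lattice_pitch) + 1
        return nr, nc


@dataclass(frozen=True)
class Segment:
    """One ground-truth vessel segment: centerline polyline plus radius."""

    segment_id: int
    generation: int
    polyline: np.ndarray        # (N, 2) float (row, col)
    radius: float               # constant local radius, px
    arc_length: float           # px, dense-polyline quadrature
    chord_length: float         # px, endpoint-to-endpoint

    @property
    def radius_profile(self) -> np.ndarray:
        return np.full(len(self.polyline), self.radius)

    @property
    def tortuosity(self) -> float:
        return self.arc_length / self.chord_length


@dataclass
class GroundTruth:
    """Exact geometry behind a rendered image, the oracle for every stage."""

    segments: list[Segment]
    canvas: tuple[int, int]
    total_vessel_pixels: int | None = None   # None when not rasterized
    roi_pixels: int = 0

    def __post_init__(self) -> None:
        if not self.roi_pixels:
            self.roi_pixels = int(self.canvas[0]) * int(self.canvas[1])

    # -- true morphometry ------------------------------------------------
    def tortuosity_true(self, generations: set[int] | None = None) -> float:
        """Arc-length-weighted mean arc/chord over (a generation subset of)
        segments."""
        segs = [s for s in self.segments
                if generations is None or s.generation in generations]
        if not segs:
            return math.nan
        w = np.array([s.arc_length for s in segs])
        t = np.array([s.tortuosity for s in segs])
        return float(np.sum(w * t) / np.sum(w))

    def length_true(self, generations: set[int] | None = None) -> float:
        return float(sum(s.arc_length for s in self.segments
                         if generations is None or s.generation in generations))

    def area_true(self) -> float:
        """Vessel area: exact pixel count when rasterized, else the analytic
        2*r*arc approximation (overlap at junctions ignored)."""
        if self.total_vessel_pixels is not None:
            return float(self.total_vessel_pixels)
        return float(sum(2 * s.radius * s.arc_length for s in self.segments))

    def generation_labels(self) -> dict[int, int]:
        return {s.segment_id: s.generation for s in self.segments}

    def max_generation(self) -> int:
        return max(s.generation for s in self.segments)

    def centerline_label_image(self, label: str = "generation") -> np.ndarray:
        """Rasterize centerlines carrying per-pixel labels (0 = background).

        ``label`` is ``"generation"`` or ``"segment"`` (segment_id + 1).
        Later segments overwrite earlier ones only at shared junctionpoints.
        """
        h, w = self.canvas
        img = np.zeros((h, w), dtype=np.int32)
        for s in self.segments:
            val = s.generation if label == "generation" else s.segment_id + 1
            rc = np.round(s.polyline).astype(int)
            rc[:, 0] = np.clip(rc[:, 0], 0, h - 1)
            rc[:, 1] = np.clip(rc[:, 1], 0, w - 1)
            img[rc[:, 0], rc[:, 1]] = val
        return img

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "segment_id": s.segment_id,
                "generation": s.generation,
                "radius_px": s.radius,
                "arc_length_px": s.arc_length,
                "chord_length_px": s.chord_length,
                "tortuosity": s.tortuosity,
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry helpers


def _sample_sinusoid(p0: np.ndarray, direction: np.ndarray, length: float,
                     amp: float, wavelength: float) -> np.ndarray:
    """Dense polyline of a straight run with sinusoidal perpendicular offset.

    Displacement is A*sin(2*pi*s/lambda) along the unit normal; it vanishes
    at s=0 so segments join continuously at branch points (the far end
    carries whatever phase the length dictates).
    """
    n = max(2, int(math.ceil(length / _DS)) + 1)
    s = np.linspace(0.0, length, n)
    normal = np.array([-direction[1], direction[0]])
    pts = (p0[None, :] + s[:, None] * direction[None, :])
    if amp > 0:
        pts = pts + np.sin(2 * np.pi * s / wavelength)[:, None] * amp * normal[None, :]
    return pts


def _polyline_arc(poly: np.ndarray) -> float:
    return float(np.hypot(*np.diff(poly, axis=0).T).sum())


def _stamp(mask: np.ndarray, poly: np.ndarray, radius: float) -> None:
    """Union of disks of ``radius`` centered at every polyline sample."""
    h, w = mask.shape
    r = float(radius)
    r0 = max(int(np.floor(poly[:, 0].min() - r)), 0)
    r1 = min(int(np.ceil(poly[:, 0].max() + r)), h - 1)
    c0 = max(int(np.floor(poly[:, 1].min() - r)), 0)
    c1 = min(int(np.ceil(poly[:, 1].max() + r)), w - 1)
    if r1 < r0 or c1 < c0:
        return
    yy, xx = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    grid = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    hit = np.zeros(len(grid), dtype=bool)
    # chunk over samples to bound memory
    step = max(1, int(2e6 // max(len(grid), 1)))
    r2 = r * r
    for i in range(0, len(poly), step):
        chunk = poly[i:i + step]
        d2 = ((grid[:, None, :] - chunk[None, :, :]) ** 2).sum(axis=2)
        hit |= (d2 <= r2).any(axis=1)
    sub = mask[r0:r1 + 1, c0:c1 + 1]
    sub |= hit.reshape(sub.shape)


def _check_bounds(poly: np.ndarray, radius: float, canvas: tuple[int, int],
                  seg_id: int, extra: float = 0.0) -> None:
    h, w = canvas
    pad = radius + extra
    if (poly[:, 0].min() - pad < 0 or poly[:, 0].max() + pad > h - 1
            or poly[:, 1].min() - pad < 0 or poly[:, 1].max() + pad > w - 1):
        raise CanvasOverflowError(
            f"segment {seg_id} (radius {radius:.2f} px) leaves the "
            f"{h}x{w} canvas; enlarge canvas or shrink the tree")


def _check_overlap(segments: list[Segment], parent: dict[int, int]) -> None:
    """Refuse geometry where unrelated segments touch.

    Parent/daughter and sibling pairs legitimately meet at their shared
    junction; any other pair of centerlines closer than the sum of radii
    would merge in the rasterized mask and corrupt the tree topology.
    """
    from scipy.spatial import cKDTree

    pts, ids, rads = [], [], []
    for s in segments:
        q = s.polyline[::2]
        pts.append(q)
        ids.extend([s.segment_id] * len(q))
        rads.extend([s.radius] * len(q))
    pts = np.vstack(pts)
    ids = np.asarray(ids)
    rads = np.asarray(rads)
    reach = 2 * max(s.radius for s in segments) + 0.5
    pairs = cKDTree(pts).query_pairs(r=reach, output_type="ndarray")
    for i, j in pairs:
        a, b = int(ids[i]), int(ids[j])
        if a == b or parent.get(a) == b or parent.get(b) == a \
                or parent.get(a) == parent.get(b):
            continue
        if np.hypot(*(pts[i] - pts[j])) < rads[i] + rads[j]:
            raise OverlapError(
                f"segments {a} and {b} overlap when rasterized; reduce "
                "depth/amplitude or use the default H-tree layout")


def _render(mask: np.ndarray, spec, rng: np.random.Generator) -> np.ndarray:
    img = np.full(mask.shape, float(spec.background_level))
    img[mask] = float(spec.vessel_level)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# tree generator


def generate_tree(spec: TreeSpec, render: bool = True
                  ) -> tuple[np.ndarray | None, np.ndarray | None, GroundTruth]:
    """Generate a bifurcating vascular tree.

    Returns ``(grayscale image, binary mask, ground truth)``; the image and
    mask are ``None`` when ``render=False`` (geometry-only fast path used
    for large statistical simulations).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas

    segments: list[Segment] = []
    mask = np.zeros((h, w), dtype=bool) if render else None

    root_start = np.array([h - 40.0, w / 2.0])
    # (parent id, start, unit direction, length, radius, generation, parity)
    stack = [(-1, root_start, np.array([-1.0, 0.0]), float(spec.length0),
              float(spec.root_radius), 1, 0)]
    seg_id = 0
    parent: dict[int, int] = {}
    theta = math.radians(spec.branch_angle)
    while stack:
        par, p0, d, length, radius, gen, parity = stack.pop(0)
        poly = _sample_sinusoid(p0, d, length, spec.tortuosity_amp,
                                spec.tortuosity_wavelength)
        _check_bounds(poly, radius, spec.canvas, seg_id)
        arc = _polyline_arc(poly)
        chord = float(np.hypot(*(poly[-1] - poly[0])))
        segments.append(Segment(seg_id, gen, poly, radius, arc, chord))
        parent[seg_id] = par
        if gen < spec.n_generations:
            end = poly[-1]
            big = 1.0 + spec.asymmetry
            small = 1.0 - spec.asymmetry
            # the larger daughter alternates sides with depth (deterministic)
            side = 1 if parity % 2 == 0 else -1
            for sgn, scale in ((side, big), (-side, small)):
                ang = sgn * theta
                rot = np.array([[math.cos(ang), -math.sin(ang)],
                                [math.sin(ang), math.cos(ang)]])
                stack.append((seg_id, end, rot @ d, length * spec.length_ratio,
                              radius * spec.radius_ratio * scale,
                              gen + 1, parity + 1))
        seg_id += 1

    if render:
        _check_overlap(segments, parent)
        for s in segments:
            _stamp(mask, s.polyline, s.radius)

    gt = GroundTruth(segments=segments, canvas=spec.canvas,
                     total_vessel_pixels=int(mask.sum()) if render else None)
    img = _render(mask, spec, rng) if render else None
    return img, mask, gt


# ---------------------------------------------------------------------------
# network generator


def generate_network(spec: NetworkSpec, render: bool = True
                     ) -> tuple[np.ndarray | None, np.ndarray | None, GroundTruth]:
    """Generate a closed capillary mesh with at least one cycle.

    Lattice nodes are jittered; ``loop_fraction`` sets the retained share of
    the full lattice's independent cycles (edges on cycles are removed at
    random, never disconnecting the mesh, until the target cycle rank is
    reached).
    """
    spec.validate()
    import networkx as nx

    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.grid_shape
    m = spec.margin

    pos = {}
    for i in range(nr):
        for j in range(nc):
            jit = rng.uniform(-spec.jitter, spec.jitter, size=2) if spec.jitter > 0 \
                else np.zeros(2)
            pos[(i, j)] = np.array([m + i * spec.lattice_pitch + jit[0],
                                    m + j * spec.lattice_pitch + jit[1]])

    g = nx.Graph()
    g.add_nodes_from(pos)
    for i in range(nr):
        for j in range(nc):
            if i + 1 < nr:
                g.add_edge((i, j), (i + 1, j))
            if j + 1 < nc:
                g.add_edge((i, j), (i, j + 1))

    full_rank = (nr - 1) * (nc - 1)
    target = max(1, int(round(spec.loop_fraction * full_rank)))
    rank = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
    tries = 0
    while rank > target:
        bridges = set(frozenset(e) for e in nx.bridges(g))
        cyc_edges = [e for e in g.edges if frozenset(e) not in bridges]
        if not cyc_edges:
            break
        e = cyc_edges[rng.integers(len(cyc_edges))]
        g.remove_edge(*e)
        rank -= 1
        tries += 1
        if tries > 10 * full_rank:  # pragma: no cover - safety bound
            raise SpecValidationError("cycle-rank reduction did not converge")

    h, w = spec.canvas
    mask = np.zeros((h, w), dtype=bool) if render else None
    segments: list[Segment] = []
    edges = sorted(g.edges, key=lambda e: tuple(sorted(e)))
    radii = []
    for _ in edges:
        r = rng.normal(spec.radius_mean, spec.radius_sd) if spec.radius_sd > 0 \
            else spec.radius_mean
        radii.append(float(np.clip(r, 1.0, spec.lattice_pitch / 2 - 0.5)))
    r_max = max(radii)
    for seg_id, ((a, b), radius) in enumerate(zip(edges, radii)):
        p0, p1 = pos[a], pos[b]
        length = float(np.hypot(*(p1 - p0)))
        d = (p1 - p0) / length
        poly = _sample_sinusoid(p0, d, length, 0.0, 1.0)
        _check_bounds(poly, radius, spec.canvas, seg_id)
        gen = 1 + int(math.floor(math.log2(r_max / radius) + 1e-9)) if radius < r_max else 1
        segments.append(Segment(seg_id, max(1, gen), poly, radius,
                                _polyline_arc(poly), length))
        if render:
            _stamp(mask, poly, radius)

    gt = GroundTruth(segments=segments, canvas=spec.canvas,
                     total_vessel_pixels=int(mask.sum()) if render else None)
    img = _render(mask, spec, rng) if render else None
    return img, mask, gt


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm: a label, an eye count, and effect multipliers applied
    to the template spec (tortuosity amplitude, extra branching generations)."""

    label: str
    n_eyes: int
    tortuosity_multiplier: float = 1.0
    extra_generations: int = 0

    def validate(self) -> None:
        if self.n_eyes < 3:
            raise SpecValidationError(
                f"group '{self.label}' needs n_eyes >= 3, got {self.n_eyes}")
        if self.tortuosity_multiplier <= 0:
            raise SpecValidationError("tortuosity_multiplier must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """A whole synthetic study: >=2 groups drawn from a shared template with
    per-eye biological variability (lognormal jitter on tortuosity amplitude
    and root segment length)."""

    groups: tuple[GroupSpec, ...]
    template: TreeSpec = field(default_factory=TreeSpec)
    amp_cv: float = 0.15       # between-eye CV of tortuosity amplitude
    length_cv: float = 0.05    # between-eye CV of segment lengths
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) < 2:
            raise SpecValidationError("a cohort needs >= 2 groups")
        for grp in self.groups:
            grp.validate()
        self.template.validate()


_SCOPES = ("total", "large", "medium", "micro")


def _scope_generations(scope: str, max_gen: int) -> set[int] | None:
    if scope == "total":
        return None
    if scope == "large":
        return set(range(1, 4))
    if scope == "medium":
        return {4, 5}
    return set(range(6, max_gen + 1))


def generate_cohort(spec: CohortSpec, render: bool = True):
    """Generate per-eye images/ground truth plus the tidy table of TRUE
    morphometry (one row per eye x metric x scope).

    Returns ``(eyes, table)`` where ``eyes`` is a list of dicts with keys
    ``eye_id, group, spec, image, mask, ground_truth``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    eyes = []
    rows = []
    eye_counter = 0
    for grp in spec.groups:
        for k in range(grp.n_eyes):
            child = ss.spawn(1)[0]
            eye_seed = int(child.generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(eye_seed)
            amp = (spec.template.tortuosity_amp * grp.tortuosity_multiplier
                   * math.exp(rng.normal(0.0, spec.amp_cv) - spec.amp_cv ** 2 / 2))
            length0 = (spec.template.length0
                       * math.exp(rng.normal(0.0, spec.length_cv) - spec.length_cv ** 2 / 2))
            eye_spec = replace(
                spec.template,
                tortuosity_amp=amp,
                length0=length0,
                n_generations=spec.template.n_generations + grp.extra_generations,
                seed=eye_seed,
            )
            eye_id = f"{grp.label}_eye{k:02d}"
            img, mask, gt = generate_tree(eye_spec, render=render)
            eyes.append({"eye_id": eye_id, "group": grp.label,
                         "spec": eye_spec, "image": img, "mask": mask,
                         "ground_truth": gt})
            max_gen = gt.max_generation()
            for scope in _SCOPES:
                gens = _scope_generations(scope, max_gen)
                tv = gt.tortuosity_true(gens)
                lv = gt.length_true(gens) / gt.roi_pixels
                for metric, value in (("Tv", tv), ("Lv", lv)):
                    rows.append({"eye_id": eye_id, "subject_id": eye_id,
                                 "group": grp.label, "metric": metric,
                                 "scope": scope, "value": value})
            rows.append({"eye_id": eye_id, "subject_id": eye_id,
                         "group": grp.label, "metric": "Av", "scope": "total",
                         "value": gt.area_true() / gt.roi_pixels})
            eye_counter += 1
    table = pd.DataFrame(rows)
    # empty scopes are missing values, never zero
    table.loc[(table.metric == "Lv") & (table.value == 0), "value"] = np.nan
    return eyes, table
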