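"""Quadrilateral meshing of the skin domain with the A-shaped incision.

The simulated skin is a ``width x height`` mm rectangle (default 90 x 100,
roughly three flap sizes, beyond which stresses are negligible).  The
coordinate system puts the future T-joint (base-incision centre) at the
origin with y up.  Embedded in the rectangle are:

* the excised defect triangle: apex ``(0, h)``, base corners ``B=(-d/2, 0)``
  and ``C=(d/2, 0)`` — removed from the mesh, its edges are wound margins;
* the two lateral base-extension incisions along ``y = 0`` from ``+-d/2``
  out to ``+-L`` — interior cuts, meshed with duplicated (coincident) node
  pairs on either side.

The mesher is block-structured: two mapped grids, one below the incision
line and one above the triangle/base profile, sharing nodes outside the cut
span and deliberately *not* sharing them across the cuts.  This is fully
deterministic and guarantees positive reference Jacobians at every element
size, at the cost of some sheared (low scaled-Jacobian) elements alongside
the waists — the same trade-off visible in mapped meshes from commercial
preprocessors.

:func:`closure_plan` turns the meshed wound margins into the suture-stage
boundary conditions: every margin node is assigned a target position on the
closed "T" (arc-length matching along each seam), and the node pairs that a
stitch binds are recorded for the release-stage tie constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import FlapDesign

__all__ = [
    "Domain",
    "SkinMesh",
    "MeshQualityReport",
    "ClosurePlan",
    "build_domain",
    "generate_mesh",
    "rectangle_mesh",
    "quality_report",
    "closure_plan",
    "suture_pairs",
]

# 2x2 Gauss points on [-1, 1]^2
_G = 1.0 / math.sqrt(3.0)
GAUSS_POINTS = np.array([[-_G, -_G], [_G, -_G], [_G, _G], [-_G, _G]])


@dataclass(frozen=True)
class Domain:
    """Skin rectangle with the embedded A-T incision geometry (mm)."""

    design: FlapDesign
    width: float
    height: float
    y_bottom: float  # lower edge of the rectangle (< 0)
    y_top: float  # upper edge (> flap length)
    half_span: float  # L: incision half-length along the base line

    @property
    def half_base(self) -> float:
        return self.design.flap_width / 2.0

    @property
    def flap_length(self) -> float:
        return self.design.flap_length

    @property
    def waist_length(self) -> float:
        b, h = self.half_base, self.flap_length
        return math.hypot(b, h)

    @property
    def cut_polylines(self) -> list:
        """Reference incision polylines: two waists, two extensions."""
        b, h, L = self.half_base, self.flap_length, self.half_span
        return [
            [(-b, 0.0), (0.0, h)],
            [(b, 0.0), (0.0, h)],
            [(-L, 0.0), (-b, 0.0)],
            [(L, 0.0), (b, 0.0)],
        ]


def build_domain(design: FlapDesign, width: float = 90.0, height: float = 100.0) -> Domain:
    """Lay out the rectangular analysis domain around a flap design.

    The flap bounding box is centred vertically; the incision line must fit
    inside the rectangle with a positive margin on every side.
    """
    if design.defect_radius <= 0.0:
        raise ValueError("degenerate design: defect radius must be positive")
    h = design.flap_length
    L = abs(design.incision_layout["extension_end_right"][0])
    if h >= height or 2.0 * L >= width:
        raise ValueError(
            f"flap (span {2 * L:.1f} x {h:.1f} mm) does not fit in the "
            f"{width:.0f} x {height:.0f} mm domain with a margin"
        )
    y_top = h + (height - h) / 2.0
    y_bottom = y_top - height
    return Domain(
        design=design,
        width=width,
        height=height,
        y_bottom=y_bottom,
        y_top=y_top,
        half_span=L,
    )


@dataclass
class MeshQualityReport:
    """Table-2-style mesh quality summary."""

    n_elements: int
    n_nodes: int
    n_inverted: int
    n_distorted: int
    n_bad_aspect: int
    distortion_threshold: float = 0.5
    aspect_threshold: float = 1.5


@dataclass
class SkinMesh:
    """2-D quadrilateral mesh with incision cuts and closure metadata.

    ``nodes`` are reference coordinates in mm; ``quads`` is (E, 4) int,
    counterclockwise.  ``cut_pairs`` lists geometrically coincident
    duplicated node pairs along the lateral extension cuts
    (flap side, incision side).  ``seams`` holds the ordered wound-margin
    node chains used to build suture boundary conditions:

    * ``lower_left/right``: incision-side margin, tip -> base centre,
    * ``upper_left/right``: flap-side margin, tip -> waist split point,
    * ``waist_upper_left/right``: waist split point -> apex.
    """

    nodes: np.ndarray
    quads: np.ndarray
    element_size: float
    region: np.ndarray | None = None  # per-element: 1 = flap, 0 = surrounding skin
    cut_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    seams: dict = field(default_factory=dict)
    corner_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    tip_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    apex_node: int | None = None
    center_node: int | None = None
    domain: Domain | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.quads.shape[0]


def _segment_points(x0: float, x1: float, n: int) -> np.ndarray:
    return np.linspace(x0, x1, n + 1)


def _ndiv(length: float, size: float) -> int:
    return max(1, int(math.floor(length / size + 0.5)))


def rectangle_mesh(width: float, height: float, element_size: float,
                   origin=(0.0, 0.0)) -> SkinMesh:
    """Plain structured quad mesh of a rectangle (no cuts)."""
    nx, ny = _ndiv(width, element_size), _ndiv(height, element_size)
    xs = np.linspace(origin[0], origin[0] + width, nx + 1)
    ys = np.linspace(origin[1], origin[1] + height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    quads = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            quads.append([a, a + (ny + 1), a + ny + 2, a + 1])
    return SkinMesh(
        nodes=nodes,
        quads=np.asarray(quads, dtype=int),
        element_size=element_size,
        region=np.zeros(nx * ny, dtype=int),
    )


def _x_partitions(domain: Domain, size: float):
    """x breakpoints for the lower and upper grids plus division counts.

    Both grids share the outer-skin segments ``[-W/2, -L]`` and the lateral
    extension segments ``[-L, -b]`` (and mirrors), so duplicated cut-pair
    nodes coincide and the grids merge seamlessly outside the incision.
    Inside the triangle span they differ:

    * the lower grid divides ``[-b, 0]`` uniformly into ``n_wl`` pieces,
      pairing 1:1 (by material arc length) with the lower-waist nodes;
    * the upper grid divides ``[-b, x_split]`` into ``n_wl`` pieces (the
      waist arc from B of length b, which is sutured to the base margin)
      and ``[x_split, 0]`` into ``n_wu`` pieces (the waist arc Lw - b that
      is sutured to the opposite waist).

    Waist-segment division counts use the geometric mean of arc length and
    horizontal span, balancing seam resolution against column aspect ratio.
    """
    W2, L, b = domain.width / 2.0, domain.half_span, domain.half_base
    Lw = domain.waist_length
    x_split = -b * (1.0 - b / Lw)
    n_outer = _ndiv(W2 - L, size)
    n_ext = _ndiv(L - b, size) if L - b > 1e-12 else 0
    n_wl = _ndiv(math.sqrt(b * (b * b / Lw)), size)
    n_wu = _ndiv(math.sqrt((Lw - b) * (b - b * b / Lw)), size)

    common = [_segment_points(-W2, -L, n_outer)]
    if n_ext:
        common.append(_segment_points(-L, -b, n_ext)[1:])
    common = np.concatenate(common)

    low_left = np.concatenate([common, _segment_points(-b, 0.0, n_wl)[1:]])
    up_left = np.concatenate([
        common,
        _segment_points(-b, x_split, n_wl)[1:],
        _segment_points(x_split, 0.0, n_wu)[1:],
    ])
    xs_low = np.concatenate([low_left, -low_left[-2::-1]])
    xs_up = np.concatenate([up_left, -up_left[-2::-1]])
    meta = dict(n_outer=n_outer, n_ext=n_ext, n_wl=n_wl, n_wu=n_wu,
                x_split=x_split)
    return xs_low, xs_up, meta


def generate_mesh(domain: Domain, element_size: float) -> SkinMesh:
    """Mesh the domain with quads, duplicating nodes across the cuts.

    Deterministic for fixed inputs.  Two mapped grids: the strip below the
    incision line is regular; each upper-grid column runs from the incision
    profile ``y_bot(x)`` (0 outside the triangle, the waist inside) up to
    the top edge, so the excised triangle is absent by construction and the
    waists are exact element boundaries.
    """
    if not (0.5 <= element_size <= 10.0):
        raise ValueError("element_size must be in [0.5, 10] mm")
    W2, L, b = domain.width / 2.0, domain.half_span, domain.half_base
    h = domain.flap_length
    margin = min(W2 - L, -domain.y_bottom, domain.y_top - h)
    if margin < element_size:
        raise ValueError(
            f"flap margin {margin:.2f} mm smaller than element size"
        )
    xs_low, xs_up, meta = _x_partitions(domain, element_size)
    n_outer, n_ext = meta["n_outer"], meta["n_ext"]
    n_wl, n_wu = meta["n_wl"], meta["n_wu"]
    n_low = _ndiv(-domain.y_bottom, element_size)
    n_up = _ndiv(domain.y_top, element_size)

    # index landmarks (see _x_partitions for the segment layout)
    i_tip = n_outer
    i_b = n_outer + n_ext
    i_mid_low = i_b + n_wl
    i_bR_low = i_b + 2 * n_wl
    i_tipR_low = i_bR_low + n_ext
    i_split = i_b + n_wl
    i_mid_up = i_split + n_wu
    i_splitR = i_mid_up + n_wu
    i_bR_up = i_splitR + n_wl
    i_tipR_up = i_bR_up + n_ext
    off = i_tipR_up - i_tipR_low  # right-side index offset (= 2 * n_wu)

    def y_bot(x: float) -> float:
        return h * (1.0 - abs(x) / b) if abs(x) < b - 1e-12 else 0.0

    # lower grid: regular
    ys_low = np.linspace(domain.y_bottom, 0.0, n_low + 1)
    low_ids = np.arange(xs_low.size * ys_low.size).reshape(
        xs_low.size, ys_low.size)
    nodes = [np.column_stack([np.repeat(xs_low, ys_low.size),
                              np.tile(ys_low, xs_low.size)])]
    next_id = xs_low.size * ys_low.size

    # upper grid: column-wise graded from the incision profile to the top;
    # bottom nodes outside the incision span merge with lower-grid top nodes
    up_ids = np.empty((xs_up.size, n_up + 1), dtype=int)
    up_nodes = []
    for i, x in enumerate(xs_up):
        col = np.linspace(y_bot(x), domain.y_top, n_up + 1)
        j0 = 0
        if i <= i_tip or i >= i_tipR_up:  # outside the incision: continuous
            i_low = i if i <= i_tip else i - off
            up_ids[i, 0] = low_ids[i_low, -1]
            j0 = 1
        for j in range(j0, n_up + 1):
            up_ids[i, j] = next_id
            up_nodes.append((x, col[j]))
            next_id += 1
    nodes.append(np.asarray(up_nodes))
    nodes = np.vstack(nodes)

    quads, region = [], []
    for i in range(xs_low.size - 1):
        for j in range(n_low):
            quads.append([low_ids[i, j], low_ids[i + 1, j],
                          low_ids[i + 1, j + 1], low_ids[i, j + 1]])
            region.append(0)
    for i in range(xs_up.size - 1):
        for j in range(n_up):
            quads.append([up_ids[i, j], up_ids[i + 1, j],
                          up_ids[i + 1, j + 1], up_ids[i, j + 1]])
            xc = 0.5 * (xs_up[i] + xs_up[i + 1])
            yc = 0.25 * sum(nodes[q, 1] for q in quads[-1])
            region.append(1 if (abs(xc) < L and yc < h) else 0)
    quads = np.asarray(quads, dtype=int)

    # wound-margin chains, ordered tip -> centre (lower/upper) and
    # split point -> apex (upper waists)
    lower_left = low_ids[i_tip:i_mid_low + 1, -1].copy()
    lower_right = low_ids[i_tipR_low:i_mid_low - 1:-1, -1].copy()
    upper_left = up_ids[i_tip:i_split + 1, 0].copy()
    upper_right = up_ids[i_tipR_up:i_splitR - 1:-1, 0].copy()
    waist_upper_left = up_ids[i_split:i_mid_up + 1, 0].copy()
    waist_upper_right = up_ids[i_splitR:i_mid_up - 1:-1, 0].copy()

    pairs = []  # duplicated extension-cut nodes (flap side, incision side)
    for i in range(i_tip + 1, i_b + 1):
        pairs.append((up_ids[i, 0], low_ids[i, -1]))
    for i in range(i_bR_up, i_tipR_up):
        pairs.append((up_ids[i, 0], low_ids[i - off, -1]))
    cut_pairs = np.asarray(pairs, dtype=int) if pairs else np.empty((0, 2), int)

    corners = np.asarray([
        low_ids[0, 0], low_ids[-1, 0], up_ids[0, -1], up_ids[-1, -1]
    ])
    return SkinMesh(
        nodes=nodes,
        quads=quads,
        element_size=element_size,
        region=np.asarray(region, dtype=int),
        cut_pairs=cut_pairs,
        seams={
            "lower_left": lower_left,
            "lower_right": lower_right,
            "upper_left": upper_left,
            "upper_right": upper_right,
            "waist_upper_left": waist_upper_left,
            "waist_upper_right": waist_upper_right,
        },
        corner_nodes=corners,
        tip_nodes=np.asarray([low_ids[i_tip, -1], low_ids[i_tipR_low, -1]]),
        apex_node=int(up_ids[i_mid_up, 0]),
        center_node=int(low_ids[i_mid_low, -1]),
        domain=domain,
    )


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------


def _corner_metrics(nodes: np.ndarray, quads: np.ndarray):
    """Per-element min corner cross-product, scaled Jacobian and edge lengths."""
    p = nodes[quads]  # (E, 4, 2)
    e = np.roll(p, -1, axis=1) - p  # edge vectors 0->1, 1->2, 2->3, 3->0
    lengths = np.linalg.norm(e, axis=2)
    e_in = np.roll(e, 1, axis=1)  # incoming edge at each corner
    cross = e_in[..., 0] * e[..., 1] - e_in[..., 1] * e[..., 0]
    scaled = cross / np.maximum(lengths * np.roll(lengths, 1, axis=1), 1e-30)
    return cross, scaled, lengths


def reference_jacobians(mesh: SkinMesh) -> np.ndarray:
    """det of the reference isoparametric Jacobian at the 4 Gauss points."""
    p = mesh.nodes[mesh.quads]  # (E, 4, 2)
    dets = np.empty((mesh.n_elements, 4))
    for g, (xi, eta) in enumerate(GAUSS_POINTS):
        dN = 0.25 * np.array([
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ])
        J = np.einsum("eai,aj->eij", p, dN)
        dets[:, g] = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    return dets


def quality_report(mesh: SkinMesh, distortion_threshold: float = 0.5,
                   aspect_threshold: float = 1.5) -> MeshQualityReport:
    """Count inverted, distorted and bad-aspect elements.

    * inverted: non-positive Jacobian at any Gauss point ("upside-down");
    * distorted: minimum corner scaled Jacobian below the threshold;
    * bad aspect: longest/shortest edge ratio above the threshold.
    """
    dets = reference_jacobians(mesh)
    cross, scaled, lengths = _corner_metrics(mesh.nodes, mesh.quads)
    n_inverted = int(np.sum(dets.min(axis=1) <= 0.0))
    n_distorted = int(np.sum(scaled.min(axis=1) < distortion_threshold))
    aspect = lengths.max(axis=1) / np.maximum(lengths.min(axis=1), 1e-30)
    n_bad = int(np.sum(aspect > aspect_threshold))
    return MeshQualityReport(
        n_elements=mesh.n_elements,
        n_nodes=mesh.n_nodes,
        n_inverted=n_inverted,
        n_distorted=n_distorted,
        n_bad_aspect=n_bad,
        distortion_threshold=distortion_threshold,
        aspect_threshold=aspect_threshold,
    )


# ---------------------------------------------------------------------------
# closure plan: suture targets + tie pairs
# ---------------------------------------------------------------------------


@dataclass
class ClosurePlan:
    """Suture-stage targets and release-stage tie pairs for one mesh.

    ``targets`` maps wound-margin node -> its position on the closed T
    (both dofs prescribed during the suture stage, ramped from the
    reference).  ``ties`` lists (master, slave) node pairs bound to equal
    displacement in the release stage; each pair is one stitch.
    """

    targets: dict
    ties: list
    joint_height: float
    apex_target: np.ndarray

    @property
    def prescribed_nodes(self) -> np.ndarray:
        return np.asarray(sorted(self.targets), dtype=int)

    def max_prescribed_displacement(self, nodes: np.ndarray) -> float:
        ids = self.prescribed_nodes
        tg = np.asarray([self.targets[i] for i in ids])
        return float(np.max(np.linalg.norm(tg - nodes[ids], axis=1)))


def _joint_height(b: float, h: float, Lw: float) -> float:
    """Height of the T-joint in the closed configuration.

    Chosen to minimise the largest prescribed suture displacement: the two
    extreme movers are the base centre (rising to the joint) and the waist
    split point (swinging in to the joint); equating their travel gives the
    closed form below.
    """
    q = h * b / Lw
    return (b * b * (1.0 - b / Lw) ** 2 + q * q) / (2.0 * q)


def closure_plan(mesh: SkinMesh) -> ClosurePlan:
    """Construct suture targets and stitch pairs for an A-T mesh.

    The closed wound is idealised as a "T" polyline: two straight limbs
    from the cut tips to a joint at ``(0, y_J)`` and a vertical limb from
    the joint to the settled apex.  Each wound-margin chain is mapped onto
    its limb by arc length, so paired nodes on opposite margins share a
    target and every seam is closed without gaps:

    * each lateral limb joins the incision-side margin (tip -> base centre,
      arc L) to the flap-side margin (extension cut + lower waist, also arc
      L) — arc lengths match identically, so the seam is stitch-for-stitch
      length preserving;
    * the vertical limb joins the two upper waist halves (arc Lw - b each)
      to each other at their natural length.

    The base corners B and C ride with their chains onto the lateral limbs;
    the base centre and both waist split points meet at the joint.
    """
    if mesh.domain is None or not mesh.seams:
        raise ValueError("mesh carries no A-T seam metadata")
    dom = mesh.domain
    b, h, L, Lw = dom.half_base, dom.flap_length, dom.half_span, dom.waist_length
    y_J = _joint_height(b, h, Lw)
    joint = np.array([0.0, y_J])
    apex_target = np.array([0.0, y_J + (Lw - b)])
    X = mesh.nodes
    targets: dict = {}

    def set_target(node: int, pos: np.ndarray) -> None:
        if node in targets and not np.allclose(targets[node], pos, atol=1e-9):
            raise ValueError(f"conflicting suture targets for node {node}")
        targets[node] = np.asarray(pos, dtype=float)

    def lateral_arc(node: int, flap_side: bool) -> float:
        """Material arc length from the cut tip along a lateral seam."""
        x, y = X[node]
        ax = abs(x)
        if y <= 1e-9:  # on the base line: extension cut or incision margin
            return L - ax
        # on a waist: arc from B/C is proportional to horizontal progress
        return (L - b) + (b - ax) * Lw / b

    for side, sgn in (("left", -1.0), ("right", 1.0)):
        tip = np.array([sgn * L, 0.0])
        limb = joint - tip
        lower = mesh.seams[f"lower_{side}"]
        upper = mesh.seams[f"upper_{side}"]
        if lower.size != upper.size:
            raise ValueError("unmatched cut node: seam chains differ in length")
        for chain in (lower, upper):
            for node in chain:
                t = lateral_arc(node, chain is upper)
                set_target(node, tip + (t / L) * limb)
        wchain = mesh.seams[f"waist_upper_{side}"]
        for node in wchain:
            x, y = X[node]
            s = (b - abs(x)) * Lw / b  # waist arc from B/C
            set_target(node, joint + np.array([0.0, s - b]))
    set_target(mesh.apex_node, apex_target)
    set_target(mesh.center_node, joint)

    ties: list = []
    for side in ("left", "right"):
        lower = mesh.seams[f"lower_{side}"]
        upper = mesh.seams[f"upper_{side}"]
        for k in range(1, lower.size):  # k = 0 is the shared cut-tip node
            ties.append((int(lower[k]), int(upper[k])))
    wl, wr = mesh.seams["waist_upper_left"], mesh.seams["waist_upper_right"]
    for j in range(1, wl.size - 1):  # ends: joint (tied via chains) and apex
        ties.append((int(wl[j]), int(wr[j])))
    return ClosurePlan(
        targets=targets, ties=ties, joint_height=y_J, apex_target=apex_target
    )


def suture_pairs(mesh: SkinMesh):
    """Ordered stitch pairs with their common target positions.

    Returns a list of ``(node_a, node_b, target)`` covering every bound
    margin pair (the apex, being a single shared node, is not a pair).
    """
    plan = closure_plan(mesh)
    out = []
    for a, bnode in plan.ties:
        ta, tb = plan.targets[a], plan.targets[bnode]
        if not np.allclose(ta, tb, atol=1e-9):
            raise ValueError(f"pair ({a}, {bnode}) has mismatched targets")
        out.append((a, bnode, ta))
    return out
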