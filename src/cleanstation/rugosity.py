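"""Virtual-chain rugosity of a 2-D surface profile.

The chain-and-tape method drapes a chain of rigid links (default 2 cm)
over a surface transect and compares the straight-line span covered to
the length of chain used:

    R = span / (n_links * link_cm)

R = 1 on a perfectly flat plane and decreases toward 0 as the surface
becomes more rugose (more chain is consumed per unit of horizontal
distance).  Profiles are functional polylines: ordered (x, z) vertices
with strictly increasing x (overhangs are rejected).

Draping is greedy and exact: from the current chain node, the next node
is the farthest-forward intersection of a circle of radius ``link_cm``
(centred on the current node) with the profile polyline.  The chain uses
whole links only; a terminal remainder shorter than one link is dropped
unless ``fractional_tail`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurfaceProfile", "ChainDrape", "drape_chain", "rugosity", "mean_rugosity"]


@dataclass(frozen=True)
class SurfaceProfile:
    """Functional 2-D transect: vertices (x_cm, z_cm), x strictly increasing."""

    x_cm: np.ndarray
    z_cm: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x_cm, dtype=float)
        z = np.asarray(self.z_cm, dtype=float)
        object.__setattr__(self, "x_cm", x)
        object.__setattr__(self, "z_cm", z)
        if x.ndim != 1 or x.shape != z.shape or x.size < 2:
            raise ValueError("profile needs >= 2 (x, z) vertex pairs")
        if not (np.isfinite(x).all() and np.isfinite(z).all()):
            raise ValueError("profile coordinates must be finite")
        if not (np.diff(x) > 0).all():
            raise ValueError("x coordinates must be strictly increasing (no overhangs)")

    @property
    def span_cm(self) -> float:
        return float(self.x_cm[-1] - self.x_cm[0])

    @property
    def arc_length_cm(self) -> float:
        return float(np.hypot(np.diff(self.x_cm), np.diff(self.z_cm)).sum())


@dataclass(frozen=True)
class ChainDrape:
    """Chain node positions on a profile, consecutive nodes link_cm apart."""

    nodes: np.ndarray  # (n_nodes, 2) array of (x, z)
    link_cm: float

    @property
    def n_links(self) -> int:
        return len(self.nodes) - 1

    @property
    def chain_length_cm(self) -> float:
        return self.n_links * self.link_cm

    @property
    def span_cm(self) -> float:
        return float(self.nodes[-1, 0] - self.nodes[0, 0])


def _circle_segment_intersections(c, radius, a, b):
    """Parameters t in [0, 1] where |a + t(b-a) - c| = radius."""
    d = b - a
    f = a - c
    A = d @ d
    B = 2.0 * (f @ d)
    C = f @ f - radius * radius
    if A == 0.0:
        return []
    disc = B * B - 4.0 * A * C
    # near-tangency: the double root is ill-conditioned (error ~ sqrt(eps)),
    # so snap tiny discriminants to the exact tangent point
    if disc < 1e-12 * A * radius * radius:
        if disc < -1e-12 * A * radius * radius:
            return []
        disc = 0.0
    sq = np.sqrt(disc)
    out = []
    for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
        if -1e-12 <= t <= 1.0 + 1e-12:
            out.append(min(max(t, 0.0), 1.0))
    return out


def drape_chain(profile: SurfaceProfile, link_cm: float = 2.0) -> ChainDrape:
    """Greedy forward chain placement over a profile.

    The first node sits on the first vertex.  Each subsequent node is the
    farthest-forward (largest arc position) point of the polyline exactly
    ``link_cm`` from the current node.  Placement stops when no forward
    intersection remains.
    """
    if link_cm <= 0:
        raise ValueError("link_cm must be positive")
    if profile.span_cm < link_cm:
        raise ValueError(
            f"profile span {profile.span_cm:.3f} cm is shorter than one "
            f"{link_cm:.3f} cm link"
        )
    verts = np.column_stack([profile.x_cm, profile.z_cm])
    n_seg = len(verts) - 1
    nodes = [verts[0].copy()]
    seg_i, seg_t = 0, 0.0  # arc position of the current node

    while True:
        c = nodes[-1]
        best = None  # (segment, t)
        for j in range(seg_i, n_seg):
            a, b = verts[j], verts[j + 1]
            if a[0] > c[0] + link_cm:
                break  # x is monotone: no later segment can reach the circle
            for t in _circle_segment_intersections(c, link_cm, a, b):
                if j == seg_i and t <= seg_t + 1e-12:
                    continue  # behind or at the current node
                if best is None or (j, t) > best:
                    best = (j, t)
        if best is None:
            break
        seg_i, seg_t = best
        a, b = verts[seg_i], verts[seg_i + 1]
        nodes.append(a + seg_t * (b - a))
    return ChainDrape(np.array(nodes), float(link_cm))


def rugosity(
    profile: SurfaceProfile, link_cm: float = 2.0, *, fractional_tail: bool = False
) -> float:
    """Span-to-chain-length rugosity ratio in (0, 1].

    With ``fractional_tail`` the remainder of profile past the last whole
    link contributes a partial link (straight-line distance from the last
    node to the final vertex), slightly lowering the discretisation bias
    on short profiles.
    """
    drape = drape_chain(profile, link_cm)
    chain = drape.chain_length_cm
    span = drape.span_cm
    if fractional_tail:
        last = drape.nodes[-1]
        end = np.array([profile.x_cm[-1], profile.z_cm[-1]])
        tail = float(np.hypot(*(end - last)))
        chain += tail
        span = float(end[0] - drape.nodes[0, 0])
    if chain == 0:
        raise ValueError("chain has zero length")
    return span / chain


def mean_rugosity(profiles, link_cm: float = 2.0) -> float:
    """Average chain rugosity over several transects of one station."""
    vals = [rugosity(p, link_cm) for p in profiles]
    if not vals:
        raise ValueError("no profiles supplied")
    return float(np.mean(vals))
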