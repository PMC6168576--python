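"""Tri-junction statistics of 2D crack and trough networks.

Crack networks on skin (and their simulated counterparts) consist almost
exclusively of tri-junctions.  Since the three angles of a junction sorted
as ``theta1 <= theta2 <= theta3`` sum to 360 deg, every junction maps to a
single point ``(theta1, theta2)`` — the angular scatter plot, which avoids
the information loss of binned density profiles.  The scalar dispersion of
a junction population is the angular spreading ``sigma_theta``: the radius
of the circle whose area equals that of the 68%-probability-mass error
ellipse of the fitted 2D Gaussian.  Junctions are classified against three
archetypes (triple-120, 90-135-135, T-junction) by nearest archetype in the
``(theta1, theta2)`` plane — the Voronoi partition of the admissible region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .substrate import PapillaConfig, Substrate

__all__ = [
    "PlanarNetwork",
    "Junction",
    "JunctionStats",
    "ARCHETYPES",
    "project_crack_network",
    "extract_junctions",
    "angular_scatter",
    "angular_spreading",
    "classify_junction",
    "angle_pdf",
    "prob_in_range",
    "generate_trough_network",
    "compute_junction_stats",
    "junctions_to_dataframe",
]

#: archetypal junctions in the (theta1, theta2) plane, in tie-break priority order
ARCHETYPES: dict[str, tuple[float, float]] = {
    "triple-120": (120.0, 120.0),
    "90-135-135": (90.0, 135.0),
    "T-junction": (90.0, 90.0),
}

#: 68% probability mass of a 2D Gaussian: Mahalanobis radius^2
_C68 = -2.0 * np.log(1.0 - 0.68)


@dataclass
class PlanarNetwork:
    """Straight-segment graph in the plane (positions in mm)."""

    nodes: np.ndarray  # (n, 2)
    segments: np.ndarray  # (m, 2) node index pairs
    provenance: str = "external-CSV"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.float64).reshape(-1, 2)
        self.segments = np.asarray(self.segments, dtype=np.int64).reshape(-1, 2)
        if len(self.segments) and np.any(self.segments[:, 0] == self.segments[:, 1]):
            raise ValueError("self-loop segment")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("non-finite node position")

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=np.int64)
        np.add.at(deg, self.segments.reshape(-1), 1)
        return deg

    def to_csv(self, nodes_path: str, segments_path: str) -> None:
        pd.DataFrame(
            {"id": np.arange(len(self.nodes)), "x_mm": self.nodes[:, 0], "y_mm": self.nodes[:, 1]}
        ).to_csv(nodes_path, index=False)
        pd.DataFrame({"id_a": self.segments[:, 0], "id_b": self.segments[:, 1]}).to_csv(
            segments_path, index=False
        )

    @classmethod
    def from_csv(cls, nodes_path: str, segments_path: str, provenance: str = "external-CSV"):
        nd = pd.read_csv(nodes_path)
        sg = pd.read_csv(segments_path)
        order = np.argsort(nd["id"].to_numpy())
        nodes = nd[["x_mm", "y_mm"]].to_numpy()[order]
        remap = {int(i): k for k, i in enumerate(nd["id"].to_numpy()[order])}
        segs = np.array(
            [(remap[int(a)], remap[int(b)]) for a, b in zip(sg["id_a"], sg["id_b"])],
            dtype=np.int64,
        ).reshape(-1, 2)
        return cls(nodes, segs, provenance)


@dataclass
class Junction:
    """A tri-junction: position and sorted angles (degrees, summing to 360)."""

    position: np.ndarray
    angles: tuple[float, float, float]

    def __post_init__(self) -> None:
        t1, t2, t3 = self.angles
        if not (t1 <= t2 <= t3):
            raise ValueError("junction angles must be sorted ascending")
        if abs(t1 + t2 + t3 - 360.0) > 1e-9:
            raise ValueError("junction angles must sum to 360 deg")
        if t1 <= 0:
            raise ValueError("junction angles must be positive")


@dataclass
class JunctionStats:
    """Scatter summary of a junction population."""

    points: np.ndarray  # (n, 2) (theta1, theta2)
    mean: np.ndarray  # (2,)
    cov: np.ndarray  # (2, 2)
    sigma_theta: float  # degrees
    ellipse_area: float  # A_1sigma, deg^2
    degenerate: bool
    archetype_counts: dict[str, int]
    pooled_angles: np.ndarray  # all 3n angles
    n_excluded_degree4plus: int = 0


# -- network construction ---------------------------------------------------


def project_crack_network(result, substrate: Substrate | None = None) -> PlanarNetwork:
    """Project the broken edges of a simulation onto the plane as a crack graph.

    Bending-driven cracks break mesh edges lying *along* the crack line, so
    the broken edges themselves are the crack segments: network nodes are
    the mesh vertices incident to at least one broken edge (at their rest
    positions, orthographically projected by dropping the height) and each
    broken edge contributes one segment.  Crack lines appear as degree-2
    chains and crack branching as degree-3 nodes, with no artificial
    cliques at meeting points.
    """
    import warnings

    state = result.final_state if hasattr(result, "final_state") else result
    mesh = state.mesh
    broken = np.flatnonzero(state.broken)
    if len(broken) == 0:
        warnings.warn("no broken edges; empty crack network")
        return PlanarNetwork(np.zeros((0, 2)), np.zeros((0, 2), dtype=np.int64), "simulated-cracks")
    used = np.unique(mesh.edges[broken].reshape(-1))
    remap = {int(v): i for i, v in enumerate(used)}
    nodes = state.foot[used, :2]
    segments = np.array(
        [(remap[int(a)], remap[int(b)]) for a, b in mesh.edges[broken]], dtype=np.int64
    )
    return PlanarNetwork(nodes, segments, "simulated-cracks")


# -- junction extraction ----------------------------------------------------


def _chains(network: PlanarNetwork):
    """Contract degree-2 nodes: return polyline chains between junction/end nodes.

    Each chain is a list of node indices whose interior nodes all have
    degree 2.  Closed loops without any junction node are ignored (they
    carry no junctions).
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(network.nodes)))
    g.add_edges_from(map(tuple, network.segments))
    deg = dict(g.degree())
    anchors = {n for n, d in deg.items() if d != 2}
    chains = []
    visited = set()
    for a in anchors:
        for b in g.neighbors(a):
            key = (a, b)
            if key in visited:
                continue
            chain = [a, b]
            visited.add((a, b))
            visited.add((b, a))
            prev, cur = a, b
            while deg[cur] == 2 and cur not in anchors:
                nxt = [n for n in g.neighbors(cur) if n != prev]
                if not nxt:
                    break
                visited.add((cur, nxt[0]))
                visited.add((nxt[0], cur))
                prev, cur = cur, nxt[0]
                chain.append(cur)
            chains.append(chain)
    return chains, deg, anchors


def _branch_bearing(network: PlanarNetwork, chain: list[int], r: float) -> float | None:
    """Bearing (radians) from the chain start to the point at arc length r along it."""
    pts = network.nodes[chain]
    seglens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seglens.sum()
    if total == 0:
        return None
    target = min(r, total)
    acc = 0.0
    for k, sl in enumerate(seglens):
        if acc + sl >= target - 1e-12:
            t = (target - acc) / sl if sl > 0 else 0.0
            p = pts[k] + t * (pts[k + 1] - pts[k])
            v = p - pts[0]
            n = np.linalg.norm(v)
            if n == 0:
                continue
            return float(np.arctan2(v[1], v[0]))
        acc += sl
    v = pts[-1] - pts[0]
    n = np.linalg.norm(v)
    return float(np.arctan2(v[1], v[0])) if n > 0 else None


def extract_junctions(
    network: PlanarNetwork, branch_arc_length: float
) -> tuple[list[Junction], int]:
    """Tri-junctions of the chain-contracted network with their sorted angles.

    Junction nodes are nodes of degree 3 after contracting degree-2 chains.
    Each branch direction is measured from the junction to the point at arc
    length ``branch_arc_length`` along the incident chain (or its end, if
    shorter); the three angles are the circular gaps between the branch
    bearings, sorted ascending.  Nodes of degree >= 4 are excluded and
    counted separately.  Returns ``(junctions, n_excluded_degree4plus)``.
    """
    if branch_arc_length <= 0:
        raise ValueError("branch_arc_length must be positive")
    chains, deg, anchors = _chains(network)
    by_anchor: dict[int, list] = {}
    for ch in chains:
        by_anchor.setdefault(ch[0], []).append(ch)
        # a chain also provides a branch at its far end if that is an anchor
        if ch[-1] in anchors:
            by_anchor.setdefault(ch[-1], []).append(list(reversed(ch)))
    junctions: list[Junction] = []
    n_excluded = 0
    for node, d in deg.items():
        if d < 3:
            continue
        if d > 3:
            n_excluded += 1
            continue
        branches = [c for c in by_anchor.get(node, []) if c[0] == node]
        bearings = []
        for ch in branches:
            b = _branch_bearing(network, ch, branch_arc_length)
            if b is not None:
                bearings.append(b)
        if len(bearings) != 3:
            n_excluded += 1
            continue
        bearings = np.sort(np.mod(bearings, 2 * np.pi))
        gaps = np.diff(np.append(bearings, bearings[0] + 2 * np.pi))
        ang = tuple(sorted(np.degrees(gaps)))
        if ang[0] <= 0:
            n_excluded += 1
            continue
        junctions.append(Junction(network.nodes[node].copy(), ang))
    return junctions, n_excluded


# -- scatter statistics -----------------------------------------------------


def _validate_point(t1: float, t2: float) -> None:
    t3 = 360.0 - t1 - t2
    if not (0 < t1 <= t2 <= t3 + 1e-9):
        raise ValueError(f"({t1}, {t2}) outside the admissible region theta1 <= theta2 <= theta3")


def angular_scatter(junctions: Iterable[Junction]) -> tuple[np.ndarray, np.ndarray]:
    """(theta1, theta2) scatter points and their component-wise mean."""
    pts = np.array([(j.angles[0], j.angles[1]) for j in junctions], dtype=np.float64)
    if len(pts) == 0:
        raise ValueError("no junctions")
    for t1, t2 in pts:
        _validate_point(t1, t2)
    return pts, pts.mean(axis=0)


def angular_spreading(
    junctions: Iterable[Junction] | np.ndarray, mass: float = 0.68
) -> tuple[float, dict]:
    """Angular spreading sigma_theta and the fitted error ellipse.

    Fits a 2D Gaussian to the (theta1, theta2) points; the ellipse enclosing
    ``mass`` probability has area ``A = pi * c * sqrt(det Sigma)`` with
    ``c = -2 ln(1 - mass)``, and ``sigma_theta = sqrt(A / pi)``.  With
    ``mass=0.68`` this is the one-standard-deviation (~68% confidence)
    ellipse; passing the Mahalanobis-1 variant is a matter of ``mass``
    ≈ 0.3935.  Degenerate samples (identical or collinear points) return
    sigma_theta 0 with a flag.
    """
    if isinstance(junctions, np.ndarray):
        pts = junctions
    else:
        pts, _ = angular_scatter(junctions)
    if len(pts) < 3:
        raise ValueError("need at least 3 junctions for a covariance")
    c = -2.0 * np.log(1.0 - mass)
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T)
    det = float(np.linalg.det(cov))
    if det <= 1e-12:
        return 0.0, {"mean": mean, "cov": cov, "area": 0.0, "degenerate": True, "c": c}
    area = float(np.pi * c * np.sqrt(det))
    sigma = float(np.sqrt(c) * det**0.25)
    return sigma, {"mean": mean, "cov": cov, "area": area, "degenerate": False, "c": c}


def classify_junction(theta1: float, theta2: float) -> str:
    """Nearest archetype in the (theta1, theta2) plane (Voronoi classification).

    Exact ties resolve in the fixed order triple-120 > 90-135-135 > T-junction.
    """
    _validate_point(theta1, theta2)
    best = None
    best_d = np.inf
    for name, (a1, a2) in ARCHETYPES.items():
        d = np.hypot(theta1 - a1, theta2 - a2)
        if d < best_d:  # strict: earlier archetypes win ties
            best, best_d = name, d
    return best


# -- angle densities --------------------------------------------------------


def angle_pdf(
    angles: np.ndarray,
    bandwidth: float | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> dict:
    """Reflected Gaussian KDE of pooled junction angles with a bootstrap band.

    The density lives on [0, 360] deg with boundary reflection at 0 (and,
    symmetrically, at 360).  Bandwidth defaults to Silverman's rule.  The
    95% band is the pointwise 2.5-97.5 percentile envelope over ``n_bootstrap``
    seeded resamples.
    """
    angles = np.asarray(angles, dtype=np.float64).ravel()
    if len(angles) < 2:
        raise ValueError("need at least 2 angles")
    if grid is None:
        grid = np.linspace(0.0, 360.0, 361)
    sd = angles.std(ddof=1)
    if bandwidth is None:
        bandwidth = 0.9 * min(sd, (np.percentile(angles, 75) - np.percentile(angles, 25)) / 1.34)
        bandwidth *= len(angles) ** (-1 / 5)
        bandwidth = max(bandwidth, 1e-6)

    def kde(sample: np.ndarray) -> np.ndarray:
        # reflect at both domain boundaries so mass does not leak
        data = np.concatenate([sample, -sample, 720.0 - sample])
        z = (grid[:, None] - data[None, :]) / bandwidth
        dens = np.exp(-0.5 * z**2).sum(axis=1)
        return dens / (len(sample) * bandwidth * np.sqrt(2 * np.pi))

    point = kde(angles)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, len(grid)))
    for b in range(n_bootstrap):
        boots[b] = kde(rng.choice(angles, size=len(angles), replace=True))
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return {
        "grid": grid,
        "density": point,
        "band_lo": lo,
        "band_hi": hi,
        "bandwidth": bandwidth,
    }


def prob_in_range(angles: np.ndarray, lo: float, hi: float) -> float:
    """Empirical fraction of pooled angles falling in [lo, hi] degrees."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    angles = np.asarray(angles, dtype=np.float64).ravel()
    return float(np.mean((angles >= lo) & (angles <= hi)))


# -- trough-line comparator network ----------------------------------------


def generate_trough_network(
    source: Substrate | PapillaConfig | np.ndarray,
    domain_size: tuple[float, float] | None = None,
) -> PlanarNetwork:
    """Valley-line network: the Voronoi tessellation of the papilla centers.

    The troughs between papillae run along the loci equidistant from
    neighbouring centers, i.e. the Voronoi edges, clipped to the domain.
    For an unjittered hexagonal lattice every interior junction is the
    honeycomb vertex (120, 120, 120).
    """
    from scipy.spatial import Voronoi
    from shapely.geometry import LineString, box

    if isinstance(source, PapillaConfig):
        from .substrate import _hex_centers

        centers = _hex_centers(source)
        domain = source.domain_size
    elif isinstance(source, Substrate):
        if source.centers is None:
            raise ValueError("substrate has no papilla centers")
        centers = source.centers
        domain = source.domain_size
    else:
        centers = np.asarray(source, dtype=np.float64)
        domain = domain_size
    if len(centers) < 3:
        raise ValueError("need at least 3 papilla centers")
    vor = Voronoi(centers)
    clip = box(0.0, 0.0, *domain) if domain and domain[0] > 0 else None

    pts: list[tuple[float, float]] = []
    index: dict[tuple[float, float], int] = {}
    segs: set[tuple[int, int]] = set()

    def add_point(p) -> int:
        key = (round(float(p[0]), 9), round(float(p[1]), 9))
        if key not in index:
            index[key] = len(pts)
            pts.append(key)
        return index[key]

    for (a, b) in vor.ridge_vertices:
        if a == -1 or b == -1:
            continue  # infinite ridges terminate outside any sensible domain
        pa, pb = vor.vertices[a], vor.vertices[b]
        if clip is not None:
            ls = LineString([pa, pb]).intersection(clip)
            if ls.is_empty or ls.geom_type != "LineString":
                continue
            (xa, ya), (xb, yb) = ls.coords[0], ls.coords[-1]
            pa, pb = np.array([xa, ya]), np.array([xb, yb])
        ia, ib = add_point(pa), add_point(pb)
        if ia != ib:
            segs.add((min(ia, ib), max(ia, ib)))
    return PlanarNetwork(
        np.array(pts, dtype=np.float64).reshape(-1, 2),
        np.array(sorted(segs), dtype=np.int64).reshape(-1, 2),
        "trough-lines",
    )


def junctions_to_dataframe(junctions: Iterable[Junction]) -> pd.DataFrame:
    """Tabulate junctions: position, sorted angles and archetype class."""
    rows = []
    for j in junctions:
        t1, t2, t3 = j.angles
        rows.append(
            {
                "x": j.position[0],
                "y": j.position[1],
                "theta1": t1,
                "theta2": t2,
                "theta3": t3,
                "archetype": classify_junction(t1, t2),
            }
        )
    return pd.DataFrame(rows, columns=["x", "y", "theta1", "theta2", "theta3", "archetype"])


# -- one-call summary -------------------------------------------------------


def compute_junction_stats(
    network: PlanarNetwork, branch_arc_length: float, interior_margin: float | None = None,
    domain_size: tuple[float, float] | None = None,
) -> JunctionStats:
    """Extract junctions and compute the full angular summary of a network.

    ``interior_margin`` (mm) optionally discards junctions closer than the
    margin to the domain boundary, where clipped branches bias the angles.
    """
    junctions, n_excl = extract_junctions(network, branch_arc_length)
    if interior_margin is not None and domain_size is not None:
        w, h = domain_size
        junctions = [
            j
            for j in junctions
            if interior_margin <= j.position[0] <= w - interior_margin
            and interior_margin <= j.position[1] <= h - interior_margin
        ]
    if not junctions:
        raise ValueError("no tri-junctions found")
    pts, mean = angular_scatter(junctions)
    if len(pts) >= 3:
        sigma, ell = angular_spreading(pts)
    else:
        sigma, ell = 0.0, {"cov": np.full((2, 2), np.nan), "area": 0.0, "degenerate": True}
    counts = dict.fromkeys(ARCHETYPES, 0)
    for t1, t2 in pts:
        counts[classify_junction(t1, t2)] += 1
    pooled = np.array([a for j in junctions for a in j.angles])
    return JunctionStats(
        points=pts,
        mean=mean,
        cov=np.asarray(ell["cov"]),
        sigma_theta=sigma,
        ellipse_area=float(ell["area"]),
        degenerate=bool(ell["degenerate"]),
        archetype_counts=counts,
        pooled_angles=pooled,
        n_excluded_degree4plus=n_excl,
    )
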