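"""Lattice-spring shell mechanics with a curved stress-free configuration.

The outer stratum corneum is modelled as a thin brittle sheet discretised on
a triangle mesh.  Its rest configuration is the shape it had when formed on
the papillated substrate, so a papillated initial state carries zero energy.
The energy terms acting on the node positions:

* stretching   — per-edge springs, quadratic in the engineering strain;
* bending      — per-hinge penalty on the deviation of the dihedral angle
                 from its frozen rest value;
* area         — per-face penalty on relative area change (the in-plane
                 "volumetric" response of the sheet);
* substrate    — per-node tether to an offset surface: each node is pulled
                 toward its frozen foot point displaced by the growth offset
                 ``h`` along the frozen substrate normal ("pushed outwards"
                 by layers added from below);
* penetration  — one-sided penalty keeping the sheet above the solid dermis
                 (troughs may lift off; papilla caps cannot be sunk into);
* contact      — one-sided node-face penalty preventing self-penetration.

Every force routine is the exact negative gradient of its energy (verified
against central finite differences in the test suite).  Fracture uses a
fibre strain of a sheet of thickness ``t_s``: membrane strain plus a
``t_s/2`` times the change in edge curvature, so that bending can break
bonds — the mechanism that confines growth cracks to the substrate troughs
(see :func:`effective_edge_strain` for the criterion variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TriMesh
from .substrate import Substrate

__all__ = [
    "ShellParams",
    "ShellState",
    "init_shell",
    "stretch_energy",
    "stretch_forces",
    "bend_energy",
    "bend_forces",
    "area_energy",
    "area_forces",
    "substrate_energy",
    "substrate_forces",
    "penetration_energy",
    "penetration_forces",
    "contact_energy",
    "contact_forces",
    "contact_pairs",
    "total_energy",
    "total_forces",
    "effective_edge_strain",
]


@dataclass
class ShellParams:
    """Material and numerical parameters of the shell (mm / dimensionless units).

    ``k_s`` is an energy per unit length (the spring term is
    ``(k_s/2) l0 eps^2``, so refinement does not change the material),
    ``k_b`` an energy, ``k_v`` an energy per unit area, ``k_sub`` and
    ``k_c`` energies per unit length squared.  ``t_s`` is the mechanical
    sheet thickness entering the outer-fibre fracture strain; ``eps_c`` the
    critical strain at which an edge breaks.
    """

    k_s: float = 1.0
    k_b: float = 0.005
    k_v: float = 0.5
    k_sub: float = 0.5
    k_pen: float = 30.0
    k_c: float = 2.0
    contact_range: float = 0.08
    t_s: float = 0.2
    eps_c: float = 0.3
    mass: float = 1.0
    damping: float = 6.0
    strain_criterion: str = "inner-fibre"  # or "outer-fibre" | "membrane"

    def __post_init__(self) -> None:
        for name in ("k_s", "k_b", "k_v", "k_sub", "k_pen", "k_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.eps_c <= 0 or self.t_s <= 0 or self.contact_range <= 0:
            raise ValueError("eps_c, t_s and contact_range must be positive")
        if self.strain_criterion not in ("inner-fibre", "outer-fibre", "membrane"):
            raise ValueError(
                "strain_criterion must be 'inner-fibre', 'outer-fibre' or 'membrane'"
            )


@dataclass
class ShellState:
    """Dynamic state of the shell on a fixed mesh topology.

    Rest quantities (``l0``, ``theta0``, rest areas, rest hinge heights,
    foot points and foot normals) are frozen at initialisation; only the
    shrinkage protocol rescales the in-plane rest metric.
    """

    mesh: TriMesh
    X: np.ndarray  # (n, 3) positions
    V: np.ndarray  # (n, 3) velocities
    l0: np.ndarray  # (E,) rest lengths
    theta0: np.ndarray  # (H,) rest dihedral angles
    A0: np.ndarray  # (F,) rest face areas
    hinge_h0: np.ndarray  # (H,) rest sum of the two triangle heights over the edge
    broken: np.ndarray  # (E,) bool
    foot: np.ndarray  # (n, 3) frozen substrate foot points
    foot_normal: np.ndarray  # (n, 3) frozen substrate normals at the foot points
    h: float = 0.0  # growth offset
    s: float = 0.0  # cumulative shrink factor
    fixed: np.ndarray | None = None  # optional (n,) bool mask of clamped nodes

    def copy(self) -> "ShellState":
        return ShellState(
            self.mesh,
            self.X.copy(),
            self.V.copy(),
            self.l0.copy(),
            self.theta0.copy(),
            self.A0.copy(),
            self.hinge_h0.copy(),
            self.broken.copy(),
            self.foot,
            self.foot_normal,
            self.h,
            self.s,
            None if self.fixed is None else self.fixed.copy(),
        )

    # -- masks --------------------------------------------------------------

    @property
    def active_edges(self) -> np.ndarray:
        return ~self.broken

    @property
    def active_hinges(self) -> np.ndarray:
        """Hinges whose shared edge is unbroken."""
        return ~self.broken[self.mesh.hinge_edge]

    @property
    def active_faces(self) -> np.ndarray:
        """Faces none of whose three edges are broken."""
        return ~np.any(self.broken[self.mesh.face_edges], axis=1)

    @property
    def broken_fraction(self) -> float:
        return float(self.broken.mean()) if len(self.broken) else 0.0

    def break_edge(self, edge_id: int) -> None:
        """Irreversibly deactivate one edge (its hinge and faces follow via the masks)."""
        self.broken[edge_id] = True

    def apply_shrink(self, ds: float) -> None:
        """Uniform in-plane rest-metric shrink by a factor (1 - ds).

        Rest lengths and rest hinge heights scale by ``1 - ds``, rest areas
        by ``(1 - ds)^2``; rest dihedral angles are deliberately unchanged
        (isotropic in-plane desiccation of an intrinsically curved sheet).
        """
        if not 0 < ds < 1:
            raise ValueError("ds must be in (0, 1)")
        f = 1.0 - ds
        self.l0 *= f
        self.A0 *= f * f
        self.hinge_h0 *= f
        self.s = 1.0 - (1.0 - self.s) * f


def _triangle_normals(X: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = X[faces[:, 0]], X[faces[:, 1]], X[faces[:, 2]]
    return np.cross(b - a, c - a)


def _hinge_geometry(X: np.ndarray, hinges: np.ndarray):
    """Edge vectors, unnormalised face normals and signed dihedral angles.

    A hinge row is ``(a, b, c, d)``: edge ``a-b``, ``c`` opposite in the face
    traversing ``a -> b``, ``d`` opposite in the face traversing ``b -> a``.
    The dihedral angle is 0 for coplanar faces, positive when the hinge folds
    toward the face normals (convex crease), negative otherwise.
    """
    x0, x1 = X[hinges[:, 0]], X[hinges[:, 1]]
    x2, x3 = X[hinges[:, 2]], X[hinges[:, 3]]
    e = x1 - x0
    n1 = np.cross(e, x2 - x0)  # normal of (a, b, c) x ... consistent orientation
    n2 = np.cross(x3 - x0, e)  # normal of (b, a, d) re-expressed on (a, b)
    L = np.linalg.norm(e, axis=1)
    nn1 = np.linalg.norm(n1, axis=1)
    nn2 = np.linalg.norm(n2, axis=1)
    sin_t = np.einsum("ij,ij->i", np.cross(n1, n2), e) / np.maximum(nn1 * nn2 * L, 1e-300)
    cos_t = np.einsum("ij,ij->i", n1, n2) / np.maximum(nn1 * nn2, 1e-300)
    theta = np.arctan2(sin_t, cos_t)
    return e, L, n1, n2, nn1, nn2, theta


def hinge_angles(X: np.ndarray, hinges: np.ndarray) -> np.ndarray:
    """Signed dihedral angles for every hinge (0 when coplanar)."""
    if len(hinges) == 0:
        return np.zeros(0)
    return _hinge_geometry(X, hinges)[-1]


def init_shell(substrate_mesh: TriMesh, substrate: Substrate | None = None) -> ShellState:
    """Freeze the substrate mesh as the stress-free configuration of the shell.

    Positions, rest lengths, rest dihedral angles and rest areas are taken
    from the mesh, so the total internal energy is exactly zero at ``h = 0``.
    Foot points are the initial positions; foot normals are substrate
    normals queried once at the foot points (vertical for a flat or absent
    substrate) and never re-associated.
    """
    m = substrate_mesh
    X = m.vertices.copy()
    l0 = m.edge_lengths()
    if np.any(l0 <= 0):
        raise ValueError("mesh has a zero-length edge")
    theta0 = hinge_angles(X, m.hinges)
    n = _triangle_normals(X, m.faces)
    A0 = 0.5 * np.linalg.norm(n, axis=1)
    if np.any(A0 <= 0):
        raise ValueError("mesh has a degenerate face")
    # rest hinge heights: h_i = 2 A_i / L summed over the two incident faces
    he = m.hinge_edge
    L = l0[he]
    f1 = m.edge_faces[he, 0]
    f2 = m.edge_faces[he, 1]
    hinge_h0 = 2.0 * (A0[f1] + A0[f2]) / L
    if substrate is not None:
        normals = substrate.normal(X[:, :2])
    else:
        normals = np.tile(np.array([0.0, 0.0, 1.0]), (len(X), 1))
    return ShellState(
        mesh=m,
        X=X,
        V=np.zeros_like(X),
        l0=l0,
        theta0=theta0,
        A0=A0,
        hinge_h0=hinge_h0,
        broken=np.zeros(m.n_edges, dtype=bool),
        foot=X.copy(),
        foot_normal=normals,
    )


def _scatter_add(n: int, idx: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Sum (m, 3) contributions into an (n, 3) array by node index."""
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.bincount(idx, weights=vals[:, k], minlength=n)
    return out


# -- stretching -------------------------------------------------------------


def _stretch(state: ShellState, params: ShellParams, want_forces: bool):
    m = state.mesh
    act = state.active_edges
    ea, eb = m.edges[act, 0], m.edges[act, 1]
    e = state.X[eb] - state.X[ea]
    L = np.linalg.norm(e, axis=1)
    if np.any(L <= 0):
        raise FloatingPointError("zero-length edge in current configuration")
    l0 = state.l0[act]
    eps = (L - l0) / l0
    E = 0.5 * params.k_s * np.sum(l0 * eps**2)
    if not want_forces:
        return E, None
    # dE/dxb = k_s * eps * e_hat
    g = (params.k_s * eps / L)[:, None] * e
    F = _scatter_add(len(state.X), ea, g) - _scatter_add(len(state.X), eb, g)
    return E, F


def stretch_energy(state: ShellState, params: ShellParams) -> float:
    """Spring energy ``sum (k_s/2) l0 eps^2`` over unbroken edges."""
    return _stretch(state, params, False)[0]


def stretch_forces(state: ShellState, params: ShellParams) -> np.ndarray:
    return _stretch(state, params, True)[1]


# -- bending ----------------------------------------------------------------


def _bend(state: ShellState, params: ShellParams, want_forces: bool):
    m = state.mesh
    act = state.active_hinges
    hg = m.hinges[act]
    if len(hg) == 0:
        return 0.0, (np.zeros_like(state.X) if want_forces else None)
    e, L, n1, n2, nn1, nn2, theta = _hinge_geometry(state.X, hg)
    if np.any(nn1 <= 0) or np.any(nn2 <= 0):
        raise FloatingPointError("degenerate face adjacent to a hinge")
    dtheta = theta - state.theta0[act]
    E = params.k_b * np.sum(dtheta**2)
    if not want_forces:
        return E, None
    # gradient of the dihedral angle (discrete-shells form)
    g2 = (-L / nn1**2)[:, None] * n1
    g3 = (-L / nn2**2)[:, None] * n2
    x0 = state.X[hg[:, 0]]
    t2 = np.einsum("ij,ij->i", state.X[hg[:, 2]] - x0, e) / L**2
    t3 = np.einsum("ij,ij->i", state.X[hg[:, 3]] - x0, e) / L**2
    g1 = -(t2[:, None] * g2 + t3[:, None] * g3)
    g0 = -((1.0 - t2)[:, None] * g2 + (1.0 - t3)[:, None] * g3)
    w = (2.0 * params.k_b * dtheta)[:, None]
    n = len(state.X)
    F = -(
        _scatter_add(n, hg[:, 0], w * g0)
        + _scatter_add(n, hg[:, 1], w * g1)
        + _scatter_add(n, hg[:, 2], w * g2)
        + _scatter_add(n, hg[:, 3], w * g3)
    )
    return E, F


def bend_energy(state: ShellState, params: ShellParams) -> float:
    """Hinge energy ``sum k_b (theta - theta0)^2`` over active hinges."""
    return _bend(state, params, False)[0]


def bend_forces(state: ShellState, params: ShellParams) -> np.ndarray:
    return _bend(state, params, True)[1]


# -- area -------------------------------------------------------------------


def _area(state: ShellState, params: ShellParams, want_forces: bool):
    m = state.mesh
    act = state.active_faces
    faces = m.faces[act]
    if len(faces) == 0:
        return 0.0, (np.zeros_like(state.X) if want_forces else None)
    a, b, c = state.X[faces[:, 0]], state.X[faces[:, 1]], state.X[faces[:, 2]]
    nvec = np.cross(b - a, c - a)
    nn = np.linalg.norm(nvec, axis=1)
    if np.any(nn <= 0):
        raise FloatingPointError("degenerate face")
    A = 0.5 * nn
    A0 = state.A0[act]
    rel = A / A0 - 1.0
    E = 0.5 * params.k_v * np.sum(A0 * rel**2)
    if not want_forces:
        return E, None
    nhat = nvec / nn[:, None]
    w = (params.k_v * rel)[:, None]
    ga = 0.5 * np.cross(nhat, c - b)
    gb = 0.5 * np.cross(nhat, a - c)
    gc = 0.5 * np.cross(nhat, b - a)
    n = len(state.X)
    F = -(
        _scatter_add(n, faces[:, 0], w * ga)
        + _scatter_add(n, faces[:, 1], w * gb)
        + _scatter_add(n, faces[:, 2], w * gc)
    )
    return E, F


def area_energy(state: ShellState, params: ShellParams) -> float:
    """Area-preservation energy ``sum (k_v/2) A0 (A/A0 - 1)^2`` over active faces."""
    return _area(state, params, False)[0]


def area_forces(state: ShellState, params: ShellParams) -> np.ndarray:
    return _area(state, params, True)[1]


# -- substrate tether -------------------------------------------------------


def _substrate(state: ShellState, params: ShellParams, want_forces: bool):
    target = state.foot + state.h * state.foot_normal
    d = state.X - target
    E = 0.5 * params.k_sub * np.sum(d * d)
    if not want_forces:
        return E, None
    return E, -params.k_sub * d


def substrate_energy(state: ShellState, substrate: Substrate | None, params: ShellParams) -> float:
    """Tether to the offset surface: ``sum (k_sub/2) |x - (p + h n)|^2``.

    Foot points and normals were frozen at initialisation, so the substrate
    argument is accepted for interface symmetry only.
    """
    return _substrate(state, params, False)[0]


def substrate_forces(state: ShellState, substrate: Substrate | None, params: ShellParams) -> np.ndarray:
    return _substrate(state, params, True)[1]


# -- substrate penetration penalty -----------------------------------------


def _penetration(state: ShellState, substrate: Substrate | None, params: ShellParams, want_forces: bool):
    if substrate is None or params.k_pen == 0:
        return 0.0, (np.zeros_like(state.X) if want_forces else None)
    xy = state.X[:, :2]
    s = substrate.height(xy)
    depth = s - state.X[:, 2]
    pen = depth > 0
    E = 0.5 * params.k_pen * float(np.sum(depth[pen] ** 2))
    if not want_forces:
        return E, None
    F = np.zeros_like(state.X)
    if np.any(pen):
        g = substrate.gradient(xy[pen])
        w = params.k_pen * depth[pen]
        F[pen, 0] = -w * g[:, 0]
        F[pen, 1] = -w * g[:, 1]
        F[pen, 2] = w
    return E, F


def penetration_energy(state: ShellState, substrate: Substrate | None, params: ShellParams) -> float:
    """One-sided penalty keeping the sheet above the solid dermis surface.

    ``E = sum (k_pen/2) max(0, S(x, y) - z)^2`` over nodes: the dermis is
    impenetrable from above but does not hold the sheet down, so troughs can
    lift off (desiccation relief) while papilla caps cannot be sunk into.
    """
    return _penetration(state, substrate, params, False)[0]


def penetration_forces(state: ShellState, substrate: Substrate | None, params: ShellParams) -> np.ndarray:
    return _penetration(state, substrate, params, True)[1]


# -- self-contact -----------------------------------------------------------


def _vertex_rings(mesh: TriMesh) -> list[set]:
    ring: list[set] = [set() for _ in range(mesh.n_vertices)]
    for a, b in mesh.edges:
        ring[a].add(int(b))
        ring[b].add(int(a))
    return ring


def contact_pairs(state: ShellState, params: ShellParams, margin: float = 0.0) -> np.ndarray:
    """Candidate (node, face) pairs with distance possibly below ``contact_range``.

    Excludes pairs where the node is a vertex of the face or is joined to a
    face vertex by a mesh edge (its 1-ring), which would otherwise generate
    spurious self-forces at rest.  ``margin`` widens the search so the pair
    list can be reused over several integration steps.
    """
    from scipy.spatial import cKDTree

    m = state.mesh
    act = np.flatnonzero(state.active_faces)
    if len(act) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    faces = m.faces[act]
    tri = state.X[faces]  # (F, 3, 3)
    cent = tri.mean(axis=1)
    rad = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(state.X)
    reach = rad + params.contact_range + margin
    ring = _vertex_rings(m)
    pairs: list[tuple[int, int]] = []
    hits = tree.query_ball_point(cent, reach)
    for k, nodes in enumerate(hits):
        f = act[k]
        fv = faces[k]
        excl = ring[fv[0]] | ring[fv[1]] | ring[fv[2]] | {int(fv[0]), int(fv[1]), int(fv[2])}
        pairs.extend((node, f) for node in nodes if node not in excl)
    if not pairs:
        return np.zeros((0, 2), dtype=np.int64)
    return np.array(pairs, dtype=np.int64)


def _point_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Vectorised closest point on triangle (a, b, c) to p; returns (closest, bary)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    n = len(p)
    u = np.zeros(n)
    v = np.zeros(n)
    done = np.zeros(n, dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    done |= m

    m = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    u[m] = 1.0
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    denom = np.where(d1 - d3 != 0, d1 - d3, 1.0)
    u[m] = (d1 / denom)[m]
    done |= m

    m = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    v[m] = 1.0
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    denom = np.where(d2 - d6 != 0, d2 - d6, 1.0)
    v[m] = (d2 / denom)[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) + (d5 - d6), 1.0)
    w_ = ((d4 - d3) / denom)
    u[m] = (1.0 - w_)[m]
    v[m] = w_[m]
    done |= m

    m = ~done  # interior
    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    u[m] = (vb / denom)[m]
    v[m] = (vc / denom)[m]

    closest = a + u[:, None] * ab + v[:, None] * ac
    bary = np.column_stack([1.0 - u - v, u, v])
    return closest, bary


def _contact(state: ShellState, params: ShellParams, want_forces: bool, pairs: np.ndarray | None = None):
    if params.k_c == 0:
        return 0.0, (np.zeros_like(state.X) if want_forces else None)
    if pairs is None:
        pairs = contact_pairs(state, params)
    if len(pairs) == 0:
        return 0.0, (np.zeros_like(state.X) if want_forces else None)
    m = state.mesh
    nodes = pairs[:, 0]
    faces = m.faces[pairs[:, 1]]
    p = state.X[nodes]
    a, b, c = state.X[faces[:, 0]], state.X[faces[:, 1]], state.X[faces[:, 2]]
    closest, bary = _point_triangle(p, a, b, c)
    dvec = p - closest
    d = np.linalg.norm(dvec, axis=1)
    pen = params.contact_range - d
    hit = (pen > 0) & (d > 1e-12)
    E = 0.5 * params.k_c * np.sum(pen[hit] ** 2)
    if not want_forces:
        return E, None
    n = len(state.X)
    F = np.zeros((n, 3))
    if np.any(hit):
        g = (params.k_c * pen[hit] / d[hit])[:, None] * dvec[hit]  # force on the node
        F += _scatter_add(n, nodes[hit], g)
        for k in range(3):
            F -= _scatter_add(n, faces[hit, k], bary[hit, k][:, None] * g)
    return E, F


def contact_energy(state: ShellState, params: ShellParams, pairs: np.ndarray | None = None) -> float:
    """Node-face penalty ``(k_c/2)(d_c - d)^2`` for non-incident pairs closer than d_c."""
    return _contact(state, params, False, pairs)[0]


def contact_forces(state: ShellState, params: ShellParams, pairs: np.ndarray | None = None) -> np.ndarray:
    return _contact(state, params, True, pairs)[1]


# -- totals -----------------------------------------------------------------


def total_energy(
    state: ShellState,
    substrate: Substrate | None,
    params: ShellParams,
    pairs: np.ndarray | None = None,
) -> dict[str, float]:
    """All energy terms plus their sum, keyed by name."""
    terms = {
        "stretch": stretch_energy(state, params),
        "bend": bend_energy(state, params),
        "area": area_energy(state, params),
        "substrate": substrate_energy(state, substrate, params),
        "penetration": penetration_energy(state, substrate, params),
        "contact": contact_energy(state, params, pairs),
    }
    terms["total"] = sum(terms.values())
    return terms


def total_forces(
    state: ShellState,
    substrate: Substrate | None,
    params: ShellParams,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    F = _stretch(state, params, True)[1]
    F += _bend(state, params, True)[1]
    F += _area(state, params, True)[1]
    F += _substrate(state, params, True)[1]
    if substrate is not None and params.k_pen > 0:
        F += _penetration(state, substrate, params, True)[1]
    if params.k_c > 0:
        F += _contact(state, params, True, pairs)[1]
    if state.fixed is not None:
        F[state.fixed] = 0.0
    return F


# -- fracture strain --------------------------------------------------------


def effective_edge_strain(
    state: ShellState, params: ShellParams, edges: np.ndarray | None = None
) -> np.ndarray:
    """Fracture strain per edge: membrane strain plus a bending contribution.

    The edge curvature is ``kappa = 2 theta / (h1 + h2)`` (``h_i`` the
    heights of the two incident triangles over the shared edge; ``kappa``
    is negative in a valley for an upward-oriented mesh).  The criterion
    (``params.strain_criterion``) selects which fibre of a sheet of
    thickness ``t_s`` must fail in tension:

    ``inner-fibre`` (default)
        ``eps_membrane - (t_s/2) (kappa - kappa0)`` — the tensile strain of
        the substrate-facing fibre.  Deepening a valley or flattening a
        papilla cap loads it; flattening a valley protects it.  This is the
        criterion that lets growth-induced bending break trough bonds while
        desiccation cracks avoid the troughs.
    ``outer-fibre``
        ``eps_membrane + (t_s/2) |kappa - kappa0|`` — the worst fibre on
        either side (sign-blind).
    ``membrane``
        spring elongation only.

    Boundary edges carry the membrane term only; broken edges are NaN.
    """
    m = state.mesh
    X = state.X
    ea, eb = m.edges[:, 0], m.edges[:, 1]
    L = np.linalg.norm(X[eb] - X[ea], axis=1)
    eps = (L - state.l0) / state.l0
    out = eps.copy()
    if params.strain_criterion != "membrane" and len(m.hinges):
        act = state.active_hinges
        hg = m.hinges[act]
        he = m.hinge_edge[act]
        theta = hinge_angles(X, hg)
        # current hinge heights from current face areas
        f1 = m.edge_faces[he, 0]
        f2 = m.edge_faces[he, 1]
        nvec = _triangle_normals(X, m.faces)
        A = 0.5 * np.linalg.norm(nvec, axis=1)
        hh = 2.0 * (A[f1] + A[f2]) / np.maximum(L[he], 1e-300)
        kappa = 2.0 * theta / np.maximum(hh, 1e-300)
        kappa0 = 2.0 * state.theta0[act] / np.maximum(state.hinge_h0[act], 1e-300)
        if params.strain_criterion == "inner-fibre":
            out[he] = eps[he] - 0.5 * params.t_s * (kappa - kappa0)
        else:
            out[he] = eps[he] + 0.5 * params.t_s * np.abs(kappa - kappa0)
    out[state.broken] = np.nan
    if edges is not None:
        out = out[edges]
    return out
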