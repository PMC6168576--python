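"""Quasi-static loading, damped relaxation and the bond-breaking loop.

Loading is applied in small increments (growth offset ``h`` or uniform
rest-metric shrinkage ``s``); after each increment the shell is relaxed to
a force balance by damped Newtonian dynamics, and edges whose fibre
strain exceeds the critical strain are broken one at a time — re-relaxing
after every break so that stress redistribution, not inertia, drives crack
propagation.  The loop stops at a target broken-edge fraction or at the
maximum load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh import TriMesh
from .substrate import Substrate
from . import shell as _shell
from .shell import ShellParams, ShellState, init_shell

__all__ = [
    "SimConfig",
    "RelaxInfo",
    "FractureEvent",
    "SimResult",
    "RelaxationError",
    "relax",
    "break_bonds",
    "run_growth",
    "run_shrinkage",
    "strain_field",
    "virtual_section",
    "save_snapshot",
]


class RelaxationError(RuntimeError):
    """Raised when damped dynamics fails to reach the force tolerance."""


@dataclass
class SimConfig:
    """Protocol and integrator settings.

    The defaults implement the standard operating point: load until ~3% of
    the mesh edges are broken or the growth offset reaches ``h_max``
    (typically one sixth of the papilla spacing).  ``dt=None`` auto-caps the
    time step at half the stability bound of the stiffest term.  Inner
    tolerances are used for the short re-relaxations inside the breaking
    loop; the looser value is adequate because each break perturbs the
    state only locally.
    """

    protocol: str = "growth"  # or "shrinkage"
    dh: float | None = None  # growth increment; default h_max / 8
    ds: float = 0.02  # shrink increment per step
    h_max: float | None = None  # default: spacing / 6, resolved by the caller
    s_max: float = 0.45
    break_target: float = 0.03  # stop at this broken-edge fraction
    dt: float | None = None
    tol_f: float = 0.02  # convergence: max nodal force (~7% of a break-level edge tension)
    tol_v: float = 5e-3  # convergence: max nodal speed; must exceed tol_f/damping,
    # the overdamped terminal speed at the force tolerance
    inner_tol_f: float = 0.03
    inner_tol_v: float = 8e-3
    max_iter: int = 60000
    inner_max_iter: int = 15000
    max_breaks: int = 100000
    contact_refresh: int = 25  # steps between contact pair-list rebuilds
    snapshot_every: int = 1  # protocol steps between stored snapshots
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("growth", "shrinkage"):
            raise ValueError("protocol must be 'growth' or 'shrinkage'")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if not 0 < self.ds < 1:
            raise ValueError("ds must be in (0, 1)")
        if not 0 < self.break_target < 1:
            raise ValueError("break_target must be in (0, 1)")
        if self.tol_f <= 0 or self.tol_v <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class RelaxInfo:
    iterations: int
    max_force: float
    max_speed: float
    converged: bool
    energy_start: float
    energy_end: float


@dataclass
class FractureEvent:
    step: int  # protocol step index at which the break occurred
    edge: int
    strain: float
    h: float
    s: float


@dataclass
class SimResult:
    """Snapshots, fracture events and per-step summary of one protocol run."""

    states: list[ShellState] = field(default_factory=list)
    events: list[FractureEvent] = field(default_factory=list)
    summary: list[dict] = field(default_factory=list)

    @property
    def final_state(self) -> ShellState:
        return self.states[-1]

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.step, e.edge, e.strain, e.h, e.s) for e in self.events],
            columns=["step", "edge", "strain", "h", "s"],
        )

    def summary_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.summary)


def _stable_dt(state: ShellState, params: ShellParams) -> float:
    """Half the explicit stability bound for the stiffest single-node term."""
    l0min = float(state.l0.min())
    # the bending coefficient is deliberately conservative: strongly folded
    # hinges (open crack flaps) stiffen far beyond the flat-state estimate
    k_eff = (
        8.0 * params.k_s / l0min
        + 600.0 * params.k_b / l0min**2
        + 3.0 * params.k_v
        + params.k_sub
        + params.k_pen
        + params.k_c
    )
    return 0.5 * np.sqrt(params.mass / k_eff)


def relax(
    state: ShellState,
    substrate: Substrate | None,
    params: ShellParams,
    config: SimConfig,
    tol_f: float | None = None,
    tol_v: float | None = None,
    max_iter: int | None = None,
) -> RelaxInfo:
    """Integrate damped Newtonian dynamics to a force balance, in place.

    Semi-implicit Euler on ``m a = F - gamma v`` until both the largest
    nodal force and the largest nodal speed fall below tolerance.  Raises
    :class:`RelaxationError` with the worst-residual node if the iteration
    budget is exhausted.
    """
    tf = config.tol_f if tol_f is None else tol_f
    tv = config.tol_v if tol_v is None else tol_v
    iters = config.max_iter if max_iter is None else max_iter
    dt = config.dt or _stable_dt(state, params)
    m = params.mass
    gam = params.damping
    damp = max(0.0, 1.0 - dt * gam / m)

    use_contact = params.k_c > 0
    pairs = None
    e0 = _shell.total_energy(state, substrate, params)["total"]
    Fmax = vmax = np.inf
    it = 0
    while it < iters:
        if use_contact and it % config.contact_refresh == 0:
            margin = 2.0 * config.contact_refresh * dt * max(
                float(np.abs(state.V).max()), tv
            )
            pairs = _shell.contact_pairs(state, params, margin=margin)
        F = _shell.total_forces(state, substrate, params, pairs)
        state.V = state.V * damp + (dt / m) * F
        if state.fixed is not None:
            state.V[state.fixed] = 0.0
        state.X = state.X + dt * state.V
        it += 1
        if it % 20 == 0 or it == iters:
            Fmax = float(np.abs(F).max())
            vmax = float(np.abs(state.V).max())
            if Fmax < tf and vmax < tv:
                break
    e1 = _shell.total_energy(state, substrate, params)["total"]
    converged = Fmax < tf and vmax < tv
    if not converged:
        worst = int(np.argmax(np.linalg.norm(F, axis=1)))
        raise RelaxationError(
            f"no convergence in {iters} iterations: max force {Fmax:.3g} at node "
            f"{worst} {state.X[worst]}, max speed {vmax:.3g}"
        )
    state.V[:] = 0.0
    return RelaxInfo(it, Fmax, vmax, converged, e0, e1)


def break_bonds(
    state: ShellState,
    substrate: Substrate | None,
    params: ShellParams,
    config: SimConfig,
    step: int = 0,
    stop_fraction: float | None = None,
) -> list[FractureEvent]:
    """Break over-strained edges one at a time, re-relaxing after each.

    Repeatedly computes the effective strain of all unbroken edges; while
    the maximum exceeds ``eps_c``, exactly the single highest-strain edge is
    broken (ties resolved to the lowest edge id), its hinge and faces drop
    out of the energy via the activity masks, and the shell is re-relaxed at
    the inner tolerance.  Stops early if the broken fraction reaches
    ``stop_fraction``.
    """
    events: list[FractureEvent] = []
    ne = state.mesh.n_edges
    while len(events) < config.max_breaks:
        eps = _shell.effective_edge_strain(state, params)
        with np.errstate(invalid="ignore"):
            top = np.nanmax(eps) if not np.all(np.isnan(eps)) else -np.inf
        if not top > params.eps_c:
            break
        edge = int(np.flatnonzero(eps == top)[0])  # lowest id on exact ties
        state.break_edge(edge)
        events.append(FractureEvent(step, edge, float(top), state.h, state.s))
        relax(
            state,
            substrate,
            params,
            config,
            tol_f=config.inner_tol_f,
            tol_v=config.inner_tol_v,
            max_iter=config.inner_max_iter,
        )
        if stop_fraction is not None and state.broken.sum() >= stop_fraction * ne:
            break
    return events


def _run(
    substrate: Substrate | None,
    mesh: TriMesh,
    params: ShellParams,
    config: SimConfig,
) -> SimResult:
    state = init_shell(mesh, substrate)
    result = SimResult()
    relax(state, substrate, params, config)  # exact no-op at rest, cheap
    step = 0
    growth = config.protocol == "growth"
    if growth:
        if config.h_max is None:
            raise ValueError("h_max must be set for the growth protocol")
        dh = config.dh if config.dh is not None else config.h_max / 8.0
    ne = mesh.n_edges
    target = config.break_target

    def record(info: RelaxInfo) -> None:
        en = _shell.total_energy(state, substrate, params)
        row = {
            "step": step,
            "h": state.h,
            "s": state.s,
            "broken_fraction": state.broken_fraction,
            "relax_iterations": info.iterations,
        }
        row.update({f"E_{k}": v for k, v in en.items()})
        result.summary.append(row)
        if step % config.snapshot_every == 0:
            result.states.append(state.copy())

    while state.broken.sum() < target * ne:
        if growth:
            if state.h >= config.h_max - 1e-12:
                break
            state.h = min(state.h + dh, config.h_max)
        else:
            if state.s >= config.s_max - 1e-12:
                break
            ds = min(config.ds, 1.0 - (1.0 - state.s) / (1.0 - config.s_max))
            state.apply_shrink(ds if ds > 0 else config.ds)
        step += 1
        info = relax(state, substrate, params, config)
        ev = break_bonds(
            state, substrate, params, config, step=step, stop_fraction=target
        )
        result.events.extend(ev)
        record(info)
    if not result.states or result.states[-1] is not state:
        result.states.append(state.copy())
    return result


def run_growth(
    substrate: Substrate | None,
    mesh: TriMesh,
    params: ShellParams,
    config: SimConfig,
) -> SimResult:
    """Quasi-static growth: raise the tether offset ``h`` step by step.

    Models the addition of keratinous sheets from below, which pushes the
    curved outer sheet outwards and concentrates bending strain in the
    substrate troughs.
    """
    if config.protocol != "growth":
        config = replace(config, protocol="growth")
    return _run(substrate, mesh, params, config)


def run_shrinkage(
    substrate: Substrate | None,
    mesh: TriMesh,
    params: ShellParams,
    config: SimConfig,
) -> SimResult:
    """Quasi-static desiccation: shrink the in-plane rest metric uniformly.

    The tether offset stays fixed; frustration against the substrate tether
    produces the classic mud-crack loading instead of trough bending.
    """
    if config.protocol != "shrinkage":
        config = replace(config, protocol="shrinkage")
    return _run(substrate, mesh, params, config)


# -- strain field -----------------------------------------------------------


def strain_field(state: ShellState, params: ShellParams) -> dict[str, np.ndarray]:
    """Per-edge effective strain and per-face membrane Green strain.

    Each face's in-plane deformation gradient is computed from its rest
    shape (reconstructed from rest edge lengths) to its current shape; the
    Green strain ``E = (F^T F - I)/2`` is eigen-decomposed into principal
    strains and principal directions (expressed as 3D vectors in the current
    face plane).  Faces with a broken edge are masked NaN.
    """
    m = state.mesh
    X = state.X
    fe = m.face_edges
    f = m.faces
    # rest edge lengths in face order: (v0-v1, v1-v2, v2-v0)
    l01 = state.l0[fe[:, 0]]
    l12 = state.l0[fe[:, 1]]
    l20 = state.l0[fe[:, 2]]
    x2 = (l01**2 + l20**2 - l12**2) / (2.0 * l01)
    y2sq = np.maximum(l20**2 - x2**2, 1e-300)
    y2 = np.sqrt(y2sq)
    # rest shape matrix D = [[l01, x2], [0, y2]]; inverse analytic
    invD00 = 1.0 / l01
    invD01 = -x2 / (l01 * y2)
    invD11 = 1.0 / y2

    a, b, c = X[f[:, 0]], X[f[:, 1]], X[f[:, 2]]
    u = b - a
    v = c - a
    lu = np.linalg.norm(u, axis=1)
    e1 = u / np.maximum(lu[:, None], 1e-300)
    vperp = v - np.einsum("ij,ij->i", v, e1)[:, None] * e1
    lv = np.linalg.norm(vperp, axis=1)
    e2 = vperp / np.maximum(lv[:, None], 1e-300)
    # current shape matrix in the (e1, e2) frame
    c00 = lu
    c01 = np.einsum("ij,ij->i", v, e1)
    c11 = lv
    # F = Dc @ inv(D)
    F00 = c00 * invD00
    F01 = c00 * invD01 + c01 * invD11
    F10 = np.zeros_like(F00)
    F11 = c11 * invD11
    # Green strain E = (F^T F - I) / 2
    E00 = 0.5 * (F00**2 + F10**2 - 1.0)
    E01 = 0.5 * (F00 * F01 + F10 * F11)
    E11 = 0.5 * (F01**2 + F11**2 - 1.0)

    tr = E00 + E11
    det = E00 * E11 - E01**2
    disc = np.sqrt(np.maximum((0.5 * (E00 - E11)) ** 2 + E01**2, 0.0))
    lam1 = 0.5 * tr + disc
    lam2 = 0.5 * tr - disc
    # principal direction of lam1 in the local frame
    ang = 0.5 * np.arctan2(2.0 * E01, E00 - E11)
    cos_a = np.cos(ang)
    sin_a = np.sin(ang)
    dir1 = cos_a[:, None] * e1 + sin_a[:, None] * e2
    dir2 = -sin_a[:, None] * e1 + cos_a[:, None] * e2

    inactive = ~state.active_faces
    tensor = np.empty((len(f), 2, 2))
    tensor[:, 0, 0] = E00
    tensor[:, 0, 1] = tensor[:, 1, 0] = E01
    tensor[:, 1, 1] = E11
    tensor[inactive] = np.nan
    lam1 = np.where(inactive, np.nan, lam1)
    lam2 = np.where(inactive, np.nan, lam2)
    dir1[inactive] = np.nan
    dir2[inactive] = np.nan

    return {
        "edge_strain": _shell.effective_edge_strain(state, params),
        "green": tensor,
        "principal_strains": np.column_stack([lam1, lam2]),
        "principal_dir1": dir1,
        "principal_dir2": dir2,
    }


# -- virtual cross-sections -------------------------------------------------


def virtual_section(
    result: SimResult,
    substrate: Substrate | None,
    cut_line: tuple[tuple[float, float], tuple[float, float]],
    n_sheets: int = 5,
    n_samples: int = 400,
    uncracked_fraction: float = 0.5,
) -> dict:
    """Stacked 2D sheet profiles along a planar cut through the final state.

    Emits the substrate profile, the deformed shell profile and
    ``n_sheets - 1`` intermediate sheets interpolated between them, sampled
    at ``n_samples`` points along the cut.  Where the cut crosses a broken
    (cracked) shell edge, sheets above ``uncracked_fraction`` of the stack
    are interrupted by a gap of one local edge length (NaN samples); the
    innermost sheets are drawn continuous, mirroring the intact deep
    stratum corneum.
    """
    from scipy.interpolate import LinearNDInterpolator

    state = result.final_state
    (x0, y0), (x1, y1) = cut_line
    p0 = np.array([x0, y0])
    p1 = np.array([x1, y1])
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("cut_line endpoints coincide")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    svals = t * length

    xy = state.X[:, :2]
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    inside = np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)
    if not inside.any():
        warnings.warn("cut line misses the mesh; empty section")
        return {"s": svals, "substrate": np.full(n_samples, np.nan), "sheets": [], "gaps": []}

    interp = LinearNDInterpolator(xy, state.X[:, 2])
    z_shell = interp(pts)
    if substrate is not None:
        z_sub = substrate.height(pts)
    else:
        z_sub = np.zeros(n_samples)

    # crack gaps: broken edges whose (projected) segment crosses the cut
    gaps: list[tuple[float, float]] = []
    broken = np.flatnonzero(state.broken)
    if len(broken):
        ea = xy[state.mesh.edges[broken, 0]]
        eb = xy[state.mesh.edges[broken, 1]]
        d = p1 - p0
        for k in range(len(broken)):
            a, bb = ea[k], eb[k]
            r = bb - a
            den = d[0] * r[1] - d[1] * r[0]
            if abs(den) < 1e-14:
                continue
            qp = a - p0
            tt = (qp[0] * r[1] - qp[1] * r[0]) / den
            uu = (qp[0] * d[1] - qp[1] * d[0]) / den
            if 0 <= tt <= 1 and 0 <= uu <= 1:
                w = float(np.linalg.norm(r))  # gap of order the mesh spacing
                center = tt * length
                gaps.append((center - w / 2, center + w / 2))

    sheets = []
    for k in range(n_sheets):
        frac = k / max(n_sheets - 1, 1)
        z = z_sub + frac * (z_shell - z_sub)
        if frac > uncracked_fraction:
            z = z.copy()
            for g0, g1 in gaps:
                z[(svals >= g0) & (svals <= g1)] = np.nan
        sheets.append(z)
    return {"s": svals, "substrate": z_sub, "sheets": sheets, "gaps": gaps}


# -- snapshot export --------------------------------------------------------


def save_snapshot(
    state: ShellState, params: ShellParams, basename: str
) -> list[str]:
    """Export a state for visualisation: PLY geometry, VTK lines, edge CSV.

    Writes ``<basename>.ply`` (the deformed triangulated shell),
    ``<basename>.vtk`` (legacy ASCII polydata of the mesh edges with the
    effective strain and broken flag as cell data) and
    ``<basename>-edges.csv`` (edge id, endpoints, strain, broken).
    """
    import trimesh as _trimesh

    m = state.mesh
    paths = []
    tm = _trimesh.Trimesh(state.X.copy(), m.faces.copy(), process=False)
    ply_path = f"{basename}.ply"
    with open(ply_path, "wb") as fh:
        fh.write(tm.export(file_type="ply", encoding="ascii"))
    paths.append(ply_path)

    eps = effective_edge_strain_safe(state, params)
    vtk_path = f"{basename}.vtk"
    with open(vtk_path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nshell edges\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(state.X)} float\n")
        for p in state.X:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"LINES {m.n_edges} {3 * m.n_edges}\n")
        for a, b in m.edges:
            fh.write(f"2 {a} {b}\n")
        fh.write(f"CELL_DATA {m.n_edges}\nSCALARS strain float 1\nLOOKUP_TABLE default\n")
        for v in np.nan_to_num(eps):
            fh.write(f"{v:.6g}\n")
        fh.write("SCALARS broken int 1\nLOOKUP_TABLE default\n")
        for b in state.broken:
            fh.write(f"{int(b)}\n")
    paths.append(vtk_path)

    csv_path = f"{basename}-edges.csv"
    pd.DataFrame(
        {
            "edge": np.arange(m.n_edges),
            "v0": m.edges[:, 0],
            "v1": m.edges[:, 1],
            "strain": eps,
            "broken": state.broken.astype(int),
        }
    ).to_csv(csv_path, index=False)
    paths.append(csv_path)
    return paths


def effective_edge_strain_safe(state: ShellState, params: ShellParams) -> np.ndarray:
    """Effective strain with degenerate geometry mapped to NaN instead of raising."""
    try:
        return _shell.effective_edge_strain(state, params)
    except FloatingPointError:
        return np.full(state.mesh.n_edges, np.nan)
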