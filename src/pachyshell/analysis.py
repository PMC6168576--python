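"""Derived metrics: crack localisation, orientation and protocol comparison.

These are the quantities used to contrast the growth and shrinkage
hypotheses on one substrate: the fraction of broken edges confined to the
trough mask, the angles between cracks and the local trough (valley-line)
direction, and the junction statistics of crack versus trough networks.
"""

from __future__ import annotations

import numpy as np

from .substrate import Substrate, label_troughs, trough_directions
from .shell import ShellParams, ShellState
from .simulate import SimConfig, SimResult, run_growth, run_shrinkage
from . import crackstats as cs

__all__ = [
    "broken_edge_metrics",
    "crack_segment_angles",
    "compare_protocols",
    "mature_crack_network",
    "validate_compare_report",
]

#: required structure of a comparison report: block -> required numeric keys
_REPORT_SCHEMA = {
    "growth": (
        "n_broken",
        "broken_fraction",
        "trough_fraction",
        "mean_angle_to_trough_deg",
        "mean_segment_angle_to_trough_deg",
        "final_h",
    ),
    "shrinkage": (
        "n_broken",
        "broken_fraction",
        "trough_fraction",
        "mean_angle_to_trough_deg",
        "mean_segment_angle_to_trough_deg",
        "final_s",
    ),
    "contrast": ("trough_fraction_difference", "segment_angle_difference_deg"),
}


def validate_compare_report(report: dict) -> None:
    """Structural validation of a protocol-comparison report.

    Raises ``ValueError`` naming the first missing block or key, or a value
    that is not a real number; the ``junctions`` block must be present and
    each non-null entry must carry the junction summary keys.
    """
    for block, keys in _REPORT_SCHEMA.items():
        if block not in report:
            raise ValueError(f"report missing block {block!r}")
        for key in keys:
            if key not in report[block]:
                raise ValueError(f"report block {block!r} missing key {key!r}")
            v = report[block][key]
            if not isinstance(v, (int, float, np.integer, np.floating)):
                raise ValueError(f"report[{block!r}][{key!r}] is not numeric")
    if "junctions" not in report:
        raise ValueError("report missing block 'junctions'")
    for name, entry in report["junctions"].items():
        if entry is None:
            continue
        for key in ("n", "mean_theta1", "mean_theta2", "sigma_theta_deg"):
            if key not in entry:
                raise ValueError(f"junction entry {name!r} missing key {key!r}")


def _acute_angles_deg(vectors: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Acute angle (deg) between unit 2D vectors and reference directions (mod 180)."""
    dots = np.abs(np.einsum("ij,ij->i", vectors, references))
    return np.degrees(np.arccos(np.clip(dots, 0.0, 1.0)))


def broken_edge_metrics(
    state: ShellState,
    substrate: Substrate,
    tau: float = 0.4,
    direction_step: float | None = None,
) -> dict:
    """Localisation and orientation of the broken edges of a fractured shell.

    An edge counts as "in the trough" when the substrate height at the
    midpoint of its rest position is below ``tau`` times the papilla
    amplitude.  Orientation is the acute angle between the (projected) edge
    direction and the local trough direction at the edge midpoint; edges at
    umbilic points (no defined trough direction) are excluded from the
    angle average but not from the localisation fraction.
    """
    mesh = state.mesh
    br = np.flatnonzero(state.broken)
    out = {
        "n_broken": int(len(br)),
        "broken_fraction": state.broken_fraction,
        "trough_fraction": np.nan,
        "non_trough_fraction": np.nan,
        "mean_angle_to_trough_deg": np.nan,
        "angles_deg": np.zeros(0),
        "n_oriented": 0,
    }
    if len(br) == 0:
        return out
    mid = 0.5 * (state.foot[mesh.edges[br, 0]] + state.foot[mesh.edges[br, 1]])
    z = substrate.height(mid[:, :2])
    in_trough = z < tau * substrate.amplitude if substrate.amplitude > 0 else np.zeros(len(br), bool)
    ev = state.foot[mesh.edges[br, 1], :2] - state.foot[mesh.edges[br, 0], :2]
    ev = ev / np.linalg.norm(ev, axis=1, keepdims=True)
    dirs, ok = trough_directions(substrate, mid[:, :2], step=direction_step)
    ang = _acute_angles_deg(ev[ok], dirs[ok])
    out.update(
        trough_fraction=float(in_trough.mean()),
        non_trough_fraction=float(1.0 - in_trough.mean()),
        mean_angle_to_trough_deg=float(ang.mean()) if len(ang) else np.nan,
        angles_deg=ang,
        n_oriented=int(ok.sum()),
    )
    return out


def crack_segment_angles(
    network: cs.PlanarNetwork,
    substrate: Substrate,
    direction_step: float | None = None,
) -> np.ndarray:
    """Acute angles (deg) between crack-chain segments and the local trough direction."""
    if len(network.segments) == 0:
        return np.zeros(0)
    a = network.nodes[network.segments[:, 0]]
    b = network.nodes[network.segments[:, 1]]
    v = b - a
    n = np.linalg.norm(v, axis=1)
    keep = n > 1e-12
    v = v[keep] / n[keep, None]
    mids = 0.5 * (a + b)[keep]
    dirs, ok = trough_directions(substrate, mids, step=direction_step)
    return _acute_angles_deg(v[ok], dirs[ok])


def compare_protocols(
    substrate: Substrate,
    mesh,
    params: ShellParams,
    growth_config: SimConfig,
    shrink_config: SimConfig,
    tau: float = 0.4,
    branch_arc_length: float | None = None,
    trough_branch_arc_length: float | None = None,
    interior_margin: float | None = None,
    return_results: bool = False,
) -> dict:
    """Run growth and shrinkage on the same substrate and contrast them.

    Returns a nested dict: per-protocol localisation/orientation metrics,
    junction statistics for growth cracks and trough lines, and the headline
    contrast numbers (localisation difference, orientation difference,
    sigma_theta ordering, distance of mean scatter points to (120, 120)).
    """
    mean_edge = float(np.mean(mesh.edge_lengths()))
    if branch_arc_length is None:
        branch_arc_length = 2.0 * mean_edge
    if trough_branch_arc_length is None:
        d = _spacing_estimate(substrate)
        trough_branch_arc_length = 0.2 * d

    res_g = run_growth(substrate, mesh, params, growth_config)
    res_s = run_shrinkage(substrate, mesh, params, shrink_config)

    mg = broken_edge_metrics(res_g.final_state, substrate, tau)
    ms = broken_edge_metrics(res_s.final_state, substrate, tau)
    net_g = cs.project_crack_network(res_g, substrate)
    net_s = cs.project_crack_network(res_s, substrate)
    seg_g = crack_segment_angles(net_g, substrate)
    seg_s = crack_segment_angles(net_s, substrate)

    report: dict = {
        "growth": {
            **{k: v for k, v in mg.items() if not isinstance(v, np.ndarray)},
            "mean_segment_angle_to_trough_deg": float(seg_g.mean()) if len(seg_g) else np.nan,
            "final_h": res_g.final_state.h,
        },
        "shrinkage": {
            **{k: v for k, v in ms.items() if not isinstance(v, np.ndarray)},
            "mean_segment_angle_to_trough_deg": float(seg_s.mean()) if len(seg_s) else np.nan,
            "final_s": res_s.final_state.s,
        },
    }
    report["contrast"] = {
        "trough_fraction_difference": report["growth"]["trough_fraction"]
        - report["shrinkage"]["trough_fraction"],
        "segment_angle_difference_deg": report["shrinkage"]["mean_segment_angle_to_trough_deg"]
        - report["growth"]["mean_segment_angle_to_trough_deg"],
    }

    # junction statistics: growth cracks vs trough lines
    dom = substrate.domain_size
    stats = {}
    try:
        stats["growth_cracks"] = cs.compute_junction_stats(
            net_g, branch_arc_length, interior_margin=interior_margin, domain_size=dom
        )
    except ValueError:
        stats["growth_cracks"] = None
    trough_net = cs.generate_trough_network(substrate)
    try:
        stats["trough_lines"] = cs.compute_junction_stats(
            trough_net, trough_branch_arc_length, interior_margin=interior_margin, domain_size=dom
        )
    except ValueError:
        stats["trough_lines"] = None
    report["junctions"] = {}
    for key, st in stats.items():
        if st is None:
            report["junctions"][key] = None
            continue
        report["junctions"][key] = {
            "n": int(len(st.points)),
            "mean_theta1": float(st.mean[0]),
            "mean_theta2": float(st.mean[1]),
            "sigma_theta_deg": float(st.sigma_theta),
            "dist_to_120": float(np.hypot(st.mean[0] - 120.0, st.mean[1] - 120.0)),
            "archetype_counts": st.archetype_counts,
            "prob_100_140": cs.prob_in_range(st.pooled_angles, 100.0, 140.0),
            "n_excluded_degree4plus": st.n_excluded_degree4plus,
        }
    if return_results:
        report["_results"] = {"growth": res_g, "shrinkage": res_s}
        report["_stats"] = stats
        report["_networks"] = {"growth": net_g, "shrinkage": net_s, "troughs": trough_net}
    return report


def mature_crack_network(
    state: ShellState,
    substrate: Substrate,
    params: ShellParams,
    h_max: float = 0.55,
    break_target: float = 0.055,
    dh: float | None = None,
) -> ShellState:
    """Continue growth beyond the presentation point to mature the crack network.

    At a ~3% broken-edge stop, crack lines are mostly isolated and carry
    few tri-junctions; junction statistics need the network to develop
    further, which continued thickening provides.  Returns a new state
    (the input is copied) grown to ``h_max`` or ``break_target``, whichever
    comes first, using slightly looser inner tolerances since only the
    final network geometry is consumed.
    """
    from .simulate import SimConfig, relax, break_bonds

    st = state.copy()
    cfg = SimConfig(
        h_max=h_max,
        tol_f=0.04,
        tol_v=1e-2,
        inner_tol_f=0.05,
        inner_tol_v=1e-2,
        inner_max_iter=8000,
    )
    if dh is None:
        dh = h_max / 16.0
    ne = st.mesh.n_edges
    while st.broken.sum() < break_target * ne and st.h < h_max - 1e-9:
        st.h = min(st.h + dh, h_max)
        relax(st, substrate, params, cfg)
        break_bonds(st, substrate, params, cfg, stop_fraction=break_target)
    return st


def _spacing_estimate(substrate: Substrate) -> float:
    """Mean nearest-neighbour papilla spacing, from the center list."""
    from scipy.spatial import cKDTree

    if substrate.centers is None or len(substrate.centers) < 2:
        return 1.0
    dd, _ = cKDTree(substrate.centers).query(substrate.centers, k=2)
    return float(dd[:, 1].mean())
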