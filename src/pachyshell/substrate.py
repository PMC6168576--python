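"""Synthetic papillary substrates and height-field queries.

The dermal surface under the stratum corneum is a quasi-regular lattice of
millimetric elevations (papillae) separated by connected troughs.  This
module generates such substrates analytically: papilla centers on a jittered
hexagonal lattice, each carrying a compactly-supported smooth bump, combined
with a smooth maximum so that troughs between papillae are genuinely flat
where no bump reaches.  The :class:`Substrate` wrapper also serves arbitrary
analytic height fields (e.g. sinusoidal ridges used as test fixtures).

Queries provided: height, gradient, unit normal, vertical projection onto
the surface, trough labelling by a height threshold, and the local trough
(valley-line) direction from the height-field Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mesh import TriMesh, make_triangular_grid

__all__ = [
    "PapillaConfig",
    "Substrate",
    "generate_papilla_substrate",
    "label_troughs",
    "local_trough_direction",
    "trough_directions",
]

#: exponent of the p-norm smooth maximum combining overlapping bumps
_PNORM = 8.0


@dataclass
class PapillaConfig:
    """Geometry of the synthetic papillated substrate.

    All lengths in millimetres.  Defaults emulate millimetric elephant-skin
    papillae: spacing ``mean_spacing`` = 2 mm between neighbouring apexes,
    bump amplitude about a third of the spacing, compact bump support
    slightly under half the spacing so troughs form a connected network,
    and a small positional jitter giving a quasi-regular (not crystalline)
    arrangement.
    """

    mean_spacing: float = 2.0
    amplitude: float = 0.7
    papilla_radius: float = 0.9
    jitter_sd: float = 0.25
    domain_size: tuple[float, float] = (8.0, 7.0)
    bump_profile: str = "bump"
    seed: int = 0
    mesh_edge_length: float | None = None  # default: mean_spacing / 12

    def __post_init__(self) -> None:
        if self.mean_spacing <= 0:
            raise ValueError("mean_spacing must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not self.jitter_sd < self.mean_spacing / 2:
            raise ValueError("jitter_sd must be < mean_spacing/2 (quasi-regularity)")
        if not self.papilla_radius < self.mean_spacing:
            raise ValueError("papilla_radius must be < mean_spacing (troughs must exist)")
        if self.bump_profile not in ("bump", "dome"):
            raise ValueError(f"unknown bump_profile {self.bump_profile!r}")
        w, h = self.domain_size
        if w < self.mean_spacing or h < self.mean_spacing * np.sqrt(3) / 2:
            raise ValueError("domain too small for one lattice cell")


def _bump(r2u: np.ndarray, q: float = 1.0) -> np.ndarray:
    """Smooth compact kernel b = exp(1 - 1/(1 - u^q)), u = (r/R)^2 < 1, else 0.

    ``q = 1`` is a peaked bump; ``q = 2`` ("dome") has a flatter top and a
    steeper flank, closer to the shape of dermal papillae.
    """
    out = np.zeros_like(r2u)
    m = r2u < 1.0
    out[m] = np.exp(1.0 - 1.0 / (1.0 - r2u[m] ** q))
    return out


def _bump_d(r2u: np.ndarray, q: float = 1.0) -> np.ndarray:
    """d b / d u."""
    out = np.zeros_like(r2u)
    m = r2u < 1.0
    u = r2u[m]
    uq = u ** q
    out[m] = -np.exp(1.0 - 1.0 / (1.0 - uq)) * q * u ** (q - 1.0) / (1.0 - uq) ** 2
    return out


class Substrate:
    """Smooth height field z = S(x, y) with derivative and projection queries.

    Backed either by an analytic callable or by the papilla-center
    construction.  Normals always point upward (+z half-space); for zero
    amplitude the field is identically zero and normals are vertical.
    """

    def __init__(
        self,
        height: Callable[[np.ndarray], np.ndarray],
        gradient: Callable[[np.ndarray], np.ndarray] | None = None,
        centers: np.ndarray | None = None,
        amplitude: float = 0.0,
        papilla_radius: float = 0.0,
        domain_size: tuple[float, float] = (0.0, 0.0),
        fd_step: float = 1e-3,
        analytic: bool = True,
    ) -> None:
        self._height = height
        self._gradient = gradient
        self.centers = centers
        self.amplitude = float(amplitude)
        self.papilla_radius = float(papilla_radius)
        self.domain_size = domain_size
        self.fd_step = float(fd_step)
        self.analytic = analytic

    # -- scalar field -------------------------------------------------------

    def height(self, xy: np.ndarray) -> np.ndarray:
        """S at (n, 2) points; returns (n,)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        return np.asarray(self._height(xy), dtype=np.float64)

    def gradient(self, xy: np.ndarray) -> np.ndarray:
        """(dS/dx, dS/dy) at (n, 2) points; analytic if available, else central FD."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        if self._gradient is not None:
            return np.asarray(self._gradient(xy), dtype=np.float64)
        h = self.fd_step
        ex = np.array([h, 0.0])
        ey = np.array([0.0, h])
        gx = (self.height(xy + ex) - self.height(xy - ex)) / (2 * h)
        gy = (self.height(xy + ey) - self.height(xy - ey)) / (2 * h)
        return np.column_stack([gx, gy])

    def normal(self, xy: np.ndarray) -> np.ndarray:
        """Upward unit surface normals at (n, 2) points; returns (n, 3)."""
        g = self.gradient(xy)
        n = np.column_stack([-g[:, 0], -g[:, 1], np.ones(len(g))])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def hessian(self, xy: np.ndarray, step: float | None = None) -> np.ndarray:
        """Central-difference Hessian of S; returns (n, 2, 2)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        h = self.fd_step if step is None else step
        ex = np.array([h, 0.0])
        ey = np.array([0.0, h])
        s0 = self.height(xy)
        sxx = (self.height(xy + ex) - 2 * s0 + self.height(xy - ex)) / h**2
        syy = (self.height(xy + ey) - 2 * s0 + self.height(xy - ey)) / h**2
        sxy = (
            self.height(xy + ex + ey)
            - self.height(xy + ex - ey)
            - self.height(xy - ex + ey)
            + self.height(xy - ex - ey)
        ) / (4 * h**2)
        H = np.empty((len(xy), 2, 2))
        H[:, 0, 0] = sxx
        H[:, 1, 1] = syy
        H[:, 0, 1] = H[:, 1, 0] = sxy
        return H

    def project(self, points: np.ndarray) -> np.ndarray:
        """Vertical projection of (n, 3) points onto the surface (x, y, S(x, y))."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        z = self.height(points[:, :2])
        return np.column_stack([points[:, 0], points[:, 1], z])


def _hex_centers(config: PapillaConfig) -> np.ndarray:
    """Jittered hexagonal lattice of papilla centers covering the domain.

    Deterministic function of the config (including seed): the unjittered
    lattice is laid out row by row, then each center receives an isotropic
    2D Gaussian displacement.
    """
    d = config.mean_spacing
    w, h = config.domain_size
    dy = d * np.sqrt(3) / 2
    margin = d  # one ring beyond the domain keeps boundary troughs shaped
    rows = []
    j = 0
    y = -margin + ((h + 2 * margin) % dy) / 2
    while y <= h + margin:
        x0 = -margin + (0.5 * d if j % 2 else 0.0)
        xs = np.arange(x0, w + margin + 1e-9, d)
        rows.append(np.column_stack([xs, np.full(len(xs), y)]))
        y += dy
        j += 1
    centers = np.concatenate(rows, axis=0)
    if config.jitter_sd > 0:
        rng = np.random.default_rng(config.seed)
        centers = centers + rng.normal(0.0, config.jitter_sd, centers.shape)
    return centers


def generate_papilla_substrate(
    config: PapillaConfig,
) -> tuple[Substrate, TriMesh]:
    """Build the analytic papillated substrate and its sampled triangle mesh.

    The height field is the p-norm smooth maximum of compact radial bumps
    at the (jittered) hexagonal centers; the mesh is a near-equilateral
    triangular grid over the domain with vertices lifted onto the field.
    Identical config (including seed) gives bit-identical output.
    """
    centers = _hex_centers(config)
    A = config.amplitude
    R = config.papilla_radius
    p = _PNORM
    q = 2.0 if config.bump_profile == "dome" else 1.0

    def height(xy: np.ndarray) -> np.ndarray:
        # compact support: only centers within R of a query can contribute
        d2 = (
            (xy[:, None, 0] - centers[None, :, 0]) ** 2
            + (xy[:, None, 1] - centers[None, :, 1]) ** 2
        )
        b = _bump(d2 / R**2, q)
        if A == 0:
            return np.zeros(len(xy))
        s = np.sum(b**p, axis=1)
        return A * s ** (1.0 / p)

    def gradient(xy: np.ndarray) -> np.ndarray:
        if A == 0:
            return np.zeros((len(xy), 2))
        dx = xy[:, None, 0] - centers[None, :, 0]
        dyv = xy[:, None, 1] - centers[None, :, 1]
        d2 = dx**2 + dyv**2
        u = d2 / R**2
        b = _bump(u, q)
        db = _bump_d(u, q)
        s = np.sum(b**p, axis=1)
        pref = np.zeros_like(s)
        pos = s > 0
        pref[pos] = s[pos] ** (1.0 / p - 1.0)
        # dS/dx = A/p * s^(1/p-1) * sum p b^(p-1) db/du * du/dx
        w = b ** (p - 1.0) * db * (2.0 / R**2)
        gx = A * pref * np.sum(w * dx, axis=1)
        gy = A * pref * np.sum(w * dyv, axis=1)
        return np.column_stack([gx, gy])

    sub = Substrate(
        height,
        gradient,
        centers=centers,
        amplitude=A,
        papilla_radius=R,
        domain_size=config.domain_size,
        fd_step=0.02 * config.mean_spacing,
    )

    el = config.mesh_edge_length or config.mean_spacing / 12.0
    w, h = config.domain_size
    nx = int(np.floor(w / el)) + 1
    ny = int(np.floor(h / (el * np.sqrt(3) / 2))) + 1
    grid = make_triangular_grid(nx, ny, el)
    verts = sub.project(grid.vertices)
    return sub, TriMesh(verts, grid.faces)


def label_troughs(substrate: Substrate, mesh: TriMesh, height_fraction: float = 0.4) -> np.ndarray:
    """Boolean per-vertex mask: True where S(vertex) < height_fraction * amplitude.

    By convention the mask is empty for a flat (zero-amplitude) substrate.
    """
    if not 0 < height_fraction < 1:
        raise ValueError("height_fraction must be in (0, 1)")
    if substrate.amplitude == 0:
        return np.zeros(mesh.n_vertices, dtype=bool)
    z = substrate.height(mesh.vertices[:, :2])
    return z < height_fraction * substrate.amplitude


def trough_directions(
    substrate: Substrate,
    points: np.ndarray,
    step: float | None = None,
    umbilic_rtol: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Local valley-line directions at (n, 2) points.

    The direction is the eigenvector of the height-field Hessian with the
    smallest absolute eigenvalue (the direction of least bending of the
    surface), identified modulo 180 deg and normalised to the upper half
    plane.  Points where the two absolute eigenvalues differ by less than
    ``umbilic_rtol`` of the larger one are flagged undefined (umbilic).

    Returns ``(directions, defined)`` where ``directions`` is (n, 2) unit
    vectors (NaN where undefined) and ``defined`` a boolean mask.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    H = substrate.hessian(points, step=step)
    evals, evecs = np.linalg.eigh(H)  # ascending
    aev = np.abs(evals)
    small = np.argmin(aev, axis=1)
    big = 1 - small
    idx = np.arange(len(points))
    lo = aev[idx, small]
    hi = aev[idx, big]
    defined = (hi - lo) > umbilic_rtol * np.maximum(hi, 1e-300)
    vec = evecs[idx, :, small]
    # canonicalise mod 180 deg: upper half plane, +x on the axis
    flip = (vec[:, 1] < 0) | ((vec[:, 1] == 0) & (vec[:, 0] < 0))
    vec[flip] *= -1.0
    vec[~defined] = np.nan
    return vec, defined


def local_trough_direction(
    substrate: Substrate, point: np.ndarray, step: float | None = None
) -> tuple[np.ndarray, bool]:
    """Valley-line direction at a single point; see :func:`trough_directions`."""
    v, ok = trough_directions(substrate, np.atleast_2d(point), step=step)
    return v[0], bool(ok[0])
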