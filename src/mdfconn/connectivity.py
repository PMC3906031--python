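"""Expected number of potential synapses between displaced neuron pairs.

A potential synapse is a site where an axonal segment of the pre-synaptic
neuron and a dendritic segment of the post-synaptic neuron pass within a
threshold distance s.  Because both density fields are cylindrically
symmetric, the expected count K depends on the soma displacement only
through (rho, zeta) = (horizontal, vertical) offset; the displacement
vector is taken as d = (rho, 0, zeta) without loss of generality.

Three estimators are provided:

* ``k_uniform`` (tag U): overlap integral of the two MDFs assuming segment
  orientations uniform on the unit sphere,
  K_U = (pi/4) * 2s * sum_v rho_a(x_v) rho_d(x_v - d) dV.
  The factor pi/4 is the mean |sin theta| between two independent uniform
  orientations; 2s is the thickness of the contact slab.
* ``k_template`` (tag O): same integral with both densities resolved into
  seven principal orientation axes, weighting each channel pair by
  |sin theta_ij| between the axes expressed in the global frame.
* ``k_kernel`` (tag S): Gaussian-kernel smoothing of two individual
  segment clouds; a closed-form double sum over segment pairs.

``count_potential_synapses`` is the direct geometric count on a morphology
pair, used as the Monte-Carlo oracle for the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mdf import CylindricalGrid, deposit_segments, sample_density
from .morphology import Morphology

__all__ = [
    "Displacement", "SynapseParams", "OrientationTemplate", "ConnectivityGrid",
    "k_uniform", "build_template", "k_template", "k_kernel",
    "count_potential_synapses", "connectivity_map", "interpolate_k",
]

UNIFORM_ORIENTATION_FACTOR = np.pi / 4.0  # mean |sin(angle)| of two uniform axes


@dataclass(frozen=True)
class Displacement:
    """Soma displacement (rho >= 0 horizontal, zeta vertical), micrometres."""

    rho: float
    zeta: float

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be >= 0 (cylindrical symmetry)")

    @classmethod
    def from_vector(cls, dx: float, dy: float, dz: float) -> "Displacement":
        """Canonicalize a full 3-D displacement using cylindrical symmetry."""
        return cls(float(np.hypot(dx, dy)), float(dz))

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.rho, 0.0, self.zeta])


@dataclass(frozen=True)
class SynapseParams:
    """Contact threshold s (um) and the integration lattice step (um)."""

    s: float = 2.0
    integration_step: float = 2.0

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("threshold distance s must be positive")
        if self.integration_step <= 0:
            raise ValueError("integration_step must be positive")


# --- uniform-orientation estimator -----------------------------------------

def _support(g: CylindricalGrid):
    return g.r_edges[-1], g.z_edges[0], g.z_edges[-1]


def _overlap_bounds(mdf_a, mdf_d, d: Displacement, step: float):
    """Lattice bounds (x0, y0, zlo, nx, ny, nz) covering the support
    overlap, or None if the supports are disjoint."""
    ra, za0, za1 = _support(mdf_a)
    rd, zd0, zd1 = _support(mdf_d)
    xlo = max(-ra, d.rho - rd); xhi = min(ra, d.rho + rd)
    ylo = max(-ra, -rd); yhi = min(ra, rd)
    zlo = max(za0, d.zeta + zd0); zhi = min(za1, d.zeta + zd1)
    if xlo >= xhi or ylo >= yhi or zlo >= zhi:
        return None
    nx = int(np.ceil((xhi - xlo) / step))
    ny = int(np.ceil((yhi - ylo) / step))
    nz = int(np.ceil((zhi - zlo) / step))
    return xlo, ylo, zlo, nx, ny, nz


def k_uniform(mdf_a: CylindricalGrid, mdf_d: CylindricalGrid,
              d: Displacement, p: SynapseParams = SynapseParams()) -> float:
    """Expected potential-synapse count under uniform segment orientations.

    Numerically integrates the product of the axonal field (pre-synaptic,
    anchored at the origin) and the dendritic field displaced by
    (rho, 0, zeta) over the support overlap; both fields are evaluated by
    the same bilinear (r, z) rule as ``sample_density``.
    """
    from ._integrate import product_sum

    step = p.integration_step
    bounds = _overlap_bounds(mdf_a, mdf_d, d, step)
    if bounds is None:
        return 0.0
    x0, y0, zlo, nx, ny, nz = bounds
    total = product_sum(mdf_a.values, mdf_a.h, mdf_a.z_edges[0],
                        mdf_d.values, mdf_d.h, mdf_d.z_edges[0],
                        d.rho, d.zeta, x0, y0, zlo, nx, ny, nz, step)
    return UNIFORM_ORIENTATION_FACTOR * 2.0 * p.s * total * step ** 3


# --- orientation templates ---------------------------------------------------

def _canonical_axes() -> np.ndarray:
    """Seven sign-free orientation axes in the local (e_rho, e_phi, e_z)
    frame: the vertical axis, three equatorial axes at azimuths 0/60/120
    degrees, and three oblique axes at polar 45 degrees, azimuths
    0/120/240 degrees."""
    axes = [(0.0, 0.0, 1.0)]
    for a in np.deg2rad([0.0, 60.0, 120.0]):
        axes.append((np.cos(a), np.sin(a), 0.0))
    s45 = np.sin(np.pi / 4)
    for a in np.deg2rad([0.0, 120.0, 240.0]):
        axes.append((s45 * np.cos(a), s45 * np.sin(a), s45))
    return np.array(axes)


CANONICAL_AXES = _canonical_axes()


@dataclass
class OrientationTemplate:
    """Cylindrical density grid resolved into the 7 orientation channels.

    ``values`` has shape (7, nr, nz); summing over channels recovers the
    plain MDF exactly (each segment's mass goes to exactly one channel).
    """

    r_edges: np.ndarray
    z_edges: np.ndarray
    values: np.ndarray          # (7, nr, nz)
    voxel_counts: np.ndarray
    n_neurons: int
    h: float

    def channel(self, i: int) -> CylindricalGrid:
        return CylindricalGrid(self.r_edges, self.z_edges, self.values[i],
                               self.voxel_counts, self.n_neurons, self.h)

    def plain(self) -> CylindricalGrid:
        """Channel-summed grid; equals the plain MDF estimate."""
        return CylindricalGrid(self.r_edges, self.z_edges, self.values.sum(axis=0),
                               self.voxel_counts, self.n_neurons, self.h)

    def sample_channels(self, x, y, z) -> np.ndarray:
        """(n_points, 7) channel densities at 3-D points."""
        cols = [sample_density(self.channel(i), x, y, z) for i in range(7)]
        return np.stack(cols, axis=-1)

    def channel_masses(self) -> np.ndarray:
        vol = self.voxel_counts * self.h ** 3
        return (self.values * vol[None, :, None]).sum(axis=(1, 2))


def assign_channels(midpoints: np.ndarray, orientations: np.ndarray) -> np.ndarray:
    """Nearest canonical axis (by |cos|) of each segment, with the axis set
    expressed in the local cylindrical frame at the segment midpoint."""
    phi = np.arctan2(midpoints[:, 1], midpoints[:, 0])
    c, s = np.cos(phi), np.sin(phi)
    u = orientations
    u_local = np.column_stack([
        u[:, 0] * c + u[:, 1] * s,        # e_rho component
        -u[:, 0] * s + u[:, 1] * c,       # e_phi component
        u[:, 2],
    ])
    return np.argmax(np.abs(u_local @ CANONICAL_AXES.T), axis=1)


def build_template(ensemble, kind: str, h: float = 1.0,
                   r_max: float = 500.0, z_range=(-500.0, 500.0)) -> OrientationTemplate:
    """Estimate an orientation-resolved density template from an ensemble."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    starts = np.vstack([m.starts[m.mask(kind)] for m in ensemble])
    ends = np.vstack([m.ends[m.mask(kind)] for m in ensemble])
    mid = 0.5 * (starts + ends)
    d = ends - starts
    u = d / np.linalg.norm(d, axis=1, keepdims=True)
    ch = assign_channels(mid, u)
    grids = []
    for i in range(7):
        m = ch == i
        if np.any(m):
            g = deposit_segments(starts[m], ends[m], len(ensemble), h, r_max, z_range)
        else:
            g = deposit_segments(np.zeros((0, 3)), np.zeros((0, 3)),
                                 len(ensemble), h, r_max, z_range)
        grids.append(g)
    base = grids[0]
    return OrientationTemplate(base.r_edges, base.z_edges,
                               np.stack([g.values for g in grids]),
                               base.voxel_counts, len(ensemble), h)


def save_template(t: OrientationTemplate, path) -> None:
    """Write an orientation template to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=t.values)
        f.create_dataset("r_edges", data=t.r_edges)
        f.create_dataset("z_edges", data=t.z_edges)
        f.create_dataset("voxel_counts", data=t.voxel_counts)
        f.attrs["n_neurons"] = t.n_neurons
        f.attrs["h"] = t.h
        f.attrs["channels"] = 7


def load_template(path) -> OrientationTemplate:
    import h5py

    with h5py.File(path, "r") as f:
        return OrientationTemplate(
            r_edges=f["r_edges"][:], z_edges=f["z_edges"][:],
            values=f["values"][:], voxel_counts=f["voxel_counts"][:],
            n_neurons=int(f.attrs["n_neurons"]), h=float(f.attrs["h"]))


def _rotate_axes_z(angles: np.ndarray) -> np.ndarray:
    """(n, 7, 3) canonical axes rotated about z by per-point angles."""
    c, s = np.cos(angles), np.sin(angles)
    ax = CANONICAL_AXES
    out = np.empty((len(angles), 7, 3))
    out[:, :, 0] = c[:, None] * ax[None, :, 0] - s[:, None] * ax[None, :, 1]
    out[:, :, 1] = s[:, None] * ax[None, :, 0] + c[:, None] * ax[None, :, 1]
    out[:, :, 2] = ax[None, :, 2]
    return out


def k_template(t_a: OrientationTemplate, t_d: OrientationTemplate,
               d: Displacement, p: SynapseParams = SynapseParams(integration_step=4.0)
               ) -> float:
    """Expected count using the actual (7-axis discretized) orientations.

    K_O = 2s * sum_v sum_ij |sin theta_ij(v)| T_a(x_v, i) T_d(x_v - d, j) dV,
    where the channel axes are rotated into the global frame by the local
    azimuth of each evaluation point in the respective field's frame.
    """
    from ._integrate import template_sum

    if t_a.values.shape[0] != 7 or t_d.values.shape[0] != 7:
        raise ValueError("templates must have exactly 7 orientation channels")
    if not np.isclose(t_a.h, t_d.h):
        raise ValueError("templates must share the same voxel size")
    step = p.integration_step
    bounds = _overlap_bounds(t_a.plain(), t_d.plain(), d, step)
    if bounds is None:
        return 0.0
    x0, y0, zlo, nx, ny, nz = bounds
    total = template_sum(t_a.values, t_a.h, t_a.z_edges[0],
                         t_d.values, t_d.h, t_d.z_edges[0],
                         CANONICAL_AXES, d.rho, d.zeta,
                         x0, y0, zlo, nx, ny, nz, step)
    return 2.0 * p.s * total * step ** 3


# --- kernel-smoothing estimator ---------------------------------------------

def _inventory_arrays(inv):
    if isinstance(inv, pd.DataFrame):
        m = inv[["x", "y", "z"]].to_numpy(float)
        length = inv["length"].to_numpy(float)
        u = inv[["ux", "uy", "uz"]].to_numpy(float)
        return m, length, u
    raise TypeError("inventory must be a segment_inventory DataFrame")


def k_kernel(inv_a, inv_d, d: Displacement, p: SynapseParams = SynapseParams(),
             sigma: float = 10.0) -> float:
    """Gaussian-kernel estimate from two individual segment inventories.

    Both segment clouds are notionally convolved with an isotropic Gaussian
    of standard deviation sigma; the product integral of two such kernels
    collapses to a single Gaussian of per-axis std sqrt(2) sigma evaluated
    at the midpoint offset, giving the closed form
    K_S = 2s * sum_i sum_j l_a,i l_d,j |sin theta_ij| g(m_a,i - m_d,j - d).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ma, la, ua = _inventory_arrays(inv_a)
    md, ld, ud = _inventory_arrays(inv_d)
    if len(ma) == 0 or len(md) == 0:
        return 0.0
    var = 2.0 * sigma ** 2
    norm = (2.0 * np.pi * var) ** -1.5
    md_shift = md + d.vector[None, :]
    total = 0.0
    chunk = max(1, int(4e6 // max(len(md), 1)))
    for i in range(0, len(ma), chunk):
        diff = ma[i:i + chunk, None, :] - md_shift[None, :, :]
        q = np.einsum("abc,abc->ab", diff, diff)
        g = norm * np.exp(-q / (2.0 * var))
        dots = np.clip(np.abs(ua[i:i + chunk] @ ud.T), 0.0, 1.0)
        sin = np.sqrt(1.0 - dots * dots)
        total += float(np.einsum("a,b,ab,ab->", la[i:i + chunk], ld, sin, g))
    return 2.0 * p.s * total


# --- geometric oracle --------------------------------------------------------

def segment_pair_distances(p1, q1, p2, q2) -> np.ndarray:
    """Minimum distances between segment pairs (p1[i], q1[i]) and
    (p2[i], q2[i]), vectorized clamped closest-point computation."""
    p1 = np.atleast_2d(p1); q1 = np.atleast_2d(q1)
    p2 = np.atleast_2d(p2); q2 = np.atleast_2d(q2)
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-14, (b * f - c * e) / np.where(denom > 1e-14, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    # t from s, then re-clamp s
    t = np.where(e > 1e-14, (b * s + f) / np.where(e > 1e-14, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    s = np.where(a > 1e-14, (b * t_cl - c) / np.where(a > 1e-14, a, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    closest1 = p1 + s[:, None] * d1
    closest2 = p2 + t_cl[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1)


def _local_adjacency(parents: np.ndarray, idx: np.ndarray) -> list[list[int]]:
    """Neighbour lists (within the selected subset) of segments sharing an
    endpoint: parent-child links and siblings at a common branch point."""
    pos = {int(o): k for k, o in enumerate(idx)}
    nbr: list[list[int]] = [[] for _ in idx]
    by_parent: dict[int, list[int]] = {}
    for k, o in enumerate(idx):
        par = int(parents[o])
        if par < 0:
            continue
        pl = pos.get(par)
        if pl is not None:
            nbr[k].append(pl)
            nbr[pl].append(k)
        by_parent.setdefault(par, []).append(k)
    for sibs in by_parent.values():
        for a in sibs:
            for b in sibs:
                if a != b:
                    nbr[a].append(b)
    return nbr


def count_potential_synapses(m_a: Morphology, m_d: Morphology,
                             d: Displacement, p: SynapseParams = SynapseParams(),
                             mode: str = "sites") -> int:
    """Count potential synapses between an axonal and a dendritic arbor.

    The post-synaptic morphology is translated by (rho, 0, zeta); a segment
    pair qualifies when its minimum Euclidean distance (exact clamped
    closest-point computation) is at most s.

    mode='sites' (default) counts contact sites: maximal connected runs of
    qualifying pairs, where two pairs belong to the same site when their
    segments are identical or share an endpoint in both arbors.  This is
    the quantity the overlap-integral estimators predict, since one
    geometric contact spans several consecutive short segments on each
    side.  mode='pairs' returns the raw qualifying-pair count.
    """
    if mode not in ("sites", "pairs"):
        raise ValueError("mode must be 'sites' or 'pairs'")
    a_idx = np.where(m_a.mask("axon"))[0]
    d_idx = np.where(m_d.mask("dendrite"))[0]
    a_start, a_end = m_a.starts[a_idx], m_a.ends[a_idx]
    off = d.vector
    d_start, d_end = m_d.starts[d_idx] + off, m_d.ends[d_idx] + off
    if len(a_start) == 0 or len(d_start) == 0:
        return 0
    a_mid = 0.5 * (a_start + a_end)
    d_mid = 0.5 * (d_start + d_end)
    a_half = 0.5 * np.linalg.norm(a_end - a_start, axis=1)
    d_half = 0.5 * np.linalg.norm(d_end - d_start, axis=1)
    radius = p.s + a_half.max() + d_half.max()
    tree = cKDTree(d_mid)
    neighbours = tree.query_ball_point(a_mid, r=radius)
    ii = np.fromiter((i for i, nb in enumerate(neighbours) for _ in nb), dtype=np.int64,
                     count=sum(len(nb) for nb in neighbours))
    jj = np.fromiter((j for nb in neighbours for j in nb), dtype=np.int64, count=len(ii))
    if len(ii) == 0:
        return 0
    hit = np.zeros(len(ii), dtype=bool)
    chunk = 2_000_000
    for i in range(0, len(ii), chunk):
        sl = slice(i, i + chunk)
        dist = segment_pair_distances(a_start[ii[sl]], a_end[ii[sl]],
                                      d_start[jj[sl]], d_end[jj[sl]])
        hit[sl] = dist <= p.s
    ii, jj = ii[hit], jj[hit]
    if mode == "pairs" or len(ii) == 0:
        return int(len(ii))

    # union-find over qualifying pairs linked through endpoint-sharing
    # segments on both sides
    nbr_a = _local_adjacency(m_a.parents, a_idx)
    nbr_d = _local_adjacency(m_d.parents, d_idx)
    index = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(ii, jj))}
    parent = list(range(len(ii)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (i, j) in enumerate(zip(ii, jj)):
        for i2 in (int(i), *nbr_a[int(i)]):
            for j2 in (int(j), *nbr_d[int(j)]):
                k2 = index.get((i2, j2))
                if k2 is not None and k2 != k:
                    ra, rb = find(k), find(k2)
                    if ra != rb:
                        parent[rb] = ra
    return len({find(k) for k in range(len(ii))})


# --- stored connectivity surfaces -------------------------------------------

@dataclass
class ConnectivityGrid:
    """Expected potential-synapse counts K on a (rho, zeta) lattice."""

    rho: np.ndarray
    zeta: np.ndarray
    K: np.ndarray               # (n_rho, n_zeta)
    estimator: str = "U"        # U (uniform) | O (orientations) | S (smoothing)

    def __post_init__(self):
        self.rho = np.asarray(self.rho, float)
        self.zeta = np.asarray(self.zeta, float)
        self.K = np.asarray(self.K, float)
        if np.any(np.diff(self.rho) <= 0) or np.any(np.diff(self.zeta) <= 0):
            raise ValueError("rho and zeta lattices must be strictly increasing")
        if self.K.shape != (len(self.rho), len(self.zeta)):
            raise ValueError("K shape must be (len(rho), len(zeta))")

    def to_frame(self) -> pd.DataFrame:
        R, Z = np.meshgrid(self.rho, self.zeta, indexing="ij")
        return pd.DataFrame({"rho": R.ravel(), "zeta": Z.ravel(), "K": self.K.ravel()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, estimator: str = "U") -> "ConnectivityGrid":
        rho = np.unique(df["rho"].to_numpy(float))
        zeta = np.unique(df["zeta"].to_numpy(float))
        K = (df.sort_values(["rho", "zeta"])["K"].to_numpy(float)
             .reshape(len(rho), len(zeta)))
        return cls(rho, zeta, K, estimator)


def connectivity_map(mdf_a, mdf_d, rhos, zetas,
                     p: SynapseParams = SynapseParams(),
                     estimator: str = "uniform") -> ConnectivityGrid:
    """Tabulate K over a (rho, zeta) lattice for later interpolation.

    ``estimator`` is 'uniform' (mdf_a/mdf_d are CylindricalGrids) or
    'template' (OrientationTemplates).
    """
    rhos = np.asarray(rhos, float)
    zetas = np.asarray(zetas, float)
    K = np.empty((len(rhos), len(zetas)))
    if estimator == "uniform":
        fn, tag = k_uniform, "U"
    elif estimator == "template":
        fn, tag = k_template, "O"
    else:
        raise ValueError("estimator must be 'uniform' or 'template'")
    for i, r in enumerate(rhos):
        for j, zt in enumerate(zetas):
            K[i, j] = fn(mdf_a, mdf_d, Displacement(r, zt), p)
    return ConnectivityGrid(rhos, zetas, K, tag)


def interpolate_k(cg: ConnectivityGrid, d: Displacement) -> float:
    """Bilinear interpolation of the stored K surface; 0 beyond the hull."""
    return float(interpolate_k_many(cg, np.array([d.rho]), np.array([d.zeta]))[0])


def interpolate_k_many(cg: ConnectivityGrid, rho, zeta) -> np.ndarray:
    rho = np.asarray(rho, float)
    zeta = np.asarray(zeta, float)
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    from scipy.interpolate import RegularGridInterpolator

    itp = RegularGridInterpolator((cg.rho, cg.zeta), cg.K,
                                  bounds_error=False, fill_value=0.0)
    return itp(np.column_stack([rho, zeta]))
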