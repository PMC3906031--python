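"""Cylindrically-averaged morpho-density fields (MDFs).

An MDF gives the expected neurite segment length per unit volume
(micrometre of segment per cubic micrometre, i.e. um^-2) as a function of
position relative to the soma, separately for the axonal and the dendritic
(apical + basal) arbors.  Estimation superimposes an ensemble of
morphologies with somata at the origin and apical axes aligned with +z,
deposits exact segment-voxel intersection lengths on a cubic voxel grid,
and then averages azimuthally: all voxels whose centre radius falls in the
same radial bin are pooled, so the field is stored on a 2-D
(radius, height) grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["CylindricalGrid", "estimate_mdf", "total_mass", "sample_density"]


@dataclass
class CylindricalGrid:
    """Azimuthally averaged density on a (radius, height) grid.

    ``values[k, m]`` is the density (um^-2) in radial bin
    ``[r_edges[k], r_edges[k+1])`` and height bin
    ``[z_edges[m], z_edges[m+1])``.  ``voxel_counts[k]`` is the number of
    cubic voxels in one z-slab whose centre radius falls in radial bin k;
    bin volumes are computed from it so that mass accounting is exact.
    """

    r_edges: np.ndarray
    z_edges: np.ndarray
    values: np.ndarray          # (nr, nz)
    voxel_counts: np.ndarray    # (nr,)
    n_neurons: int
    h: float

    def __post_init__(self):
        self.r_edges = np.asarray(self.r_edges, float)
        self.z_edges = np.asarray(self.z_edges, float)
        self.values = np.asarray(self.values, float)
        self.voxel_counts = np.asarray(self.voxel_counts, np.int64)

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def bin_volumes(self) -> np.ndarray:
        """(nr,) volume (um^3) of each radial bin within one height slab."""
        return self.voxel_counts * self.h ** 3

    def compatible_with(self, other: "CylindricalGrid") -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.r_edges, other.r_edges)
                and np.allclose(self.z_edges, other.z_edges))


def _lattice_counts(nr: int, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Radial-bin index of each (ix, iy) voxel column and per-bin counts.

    Voxel centres sit at half-integer multiples of h; the column map covers
    x, y in [-nr*h, nr*h].  Columns with centre radius >= nr*h fall outside
    the cylindrical extent and are marked -1.
    """
    n = 2 * nr
    c = (np.arange(n) + 0.5) * h - nr * h
    rc = np.hypot(c[:, None], c[None, :])
    rbin = np.floor(rc / h).astype(np.int32)
    rbin[rbin >= nr] = -1
    counts = np.bincount(rbin[rbin >= 0].ravel(), minlength=nr).astype(np.int64)
    return rbin, counts


@njit(cache=True)
def _deposit(starts, ends, h, nr, nz, z0, rbin_map, out):  # pragma: no cover - numba
    """Accumulate exact segment-voxel intersection lengths into (nr, nz) bins.

    Returns the total segment length falling outside the grid.
    """
    clipped = 0.0
    half = nr * h  # x, y in [-half, half]
    for s in range(starts.shape[0]):
        x0 = starts[s, 0]; y0 = starts[s, 1]; zz0 = starts[s, 2]
        dx = ends[s, 0] - x0; dy = ends[s, 1] - y0; dz = ends[s, 2] - zz0
        L = (dx * dx + dy * dy + dz * dz) ** 0.5
        if L <= 0.0:
            continue
        # parametric crossings with the voxel planes of each axis
        ncross = (int(abs(dx) / h) + int(abs(dy) / h) + int(abs(dz) / h) + 8)
        ts = np.empty(2 + 3 * ncross)
        ts[0] = 0.0
        ts[1] = 1.0
        m = 2
        for axis in range(3):
            if axis == 0:
                p, d, orig = x0, dx, -half
            elif axis == 1:
                p, d, orig = y0, dy, -half
            else:
                p, d, orig = zz0, dz, z0
            if d == 0.0:
                continue
            f0 = (p - orig) / h
            f1 = (p + d - orig) / h
            lo = min(f0, f1)
            hi = max(f0, f1)
            k = int(np.ceil(lo))
            while k < hi:
                t = (k * h + orig - p) / d
                if 0.0 < t < 1.0:
                    ts[m] = t
                    m += 1
                k += 1
        tsub = np.sort(ts[:m])
        for q in range(m - 1):
            ta = tsub[q]; tb = tsub[q + 1]
            if tb <= ta:
                continue
            tm = 0.5 * (ta + tb)
            seg_len = (tb - ta) * L
            xm = x0 + tm * dx; ym = y0 + tm * dy; zm = zz0 + tm * dz
            ix = int(np.floor((xm + half) / h))
            iy = int(np.floor((ym + half) / h))
            iz = int(np.floor((zm - z0) / h))
            if ix < 0 or ix >= 2 * nr or iy < 0 or iy >= 2 * nr or iz < 0 or iz >= nz:
                clipped += seg_len
                continue
            rb = rbin_map[ix, iy]
            if rb < 0:
                clipped += seg_len
            else:
                out[rb, iz] += seg_len
    return clipped


def deposit_segments(starts, ends, n_neurons, h, r_max, z_range) -> CylindricalGrid:
    """Deposit a batch of segments (already superimposed at the origin)
    into a fresh cylindrical grid and normalize to density per neuron."""
    if h <= 0:
        raise ValueError("voxel size h must be positive")
    nr = int(np.ceil(r_max / h))
    z_lo = np.floor(z_range[0] / h) * h
    nz = int(np.ceil((z_range[1] - z_lo) / h))
    rbin_map, counts = _lattice_counts(nr, h)
    mass = np.zeros((nr, nz))
    starts = np.ascontiguousarray(starts, dtype=np.float64)
    ends = np.ascontiguousarray(ends, dtype=np.float64)
    clipped = _deposit(starts, ends, float(h), nr, nz, float(z_lo), rbin_map, mass)
    total = np.linalg.norm(ends - starts, axis=1).sum()
    if clipped > 0 and total > 0:
        warnings.warn(
            f"{clipped / total:.2%} of segment mass fell outside the grid extent "
            f"(r_max={r_max}, z_range={z_range}) and was clipped")
    values = mass / (n_neurons * counts[:, None] * h ** 3)
    return CylindricalGrid(
        r_edges=np.arange(nr + 1) * h,
        z_edges=z_lo + np.arange(nz + 1) * h,
        values=values, voxel_counts=counts, n_neurons=n_neurons, h=float(h))


def estimate_mdf(ensemble, kind: str, h: float = 1.0,
                 r_max: float = 500.0, z_range=(-500.0, 500.0)) -> CylindricalGrid:
    """Estimate the axonal or dendritic MDF from a morphology ensemble.

    Parameters
    ----------
    ensemble : iterable of Morphology, superimposed with somata at the
        origin and apical axis along +z (the generator's convention).
    kind : 'axonal' or 'dendritic' ('dendritic' pools apical + basal).
    h : cubic voxel edge in um; also the radial and height bin width.
    r_max, z_range : cylindrical extent of the grid in um.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    if kind not in ("axonal", "dendritic", "axon", "dendrite"):
        raise ValueError(f"kind must be 'axonal' or 'dendritic', got {kind!r}")
    starts = np.vstack([m.starts[m.mask(kind)] for m in ensemble])
    ends = np.vstack([m.ends[m.mask(kind)] for m in ensemble])
    return deposit_segments(starts, ends, len(ensemble), h, r_max, z_range)


def total_mass(g: CylindricalGrid) -> float:
    """Total mass sum(value * bin volume) in um of segment length.

    Equals the mean per-neuron arbor length of the contributing class when
    no mass was clipped.
    """
    return float((g.values * g.bin_volumes[:, None]).sum())


def sample_density(g: CylindricalGrid, x, y, z) -> np.ndarray:
    """Evaluate the field at 3-D points by bilinear interpolation in (r, z).

    Values are interpolated between bin centres; beyond the last radial
    bin centre the field decays linearly to zero over one bin width, and
    likewise beyond the outermost height centres.  Radii inside the first
    bin centre clamp to the innermost bin value.
    """
    x = np.asarray(x, float); y = np.asarray(y, float); z = np.asarray(z, float)
    r = np.hypot(x, y)
    h = g.h
    nr, nz = g.values.shape
    # fractional bin-centre coordinates
    fr = r / h - 0.5
    fz = (z - g.z_edges[0]) / h - 0.5
    out = np.zeros(np.broadcast(fr, fz).shape, float)
    fr = np.broadcast_to(fr, out.shape)
    fz = np.broadcast_to(fz, out.shape)
    inside = (fr < nr) & (fz > -1.0) & (fz < nz)
    if not np.any(inside):
        return out if out.shape else float(out)
    fr_i = np.clip(fr[inside], 0.0, None)   # clamp below first radial centre
    fz_i = fz[inside]
    k0 = np.floor(fr_i).astype(np.int64)
    m0 = np.floor(fz_i).astype(np.int64)
    tr = fr_i - k0
    tz = fz_i - m0

    def val(k, m):
        ok = (k >= 0) & (k < nr) & (m >= 0) & (m < nz)
        v = np.zeros(len(k))
        v[ok] = g.values[k[ok], m[ok]]
        return v

    v = ((1 - tr) * (1 - tz) * val(k0, m0)
         + tr * (1 - tz) * val(k0 + 1, m0)
         + (1 - tr) * tz * val(k0, m0 + 1)
         + tr * tz * val(k0 + 1, m0 + 1))
    out[inside] = v
    return out if out.shape else float(out)


def save_grid(g: CylindricalGrid, path) -> None:
    """Write a grid to an HDF5 file (datasets + attrs; self-describing)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=g.values)
        f.create_dataset("r_edges", data=g.r_edges)
        f.create_dataset("z_edges", data=g.z_edges)
        f.create_dataset("voxel_counts", data=g.voxel_counts)
        f.attrs["n_neurons"] = g.n_neurons
        f.attrs["h"] = g.h
        f.attrs["units"] = "um^-2 (um segment length per um^3)"


def load_grid(path) -> CylindricalGrid:
    import h5py

    with h5py.File(path, "r") as f:
        return CylindricalGrid(
            r_edges=f["r_edges"][:], z_edges=f["z_edges"][:],
            values=f["values"][:], voxel_counts=f["voxel_counts"][:],
            n_neurons=int(f.attrs["n_neurons"]), h=float(f.attrs["h"]))


def plot_log_density(g: CylindricalGrid, path, title: str = "") -> None:
    """Heat map of log10 density over (r, z); zero bins are masked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with np.errstate(divide="ignore"):
        logv = np.where(g.values > 0, np.log10(g.values), np.nan)
    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.pcolormesh(g.r_edges, g.z_edges, logv.T, shading="flat")
    fig.colorbar(im, ax=ax, label=r"$\log_{10}$ density ($\mu m^{-2}$)")
    ax.set_xlabel(r"radius $r$ ($\mu$m)")
    ax.set_ylabel(r"height $z$ ($\mu$m)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
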