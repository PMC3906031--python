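"""Random directed weighted neural networks from a stored connectivity surface.

Somata are placed uniformly in a cylinder with a hard minimum pairwise
distance (somata are ~10 um spheres, so centres may not approach closer
than 20 um).  For every ordered pair (i, j) the expected potential-synapse
count K_ij is read off the connectivity surface at the pair's displacement
(rho_ij, zeta_ij = z_j - z_i); the edge indicator is a Bernoulli draw with
p_ij = 1 - exp(-K_ij) (the probability of at least one potential synapse
under a Poisson count with mean K_ij) and the weight w_ij = K_ij / p_ij is
defined for all pairs, so that E[a_ij w_ij] = K_ij exactly: the realized
weighted connection strength is linear in the expected potential-synapse
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityGrid, interpolate_k_many
from .errors import InfeasibleDensityError

__all__ = ["SomaLayout", "WeightedNetwork", "place_somata", "build_network"]

_PACKING_FRACTION = np.pi / np.sqrt(18.0)  # densest sphere packing


@dataclass
class SomaLayout:
    """Soma centre positions inside a cylinder (radius R, height H)."""

    positions: np.ndarray       # (n, 3), um; z in [0, H]
    radius: float
    height: float
    min_distance: float = 20.0
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class WeightedNetwork:
    """Directed weighted graph over soma positions.

    ``adjacency`` is 0/1 with zero diagonal; ``weights`` >= 0 is defined
    for every ordered pair (including absent edges); ``K`` holds the
    underlying expected potential-synapse counts.
    """

    adjacency: np.ndarray       # (n, n) int8
    weights: np.ndarray         # (n, n) float
    K: np.ndarray               # (n, n) float
    layout: SomaLayout | None = None

    @property
    def n(self) -> int:
        return len(self.adjacency)

    def edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(~np.eye(self.n, dtype=bool))
        return pd.DataFrame({
            "i": i, "j": j,
            "a": self.adjacency[i, j],
            "w": self.weights[i, j],
            "K": self.K[i, j],
        })


def place_somata(n: int, R: float, H: float, min_distance: float = 20.0,
                 seed: int = 0, max_attempts: int | None = None) -> SomaLayout:
    """Uniform rejection sampling of n soma centres in a cylinder, honouring
    the minimum pairwise distance; deterministic under ``seed``.

    Raises :class:`InfeasibleDensityError` when the request exceeds the
    densest-sphere-packing bound of the (dilated) cylinder or when
    rejection sampling exhausts its attempt budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if R <= 0 or H <= 0 or min_distance < 0:
        raise ValueError("R, H must be positive and min_distance >= 0")
    if min_distance > 0:
        r_sphere = min_distance / 2.0
        v_dilated = np.pi * (R + r_sphere) ** 2 * (H + min_distance)
        n_max = _PACKING_FRACTION * v_dilated / ((4.0 / 3.0) * np.pi * r_sphere ** 3)
        if n > n_max:
            raise InfeasibleDensityError(
                f"{n} somata with min distance {min_distance} um exceed the "
                f"sphere-packing bound (~{int(n_max)}) of the cylinder "
                f"R={R}, H={H}")
    if max_attempts is None:
        max_attempts = max(10_000, 2_000 * n)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    pts = np.empty((n, 3))
    placed = 0
    attempts = 0
    while placed < n:
        if attempts >= max_attempts:
            raise InfeasibleDensityError(
                f"failed to place {n} somata in cylinder R={R}, H={H} with "
                f"min distance {min_distance} um after {max_attempts} attempts")
        attempts += 1
        r = R * np.sqrt(rng.random())
        phi = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(0, H)
        cand = np.array([r * np.cos(phi), r * np.sin(phi), z])
        if placed and np.min(np.linalg.norm(pts[:placed] - cand, axis=1)) < min_distance:
            continue
        pts[placed] = cand
        placed += 1
    return SomaLayout(pts, R, H, min_distance, seed)


def build_network(layout: SomaLayout, cg: ConnectivityGrid, seed: int = 0
                  ) -> WeightedNetwork:
    """Draw a directed weighted network from the connectivity surface."""
    pos = layout.positions
    n = len(pos)
    dx = pos[None, :, 0] - pos[:, None, 0]
    dy = pos[None, :, 1] - pos[:, None, 1]
    rho = np.hypot(dx, dy)
    zeta = pos[None, :, 2] - pos[:, None, 2]   # z_post - z_pre
    K = interpolate_k_many(cg, rho.ravel(), zeta.ravel()).reshape(n, n)
    np.clip(K, 0.0, None, out=K)
    np.fill_diagonal(K, 0.0)
    p = -np.expm1(-K)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    a = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)
    w = np.where(p > 0, K / np.where(p > 0, p, 1.0), 1.0)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(a, w, K, layout)


def bernoulli_weight(K) -> tuple[np.ndarray, np.ndarray]:
    """Edge probability p = 1 - exp(-K) and weight w = K / p.

    At K = 0 the weight takes its continuous limit w = 1 (K/p -> 1 as
    K -> 0), so weights are defined for every pair, including those whose
    connection can never be realized; E[a w] = K holds in all cases."""
    K = np.asarray(K, float)
    p = -np.expm1(-K)
    w = np.where(p > 0, K / np.where(p > 0, p, 1.0), 1.0)
    return p, w


def save_network(net: WeightedNetwork, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("adjacency", data=net.adjacency)
        f.create_dataset("weights", data=net.weights)
        f.create_dataset("K", data=net.K)
        if net.layout is not None:
            f.create_dataset("positions", data=net.layout.positions)
            f.attrs["radius"] = net.layout.radius
            f.attrs["height"] = net.layout.height
            f.attrs["min_distance"] = net.layout.min_distance


def load_network(path) -> WeightedNetwork:
    import h5py

    with h5py.File(path, "r") as f:
        layout = None
        if "positions" in f:
            layout = SomaLayout(f["positions"][:], float(f.attrs["radius"]),
                                float(f.attrs["height"]),
                                float(f.attrs["min_distance"]))
        return WeightedNetwork(f["adjacency"][:], f["weights"][:], f["K"][:], layout)
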