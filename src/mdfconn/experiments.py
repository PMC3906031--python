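"""Scripted, seeded computational experiments.

Three studies, each reproducible under (configuration, seed):

* sparse-data variability: how the spread of the uniform-orientation
  estimate K_U across replicate ensembles shrinks with sample size;
* kernel-method variability: spread of the Gaussian-smoothing estimate
  K_S across individual neurons for several kernel widths sigma;
* economic small-world study: efficiency and cost of generated networks
  in cylinders of equal volume but different shape.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .connectivity import (Displacement, SynapseParams, connectivity_map,
                           k_kernel, k_uniform)
from .efficiency import efficiency_report
from .mdf import estimate_mdf
from .morphogen import GrowthParams, derive_seeds, grow_ensemble
from .morphology import segment_inventory
from .netgen import build_network, place_somata

__all__ = ["variability_vs_sample_size", "kernel_sigma_sweep",
           "network_efficiency_experiment"]

# Table-3 study geometry: equal-volume cylinders (radius, height) in um --
# a tall pipe, an intermediate cylinder and a flat disc -- at a packing
# density of 75,000 neurons/mm^3 for the full-scale 2000-neuron network.
DEFAULT_SHAPES = ((130.0, 500.0), (200.0, 212.0), (500.0, 34.0))
REFERENCE_DENSITY_MM3 = 75_000.0


def _stats(values: np.ndarray) -> dict:
    values = np.asarray(values, float)
    return {
        "mean": float(values.mean()),
        "std": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
        "min": float(values.min()),
        "max": float(values.max()),
        "n_values": int(len(values)),
    }


def variability_vs_sample_size(sizes=(10, 40, 160), n_replicates: int = 20,
                               displacements=((30.0, 0.0),),
                               params: GrowthParams | None = None,
                               seed: int = 0,
                               synapse: SynapseParams = SynapseParams(),
                               h: float = 2.0, r_max: float = 340.0,
                               z_range=(-480.0, 480.0)) -> pd.DataFrame:
    """Spread of K_U across replicate ensembles, per sample size.

    For every sample size and replicate an independent ensemble is grown,
    an axonal/dendritic MDF pair estimated, and K_U computed at each
    displacement; rows hold mean/std/min/max over replicates.
    """
    sizes = list(sizes)
    if sorted(sizes) != sizes:
        raise ValueError("sizes must be ascending")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    params = params or GrowthParams()
    ds = [Displacement(*d) for d in displacements]
    master = derive_seeds(seed, len(sizes) * n_replicates)
    rows = []
    k_values: dict[tuple, list] = {}
    idx = 0
    for size in sizes:
        ks = {d: [] for d in ds}
        for _ in range(n_replicates):
            ens = grow_ensemble(params, size, int(master[idx]))
            idx += 1
            ga = estimate_mdf(ens, "axonal", h, r_max, z_range)
            gd = estimate_mdf(ens, "dendritic", h, r_max, z_range)
            for d in ds:
                ks[d].append(k_uniform(ga, gd, d, synapse))
        for d in ds:
            rows.append({"n": size, "rho": d.rho, "zeta": d.zeta,
                         **_stats(np.array(ks[d]))})
            k_values[(size, d.rho, d.zeta)] = ks[d]
    df = pd.DataFrame(rows)
    df.attrs["k_values"] = k_values
    return df


def kernel_sigma_sweep(n_neurons: int = 10, sigmas=(10.0, 20.0, 30.0),
                       displacements=((30.0, 0.0, 0.0), (0.0, 30.0, 0.0)),
                       params: GrowthParams | None = None, seed: int = 0,
                       synapse: SynapseParams = SynapseParams()) -> pd.DataFrame:
    """Spread of the Gaussian-kernel estimate K_S across single neurons.

    Each neuron's axonal inventory is combined with the same neuron's
    dendritic inventory.  ``displacements`` are full 3-D vectors
    (dx, dy, dz); symmetry-equivalent vectors (equal horizontal magnitude
    and dz) reduce to the same canonical (rho, zeta) and the per-sigma
    statistics are pooled over them.
    """
    if any(s <= 0 for s in sigmas):
        raise ValueError("sigmas must be positive")
    params = params or GrowthParams()
    ens = grow_ensemble(params, n_neurons, seed)
    invs_a = [segment_inventory(m).query("kind == 'axon'") for m in ens]
    invs_d = [segment_inventory(m).query("kind != 'axon'") for m in ens]
    ds = [Displacement.from_vector(*v) for v in displacements]
    rows = []
    for sigma in sigmas:
        pooled = []
        for d in ds:
            for ia, idn in zip(invs_a, invs_d):
                pooled.append(k_kernel(ia, idn, d, synapse, sigma=sigma))
        rows.append({"sigma": float(sigma), **_stats(np.array(pooled))})
    return pd.DataFrame(rows)


def network_efficiency_experiment(shapes=DEFAULT_SHAPES, n: int = 200,
                                  params: GrowthParams | None = None,
                                  seed: int = 0,
                                  n_morphologies: int = 50,
                                  synapse: SynapseParams = SynapseParams(
                                      s=2.0, integration_step=4.0),
                                  rho_max: float = 300.0, zeta_max: float = 300.0,
                                  lattice_step: float = 20.0,
                                  h: float = 2.0,
                                  cg=None) -> pd.DataFrame:
    """Efficiency and cost of generated networks per cylinder shape.

    Grows an ensemble, tabulates K_U on a (rho, zeta) lattice (unless a
    precomputed ConnectivityGrid is supplied), then for each (R, H) places
    ``n`` somata, draws a network and computes the efficiency report.
    """
    params = params or GrowthParams()
    seeds = derive_seeds(seed, 2 + 2 * len(shapes))
    if cg is None:
        ens = grow_ensemble(params, n_morphologies, int(seeds[0]))
        ga = estimate_mdf(ens, "axonal", h, rho_max + 40, (-zeta_max - 40, zeta_max + 40))
        gd = estimate_mdf(ens, "dendritic", h, rho_max + 40, (-zeta_max - 40, zeta_max + 40))
        rhos = np.arange(0.0, rho_max + lattice_step / 2, lattice_step)
        zetas = np.arange(-zeta_max, zeta_max + lattice_step / 2, lattice_step)
        cg = connectivity_map(ga, gd, rhos, zetas, synapse)
    rows = []
    for k, (R, H) in enumerate(shapes):
        density = n / (np.pi * R * R * H * 1e-9)  # neurons per mm^3
        if n >= 1000 and abs(density / REFERENCE_DENSITY_MM3 - 1.0) > 0.1:
            warnings.warn(
                f"density {density:.0f} mm^-3 for shape (R={R}, H={H}) deviates "
                f">10% from the reference {REFERENCE_DENSITY_MM3:.0f} mm^-3")
        layout = place_somata(n, R, H, 20.0, int(seeds[2 + 2 * k]))
        net = build_network(layout, cg, int(seeds[3 + 2 * k]))
        rep = efficiency_report(net)
        rows.append({"radius": R, "height": H,
                     "global_efficiency": rep.global_efficiency,
                     "local_efficiency": rep.local_efficiency,
                     "cost": rep.cost, "n": n,
                     "density_mm3": density})
    df = pd.DataFrame(rows)
    df.attrs["connectivity_grid"] = cg
    return df
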