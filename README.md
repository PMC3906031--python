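# mdfconn

Morpho-density fields for estimating neural connectivity.

Synaptic connectivity in cortex is hard to measure directly: it requires
knowing where axons of one neuron pass close to dendrites of another, over
many neuron pairs. `mdfconn` implements the *morpho-density field* (MDF)
approach: instead of juxtaposing a handful of reconstructed neurons, it
estimates smooth axonal and dendritic density fields from a large ensemble
of generated morphologies and derives the expected number of *potential
synapses* — sites where an axonal and a dendritic segment pass within a
threshold distance *s* — between neuron pairs at any soma displacement.
The package is aimed at computational neuroscientists studying the link
between single-neuron morphology and network-level connectivity.

## What it computes

A morphology ensemble (layer 2/3 pyramidal-like: downward axon, upward
apical dendrite, 4–8 basal dendrites) is grown by a seeded stochastic
model or read from SWC files. With somata superimposed at the origin and
the apical axis along *z*, the MDF

ρ̂(r, z)  [µm of segment length per µm³]

is estimated by exact segment–voxel deposition followed by azimuthal
(cylindrical) averaging. Connectivity between a pre-synaptic neuron and a
post-synaptic neuron displaced by d = (ρ, ζ) is then estimated three ways:

* **K_U** (uniform orientations): K_U(d) = (π/4) · 2s · Σ_v ρ̂_a(x_v) ρ̂_d(x_v − d) ΔV,
  the overlap integral of the two fields; π/4 is the mean |sin θ| between
  two uniformly distributed orientations.
* **K_O** (actual orientations): the same integral with both densities
  resolved into seven principal orientation axes and each channel pair
  weighted by |sin θ_ij|.
* **K_S** (kernel smoothing): a closed-form double sum over the segment
  inventories of two individual neurons convolved with a Gaussian kernel
  of width σ.

A direct geometric counter (exact clamped segment–segment distances,
contact-site clustering) serves as the Monte-Carlo oracle for all three.
From a stored K(ρ, ζ) surface the package generates random directed
weighted networks (edge probability p = 1 − e^(−K), weight w = K/p, so
that E[a·w] = K) and evaluates Latora–Marchiori global efficiency, local
efficiency and cost — the weighted economic small-world measures.

## Worked example

```python
import numpy as np
from mdfconn import (GrowthParams, grow_ensemble, estimate_mdf, total_mass,
                     Displacement, SynapseParams, k_uniform,
                     count_potential_synapses)
from mdfconn.morphogen import covering_extent

params = GrowthParams()
ens = grow_ensemble(params, 500, seed=1)
r_max, z_range = covering_extent(params)
mdf_a = estimate_mdf(ens, "axonal", h=1.0, r_max=r_max, z_range=z_range)
mdf_d = estimate_mdf(ens, "dendritic", h=1.0, r_max=r_max, z_range=z_range)
print(f"mean axon length      {total_mass(mdf_a):8.1f} um")

d = Displacement(rho=30.0, zeta=0.0)
K = k_uniform(mdf_a, mdf_d, d, SynapseParams(s=2.0))
rng = np.random.default_rng(0)
pairs = rng.integers(0, 500, size=(300, 2))
counts = [count_potential_synapses(ens[i], ens[j], d)
          for i, j in pairs if i != j]
print(f"K_U(30, 0)            {K:8.3f}")
print(f"direct count (mean)   {np.mean(counts):8.3f}")
```

Output from this exact script:

```
mean axon length        1119.5 um
K_U(30, 0)               1.292
direct count (mean)      1.431
```

The overlap integral (1.292 expected potential synapses for a 30 µm
horizontal soma offset) agrees with the direct geometric count over random
morphology pairs (1.431 ± 0.118 SE) — the estimator and the definition of
a potential synapse are mutually consistent.

The same pipeline is available from the shell:

```sh
mdfconn grow --n 500 --seed 1 --out neurons/
mdfconn mdf --in neurons/ --kind axonal --out mdf_a.h5
mdfconn mdf --in neurons/ --kind dendritic --out mdf_d.h5
mdfconn connect --mdf-a mdf_a.h5 --mdf-d mdf_d.h5 --rho 0:150:10 --zeta -90:90:10 --out k.csv
mdfconn network --k k.csv --n 200 --radius 130 --height 500 --seed 7 --out net.h5
mdfconn efficiency --net net.h5 --out report.json
```

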