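"""Seeded stochastic generator of pyramidal-like neuron morphologies.

A phenomenological stand-in for full neurite-outgrowth simulators: at each
of ``n_steps`` fixed time increments every growth cone (terminal) elongates
by a fixed step length in a direction drawn from a von Mises-Fisher
distribution centred on its current direction, and bifurcates with a
probability that decays exponentially with centrifugal order.  The model
reproduces the qualitative constraints of layer 2/3 pyramidal neurons: a
downward axon root, an upward apical dendrite, 4-8 lateral/downward basal
dendrites, and extensive branching, with statistical cylindrical symmetry
about the vertical (apical) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .morphology import AXON, BASAL, APICAL, Morphology

__all__ = ["GrowthParams", "grow_neuron", "grow_ensemble", "orientation_histogram"]


def _per_kind(value, name: str) -> np.ndarray:
    """Normalize a scalar or {axon, basal, apical} mapping to a 3-vector
    indexed by kind code."""
    if isinstance(value, dict):
        try:
            arr = np.array([value["axon"], value["basal"], value["apical"]], float)
        except KeyError as exc:
            raise ConfigurationError(f"{name}: missing arbor kind {exc}") from None
    else:
        arr = np.full(3, float(value))
    return arr


@dataclass
class GrowthParams:
    """Parameters of the stochastic outgrowth model.

    All lengths in micrometres.  ``step_length``, ``branch_prob`` and
    ``turning_concentration`` accept either a scalar or a mapping with keys
    ``axon`` / ``basal`` / ``apical``.

    Attributes
    ----------
    n_steps : growth duration in fixed time increments (default 180,
        i.e. 18 simulated days at 10 increments per day).
    step_length : elongation per terminal per increment.
    branch_prob : per-terminal per-increment bifurcation probability at
        centrifugal order 0; the effective probability is
        ``branch_prob * 2**(-order_decay * order)``.
    order_decay : exponential decay rate of branching with centrifugal order.
    turning_concentration : von Mises-Fisher concentration of the step
        direction about the previous direction (0 = isotropic turning).
    branch_concentration : vMF concentration of daughter directions about
        the parent direction at a bifurcation.
    n_basal_range : inclusive integer interval for the basal dendrite count.
    polar_range_* : initial polar-angle interval (radians, measured from
        the +z apical axis) of the root direction per arbor kind.
    soma_radius : radius of the spherical soma; roots start on its surface.
    """

    n_steps: int = 180
    step_length: object = field(default_factory=lambda: {
        "axon": 3.0, "basal": 1.4, "apical": 2.2})
    branch_prob: object = field(default_factory=lambda: {
        "axon": 0.012, "basal": 0.006, "apical": 0.010})
    order_decay: float = 1.0
    turning_concentration: object = 12.0
    branch_concentration: float = 4.0
    n_basal_range: tuple[int, int] = (4, 8)
    polar_range_axon: tuple[float, float] = (np.deg2rad(160.0), np.pi)
    polar_range_apical: tuple[float, float] = (0.0, np.deg2rad(20.0))
    polar_range_basal: tuple[float, float] = (np.deg2rad(95.0), np.deg2rad(150.0))
    soma_radius: float = 10.0

    def validate(self) -> "GrowthParams":
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        sl = _per_kind(self.step_length, "step_length")
        if np.any(sl <= 0):
            raise ConfigurationError("step_length must be positive")
        bp = _per_kind(self.branch_prob, "branch_prob")
        if np.any(bp < 0) or np.any(bp > 1):
            raise ConfigurationError("branch_prob must lie in [0, 1]")
        kappa = _per_kind(self.turning_concentration, "turning_concentration")
        if np.any(kappa < 0) or self.branch_concentration < 0:
            raise ConfigurationError("concentrations must be >= 0")
        lo, hi = self.n_basal_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("n_basal_range must be an interval of positive ints")
        for rng in (self.polar_range_axon, self.polar_range_apical, self.polar_range_basal):
            a, b = rng
            if not (0 <= a <= b <= np.pi + 1e-12):
                raise ConfigurationError("polar ranges must satisfy 0 <= lo <= hi <= pi")
        if self.order_decay < 0:
            raise ConfigurationError("order_decay must be >= 0")
        if self.soma_radius <= 0:
            raise ConfigurationError("soma_radius must be positive")
        return self


def _sample_vmf(rng: np.random.Generator, mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Draw unit vectors from vMF(mu_i, kappa_i), vectorized over rows.

    Uses the standard inverse-CDF of the cosine w = cos(angle to mu):
    w = 1 + log(u + (1-u) e^(-2k)) / k, reducing to w ~ Uniform(-1, 1) as
    k -> 0 (isotropic).
    """
    n = len(mu)
    u = rng.random(n)
    w = np.empty(n)
    pos = kappa > 1e-12
    kp = kappa[pos]
    w[pos] = 1.0 + np.log(u[pos] + (1.0 - u[pos]) * np.exp(-2.0 * kp)) / kp
    w[~pos] = 2.0 * u[~pos] - 1.0
    np.clip(w, -1.0, 1.0, out=w)

    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    # orthonormal frame perpendicular to mu
    helper = np.zeros_like(mu)
    use_x = np.abs(mu[:, 2]) > 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 2] = 1.0
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    out = (w[:, None] * mu
           + (s * np.cos(phi))[:, None] * e1
           + (s * np.sin(phi))[:, None] * e2)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _root_directions(rng, n, polar_range, azimuths=None):
    """Unit vectors with polar angle uniform in ``polar_range`` (from +z)."""
    theta = rng.uniform(polar_range[0], polar_range[1], n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n) if azimuths is None else azimuths
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def grow_neuron(params: GrowthParams, seed: int) -> Morphology:
    """Grow one morphology; identical (params, seed) gives identical output."""
    params.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    step_len = _per_kind(params.step_length, "step_length")
    branch_p = _per_kind(params.branch_prob, "branch_prob")
    kappa = _per_kind(params.turning_concentration, "turning_concentration")

    n_basal = int(rng.integers(params.n_basal_range[0], params.n_basal_range[1] + 1))
    root_dirs = [
        _root_directions(rng, 1, params.polar_range_axon),
        _root_directions(rng, 1, params.polar_range_apical),
        _root_directions(rng, n_basal, params.polar_range_basal,
                         # spread basal roots roughly evenly in azimuth
                         azimuths=(2 * np.pi * (np.arange(n_basal)
                                                + rng.random(n_basal) * 0.8) / n_basal)),
    ]
    dirs = np.vstack([root_dirs[0], root_dirs[1], root_dirs[2]])
    kinds = np.concatenate([[AXON], [APICAL], np.full(n_basal, BASAL)]).astype(np.int8)
    pos = dirs * params.soma_radius
    order = np.zeros(len(dirs), dtype=np.int64)
    parent_seg = np.full(len(dirs), -1, dtype=np.int64)

    starts_acc, ends_acc, kinds_acc, parents_acc = [], [], [], []
    n_segs = 0
    for step in range(params.n_steps):
        t = len(pos)
        if step == 0:
            # root segments extend exactly along the sampled initial
            # direction so root-orientation invariants hold by construction
            new_dir = dirs.copy()
        else:
            new_dir = _sample_vmf(rng, dirs, kappa[kinds])
        new_pos = pos + step_len[kinds][:, None] * new_dir
        seg_ids = n_segs + np.arange(t)
        starts_acc.append(pos)
        ends_acc.append(new_pos)
        kinds_acc.append(kinds.copy())
        parents_acc.append(parent_seg.copy())
        n_segs += t

        p_b = branch_p[kinds] * np.exp2(-params.order_decay * order)
        split = rng.random(t) < p_b
        if np.any(split):
            mu = new_dir[split]
            kap = np.full(split.sum(), params.branch_concentration)
            d1 = _sample_vmf(rng, mu, kap)
            d2 = _sample_vmf(rng, mu, kap)
            keep = ~split
            pos = np.vstack([new_pos[keep], new_pos[split], new_pos[split]])
            dirs = np.vstack([new_dir[keep], d1, d2])
            kinds = np.concatenate([kinds[keep], kinds[split], kinds[split]])
            order = np.concatenate([order[keep], order[split] + 1, order[split] + 1])
            parent_seg = np.concatenate([seg_ids[keep], seg_ids[split], seg_ids[split]])
        else:
            pos, dirs = new_pos, new_dir
            parent_seg = seg_ids

    return Morphology(np.vstack(starts_acc), np.vstack(ends_acc),
                      np.concatenate(kinds_acc), np.concatenate(parents_acc),
                      soma_center=np.zeros(3), soma_radius=params.soma_radius)


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-neuron seeds from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n)


def grow_ensemble(params: GrowthParams, n: int, seed: int) -> list[Morphology]:
    """Grow ``n`` independent morphologies from one master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [grow_neuron(params, int(s)) for s in derive_seeds(seed, n)]


def orientation_histogram(ensemble, kind: str = "dendrite", n_bins: int = 36):
    """Azimuth / polar histograms of segment orientations over an ensemble.

    One count per segment.  Under orientations uniform on the unit sphere
    the azimuth is uniform on [0, 2pi) and the polar angle (from +z) has
    density sin(theta)/2 on [0, pi].

    Returns a dict with bin counts and edges for both angles.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    us = []
    for m in ensemble:
        us.append(m.orientations[m.mask(kind)])
    u = np.vstack(us)
    azimuth = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2.0 * np.pi)
    polar = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    az_counts, az_edges = np.histogram(azimuth, bins=n_bins, range=(0.0, 2.0 * np.pi))
    po_counts, po_edges = np.histogram(polar, bins=n_bins, range=(0.0, np.pi))
    return {
        "azimuth_counts": az_counts, "azimuth_edges": az_edges,
        "polar_counts": po_counts, "polar_edges": po_edges,
        "n_segments": len(u),
    }


def ensemble_summary(ensemble) -> pd.DataFrame:
    """Per-neuron totals used for sanity checks and reports."""
    rows = []
    for m in ensemble:
        rows.append({
            "n_segments": m.n_segments,
            "n_basal": m.n_basal,
            "axon_length": m.total_length("axon"),
            "dendrite_length": m.total_length("dendrite"),
            "max_radius": float(np.hypot(m.ends[:, 0], m.ends[:, 1]).max()),
        })
    return pd.DataFrame(rows)


def covering_extent(params: GrowthParams) -> tuple[float, tuple[float, float]]:
    """Cylindrical extent (r_max, z_range) guaranteed to contain every
    segment any morphology grown with ``params`` can produce (worst-case
    reach: n_steps * max step length from the soma surface)."""
    reach = params.n_steps * float(np.max(_per_kind(params.step_length, "step_length")))
    r = float(np.ceil((reach + params.soma_radius) / 10.0) * 10.0)
    return r, (-r, r)


def isotropic_params(**overrides) -> GrowthParams:
    """Growth parameters with fully isotropic turning (concentration 0),
    giving segment orientations uniform on the unit sphere; used for
    validating the uniform-orientation connectivity estimator."""
    p = GrowthParams(turning_concentration=0.0, branch_concentration=0.0)
    return replace(p, **overrides) if overrides else p
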