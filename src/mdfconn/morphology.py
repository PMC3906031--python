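"""Neuron morphologies as flat segment arrays, SWC interchange, and segment inventories.

A morphology is a soma plus three classes of neurite arbors (one axon, one
apical dendrite, several basal dendrites), each a rooted tree of straight
3-D line segments anchored at the soma surface.  Segments are stored in
flat numpy arrays (start, end, kind, parent index) rather than node
objects, which keeps ensemble-scale operations vectorizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SWCParseError

# Arbor kind codes (internal); SWC type codes are mapped at the I/O boundary.
AXON = 0
BASAL = 1
APICAL = 2

KIND_NAMES = {AXON: "axon", BASAL: "basal", APICAL: "apical"}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}

# SWC structure identifiers: 1 soma, 2 axon, 3 (basal) dendrite, 4 apical dendrite.
_SWC_FROM_KIND = {AXON: 2, BASAL: 3, APICAL: 4}
_KIND_FROM_SWC = {2: AXON, 3: BASAL, 4: APICAL}


@dataclass
class Morphology:
    """A single neuron: soma sphere plus segment trees.

    Parameters
    ----------
    starts, ends : (M, 3) float arrays, segment endpoints in micrometres.
    kinds : (M,) int array of arbor kind codes (AXON / BASAL / APICAL).
    parents : (M,) int array; index of the parent segment, -1 for a root
        segment emerging from the soma surface.
    soma_center : (3,) position, conventionally the origin.
    soma_radius : micrometres.
    """

    starts: np.ndarray
    ends: np.ndarray
    kinds: np.ndarray
    parents: np.ndarray
    soma_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    soma_radius: float = 10.0

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float).reshape(-1, 3)
        self.ends = np.asarray(self.ends, dtype=float).reshape(-1, 3)
        self.kinds = np.asarray(self.kinds, dtype=np.int8).reshape(-1)
        self.parents = np.asarray(self.parents, dtype=np.int64).reshape(-1)
        self.soma_center = np.asarray(self.soma_center, dtype=float).reshape(3)
        n = len(self.starts)
        if not (len(self.ends) == len(self.kinds) == len(self.parents) == n):
            raise ValueError("segment arrays must have equal length")

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.ends - self.starts, axis=1)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def orientations(self) -> np.ndarray:
        """Unit direction of each segment (start -> end)."""
        d = self.ends - self.starts
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def mask(self, kind: str) -> np.ndarray:
        """Boolean mask selecting segments of one arbor class.

        ``kind`` is 'axon', 'apical', 'basal', 'dendrite' (apical + basal),
        'axonal' or 'dendritic'.
        """
        if kind in ("axon", "axonal"):
            return self.kinds == AXON
        if kind == "apical":
            return self.kinds == APICAL
        if kind == "basal":
            return self.kinds == BASAL
        if kind in ("dendrite", "dendritic"):
            return self.kinds != AXON
        raise ValueError(f"unknown arbor kind {kind!r}")

    @property
    def n_basal(self) -> int:
        """Number of basal dendrites = number of basal root segments."""
        return int(np.sum((self.parents == -1) & (self.kinds == BASAL)))

    def total_length(self, kind: str = "dendrite") -> float:
        m = self.mask(kind)
        return float(self.lengths[m].sum())

    def translated(self, offset) -> "Morphology":
        off = np.asarray(offset, dtype=float).reshape(3)
        return Morphology(self.starts + off, self.ends + off, self.kinds,
                          self.parents, self.soma_center + off, self.soma_radius)


def segment_inventory(m: Morphology) -> pd.DataFrame:
    """One row per segment: midpoint, length, unit orientation, arbor kind.

    This is the (position, length, orientation) characterization each
    segment contributes to the kernel-smoothing connectivity estimator.
    """
    mid = m.midpoints
    u = m.orientations
    return pd.DataFrame({
        "x": mid[:, 0], "y": mid[:, 1], "z": mid[:, 2],
        "length": m.lengths,
        "ux": u[:, 0], "uy": u[:, 1], "uz": u[:, 2],
        "kind": [KIND_NAMES[k] for k in m.kinds],
    })


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as standard 7-column SWC.

    The soma is a single type-1 node; every segment endpoint becomes one
    node.  Root segments attach their start node to the soma node.
    """
    lines = ["# index type x y z radius parent"]
    cx, cy, cz = m.soma_center
    lines.append(f"1 1 {cx:.6f} {cy:.6f} {cz:.6f} {m.soma_radius:.6f} -1")
    next_id = 2
    end_node = np.empty(m.n_segments, dtype=np.int64)
    neurite_radius = 0.5  # diameter is not modelled; nominal value
    order = _topological_order(m.parents)
    for i in order:
        t = _SWC_FROM_KIND[int(m.kinds[i])]
        if m.parents[i] == -1:
            x, y, z = m.starts[i]
            lines.append(f"{next_id} {t} {x:.6f} {y:.6f} {z:.6f} {neurite_radius} 1")
            parent_node = next_id
            next_id += 1
        else:
            parent_node = end_node[m.parents[i]]
        x, y, z = m.ends[i]
        lines.append(f"{next_id} {t} {x:.6f} {y:.6f} {z:.6f} {neurite_radius} {parent_node}")
        end_node[i] = next_id
        next_id += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _topological_order(parents: np.ndarray) -> np.ndarray:
    """Segment indices ordered parents-before-children."""
    n = len(parents)
    order = np.empty(n, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    k = 0
    # repeated sweeps; generator output is already near-topological so
    # this terminates in very few passes
    pending = np.arange(n)
    while len(pending):
        ready = [i for i in pending if parents[i] == -1 or done[parents[i]]]
        if not ready:
            raise ValueError("segment parent references contain a cycle")
        for i in ready:
            order[k] = i
            done[i] = True
            k += 1
        pending = np.array([i for i in pending if not done[i]], dtype=np.int64)
    return order


def read_swc(path) -> Morphology:
    """Parse an SWC file into a Morphology.

    Raises :class:`SWCParseError` (with the offending line number) on
    malformed rows, dangling parent references, or cyclic topology.
    """
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    lineno_of: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                idx = int(parts[0]); t = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"unparseable field: {exc}", lineno) from None
            if idx in nodes:
                raise SWCParseError(f"duplicate node index {idx}", lineno)
            nodes[idx] = (t, x, y, z, r, parent)
            lineno_of[idx] = lineno

    soma_id = None
    for idx, (t, *_rest) in nodes.items():
        if t == 1:
            soma_id = idx
            break
    if soma_id is None:
        raise SWCParseError("no soma (type 1) node found")
    soma = nodes[soma_id]
    soma_center = np.array(soma[1:4])
    soma_radius = soma[4]

    # validate parent references and acyclicity
    for idx, (t, x, y, z, r, parent) in nodes.items():
        if parent != -1 and parent not in nodes:
            raise SWCParseError(f"parent id {parent} references missing node",
                                lineno_of[idx])
    for idx in nodes:
        seen = set()
        cur = idx
        while cur != -1:
            if cur in seen:
                raise SWCParseError("cyclic parent chain", lineno_of[idx])
            seen.add(cur)
            cur = nodes[cur][5]

    starts, ends, kinds, parents = [], [], [], []
    seg_of_node: dict[int, int] = {}
    # nodes in index order give deterministic segment order; parent segments
    # may appear later, so resolve parent segment ids in a second pass
    neurite_nodes = [i for i in sorted(nodes) if nodes[i][0] != 1]
    for idx in neurite_nodes:
        t, x, y, z, r, parent = nodes[idx]
        if t not in _KIND_FROM_SWC:
            raise SWCParseError(f"unsupported SWC type {t}", lineno_of[idx])
        if parent == -1 or nodes[parent][0] == 1:
            continue  # arbor start node: no segment of its own
        px, py, pz = nodes[parent][1:4]
        seg_of_node[idx] = len(starts)
        starts.append((px, py, pz))
        ends.append((x, y, z))
        kinds.append(_KIND_FROM_SWC[t])
        parents.append(parent)  # node id for now
    parent_segs = [seg_of_node.get(p, -1) for p in parents]
    return Morphology(np.array(starts).reshape(-1, 3), np.array(ends).reshape(-1, 3),
                      np.array(kinds, dtype=np.int8),
                      np.array(parent_segs, dtype=np.int64),
                      soma_center, soma_radius)
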