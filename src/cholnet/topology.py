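"""E-I lattice geometry and the weighted directed synaptic graph.

400 excitatory cells sit on a 20x20 lattice and 100 inhibitory cells on a
10x10 lattice, each I cell at the center of a 2x2 block of E cells.  Both
lattices are periodic.  Connectivity is local-excitation / global-inhibition:
every E cell projects to its 40 nearest E cells and 10 nearest I cells, while
every I cell projects to all E cells and all other I cells.  Synaptic weights
take one of four class values (E-E, E-I, I-I, I-E).

Internal cell indices are 0-based (E: 0..399, I: 400..499); IDs written to
rasters and edge lists are 1-based, so E cells are 1..400 and I cells 401..500.
Within a lattice, index = y + x * L (column-major by lattice column).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

N_E = 400
N_I = 100
N_CELLS = N_E + N_I


@dataclass(frozen=True)
class LatticeGeometry:
    """Side lengths of the nested E and I lattices (lattice unit = minimal
    E-cell spacing = 1)."""

    L_E: int = 20
    L_I: int = 10

    def __post_init__(self) -> None:
        if self.L_E != 2 * self.L_I:
            raise ValueError("E lattice side must be twice the I lattice side")

    @property
    def n_exc(self) -> int:
        return self.L_E**2

    @property
    def n_inh(self) -> int:
        return self.L_I**2

    @property
    def n_cells(self) -> int:
        return self.n_exc + self.n_inh


@dataclass(frozen=True)
class SynapseParams:
    """Class synaptic strengths (mS/cm^2), shared decay constant (ms) and
    reversal potentials (mV)."""

    wEE: float = 0.01
    wEI: float = 0.05   # E -> I
    wII: float = 0.04
    wIE: float = 0.04   # I -> E
    tau_exc: float = 3.0
    tau_inh: float = 3.0
    E_exc: float = 0.0
    E_inh: float = -75.0


@dataclass
class NetworkTopology:
    """Weighted directed synaptic graph; ``w[i, j]`` is the weight of the
    synapse from cell j onto cell i (0 if absent)."""

    w: np.ndarray                    # (N, N) float
    cell_kind: np.ndarray            # (N,) of 'E'/'I'
    positions: np.ndarray            # (N, 2) in E-lattice units
    geometry: LatticeGeometry = field(default_factory=LatticeGeometry)

    @property
    def n_exc(self) -> int:
        return self.geometry.n_exc

    def out_targets(self, j: int) -> np.ndarray:
        return np.nonzero(self.w[:, j])[0]


def cell_id(x: int, y: int, kind: str, geom: LatticeGeometry = LatticeGeometry()) -> int:
    """Emitted (1-based) ID of the cell at lattice coordinates (x, y)."""
    L = geom.L_E if kind == "E" else geom.L_I
    if not (0 <= x < L and 0 <= y < L):
        raise ValueError(f"coordinates ({x}, {y}) outside the {kind} lattice (L={L})")
    idx = y + x * L
    return idx + 1 if kind == "E" else geom.n_exc + idx + 1


def periodic_offset(p, q, L: float) -> np.ndarray:
    """Minimum-image displacement q - p on a periodic domain of side L
    (components wrapped into [-L/2, L/2))."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return (d + L / 2.0) % L - L / 2.0


def periodic_distance(p, q, L: float) -> float:
    """Euclidean distance under the minimum-image convention."""
    return float(np.hypot(*periodic_offset(p, q, L)))


def _positions(geom: LatticeGeometry) -> np.ndarray:
    """Positions of all cells in E-lattice units; I cells sit at the centers
    of their 2x2 E blocks (offset +0.5 after doubling their coordinates)."""
    pos = np.empty((geom.n_cells, 2))
    for x in range(geom.L_E):
        for y in range(geom.L_E):
            pos[y + x * geom.L_E] = (x, y)
    for x in range(geom.L_I):
        for y in range(geom.L_I):
            pos[geom.n_exc + y + x * geom.L_I] = (2 * x + 0.5, 2 * y + 0.5)
    return pos


def nearest_cells(origin, candidates: np.ndarray, k: int, L: float,
                  cand_idx: np.ndarray | None = None) -> np.ndarray:
    """Indices of the k candidates nearest to ``origin`` under the periodic
    metric.

    Equidistant candidates are ranked by angle of the minimum-image offset
    from the +x axis (in [0, 2pi)), then by index — a deterministic rule, since
    the exact-k neighborhood on a lattice necessarily cuts through tied shells.
    """
    if cand_idx is None:
        cand_idx = np.arange(len(candidates))
    d = periodic_offset(origin, candidates, L)
    dist = np.hypot(d[:, 0], d[:, 1])
    ang = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2.0 * np.pi)
    order = np.lexsort((cand_idx, ang, np.round(dist, 9)))
    return cand_idx[order[:k]]


def build_default_topology(geom: LatticeGeometry = LatticeGeometry(),
                           syn: SynapseParams = SynapseParams()) -> NetworkTopology:
    """Construct the local-excitation / global-inhibition network.

    E out-degrees are exactly 40 (E targets) + 10 (I targets); I cells target
    all E cells and all other I cells (autapses excluded).
    """
    pos = _positions(geom)
    nE, nI, N = geom.n_exc, geom.n_inh, geom.n_cells
    w = np.zeros((N, N))
    e_idx = np.arange(nE)
    i_idx = np.arange(nE, N)
    for j in range(nE):
        others = e_idx[e_idx != j]
        targets = nearest_cells(pos[j], pos[others], 40, geom.L_E, others)
        w[targets, j] = syn.wEE
        itargets = nearest_cells(pos[j], pos[i_idx], 10, geom.L_E, i_idx)
        w[itargets, j] = syn.wEI
    for j in range(nE, N):
        w[:nE, j] = syn.wIE
        w[nE:, j] = syn.wII
        w[j, j] = 0.0
    kind = np.array(["E"] * nE + ["I"] * nI)
    return NetworkTopology(w=w, cell_kind=kind, positions=pos, geometry=geom)


def rewire_EE(topo: NetworkTopology, p: float, seed: int) -> NetworkTopology:
    """Rewire each E->E edge with probability p to a uniformly random E cell,
    avoiding self-loops and duplicate edges; out-degree 40 is preserved and
    all non-E->E edges are untouched."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("rewiring probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nE = topo.n_exc
    w = topo.w.copy()
    wEE_vals = w[:nE, :nE]
    for j in range(nE):
        targets = set(np.nonzero(wEE_vals[:, j])[0])
        for t in sorted(targets):
            if rng.random() < p:
                weight = w[t, j]
                w[t, j] = 0.0
                targets.discard(t)
                while True:
                    new = int(rng.integers(nE))
                    if new != j and new not in targets:
                        break
                w[new, j] = weight
                targets.add(new)
    return replace(topo, w=w)


def sparsify_inhibition(topo: NetworkTopology, density: float, w_inh: float,
                        seed: int) -> NetworkTopology:
    """Keep each I-sourced edge independently with probability ``density`` and
    re-weight the kept inhibitory edges to ``w_inh``; E-sourced edges are
    untouched."""
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    nE = topo.n_exc
    w = topo.w.copy()
    inh = w[:, nE:]
    mask = inh != 0.0
    keep = rng.random(inh.shape) < density
    inh[mask & keep] = w_inh
    inh[mask & ~keep] = 0.0
    w[:, nE:] = inh
    return replace(topo, w=w)


def write_edgelist(topo: NetworkTopology, path, header: dict | None = None) -> None:
    """Serialize as delimited text: one '# key=value' header block, then
    (source_ID, target_ID, weight) rows with 1-based IDs."""
    tgt, src = np.nonzero(topo.w)
    with open(path, "w") as fh:
        fh.write(f"# L_E={topo.geometry.L_E} L_I={topo.geometry.L_I}\n")
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("# source_id\ttarget_id\tweight\n")
        for s, t in zip(src, tgt):
            fh.write(f"{s + 1}\t{t + 1}\t{topo.w[t, s]:.6g}\n")


def read_edgelist(path) -> NetworkTopology:
    with open(path) as fh:
        text = fh.read()
    first = text.splitlines()[0]
    L_E = int(first.split("L_E=")[1].split()[0])
    geom = LatticeGeometry(L_E=L_E, L_I=L_E // 2)
    data = np.loadtxt(io.StringIO(text), comments="#")
    w = np.zeros((geom.n_cells, geom.n_cells))
    src = data[:, 0].astype(int) - 1
    tgt = data[:, 1].astype(int) - 1
    w[tgt, src] = data[:, 2]
    kind = np.array(["E"] * geom.n_exc + ["I"] * geom.n_inh)
    return NetworkTopology(w=w, cell_kind=kind, positions=_positions(geom),
                           geometry=geom)
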