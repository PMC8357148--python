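"""Spatially heterogeneous gKs ("ACh") maps on the E-cell lattice.

A map assigns each cell a maximal M-current conductance gKs in
[gks_min, gks_max] mS/cm^2.  Low gKs marks high local acetylcholine
(muscarinic blockade of the M-current); the default bounds are 0.2 and 1.5.
Maps are produced by an iterative lattice process that mimics point-source
release, diffusive spread and first-order decay of the neuromodulator:

    g(n+1) = D * Laplacian(g(n)) - R + B * (gks_max - g(n)) + g(n)

with unit time step and lattice spacing, periodic boundaries, and R = R_amp at
release sites and 0 elsewhere.  The iteration runs unclamped — the release
site accumulates a deep (negative) gKs deficit that acts as the reservoir
feeding diffusive hotspot growth — and the bounds are imposed by a hard clamp
when the map is frozen.  (Clamping every step instead would destroy the
released deficit at the source as fast as it is produced and cap hotspots at
an effective radius of ~1.7 lattice units, far below the radii the scenarios
require.)  The iteration is frozen once an isolated release site would have
produced a "hotspot" (sub-0.6 region) of the requested effective radius; the
frozen, clamped field is what the network simulation sees.  I cells inherit
the mean gKs of their 2x2 block of E cells.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

GKS_CONTOUR = 0.6  # mS/cm^2; the contour used to delimit hotspots


@dataclass(frozen=True)
class GKsMapParams:
    """Iteration parameters of the release-diffusion-decay process.

    D is the lattice diffusion coefficient (per step; keep D <= 0.2 — at the
    explicit 5-point scheme's stability boundary D = 0.25 the checkerboard
    mode is marginal and accumulates from a point source), B the decay rate toward the unmodulated
    baseline gks_max, and R_amp the per-step release magnitude at each site.
    The defaults were chosen so that single-site hotspots of effective radius
    up to ~6.5 lattice units (the largest scenario used) are reachable within
    ~100 iteration steps while the decay term screens each site's tail, so the
    background between hotspots stays near the unmodulated 1.5 mS/cm^2 even
    when many sites are superposed.
    """

    D: float = 0.15
    B: float = 0.05
    R_amp: float = 60.0
    sites: tuple[tuple[int, int], ...] = ()
    n_steps: int | None = None
    gks_min: float = 0.2
    gks_max: float = 1.5

    def __post_init__(self) -> None:
        if min(self.D, self.B, self.R_amp) < 0:
            raise ValueError("D, B and R_amp must be non-negative")
        if not self.gks_min < self.gks_max:
            raise ValueError("gks_min must be below gks_max")


@dataclass
class GKsMap:
    """Frozen per-cell gKs field: E_values on the (L_E, L_E) lattice indexed
    [x, y], I_values on the (L_I, L_I) lattice, plus generation provenance."""

    E_values: np.ndarray
    I_values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def per_cell(self) -> np.ndarray:
        """gKs per internal cell index (E cells 0..nE-1 then I cells)."""
        return np.concatenate([self.E_values.ravel(), self.I_values.ravel()])

    def hotspot_centers(self) -> list[tuple[float, float]]:
        return list(self.provenance.get("sites", []))


def _laplacian(field_: np.ndarray) -> np.ndarray:
    return (np.roll(field_, 1, 0) + np.roll(field_, -1, 0)
            + np.roll(field_, 1, 1) + np.roll(field_, -1, 1) - 4.0 * field_)


def iterate_step(current: np.ndarray, params: GKsMapParams) -> np.ndarray:
    """One (unclamped) update of the release-diffusion-decay iteration."""
    R = np.zeros_like(current)
    for (x, y) in params.sites:
        R[int(x) % current.shape[0], int(y) % current.shape[1]] += params.R_amp
    nxt = (current + params.D * _laplacian(current) - R
           + params.B * (params.gks_max - current))
    if not np.all(np.isfinite(nxt)):
        raise FloatingPointError(
            "gKs iteration diverged; check that D <= 0.2 and that B is a "
            "per-step rate well below 1")
    return nxt


def clamp(field_: np.ndarray, params: GKsMapParams) -> np.ndarray:
    """Impose the gKs bounds on a frozen field."""
    return np.clip(field_, params.gks_min, params.gks_max)


def hotspot_radius(E_values: np.ndarray, threshold: float = GKS_CONTOUR) -> float:
    """Effective radius of the modulated region: the radius of the circle
    whose area equals the count of sub-threshold cells, r = sqrt(count/pi)."""
    count = int(np.sum(np.asarray(E_values) < threshold))
    if count == 0:
        raise ValueError("no hotspot: no cell is below the threshold")
    return float(np.sqrt(count / np.pi))


@lru_cache(maxsize=64)
def _freeze_step(target_radius: float, D: float, B: float, R_amp: float,
                 gks_min: float, gks_max: float, L: int,
                 step_cap: int = 10_000) -> int:
    """Number of iteration steps after which an isolated site's hotspot first
    reaches ``target_radius`` (area-equivalent, 0.6 mS/cm^2 contour)."""
    p = GKsMapParams(D=D, B=B, R_amp=R_amp, sites=((L // 2, L // 2),),
                     gks_min=gks_min, gks_max=gks_max)
    g = np.full((L, L), gks_max)
    for step in range(1, step_cap + 1):
        g = iterate_step(g, p)
        if np.sum(clamp(g, p) < GKS_CONTOUR) >= np.pi * target_radius**2:
            return step
    raise RuntimeError(
        f"target radius {target_radius} not reached within the {step_cap}-step "
        "cap; raise R_amp or lower B so release outruns decay")


def generate_map(sites, target_radius: float | None = None,
                 params: GKsMapParams = GKsMapParams(), L: int = 20,
                 I_gks_zero: bool = False) -> GKsMap:
    """Generate a frozen gKs map from release-site coordinates.

    Iterates from the uniform ``gks_max`` field for the number of steps at
    which an isolated site reaches ``target_radius`` (or ``params.n_steps``
    if a radius is not given).  With no sites the map is the homogeneous
    no-modulation control.  ``I_gks_zero`` forces all I-cell gKs to 0 (the
    I-population-unmodulated variant).
    """
    sites = tuple((int(x), int(y)) for x, y in sites)
    for x, y in sites:
        if not (0 <= x < L and 0 <= y < L):
            raise ValueError(f"site ({x}, {y}) outside the {L}x{L} lattice")
    if target_radius is not None:
        n_steps = _freeze_step(float(target_radius), params.D, params.B,
                               params.R_amp, params.gks_min, params.gks_max, L)
    elif params.n_steps is not None:
        n_steps = params.n_steps
    else:
        n_steps = 0
    params = replace(params, sites=sites, n_steps=n_steps)
    g = np.full((L, L), params.gks_max)
    for _ in range(n_steps if sites else 0):
        g = iterate_step(g, params)
    g = clamp(g, params)
    I_values = assign_I_gks(g, zero=I_gks_zero)
    prov = {"sites": sites, "target_radius": target_radius, "n_steps": n_steps,
            "D": params.D, "B": params.B, "R_amp": params.R_amp,
            "gks_min": params.gks_min, "gks_max": params.gks_max}
    return GKsMap(E_values=g, I_values=I_values, provenance=prov)


def homogeneous_map(value: float, L: int = 20) -> GKsMap:
    """Uniform gKs control map (no spatial modulation)."""
    E = np.full((L, L), float(value))
    return GKsMap(E_values=E, I_values=assign_I_gks(E),
                  provenance={"sites": (), "homogeneous": float(value)})


def random_sites(n: int, seed: int, L: int = 20) -> list[tuple[int, int]]:
    """n release-site positions drawn uniformly on the E lattice (sites may
    coincide or be adjacent, so hotspots can overlap and coalesce)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return [tuple(xy) for xy in rng.integers(0, L, size=(n, 2))]


def assign_I_gks(E_values: np.ndarray, zero: bool = False) -> np.ndarray:
    """I-cell gKs: the arithmetic mean of the 2x2 E block centered on each I
    cell (or all zeros for the unmodulated-I variant)."""
    E = np.asarray(E_values, dtype=float)
    L = E.shape[0]
    if zero:
        return np.zeros((L // 2, L // 2))
    return E.reshape(L // 2, 2, L // 2, 2).mean(axis=(1, 3))


def write_map(gmap: GKsMap, path) -> None:
    """Serialize as a delimited grid: header lines, the E grid, then the I grid."""
    with open(path, "w") as fh:
        for k, v in gmap.provenance.items():
            fh.write(f"# {k}={v}\n")
        fh.write(f"# E {gmap.E_values.shape[0]}x{gmap.E_values.shape[1]}\n")
        np.savetxt(fh, gmap.E_values, fmt="%.6f")
        fh.write(f"# I {gmap.I_values.shape[0]}x{gmap.I_values.shape[1]}\n")
        np.savetxt(fh, gmap.I_values, fmt="%.6f")


def read_map(path) -> GKsMap:
    rows_E, rows_I, prov, section = [], [], {}, None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("E "):
                    section = rows_E
                elif body.startswith("I "):
                    section = rows_I
                elif "=" in body:
                    k, v = body.split("=", 1)
                    try:
                        prov[k.strip()] = ast.literal_eval(v.strip())
                    except (ValueError, SyntaxError):
                        prov[k.strip()] = v.strip()
                continue
            if section is not None and line.strip():
                section.append([float(tok) for tok in line.split()])
    return GKsMap(E_values=np.array(rows_E), I_values=np.array(rows_I),
                  provenance=prov)
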