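"""Declarative experiment configurations for the figure scenarios and
parameter scans, plus the runner that executes them end to end.

Each scenario is a named, serializable :class:`ExperimentSpec` bundling a gKs
map recipe, a topology variant, drive/noise/synapse/simulation settings, the
requested analyses and the replicate seeds (four, differing in initial
conditions, by convention).  ``run_experiment`` executes map generation ->
topology -> simulation -> analyses per seed and aggregates; ``scan`` sweeps a
grid of spec variations and tabulates summary metrics.

Scenario registry (hotspot radii r and separations d in lattice units):
random 9-hotspot map (r=4.2); single-hotspot radius scans; double-hotspot
(r, d) grids including the r=6.1, d=8 alternation case; random 6-hotspot
variability pairs (r=5.4, r=2.8); the MI-vs-distance line; stimulus gating;
no-I-cell-M-current variant; homogeneous-gKs controls; lower-bound x drive
grid; E-E rewiring; tau_z scan; current-drive hotspots; drive and inhibitory
tau scans; sparse inhibition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .gks_map import GKsMap, GKsMapParams, generate_map, homogeneous_map, random_sites
from .lfp_coupling import mi_distance_profile
from .model_core import NeuronParams
from .rhythm_analysis import (average_spectra, band_peak, band_significant,
                              classify_raster, network_spectrum,
                              THETA_BAND, GAMMA_BAND)
from .simulator import (DriveConfig, NoiseConfig, SimConfig, mean_rate,
                        run_simulation, stimulus_experiment)
from .topology import (LatticeGeometry, SynapseParams, build_default_topology,
                       rewire_EE, sparsify_inhibition)

DEFAULT_SEEDS = (101, 202, 303, 404)


@dataclass(frozen=True)
class MapRecipe:
    """How to build the gKs map: explicit sites, n random sites, a homogeneous
    value, or a current-drive-hotspot variant (homogeneous map + drive targets)."""

    kind: str = "sites"               # sites | random | homogeneous
    sites: tuple[tuple[int, int], ...] = ()
    n_random: int = 0
    site_seed: int = 0
    radius: float | None = None
    value: float = 1.5                # for homogeneous maps
    gks_min: float = 0.2
    I_gks_zero: bool = False

    def build(self) -> GKsMap:
        params = GKsMapParams(gks_min=self.gks_min)
        if self.kind == "homogeneous":
            return homogeneous_map(self.value)
        if self.kind == "random":
            sites = random_sites(self.n_random, self.site_seed)
        elif self.kind == "sites":
            sites = self.sites
        else:
            raise ValueError(f"unknown map recipe kind {self.kind!r}")
        return generate_map(sites, target_radius=self.radius, params=params,
                            I_gks_zero=self.I_gks_zero)


@dataclass(frozen=True)
class TopologyVariant:
    rewire_p: float = 0.0
    rewire_seed: int = 1
    inh_density: float = 1.0
    w_inh: float = 0.04
    sparsify_seed: int = 1

    def build(self, syn: SynapseParams):
        topo = build_default_topology(LatticeGeometry(), syn)
        if self.rewire_p > 0:
            topo = rewire_EE(topo, self.rewire_p, self.rewire_seed)
        if self.inh_density < 1.0:
            topo = sparsify_inhibition(topo, self.inh_density, self.w_inh,
                                       self.sparsify_seed)
        return topo


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    map_recipe: MapRecipe = MapRecipe()
    topology: TopologyVariant = TopologyVariant()
    drive: DriveConfig = DriveConfig()
    noise: NoiseConfig = NoiseConfig(enabled=True)
    syn: SynapseParams = SynapseParams()
    sim: SimConfig = SimConfig()
    neuron: NeuronParams = NeuronParams()
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    analyses: tuple[str, ...] = ("spectrum",)
    mi_line: tuple[tuple[float, float], ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def spec_from_dict(d: dict) -> ExperimentSpec:
    """Inverse of ExperimentSpec.to_dict (config-file round trip)."""

    def _tuplify(x):
        if isinstance(x, list):
            return tuple(_tuplify(v) for v in x)
        if isinstance(x, dict):
            return {k: _tuplify(v) for k, v in x.items()}
        return x

    d = _tuplify(d)
    return ExperimentSpec(
        name=d["name"],
        map_recipe=MapRecipe(**d["map_recipe"]),
        topology=TopologyVariant(**d["topology"]),
        drive=DriveConfig(**d["drive"]),
        noise=NoiseConfig(**d["noise"]),
        syn=SynapseParams(**d["syn"]),
        sim=SimConfig(**d["sim"]),
        neuron=NeuronParams(**d["neuron"]),
        seeds=tuple(d["seeds"]),
        analyses=tuple(d["analyses"]),
        mi_line=tuple(d.get("mi_line", ())),
    )


def run_experiment(spec: ExperimentSpec) -> dict:
    """Execute one spec end to end; returns a result bundle keyed by analysis."""
    bundle: dict = {"spec": spec, "hash": spec.hash}
    try:
        gmap = spec.map_recipe.build()
        topo = spec.topology.build(spec.syn)
    except Exception as err:
        raise RuntimeError(f"[{spec.name}] setup failed: {err}") from err
    bundle["map"] = gmap
    rasters = []
    for seed in spec.seeds:
        cfg = replace(spec.sim, seed=seed)
        try:
            raster, _ = run_simulation(topo, gmap, spec.drive, spec.noise,
                                       spec.syn, cfg, spec.neuron)
        except Exception as err:
            raise RuntimeError(f"[{spec.name}] simulation (seed {seed}) "
                               f"failed: {err}") from err
        rasters.append(raster)
    bundle["rasters"] = rasters
    if "spectrum" in spec.analyses:
        spec_avg = average_spectra([network_spectrum(r, "E") for r in rasters])
        th_f, th_p = band_peak(spec_avg, THETA_BAND)
        ga_f, ga_p = band_peak(spec_avg, GAMMA_BAND)
        bundle["spectrum"] = spec_avg
        bundle["bands"] = {
            "theta_peak_hz": th_f, "theta_power": th_p,
            "theta_significant": band_significant(spec_avg, THETA_BAND),
            "gamma_peak_hz": ga_f, "gamma_power": ga_p,
            "gamma_significant": band_significant(spec_avg, GAMMA_BAND)}
    if "rhythm" in spec.analyses:
        bundle["reports"] = [classify_raster(r) for r in rasters]
    if "mi_profile" in spec.analyses:
        bundle["mi_profile"] = mi_distance_profile(rasters, gmap,
                                                   spec.mi_line or [(10, 10)])
    return bundle


def scan(specs: list[ExperimentSpec]) -> "pandas.DataFrame":  # noqa: F821
    """Run a list of spec variants and tabulate band metrics per point.

    Failures are recorded per point (column ``error``) and the scan continues.
    """
    import pandas as pd

    rows = []
    for sp in specs:
        row = {"name": sp.name}
        try:
            bundle = run_experiment(sp)
            row.update(bundle.get("bands", {}))
            if "reports" in bundle:
                for lab in ("theta", "gamma", "mixed", "none"):
                    row[f"n_{lab}"] = float(np.mean(
                        [rep.counts[lab] for rep in bundle["reports"]]))
            row["error"] = ""
        except Exception as err:
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# scenario registry
# --------------------------------------------------------------------------

def _dbl_sites(d: float) -> tuple[tuple[int, int], tuple[int, int]]:
    """Two release sites separated by d lattice units, centered on the lattice."""
    x0 = int(round(10 - d / 2))
    return ((x0, 10), (int(round(x0 + d)), 10))


def fig2_random9(**kw) -> ExperimentSpec:
    return ExperimentSpec(name="fig2_random9",
                          map_recipe=MapRecipe(kind="random", n_random=9,
                                               site_seed=9042, radius=4.2),
                          analyses=("spectrum", "rhythm"), **kw)


def fig3_radius_scan(radii=(3.0, 4.2, 5.0, 5.5, 6.1), **kw) -> list[ExperimentSpec]:
    return [ExperimentSpec(name=f"fig3_r{r}",
                           map_recipe=MapRecipe(sites=((10, 10),), radius=r),
                           analyses=("spectrum", "rhythm"), **kw)
            for r in radii]


def fig4_rd_grid(radii=(4.2, 5.0, 5.4, 6.1), distances=(4, 6, 8), **kw):
    return [ExperimentSpec(name=f"fig4_r{r}_d{d}",
                           map_recipe=MapRecipe(sites=_dbl_sites(d), radius=r),
                           analyses=("spectrum", "rhythm"), **kw)
            for r in radii for d in distances]


def fig4H(**kw) -> ExperimentSpec:
    return ExperimentSpec(name="fig4H",
                          map_recipe=MapRecipe(sites=_dbl_sites(8), radius=6.1),
                          analyses=("spectrum", "rhythm"), **kw)


def fig5_random6(radius: float = 5.4, site_seed: int = 5001, **kw) -> ExperimentSpec:
    return ExperimentSpec(name=f"fig5_random6_r{radius}_s{site_seed}",
                          map_recipe=MapRecipe(kind="random", n_random=6,
                                               site_seed=site_seed, radius=radius),
                          analyses=("spectrum",), **kw)


def fig6_mi_line(**kw) -> ExperimentSpec:
    # line of probe locations leading away (perpendicular to the hotspot axis)
    # from the left hotspot center of the double map
    line = tuple((6.0, 10.0 + dy) for dy in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0))
    return ExperimentSpec(name="fig6_mi_line",
                          map_recipe=MapRecipe(sites=_dbl_sites(8), radius=6.1),
                          analyses=("spectrum", "mi_profile"),
                          mi_line=line, **kw)


def fig7_stimulus(map_kind: str = "single", scenario: int = 1, **kw) -> ExperimentSpec:
    sites = ((10, 10),) if map_kind == "single" else _dbl_sites(8)
    target_loc = (10, 10) if scenario == 1 else (2, 2)
    return ExperimentSpec(
        name=f"fig7_{map_kind}_scenario{scenario}",
        map_recipe=(MapRecipe(sites=sites, radius=5.0) if scenario != 3
                    else MapRecipe(kind="homogeneous", value=1.5)),
        drive=DriveConfig(I_base=3.0, I_target=4.5,
                          target_ids=_disk_ids(target_loc, 2.0)),
        analyses=(), **kw)


def _disk_ids(center, radius: float) -> tuple[int, ...]:
    from .topology import _positions
    pos = _positions(LatticeGeometry())[:400]
    d = np.hypot(*(((pos - np.asarray(center, float) + 10) % 20 - 10).T))
    return tuple(int(i) + 1 for i in np.nonzero(d <= radius)[0])


def s1_no_I_Mcurrent(**kw) -> ExperimentSpec:
    return ExperimentSpec(name="s1_no_I_Mcurrent",
                          map_recipe=MapRecipe(sites=_dbl_sites(8), radius=6.1,
                                               I_gks_zero=True),
                          syn=SynapseParams(wII=0.06, wIE=0.035),
                          analyses=("spectrum", "rhythm"), **kw)


def s2_homogeneous(value: float, **kw) -> ExperimentSpec:
    return ExperimentSpec(name=f"s2_homog_{value}",
                          map_recipe=MapRecipe(kind="homogeneous", value=value),
                          analyses=("spectrum", "rhythm"), **kw)


def s4_lb_drive_grid(lower_bounds=(0.0, 0.2, 0.5), drives=(2.0, 3.0, 4.0), **kw):
    return [ExperimentSpec(name=f"s4_lb{lb}_I{I}",
                           map_recipe=MapRecipe(sites=((10, 10),), radius=5.6,
                                                gks_min=lb),
                           drive=DriveConfig(I_base=I),
                           analyses=("spectrum", "rhythm"), **kw)
            for lb in lower_bounds for I in drives]


def s6_s9_rewiring(probs=(0.0, 0.05, 0.1, 0.25, 0.5, 0.875), double=False, **kw):
    recipe = (MapRecipe(sites=_dbl_sites(6), radius=5.4) if double
              else MapRecipe(sites=((10, 10),), radius=5.7))
    return [ExperimentSpec(name=f"s{'9' if double else '6'}_p{p}",
                           map_recipe=recipe,
                           topology=TopologyVariant(rewire_p=p, rewire_seed=7),
                           analyses=("spectrum",), **kw)
            for p in probs]


def s7_tauz(tau_values=(25.0, 50.0, 75.0, 100.0, 125.0), **kw):
    return [ExperimentSpec(name=f"s7_tauz{tz}",
                           map_recipe=MapRecipe(sites=_dbl_sites(8), radius=6.1),
                           neuron=NeuronParams(tau_z=tz),
                           analyses=("spectrum",), **kw)
            for tz in tau_values]


def s10_drive_hotspots(gks_values=(0.0, 0.2, 0.6, 1.0, 1.4), **kw):
    specs = []
    for g in gks_values:
        targets = _disk_ids((6, 10), 3.0) + _disk_ids((14, 10), 3.0)
        specs.append(ExperimentSpec(
            name=f"s10_gks{g}",
            map_recipe=MapRecipe(kind="homogeneous", value=g),
            drive=DriveConfig(I_base=3.0, I_target=4.5, target_ids=targets),
            analyses=("spectrum",), **kw))
    return specs


def s14_drive_tauI(drives=(2.5, 3.0, 3.5, 4.0), taus=(2.0, 3.0, 4.0, 5.0), **kw):
    """Drive scan at default synapses plus tau_I scan holding w_inh*tau_I fixed."""
    recipe = MapRecipe(sites=_dbl_sites(8), radius=6.1)
    specs = [ExperimentSpec(name=f"s14_I{I}", map_recipe=recipe,
                            drive=DriveConfig(I_base=I),
                            analyses=("spectrum",), **kw) for I in drives]
    for tau in taus:
        w = 0.04 * 3.0 / tau   # keep w_inh * tau_I constant
        specs.append(ExperimentSpec(
            name=f"s14_tauI{tau}", map_recipe=recipe,
            syn=SynapseParams(tau_inh=tau, wII=w, wIE=w),
            analyses=("spectrum",), **kw))
    return specs


def s15_sparse_inhibition(settings=((0.8, 0.045), (0.6, 0.048), (0.4, 0.075)), **kw):
    return [ExperimentSpec(name=f"s15_density{d}",
                           map_recipe=MapRecipe(sites=_dbl_sites(8), radius=6.1),
                           topology=TopologyVariant(inh_density=d, w_inh=w,
                                                    sparsify_seed=15),
                           analyses=("spectrum",), **kw)
            for d, w in settings]


REGISTRY = {
    "fig2_random9": fig2_random9,
    "fig4H": fig4H,
    "fig6_mi_line": fig6_mi_line,
    "s1_no_I_Mcurrent": s1_no_I_Mcurrent,
}


def stimulus_gating(map_kind: str = "single", target_radius: float = 2.0,
                    hotspot_radius_: float = 5.0, seed: int = 101,
                    sim: SimConfig = SimConfig(),
                    noise: NoiseConfig = NoiseConfig(enabled=True)) -> dict:
    """The three-condition stimulus experiment (Fig 7E quantity).

    Returns relative firing-rate changes of the targeted E subset for
    (1) targets inside a hotspot and (2) targets outside, each versus
    (3) the homogeneous no-modulation control with the same stimulus.
    """
    sites = ((10, 10),) if map_kind == "single" else _dbl_sites(8)
    gmap = generate_map(sites, target_radius=hotspot_radius_)
    homog = homogeneous_map(1.5)
    topo = build_default_topology()
    out = {}
    for scen, loc in (("inside", (10, 10)), ("outside", (2, 2))):
        targets = _disk_ids(loc, target_radius)
        cfg = replace(sim, seed=seed)
        res = stimulus_experiment(topo, gmap, homog, targets,
                                  I_base=3.0, I_target=4.5, cfg=cfg, noise=noise)
        out[scen] = res
    return out
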