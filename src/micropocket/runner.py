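"""Experiment orchestration: configuration, scenario batteries, seeds, and
file output.

A run couples one tissue domain, the initial limbal vessel, a VEGF model
(fixed gradient or dynamic pellet release) and the angiogenesis rules, and
advances them in 1 h global steps: the VEGF field is first brought to the
end of the step (dynamic model: PDE sub-steps with the current vessel sink
densities), then the network sub-stages execute. Replicates differ only in
their RNG seed; a given (config, seed) pair reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .angiogenesis import AngioParams, Simulation
from .geometry import DomainKind, GeometryParams, build_domain
from .metrics import DensityGrid, network_metrics
from .network import VesselNetwork, create_initial_vessel
from .vegf import (
    FixedField,
    PelletState,
    TissueField,
    VegfParams,
    advance_to,
    element_densities,
    initial_pellet_concentration,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "load_config",
    "simulate_one",
    "run",
    "reproduce_figure_experiment",
    "FIGURE_EXPERIMENTS",
]

# persistence noise applied when the persistence toggle is off: the walk
# loses directional memory (the upper end of the studied sigma range)
SIGMA_NO_PERSISTENCE = 20.0

DEFAULT_MESH_EDGE = {
    DomainKind.PLANAR_2D: 30.0,
    DomainKind.PLANAR_2D_FINITE: 30.0,
    DomainKind.PLANAR_3D: 30.0,
    DomainKind.PLANAR_3D_FINITE: 30.0,
    DomainKind.CIRCLE_2D: 30.0,
    DomainKind.CIRCLE_3D: 60.0,
    DomainKind.HEMISPHERE: 60.0,
}


@dataclass
class RunConfig:
    """Fully resolved description of one scenario (before seeding)."""

    geometry: GeometryParams = dfield(default_factory=GeometryParams)
    angio: AngioParams = dfield(default_factory=AngioParams)
    vegf: VegfParams = dfield(default_factory=VegfParams)
    vegf_model: str = "fixed"  # "fixed" | "dynamic"
    c_p: float = 20.0  # fixed-field pellet concentration, nM
    pellet_mass_ng: float = 300.0  # dynamic-model loading
    mw_kda: float = 45.0
    duration: float = 85.0  # h
    seeds: tuple = (1, 2, 3, 4, 5)
    node_spacing: float = 10.0
    mesh_edge: float | None = None  # None: per-domain default
    grid_spacing: float = 40.0
    anastomosis: bool = True
    sprouting: bool = True
    limbal_sprouting_only: bool = False
    chemotaxis: bool = True
    persistence: bool = True
    save_interval: float = 5.0
    log_events: bool = False
    output_dir: str | None = None
    write_snapshots: bool = False

    def __post_init__(self):
        if self.vegf_model not in ("fixed", "dynamic"):
            raise ValueError("vegf_model must be 'fixed' or 'dynamic'")
        n = self.duration / self.angio.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of the global step dt")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be distinct")
        if self.c_p < 0:
            raise ValueError("pellet concentration must be non-negative")

    def resolved_angio(self) -> AngioParams:
        """Angio parameters with the chemotaxis/persistence toggles applied."""
        par = self.angio
        chi = par.chi if self.chemotaxis else 0.0
        sigma = par.sigma if self.persistence else SIGMA_NO_PERSISTENCE
        return dataclasses.replace(par, chi=chi, sigma=sigma)

    def resolved_mesh_edge(self) -> float:
        if self.mesh_edge is not None:
            return self.mesh_edge
        return DEFAULT_MESH_EDGE[self.geometry.kind]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"]["kind"] = self.geometry.kind.value
        d["seeds"] = list(self.seeds)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


_SECTION_TYPES = {
    "geometry": GeometryParams,
    "angio": AngioParams,
    "vegf": VegfParams,
}


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML file path or a nested mapping.

    Unknown keys and out-of-range values raise with the offending fields
    listed; omitted keys fall back to the reference parameterisation."""
    if isinstance(source, (str, Path)):
        with open(source) as f:
            data = yaml.safe_load(f) or {}
    else:
        data = dict(source or {})
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    kwargs = {}
    errors = []
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            names = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - names
            if bad:
                errors.append(f"unknown {key} keys: {sorted(bad)}")
                continue
            try:
                kwargs[key] = cls(**value)
            except (ValueError, TypeError) as e:
                errors.append(f"{key}: {e}")
        elif key in top_fields:
            kwargs[key] = tuple(value) if key == "seeds" else value
        else:
            errors.append(f"unknown key: {key}")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return RunConfig(**kwargs)


@dataclass
class RunResult:
    """Outputs of one realization."""

    config: RunConfig
    seed: int
    network: VesselNetwork
    metrics: dict
    pellet_series: pd.DataFrame | None = None  # t, c_p, c_f, max tissue c
    events: list | None = None
    wall_time_s: float = 0.0


def simulate_one(config: RunConfig, seed: int) -> RunResult:
    """Run a single realization to ``duration`` and compute its metrics."""
    t0 = _time.perf_counter()
    dynamic = config.vegf_model == "dynamic"
    domain = build_domain(config.geometry, resolve_pellet=dynamic)
    network = create_initial_vessel(domain, node_spacing=config.node_spacing)
    par = config.resolved_angio()
    rng = np.random.default_rng(seed)
    series = None
    if dynamic:
        mesh = domain.generate_mesh(config.resolved_mesh_edge())
        fld = TissueField(domain, mesh, config.vegf)
        c_p0 = initial_pellet_concentration(
            config.pellet_mass_ng,
            config.mw_kda,
            np.pi * config.geometry.r_p**2 * config.geometry.T_p,
        )
        pellet = PelletState(
            c_p0,
            theta=config.vegf.theta,
            lambda_p=config.vegf.lambda_p,
            kappa_p=config.vegf.kappa_p,
            omega_p=np.pi * config.geometry.r_p**2 * config.geometry.T_p,
        )
        sim = Simulation(
            domain, network, fld, par, rng,
            anastomosis=config.anastomosis,
            sprouting=config.sprouting,
            limbal_sprouting_only=config.limbal_sprouting_only,
            log_events=config.log_events,
        )
        rows = []
        n_steps = int(round(config.duration / par.dt))
        for k in range(n_steps):
            rho_e, n_e = element_densities(fld, network)
            fld.set_element_densities(rho_e, n_e)
            pellet = advance_to(fld, pellet, sim.time, sim.time + par.dt)
            sim.step()
            rows.append(
                (sim.time, pellet.c_p, pellet.c_f, float(fld.c.max()))
            )
        series = pd.DataFrame(rows, columns=["t", "c_p", "c_f", "max_tissue_c"])
    else:
        fld = FixedField(domain, config.c_p)
        sim = Simulation(
            domain, network, fld, par, rng,
            anastomosis=config.anastomosis,
            sprouting=config.sprouting,
            limbal_sprouting_only=config.limbal_sprouting_only,
            log_events=config.log_events,
        )
        sim.run(config.duration)
    grid = DensityGrid(domain, config.grid_spacing)
    m = network_metrics(network, grid)
    metrics = {
        "seed": seed,
        "max_tip_density": m["max_tip_density"],
        "max_line_density": m["max_line_density"],
        "vascularized_fraction": m["vascularized_fraction"],
        "tip_count": int(len(network.tip_ids)),
        "total_length": network.total_length,
        "d_front_tip": m["tip"].d_front if m["tip"] else float("nan"),
        "xi_max_tip": m["tip"].xi_max if m["tip"] else float("nan"),
        "xi_halfmax_tip": m["tip"].xi_halfmax if m["tip"] else float("nan"),
        "d_front_line": m["line"].d_front if m["line"] else float("nan"),
    }
    return RunResult(
        config=config,
        seed=seed,
        network=network,
        metrics=metrics,
        pellet_series=series,
        events=sim.events if config.log_events else None,
        wall_time_s=_time.perf_counter() - t0,
    )


def aggregate(results: list[RunResult]) -> dict:
    """Mean and SD of the scalar metrics over replicate seeds."""
    keys = [k for k in results[0].metrics if k != "seed"]
    table = {k: np.array([r.metrics[k] for r in results], dtype=float) for k in keys}
    return {
        k: {"mean": float(np.nanmean(v)), "sd": float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0}
        for k, v in table.items()
    }


def run(config: RunConfig) -> dict:
    """Execute all replicate seeds of a scenario; write outputs when an
    output directory is configured. Returns the per-seed results and the
    mean +- SD aggregate."""
    results = [simulate_one(config, s) for s in config.seeds]
    agg = aggregate(results)
    out = {"results": results, "aggregate": agg, "config": config}
    if config.output_dir:
        _write_outputs(config, results, agg)
    return out


def _write_outputs(config: RunConfig, results, agg):
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "per_seed": [r.metrics for r in results],
        "aggregate": agg,
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
    for r in results:
        tag = f"seed{r.seed}"
        if config.write_snapshots:
            r.network.to_vtk(outdir / f"network_{tag}.vtk")
        r.network.to_csv(outdir / f"nodes_{tag}.csv", outdir / f"segments_{tag}.csv")
        if r.pellet_series is not None:
            r.pellet_series.to_csv(outdir / f"pellet_{tag}.csv", index=False)
        if r.events is not None:
            with open(outdir / f"events_{tag}.jsonl", "w") as f:
                for ev in r.events:
                    f.write(json.dumps(ev) + "\n")


# =========================================================================
# headline comparisons
# =========================================================================

FOLD_DOMAINS = ("planar_2d", "planar_3d", "circle_2d", "circle_3d")


def anastomosis_fold_changes(seeds=(1, 2, 3, 4, 5), c_p: float = 20.0,
                             duration: float = 85.0) -> dict:
    """Fixed-gradient ensemble comparison of maximum tip densities.

    Runs the five comparison domains with and without anastomosis for
    ``duration`` hours and returns, per domain, the fold-reduction in
    ensemble-mean maximum tip density caused by anastomosis (off/on), plus
    the no-anastomosis circular-vs-planar density ratio (circle mean over
    planar+hemisphere mean)."""
    mean_density = {}
    for kind in FOLD_DOMAINS + ("hemisphere",):
        for anast in (False, True):
            if kind == "hemisphere" and anast:
                continue
            cfg = RunConfig(
                geometry=GeometryParams(kind=kind),
                vegf_model="fixed",
                c_p=c_p,
                duration=duration,
                anastomosis=anast,
                seeds=tuple(seeds),
            )
            res = [simulate_one(cfg, s) for s in cfg.seeds]
            mean_density[(kind, anast)] = float(
                np.mean([r.metrics["max_tip_density"] for r in res])
            )
    out = {
        kind: mean_density[(kind, False)] / mean_density[(kind, True)]
        for kind in FOLD_DOMAINS
    }
    circular = np.mean(
        [mean_density[("circle_2d", False)], mean_density[("circle_3d", False)]]
    )
    planar = np.mean(
        [
            mean_density[("planar_2d", False)],
            mean_density[("planar_3d", False)],
            mean_density[("hemisphere", False)],
        ]
    )
    out["circular_to_planar_ratio"] = float(circular / planar)
    out["mean_max_tip_density"] = {
        f"{k}|anastomosis={a}": v for (k, a), v in mean_density.items()
    }
    return out


def pellet_depletion_percent(seed: int = 1, duration: float = 96.0,
                             kind: str = "planar_2d") -> float:
    """Dynamic-model pellet release: percent reduction of the spatial
    maximum tissue VEGF from its peak value at the end of the run."""
    cfg = RunConfig(
        geometry=GeometryParams(kind=kind),
        vegf_model="dynamic",
        duration=duration,
        seeds=(seed,),
    )
    r = simulate_one(cfg, seed)
    s = r.pellet_series.max_tissue_c
    return float(100.0 * (1.0 - s.iloc[-1] / s.max()))


def front_location_comparison(
    domains=("hemisphere", "planar_2d", "circle_2d"),
    seeds=(1,),
    duration: float = 85.0,
) -> dict:
    """Dynamic-model vascular front locations (1%-of-max tip density) and
    their deviation from the hemisphere reference."""
    fronts = {}
    for kind in domains:
        cfg = RunConfig(
            geometry=GeometryParams(kind=kind),
            vegf_model="dynamic",
            duration=duration,
            seeds=tuple(seeds),
        )
        res = [simulate_one(cfg, s) for s in cfg.seeds]
        fronts[kind] = float(np.mean([r.metrics["d_front_tip"] for r in res]))
    ref = fronts["hemisphere"]
    dev = {k: 100.0 * abs(v - ref) / ref for k, v in fronts.items()}
    return {"d_front": fronts, "percent_deviation": dev,
            "max_percent_deviation": max(dev.values())}


# =========================================================================
# figure-style scenario batteries
# =========================================================================

ALL_DOMAINS = [k.value for k in DomainKind]


def _battery_fig4(domains, seeds):
    for kind in domains:
        for anast in (True, False):
            yield {
                "label": f"{kind}|anastomosis={anast}",
                "config": RunConfig(
                    geometry=GeometryParams(kind=kind),
                    vegf_model="fixed",
                    c_p=20.0,
                    anastomosis=anast,
                    seeds=seeds,
                ),
            }


def _battery_fig5(domains, seeds):
    for kind in domains:
        for h in (1000.0, 700.0):
            yield {
                "label": f"{kind}|h={h}",
                "config": RunConfig(
                    geometry=GeometryParams(kind=kind, h=h),
                    vegf_model="dynamic",
                    seeds=seeds,
                ),
            }


def _battery_fig6(domains, seeds):
    toggles = {
        "baseline": {},
        "-chemotaxis": {"chemotaxis": False},
        "-persistence": {"persistence": False},
        "-sprouting": {"sprouting": False, "limbal_sprouting_only": True},
        "-anastomosis": {"anastomosis": False},
    }
    for kind in domains:
        for name, kw in toggles.items():
            yield {
                "label": f"{kind}|{name}",
                "config": RunConfig(
                    geometry=GeometryParams(kind=kind),
                    vegf_model="fixed",
                    c_p=20.0,
                    seeds=seeds,
                    **kw,
                ),
            }


def _battery_fig7(domains, seeds):
    yield from _battery_fig5(domains, seeds)


def _battery_s1(domains, seeds):
    for kind in domains:
        for c_p in (1.0, 5.0, 10.0, 20.0, 50.0, 100.0):
            yield {
                "label": f"{kind}|c_p={c_p}",
                "config": RunConfig(
                    geometry=GeometryParams(kind=kind),
                    vegf_model="fixed",
                    c_p=c_p,
                    seeds=seeds,
                ),
            }


FIGURE_EXPERIMENTS = {
    "fig4": _battery_fig4,
    "fig5": _battery_fig5,
    "fig6": _battery_fig6,
    "fig7": _battery_fig7,
    "s1": _battery_s1,
}


def reproduce_figure_experiment(
    name: str,
    domains: list[str] | None = None,
    seeds: tuple = (1, 2, 3, 4, 5),
    output_dir: str | None = None,
) -> pd.DataFrame:
    """Run one of the named scenario batteries and return a tidy table of
    aggregated metrics (one row per scenario label)."""
    if name not in FIGURE_EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; choose from {sorted(FIGURE_EXPERIMENTS)}"
        )
    domains = domains or ALL_DOMAINS
    rows = []
    for item in FIGURE_EXPERIMENTS[name](domains, tuple(seeds)):
        res = run(item["config"])
        row = {"label": item["label"]}
        for key, ms in res["aggregate"].items():
            row[key] = ms["mean"]
            row[key + "_sd"] = ms["sd"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if output_dir:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / f"{name}_summary.csv", index=False)
    return df
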