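"""Scenario presets and the replicate sweep runner.

A :class:`ScenarioConfig` describes a condition grid — cell-cell adhesion
``j_cc`` in {1, 16, 40}, MMP secretion rate ``secretion`` in [0.01, 0.1]/s,
fibre count ``xi`` in {400, 600, 1000}, orientation ``psi`` (random/aligned)
— plus run length and replication.  Presets reproduce the reference
simulation grids:

==================  =====================================================
``fig2``            J_cc sweep at lambda = 0.05, xi = 600
``fig3``            J_cc x lambda grid (0.01, 0.05, 0.1) at xi = 600
``fig4``            J_cc x xi grid at lambda = 0.05
``fig4_high_lambda``J_cc x xi grid at doubled secretion, lambda = 0.1
``fig5``            proteolysis off, random vs aligned, J_cc x xi grid
==================  =====================================================

Full scale is a 500x500 lattice (1 mm^2), 1800 MCS (18 h) and 10
replicates; ``cfg.desk()`` switches to the desk-scale regression regime
(250x250 lattice, fibre counts scaled by the area ratio, shorter runs, 5
replicates) used by the stochastic test suite.

The fibre-count default for the fig2/fig3 presets is xi = 600 (the middle
of the density grid).
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import metrics as _metrics
from .cpm import Simulation
from .ecm import (
    ALIGNED,
    RANDOM,
    AggregateLayout,
    build_initial_aggregate,
    compose_lattice,
    generate_fibre_mesh,
)
from .params import (
    ID_FIBRE,
    LATTICE_PX,
    MCS_SECONDS,
    PIXEL_UM,
    EnergyParams,
    MMPParams,
)

PRESET_NAMES = (
    "fig2",
    "fig3",
    "fig4",
    "fig4_high_lambda",
    "fig5",
    "calibration_speed",
    "calibration_rotation",
)


@dataclass
class ScenarioConfig:
    name: str = "custom"
    j_cc: tuple[float, ...] = (16.0,)
    secretion: tuple[float, ...] = (0.05,)
    xi: tuple[int, ...] = (600,)
    psi: tuple[str, ...] = (RANDOM,)
    proteolysis: bool = True
    n_mcs: int = 1800
    n_replicates: int = 10
    base_seed: int = 0
    lattice_px: int = LATTICE_PX
    aggregate_diameter_um: float = 200.0
    j_ce_override: float | None = None  # e.g. set J_ce := J_cf (adhesion-blind ECM)
    piff_layout: str | None = None      # pre-built lattice instead of mesh+aggregate
    scale: float = 1.0

    def __post_init__(self):
        self.j_cc = tuple(self.j_cc)
        self.secretion = tuple(self.secretion)
        self.xi = tuple(int(x) for x in self.xi)
        self.psi = tuple(self.psi)
        if self.n_mcs < 0 or self.n_replicates < 1:
            raise ValueError("n_mcs must be >= 0 and n_replicates >= 1")
        for p in self.psi:
            if p not in (RANDOM, ALIGNED):
                raise ValueError(f"unknown orientation mode {p!r}")
        for x in self.xi:
            if x < 0:
                raise ValueError("fibre count must be non-negative")

    # ------------------------------------------------------------ bookkeeping

    @property
    def simulated_hours(self) -> float:
        """Biological time represented by the run (36 s per MCS)."""
        return self.n_mcs * MCS_SECONDS / 3600.0

    @property
    def aggregate_margin_um(self) -> float:
        """Distance from the aggregate rim to the nearest lattice edge."""
        return self.lattice_px * PIXEL_UM / 2.0 - self.aggregate_diameter_um / 2.0

    def conditions(self) -> list[dict]:
        return [
            {"j_cc": j, "secretion": lam, "xi": x, "psi": p}
            for j, lam, x, p in itertools.product(
                self.j_cc, self.secretion, self.xi, self.psi
            )
        ]

    def desk(self, n_mcs: int = 900, n_replicates: int = 5) -> "ScenarioConfig":
        """Desk-scale variant: half-side lattice, fibre count scaled by area."""
        factor = 0.5
        return replace(
            self,
            lattice_px=int(round(self.lattice_px * factor)),
            xi=tuple(int(round(x * factor**2)) for x in self.xi),
            n_mcs=n_mcs,
            n_replicates=n_replicates,
            scale=self.scale * factor,
        )

    # ------------------------------------------------------------- round-trip

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["j_cc"] = list(self.j_cc)
        d["secretion"] = list(self.secretion)
        d["xi"] = list(self.xi)
        d["psi"] = list(self.psi)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def preset(name: str) -> ScenarioConfig:
    """Fully populated configuration for a named experiment."""
    grids = {
        "fig2": dict(j_cc=(1.0, 16.0, 40.0), secretion=(0.05,), xi=(600,)),
        "fig3": dict(j_cc=(1.0, 16.0, 40.0), secretion=(0.01, 0.05, 0.1), xi=(600,)),
        "fig4": dict(j_cc=(1.0, 16.0, 40.0), secretion=(0.05,), xi=(400, 600, 1000)),
        "fig4_high_lambda": dict(
            j_cc=(1.0, 16.0, 40.0), secretion=(0.1,), xi=(400, 600, 1000)
        ),
        "fig5": dict(
            j_cc=(1.0, 16.0, 40.0),
            secretion=(0.0,),
            xi=(400, 600, 1000),
            psi=(RANDOM, ALIGNED),
            proteolysis=False,
        ),
    }
    if name in grids:
        return ScenarioConfig(name=name, **grids[name])
    if name in ("calibration_speed", "calibration_rotation"):
        return ScenarioConfig(
            name=name, j_cc=(16.0,), secretion=(0.0,), xi=(0,), proteolysis=False,
            n_mcs=300, n_replicates=3,
        )
    raise ValueError(f"unknown preset {name!r}; valid presets: {PRESET_NAMES}")


@dataclass
class SweepResult:
    """Per-condition, per-replicate metrics plus MMP time series."""

    config: ScenarioConfig
    table: pd.DataFrame
    mmp_total: dict[tuple, np.ndarray] = field(default_factory=dict)

    def values(self, column: str, **condition) -> np.ndarray:
        """Per-replicate values of a metric at one condition."""
        t = self.table
        for k, v in condition.items():
            t = t[t[k] == v]
        return t.sort_values("replicate")[column].to_numpy()

    def summary(self) -> pd.DataFrame:
        """Per-condition mean and SEM across replicates."""
        cols = ["d_total_um", "d_net_um", "rog_um", "pct_degradation",
                "n_clusters", "mean_cluster_size"]
        g = self.table.groupby(["j_cc", "secretion", "xi", "psi"])[cols]
        out = g.agg(["mean", "sem"])
        out.columns = [f"{a}_{b}" for a, b in out.columns]
        return out.reset_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def _replicate_seeds(base_seed: int, r: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(base_seed + r)
    mesh_seed, sim_seed = (int(s) for s in ss.generate_state(2))
    return mesh_seed % 2**31, sim_seed % 2**31


def run_replicate(
    cfg: ScenarioConfig, condition: dict, replicate: int
) -> tuple[_metrics.MetricsReport, np.ndarray, Simulation]:
    """One simulation replicate of one grid condition."""
    mesh_seed, sim_seed = _replicate_seeds(cfg.base_seed, replicate)
    if cfg.piff_layout is not None:
        from .piff import piff_to_lattice, read_piff

        sigma = piff_to_lattice(read_piff(cfg.piff_layout), cfg.lattice_px)
        xs, ys = np.nonzero(sigma > 0)
        centre_px = np.array([xs.mean(), ys.mean()])
    else:
        mesh = generate_fibre_mesh(
            condition["xi"], condition["psi"], mesh_seed, cfg.lattice_px
        )
        layout = build_initial_aggregate(lattice_px=cfg.lattice_px)
        sigma = compose_lattice(mesh, layout, cfg.lattice_px)
        centre_px = np.asarray(layout.centroid_px())

    params = EnergyParams(j_cc=condition["j_cc"])
    if cfg.j_ce_override is not None:
        params.j_ce = cfg.j_ce_override
    mmp = MMPParams(secretion_per_s=condition["secretion"]) if cfg.proteolysis else None
    sim = Simulation(
        sigma, params, mmp=mmp, proteolysis=cfg.proteolysis, seed=sim_seed
    )
    sim.run(cfg.n_mcs)

    traj = sim.trajectory_um()
    rep = _metrics.report(
        traj,
        sim.sigma,
        sim.initial_fibre_px,
        int(np.count_nonzero(sim.sigma == ID_FIBRE)),
        (centre_px + 0.5) * PIXEL_UM,
    )
    return rep, np.asarray(sim.mmp_total_series), sim


def run_scenario(cfg: ScenarioConfig, progress: bool = False) -> SweepResult:
    """Run the full condition x replicate grid and assemble the results."""
    rows = []
    mmp_series: dict[tuple, np.ndarray] = {}
    for cond in cfg.conditions():
        for r in range(cfg.n_replicates):
            rep, series, _sim = run_replicate(cfg, cond, r)
            key = (cond["j_cc"], cond["secretion"], cond["xi"], cond["psi"], r)
            mmp_series[key] = series
            rows.append(
                {
                    "replicate": r,
                    "j_cc": cond["j_cc"],
                    "secretion": cond["secretion"],
                    "xi": cond["xi"],
                    "psi": cond["psi"],
                    "d_total_um": rep.d_total_um,
                    "d_net_um": rep.d_net_um,
                    "rog_um": rep.rog_um,
                    "pct_degradation": rep.pct_degradation,
                    "n_clusters": rep.n_clusters,
                    "mean_cluster_size": rep.mean_cluster_size,
                }
            )
            if progress:
                print(f"done {cond} replicate {r}")
    return SweepResult(cfg, pd.DataFrame(rows), mmp_series)


# ----------------------------------------------------------- calibration runs


def build_channel_lattice(
    lattice_px: int = 250,
    channel_spacing_px: int = 20,
    n_cells: int = 10,
) -> np.ndarray:
    """Sparse mesh with pre-existing paths: full-width horizontal fibre
    lines every ``channel_spacing_px`` rows, with single cells seeded in the
    fibre-free channels between them."""
    sigma = np.zeros((lattice_px, lattice_px), dtype=np.int32)
    for y in range(channel_spacing_px // 2, lattice_px, channel_spacing_px):
        sigma[:, y] = ID_FIBRE
    side = 10
    n_channels = (lattice_px - channel_spacing_px) // channel_spacing_px
    cid = 0
    for k in range(n_cells):
        cid += 1
        ch = k % n_channels
        y0 = channel_spacing_px // 2 + ch * channel_spacing_px + 5
        x0 = 20 + (k * 83) % (lattice_px - side - 40)
        if sigma[x0 : x0 + side, y0 : y0 + side].any():
            raise RuntimeError("cell placement collided with a fibre")
        sigma[x0 : x0 + side, y0 : y0 + side] = cid
    return sigma


def calibrate_speed(
    n_seeds: int = 3,
    base_seed: int = 0,
    n_mcs: int = 150,
    burn_in: int = 30,
    lattice_px: int = 250,
    params: EnergyParams | None = None,
) -> float:
    """Mean single-cell speed (um/h) in a path-containing sparse mesh.

    The calibration geometry is a stand-in for a sparse ECM with
    pre-existing migration paths: full-width horizontal fibre lines bound
    fibre-free channels wider than a cell, and isolated cells placed in the
    channels migrate along them (proteolysis off, so the measurement
    reflects motility alone).  Speed is the mean per-MCS centroid
    displacement (um) times 100 MCS/h (one MCS is 36 s), averaged over
    cells, post-burn-in steps and seeds.  With the reference parameter set
    this reproduces experimentally observed speeds of roughly 23 um/h.
    """
    speeds = []
    for s in range(n_seeds):
        sigma = build_channel_lattice(lattice_px)
        sim = Simulation(sigma, params or EnergyParams(), proteolysis=False,
                         seed=base_seed + s)
        sim.run(n_mcs)
        traj = sim.trajectory_um()[burn_in:]
        step = np.linalg.norm(np.diff(traj, axis=0), axis=2)
        speeds.append(step.mean() * 3600.0 / MCS_SECONDS)
    return float(np.mean(speeds))


def build_confined_aggregate(lattice_px: int = 160, ring_radius_px: int = 55
                             ) -> tuple[np.ndarray, AggregateLayout]:
    """Cell aggregate enclosed by a non-degradable circular fibre ring.

    Used for the rotation calibration: under confinement the velocity-
    aligned polarity rule produces persistent collective rotation.
    """
    layout = build_initial_aggregate(lattice_px=lattice_px)
    sigma = compose_lattice(None, layout, lattice_px)
    c = (lattice_px - 1) / 2.0
    xs, ys = np.meshgrid(np.arange(lattice_px), np.arange(lattice_px), indexing="ij")
    rr = np.hypot(xs - c, ys - c)
    ring = (rr >= ring_radius_px) & (rr < ring_radius_px + 3)
    if (sigma[ring] > 0).any():
        raise ValueError("ring overlaps the aggregate; increase ring_radius_px")
    sigma[ring] = ID_FIBRE
    return sigma, layout
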