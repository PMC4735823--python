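"""Shared fixtures: toy lattices and the desk-scale regression sweep."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from invadopotts.ecm import build_initial_aggregate, compose_lattice
from invadopotts.fixtures import make_fixture
from invadopotts.params import EnergyParams
from invadopotts.scenarios import ScenarioConfig, run_replicate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_cells():
    return make_fixture("two_cells")


@pytest.fixture
def toy_lattice():
    """30x30 lattice with four cells, a few fibres and open fluid."""
    sigma = np.zeros((30, 30), dtype=np.int32)
    sigma[2:8, 2:8] = 1
    sigma[8:14, 2:8] = 2
    sigma[4:9, 12:18] = 3
    sigma[20:27, 20:26] = 4
    sigma[15, 0:12] = -1
    sigma[0:9, 20] = -1
    return sigma


# --------------------------------------------------------------------------
# Desk-scale stochastic regression sweep (shared by the acceptance suite).
#
# 250x250 lattice, fibre counts scaled by the area ratio from the full-scale
# grid (400/600/1000 -> 100/150/250), 5 replicates per condition.  Run
# lengths per experiment group: the adhesion/secretion grids run the full
# 1800 MCS (the collective-to-single breakup and the degradation contrasts
# need the full time course), the density grids 900 MCS, and the
# proteolysis-off contact-guidance grid 600 MCS (the aligned-vs-random
# contrast develops early).  Replicate r of every condition shares
# mesh/simulation seed streams, pairing the comparisons.
# --------------------------------------------------------------------------

DESK_JCC = (1.0, 16.0, 40.0)
DESK_XI = (100, 150, 250)          # full-scale 400, 600, 1000
DESK_XI_MAP = {100: 400, 150: 600, 250: 1000}
DESK_REPS = 5
ADHESION_MCS = 1800
DENSITY_MCS = 900
GUIDANCE_MCS = 600


def _desk_groups():
    adhesion = [
        (j, lam, 150, "random")                       # J_cc x lambda grids
        for j in DESK_JCC
        for lam in (0.01, 0.05, 0.1)
    ]
    density = []
    for j in DESK_JCC:
        for xi in DESK_XI:
            density.append((j, 0.05, xi, "random"))   # density grid
        for xi in (100, 250):
            density.append((j, 0.1, xi, "random"))    # doubled secretion
    guidance = [
        (j, 0.0, xi, psi)
        for j in DESK_JCC
        for xi in DESK_XI
        for psi in ("random", "aligned")              # proteolysis off
    ]
    return (
        (adhesion, ADHESION_MCS, True),
        (density, DENSITY_MCS, True),
        (guidance, GUIDANCE_MCS, False),
    )


@pytest.fixture(scope="session")
def desk_sweep():
    """Run the full desk-scale condition grid once per test session."""
    rows = []
    for conds, n_mcs, proteo in _desk_groups():
        cfg = ScenarioConfig(
            n_mcs=n_mcs,
            n_replicates=DESK_REPS,
            base_seed=0,
            lattice_px=250,
            proteolysis=proteo,
        )
        for (j, lam, xi, psi) in conds:
            cond = {"j_cc": j, "secretion": lam, "xi": xi, "psi": psi}
            for r in range(DESK_REPS):
                rep, series, sim = run_replicate(cfg, cond, r)
                traj = sim.trajectory_um()
                net = traj[-1] - traj[0]
                norms = np.linalg.norm(net, axis=1)
                moved = norms > 0
                cos_x = float(
                    np.abs(net[moved, 0] / norms[moved]).mean()
                ) if moved.any() else np.nan
                rows.append(
                    dict(
                        j_cc=j, secretion=lam, xi=xi, psi=psi, replicate=r,
                        n_mcs=n_mcs,
                        d_total=rep.d_total_um, d_net=rep.d_net_um,
                        rog=rep.rog_um, pct=rep.pct_degradation,
                        n_clusters=rep.n_clusters,
                        mmp_mean=float(np.mean(series[len(series) // 2:])),
                        cos_x=cos_x,
                    )
                )
    return pd.DataFrame(rows)


def sweep_values(df: pd.DataFrame, column: str, **condition) -> np.ndarray:
    t = df
    for k, v in condition.items():
        t = t[t[k] == v]
    assert len(t) == DESK_REPS, f"expected {DESK_REPS} replicates, got {len(t)}"
    return t.sort_values("replicate")[column].to_numpy()
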