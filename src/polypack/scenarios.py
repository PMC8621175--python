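"""Scenario harness: scripted, seeded experiment protocols.

Each scenario builds a system (generation), brings it to its working state
(equilibration/compression) and runs production with a configured move
mix, emitting packing-density / energy / acceptance series and periodic
order summaries.  All sizes default to desk scale (hundreds to a few
thousand sites); the full-scale conditions of the corresponding
application studies are reachable through the same parameters.

Scenarios
---------
``jamming``                monomeric hard spheres compressed to their
                           jammed state (fast kernel path).
``bulk_crystallization``   monomeric hard spheres at fixed packing density;
                           crystallinity and fivefold fractions vs sweeps.
``blend``                  athermal chain/monomer blend with identity
                           exchanges.
``sw_cluster``             square-well system at low density with cluster
                           moves driving aggregation.
``confined``               chains in cylindrical or spherical confinement.
``nanocomposite``          chains around immobile nanofillers; density
                           measures and a short relaxation run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cell import CylinderConfinement, SimulationCell, SphereConfinement
from .cce import cce_norms, label_sites, order_summary
from .clusters import detect_clusters
from .configuration import Configuration
from .density import depleted_density, effective_density, packing_density
from .ensemble import EnsembleSpec, LengthDistribution
from .errors import ConfigError
from .fillers import SphereFiller
from .generate import generate_dilute_system
from .hs_fast import config_from_arrays, hs_compress, hs_nvt
from .interactions import InteractionSpec
from .sampler import run as mc_run
from .schedule import MoveSchedule
from .system import MCSystem
from .xyzio import write_xyz

SCENARIOS = (
    "jamming",
    "bulk_crystallization",
    "blend",
    "sw_cluster",
    "confined",
    "nanocomposite",
)


@dataclass
class ScenarioSpec:
    """One scenario = one (name, parameters, seed) triple."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.name!r}")


@dataclass
class ScenarioResult:
    name: str
    seed: int
    series: pd.DataFrame
    summaries: list
    final_config: Configuration
    acceptance: dict
    extras: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.series.to_csv(out / "series.csv", index=False)
        write_xyz(out / "final.xyz", self.final_config)
        payload = {
            "scenario": self.name,
            "seed": self.seed,
            "version": __version__,
            "acceptance": self.acceptance,
            "extras": self.extras,
            "summaries": [
                {
                    "fractions": s.fractions,
                    "tau_c": s.tau_c,
                    "s_fiv": s.s_fiv,
                    "cluster_sizes": [int(v) for v in s.cluster_sizes],
                }
                for s in self.summaries
            ],
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=1))
        (out / "run.log").write_text(
            f"scenario={self.name} seed={self.seed} version={__version__}\n"
        )


def chain_monomer_fraction(n_chains: int, chain_length: int, n_at: int) -> float:
    """Relative concentration of chain monomers, N_ch*N / N_at."""
    if n_at <= 0:
        raise ConfigError("N_at must be positive")
    if n_chains * chain_length > n_at:
        raise ConfigError("chain monomers exceed the total site count")
    return n_chains * chain_length / n_at


def _dilute_monomers(n: int, phi0: float, seed: int):
    L = (n * math.pi / 6.0 / phi0) ** (1.0 / 3.0)
    cfg = generate_dilute_system(0, 0, n, SimulationCell([L] * 3), seed=seed)
    return cfg.coords.copy(), np.array([L] * 3)


def _order(config, crystals, phi_step_deg=10.0, linkage=1.05, margin=2.5,
           include_voronoi=False):
    res = cce_norms(
        config,
        crystals=crystals,
        phi_step=np.deg2rad(phi_step_deg),
        on_the_fly=True,
        margin=margin,
    )
    labels = label_sites(res)
    return order_summary(
        labels, config, linkage=linkage, include_voronoi=include_voronoi,
        margin=margin,
    )


# ------------------------------------------------------------------ #
def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Execute a scenario and optionally write its run directory."""
    fn = {
        "jamming": _run_jamming,
        "bulk_crystallization": _run_crystallization,
        "blend": _run_blend,
        "sw_cluster": _run_sw_cluster,
        "confined": _run_confined,
        "nanocomposite": _run_nanocomposite,
    }[spec.name]
    result = fn(spec)
    if spec.outdir:
        result.save(spec.outdir)
    return result


def _run_jamming(spec: ScenarioSpec) -> ScenarioResult:
    p = dict(spec.params)
    n = int(p.pop("n_sites", 200))
    phi0 = float(p.pop("phi0", 0.2))
    max_cycles = int(p.pop("max_cycles", 60000))
    descriptor = bool(p.pop("descriptor", True))
    if p:
        raise ConfigError(f"unknown jamming parameters: {sorted(p)}")
    pos, L = _dilute_monomers(n, phi0, spec.seed)
    pos, L, phis = hs_compress(pos, L, seed=spec.seed, max_cycles=max_cycles)
    cfg = config_from_arrays(pos, L)
    summaries = []
    if descriptor:
        summaries.append(_order(cfg, ["FCC", "HCP", "FIV"]))
    series = pd.DataFrame({"cycle": np.arange(len(phis)), "phi": phis})
    return ScenarioResult(
        spec.name, spec.seed, series, summaries, cfg, {},
        extras={"phi_final": float(phis[-1])},
    )


def _run_crystallization(spec: ScenarioSpec) -> ScenarioResult:
    p = dict(spec.params)
    n = int(p.pop("n_sites", 1000))
    phi = float(p.pop("phi", 0.56))
    n_sweeps = int(p.pop("sweeps", 200_000))
    cadence = int(p.pop("descriptor_every", 25_000))
    disp_amp = float(p.pop("disp_amp", 0.11))
    if p:
        raise ConfigError(f"unknown crystallization parameters: {sorted(p)}")
    pos, L = _dilute_monomers(n, 0.2, spec.seed)
    pos, L, _ = hs_compress(pos, L, seed=spec.seed, target_phi=phi)
    rows = []
    summaries = []

    def snapshot(pos_now, sweep):
        cfg = config_from_arrays(pos_now.copy(), L)
        s = _order(cfg, ["FCC", "HCP", "FIV"])
        summaries.append(s)
        rows.append({"sweep": sweep, "tau_c": s.tau_c, "s_fiv": s.s_fiv})

    snapshot(pos, 0)
    hs_nvt(
        pos,
        L,
        n_sweeps=n_sweeps,
        disp_amp=disp_amp,
        seed=spec.seed,
        snapshot_every=cadence,
        snapshot_cb=snapshot,
    )
    cfg = config_from_arrays(pos, L)
    series = pd.DataFrame(rows)
    return ScenarioResult(
        spec.name, spec.seed, series, summaries, cfg, {},
        extras={"phi": phi},
    )


def _blend_schedule(seed: int) -> MoveSchedule:
    return MoveSchedule(
        probabilities={
            "displacement": 0.4,
            "flip": 0.1,
            "end_rotation": 0.1,
            "reptation": 0.15,
            "end_regrow": 0.05,
            "seb": 0.05,
            "sieb": 0.05,
            "idex1": 0.04,
            "idex2": 0.03,
            "idex3": 0.03,
        },
        seed=seed,
    )


def _run_blend(spec: ScenarioSpec) -> ScenarioResult:
    p = dict(spec.params)
    n_chains = int(p.pop("n_chains", 8))
    N = int(p.pop("chain_length", 8))
    n_singles = int(p.pop("n_singles", 40))
    phi = float(p.pop("phi", 0.10))
    steps = int(p.pop("steps", 20_000))
    dl = float(p.pop("dl", 0.1))
    if p:
        raise ConfigError(f"unknown blend parameters: {sorted(p)}")
    n_at = n_chains * N + n_singles
    L = (n_at * math.pi / 6.0 / phi) ** (1.0 / 3.0)
    ispec = InteractionSpec(dl=dl)
    cfg = generate_dilute_system(
        n_chains, N, n_singles, SimulationCell([L] * 3), ispec, seed=spec.seed
    )
    ens = EnsembleSpec(
        kind="semigrand",
        lengths=LengthDistribution("uniform", max(2, N // 2), 2 * N),
    )
    state = MCSystem(cfg, ispec, ens, _blend_schedule(spec.seed))
    mc_run(state, steps)
    series = pd.DataFrame(
        [
            {
                "chain_fraction": chain_monomer_fraction(
                    cfg.topology.n_chains,
                    int(round(cfg.topology.mean_chain_length)),
                    cfg.n_sites,
                ),
                "phi": packing_density(cfg),
            }
        ]
    )
    return ScenarioResult(
        spec.name, spec.seed, series, [], cfg, state.acceptance_rates(),
        extras={
            "chain_fraction": (n_chains * N) / n_at,
            "chain_lengths": [int(v) for v in cfg.topology.chain_lengths()],
        },
    )


def _run_sw_cluster(spec: ScenarioSpec) -> ScenarioResult:
    p = dict(spec.params)
    n_chains = int(p.pop("n_chains", 6))
    N = int(p.pop("chain_length", 4))
    n_singles = int(p.pop("n_singles", 0))
    phi = float(p.pop("phi", 0.05))
    eps_sw = float(p.pop("eps_sw", 1.2))
    sigma2 = float(p.pop("sigma2", 1.15))
    steps = int(p.pop("steps", 30_000))
    cluster_moves = bool(p.pop("cluster_moves", True))
    if p:
        raise ConfigError(f"unknown sw_cluster parameters: {sorted(p)}")
    n_at = n_chains * N + n_singles
    L = (n_at * math.pi / 6.0 / phi) ** (1.0 / 3.0)
    ispec = InteractionSpec(mode="SW", eps_sw=eps_sw, sigma2=sigma2, dl=0.1)
    cfg = generate_dilute_system(
        n_chains, N, n_singles, SimulationCell([L] * 3), ispec, seed=spec.seed
    )
    probs = {
        "displacement": 0.5,
        "reptation": 0.2,
        "end_rotation": 0.1,
        "flip": 0.1,
    }
    if cluster_moves:
        probs["cluster_displacement"] = 0.07
        probs["cluster_rotation"] = 0.03
    sched = MoveSchedule(probabilities=probs, cluster_linkage=sigma2, seed=spec.seed)
    state = MCSystem(cfg, ispec, EnsembleSpec(), sched)
    rows = []

    def cb(st, step):
        cs = detect_clusters(st.config, sigma2)
        rows.append(
            {
                "step": step,
                "n_clusters": cs.n_clusters,
                "largest": int(cs.sizes().max()),
            }
        )

    mc_run(state, steps, callback=cb, callback_every=max(1, steps // 20))
    series = pd.DataFrame(rows)
    return ScenarioResult(
        spec.name, spec.seed, series, [], cfg, state.acceptance_rates(),
        extras={"final_clusters": int(series["n_clusters"].iloc[-1])},
    )


def _run_confined(spec: ScenarioSpec) -> ScenarioResult:
    p = dict(spec.params)
    geometry = p.pop("geometry", "cylinder")
    n_chains = int(p.pop("n_chains", 6))
    N = int(p.pop("chain_length", 6))
    phi = float(p.pop("phi", 0.05))
    aspect = float(p.pop("aspect", 2.0))
    steps = int(p.pop("steps", 10_000))
    if p:
        raise ConfigError(f"unknown confined parameters: {sorted(p)}")
    n_at = n_chains * N
    vmon = math.pi / 6.0 * n_at
    if geometry == "cylinder":
        # V = pi/4 d^2 (aspect*d)
        d = (vmon / phi / (math.pi / 4.0) / aspect) ** (1.0 / 3.0)
        cell = SimulationCell(
            [d, d, aspect * d],
            confinement=CylinderConfinement(d, axis=2, closed=True),
        )
    elif geometry == "sphere":
        d = (vmon / phi / (math.pi / 6.0)) ** (1.0 / 3.0)
        cell = SimulationCell([d, d, d], confinement=SphereConfinement(d))
    else:
        raise ConfigError(f"unknown confinement geometry {geometry!r}")
    ispec = InteractionSpec(dl=0.1)
    cfg = generate_dilute_system(n_chains, N, 0, cell, ispec, seed=spec.seed)
    sched = MoveSchedule(
        probabilities={
            "displacement": 0.5,
            "flip": 0.15,
            "end_rotation": 0.15,
            "reptation": 0.2,
        },
        seed=spec.seed,
    )
    state = MCSystem(cfg, ispec, EnsembleSpec(), sched)
    mc_run(state, steps)
    series = pd.DataFrame(
        [{"phi": packing_density(cfg), "zeta": cell.aspect_ratio}]
    )
    return ScenarioResult(
        spec.name, spec.seed, series, [], cfg, state.acceptance_rates(),
        extras={"phi_dep": depleted_density(cfg)},
    )


def _run_nanocomposite(spec: ScenarioSpec) -> ScenarioResult:
    p = dict(spec.params)
    n_chains = int(p.pop("n_chains", 48))
    N = int(p.pop("chain_length", 100))
    phi = float(p.pop("phi", 9.9e-3))
    d_sph = float(p.pop("d_sph", 5.0))
    steps = int(p.pop("steps", 0))
    if p:
        raise ConfigError(f"unknown nanocomposite parameters: {sorted(p)}")
    n_at = n_chains * N
    L = (n_at * math.pi / 6.0 / phi) ** (1.0 / 3.0)
    cell = SimulationCell([L] * 3)
    filler = SphereFiller((L / 2, L / 2, L / 2), d_sph)
    if math.pi / 6.0 * d_sph**3 >= cell.volume:
        raise ConfigError("filler does not fit inside the cell")
    ispec = InteractionSpec(dl=0.1)
    cfg = generate_dilute_system(
        n_chains, N, 0, cell, ispec, seed=spec.seed, fillers=(filler,)
    )
    acceptance = {}
    if steps > 0:
        sched = MoveSchedule(
            probabilities={
                "displacement": 0.5,
                "flip": 0.2,
                "end_rotation": 0.1,
                "reptation": 0.2,
            },
            seed=spec.seed,
        )
        state = MCSystem(cfg, ispec, EnsembleSpec(), sched)
        mc_run(state, steps)
        acceptance = state.acceptance_rates()
    series = pd.DataFrame(
        [
            {
                "phi": packing_density(cfg),
                "phi_eff": effective_density(cfg),
                "phi_dep": depleted_density(cfg),
            }
        ]
    )
    return ScenarioResult(
        spec.name, spec.seed, series, [], cfg, acceptance,
        extras={
            "phi_eff": effective_density(cfg),
            "d_sph": d_sph,
        },
    )


# ------------------------------------------------------------------ #
def acceptance_profile(
    phi_ladder,
    n_chains: int = 8,
    chain_length: int = 10,
    dl: float = 0.1,
    steps_per_point: int = 8000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-move acceptance rates along a ladder of packing densities.

    A chain system is generated dilute and compressed stepwise to each
    ladder density; at each rung the full move mix runs and the acceptance
    per move is recorded.  Local-move acceptance falls with crowding while
    end-bridging acceptance grows (more bridgeable pairs).
    """
    from .moves_collective import attempt_volume_move
    from .moves_local import attempt_monomer_displacement

    phi_ladder = sorted(float(v) for v in phi_ladder)
    n_at = n_chains * chain_length
    L = (n_at * math.pi / 6.0 / phi_ladder[0]) ** (1.0 / 3.0)
    ispec = InteractionSpec(dl=dl)
    cfg = generate_dilute_system(
        n_chains, chain_length, 0, SimulationCell([L] * 3), ispec, seed=seed
    )
    ens = EnsembleSpec(
        kind="semigrand",
        lengths=LengthDistribution("uniform", max(2, chain_length // 2),
                                   2 * chain_length),
    )
    sched = MoveSchedule(
        probabilities={
            "displacement": 0.35,
            "flip": 0.1,
            "end_rotation": 0.1,
            "reptation": 0.2,
            "end_regrow": 0.1,
            "seb": 0.1,
            "sieb": 0.05,
        },
        l_disp=0.15,
        seed=seed,
    )
    state = MCSystem(cfg, ispec, ens, sched)
    rows = []
    for phi in phi_ladder:
        # compress to the rung: relaxed shrink steps of adaptive amplitude
        amp = 0.01
        guard = 0
        while packing_density(cfg) < phi - 1e-9 and guard < 20_000:
            guard += 1
            for _ in range(max(10, n_at // 4)):
                attempt_monomer_displacement(state)
            out = attempt_volume_move(
                state, pressure=0.0, shrink_only=True, amplitude=amp
            )
            if out == "accept":
                amp = min(amp * 1.3, 0.01)
            else:
                amp = max(amp * 0.7, 1e-7)
        state.stats = {}
        mc_run(state, steps_per_point)
        row = {"phi": packing_density(cfg)}
        # unconditional acceptance: accepted / attempted, skips count as
        # non-accepted (a move with no eligible candidates cannot succeed)
        for m, rec in state.stats.items():
            row[m] = rec["accepts"] / rec["attempts"]
        rows.append(row)
    return pd.DataFrame(rows)
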