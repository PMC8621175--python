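"""Structured run configuration: strict YAML parsing and serialization.

A :class:`RunConfig` gathers everything a run needs (cell, interactions,
system composition, ensemble, move schedule, scenario, descriptor
parameters, seed, output cadence).  Parsing is strict: unknown keys are
rejected, and ``parse(serialize(cfg))`` is lossless.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml

from .cell import CylinderConfinement, SimulationCell, SphereConfinement, Walls
from .ensemble import EnsembleSpec, LengthDistribution
from .errors import ConfigError
from .fillers import CylinderFiller, SphereFiller
from .interactions import BendingSpec, InteractionSpec
from .schedule import MoveSchedule


def _take(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def _cell_from(d: dict) -> SimulationCell:
    _take(d, {"lengths", "confinement", "periodic"}, "cell")
    conf = None
    c = d.get("confinement")
    if c:
        _take(c, {"kind", "dims", "diameter", "axis", "closed"}, "confinement")
        kind = c.get("kind")
        if kind == "walls":
            conf = Walls(tuple(c["dims"]))
        elif kind == "cylinder":
            conf = CylinderConfinement(
                c["diameter"], c.get("axis", 2), c.get("closed", False)
            )
        elif kind == "sphere":
            conf = SphereConfinement(c["diameter"])
        else:
            raise ConfigError(f"unknown confinement kind {kind!r}")
    return SimulationCell(
        np.asarray(d["lengths"], dtype=float),
        confinement=conf,
        periodic=d.get("periodic"),
    )


def _cell_to(cell: SimulationCell) -> dict:
    out: dict = {"lengths": [float(v) for v in cell.lengths]}
    conf = cell.confinement
    if isinstance(conf, Walls):
        out["confinement"] = {"kind": "walls", "dims": list(conf.dims)}
    elif isinstance(conf, CylinderConfinement):
        out["confinement"] = {
            "kind": "cylinder",
            "diameter": conf.diameter,
            "axis": conf.axis,
            "closed": conf.closed,
        }
    elif isinstance(conf, SphereConfinement):
        out["confinement"] = {"kind": "sphere", "diameter": conf.diameter}
    out["periodic"] = [bool(p) for p in cell.periodic]
    return out


def _interactions_from(d: dict) -> InteractionSpec:
    _take(
        d,
        {
            "mode",
            "sigma",
            "sigma2",
            "eps_sw",
            "eps_lj",
            "sigma_lj",
            "lj_cutoff",
            "lj_shift",
            "dl",
            "bond_lower",
            "bending",
            "exclude_13",
        },
        "interactions",
    )
    b = d.get("bending") or {}
    _take(b, {"k_theta", "theta0_deg"}, "bending")
    bending = BendingSpec(
        k_theta=b.get("k_theta", 0.0),
        theta0=math.radians(b.get("theta0_deg", 0.0)),
    )
    kw = {k: v for k, v in d.items() if k != "bending"}
    return InteractionSpec(bending=bending, **kw)


def _interactions_to(spec: InteractionSpec) -> dict:
    out = {
        "mode": spec.mode,
        "sigma": spec.sigma,
        "sigma2": spec.sigma2,
        "eps_sw": spec.eps_sw,
        "eps_lj": spec.eps_lj,
        "sigma_lj": spec.sigma_lj,
        "lj_cutoff": spec.lj_cutoff,
        "lj_shift": spec.lj_shift,
        "dl": spec.dl,
        "bond_lower": spec.bond_lower,
        "exclude_13": spec.exclude_13,
        "bending": {
            "k_theta": spec.bending.k_theta,
            "theta0_deg": math.degrees(spec.bending.theta0),
        },
    }
    return out


def _ensemble_from(d: dict) -> EnsembleSpec:
    _take(d, {"kind", "pressure", "lengths", "monodisperse"}, "ensemble")
    ld = d.get("lengths") or {}
    _take(ld, {"family", "n_min", "n_max", "mean"}, "ensemble.lengths")
    return EnsembleSpec(
        kind=d.get("kind", "NVT"),
        pressure=d.get("pressure", 0.0),
        lengths=LengthDistribution(
            family=ld.get("family", "uniform"),
            n_min=ld.get("n_min", 1),
            n_max=ld.get("n_max", 10**9),
            mean=ld.get("mean"),
        ),
        monodisperse=d.get("monodisperse", False),
    )


def _ensemble_to(e: EnsembleSpec) -> dict:
    return {
        "kind": e.kind,
        "pressure": e.pressure,
        "monodisperse": e.monodisperse,
        "lengths": {
            "family": e.lengths.family,
            "n_min": e.lengths.n_min,
            "n_max": e.lengths.n_max,
            "mean": e.lengths.mean,
        },
    }


def _schedule_from(d: dict) -> MoveSchedule:
    _take(
        d,
        {
            "probabilities",
            "n_trials",
            "l_disp",
            "rot_amplitude",
            "cluster_amplitude",
            "cluster_linkage",
            "volume_amplitude",
            "max_regrow",
            "seed",
        },
        "schedule",
    )
    return MoveSchedule(**d)


def _fillers_from(lst) -> tuple:
    out = []
    for d in lst or ():
        _take(d, {"kind", "center", "anchor", "diameter", "axis"}, "filler")
        if d["kind"] == "sphere":
            out.append(SphereFiller(tuple(d["center"]), d["diameter"]))
        elif d["kind"] == "cylinder":
            out.append(
                CylinderFiller(tuple(d["anchor"]), d["diameter"], d.get("axis", 2))
            )
        else:
            raise ConfigError(f"unknown filler kind {d['kind']!r}")
    return tuple(out)


def _fillers_to(fillers) -> list:
    out = []
    for f in fillers:
        if isinstance(f, SphereFiller):
            out.append(
                {"kind": "sphere", "center": list(f.center), "diameter": f.diameter}
            )
        else:
            out.append(
                {
                    "kind": "cylinder",
                    "anchor": list(f.anchor),
                    "diameter": f.diameter,
                    "axis": f.axis,
                }
            )
    return out


@dataclass
class DescriptorParams:
    phi_step_deg: float = 10.0
    eps_thres: float = 0.245
    crystals: Optional[list] = None
    on_the_fly: bool = False
    every: int = 0          # descriptor cadence in MC steps (0 = end only)
    linkage: float = 1.05


@dataclass
class SystemComposition:
    n_chains: int = 0
    chain_length: int = 0
    n_singles: int = 0


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    cell: SimulationCell
    interactions: InteractionSpec = field(default_factory=InteractionSpec)
    system: SystemComposition = field(default_factory=SystemComposition)
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    schedule: MoveSchedule = field(default_factory=MoveSchedule)
    descriptor: DescriptorParams = field(default_factory=DescriptorParams)
    fillers: tuple = ()
    seed: int = 0
    steps: int = 0
    scenario: Optional[dict] = None
    output_every: int = 0

    # ------------------------------------------------------------- #
    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _take(
            d,
            {
                "cell",
                "interactions",
                "system",
                "ensemble",
                "schedule",
                "descriptor",
                "fillers",
                "seed",
                "steps",
                "scenario",
                "output_every",
            },
            "run config",
        )
        if "cell" not in d:
            raise ConfigError("run config needs a 'cell' section")
        sysd = d.get("system") or {}
        _take(sysd, {"n_chains", "chain_length", "n_singles"}, "system")
        desc = d.get("descriptor") or {}
        _take(
            desc,
            {"phi_step_deg", "eps_thres", "crystals", "on_the_fly", "every", "linkage"},
            "descriptor",
        )
        return cls(
            cell=_cell_from(d["cell"]),
            interactions=_interactions_from(d.get("interactions") or {}),
            system=SystemComposition(**sysd),
            ensemble=_ensemble_from(d.get("ensemble") or {}),
            schedule=_schedule_from(d.get("schedule") or {}),
            descriptor=DescriptorParams(**desc),
            fillers=_fillers_from(d.get("fillers")),
            seed=int(d.get("seed", 0)),
            steps=int(d.get("steps", 0)),
            scenario=d.get("scenario"),
            output_every=int(d.get("output_every", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "cell": _cell_to(self.cell),
            "interactions": _interactions_to(self.interactions),
            "system": asdict(self.system),
            "ensemble": _ensemble_to(self.ensemble),
            "schedule": {
                "probabilities": dict(self.schedule.probabilities),
                "n_trials": dict(self.schedule.n_trials),
                "l_disp": self.schedule.l_disp
                if np.isscalar(self.schedule.l_disp)
                else [float(v) for v in np.atleast_1d(self.schedule.l_disp)],
                "rot_amplitude": self.schedule.rot_amplitude,
                "cluster_amplitude": self.schedule.cluster_amplitude,
                "cluster_linkage": self.schedule.cluster_linkage,
                "volume_amplitude": self.schedule.volume_amplitude,
                "max_regrow": self.schedule.max_regrow,
                "seed": self.schedule.seed,
            },
            "descriptor": asdict(self.descriptor),
            "fillers": _fillers_to(self.fillers),
            "seed": self.seed,
            "steps": self.steps,
            "scenario": self.scenario,
            "output_every": self.output_every,
        }

    @classmethod
    def parse(cls, text: str) -> "RunConfig":
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML: {exc}") from None
        if not isinstance(data, dict):
            raise ConfigError("run config must be a mapping")
        return cls.from_dict(data)

    def serialize(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.parse(fh.read())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.serialize())
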