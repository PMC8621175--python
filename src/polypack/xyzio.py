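"""Extended-XYZ configuration I/O.

Dialect: line 1 is the site count, line 2 a ``key=value`` header carrying
the cell (``Lattice``, orthogonal), periodicity (``pbc``), confinement and
fillers, then one line per site::

    <species> <x> <y> [<z>] <chain_id> <mono_index>

``species`` is ``C`` for chain monomers and ``S`` for singles;
``chain_id`` is -1 for singles and ``mono_index`` the position within the
chain.  Floats are written with 17 significant digits so that
write-then-read is an identity to 1e-12 and better.
"""

from __future__ import annotations

import shlex
from pathlib import Path

import numpy as np

from .cell import (
    CylinderConfinement,
    SimulationCell,
    SphereConfinement,
    Walls,
)
from .configuration import Configuration
from .errors import ParseError
from .fillers import CylinderFiller, SphereFiller
from .topology import SpeciesTopology

_F = "%.17g"


def _fmt_conf(conf) -> str:
    if conf is None:
        return "none"
    if isinstance(conf, Walls):
        return "walls:" + ",".join(str(d) for d in conf.dims)
    if isinstance(conf, CylinderConfinement):
        closed = "T" if conf.closed else "F"
        return f"cylinder:{_F % conf.diameter}:{conf.axis}:{closed}"
    if isinstance(conf, SphereConfinement):
        return f"sphere:{_F % conf.diameter}"
    raise ParseError(f"unknown confinement {conf!r}")


def _parse_conf(s: str):
    if s == "none":
        return None
    kind, _, rest = s.partition(":")
    if kind == "walls":
        return Walls(tuple(int(d) for d in rest.split(",")))
    if kind == "cylinder":
        d, axis, closed = rest.split(":")
        return CylinderConfinement(float(d), int(axis), closed == "T")
    if kind == "sphere":
        return SphereConfinement(float(rest))
    raise ParseError(f"unknown confinement spec {s!r}")


def _fmt_fillers(fillers) -> str:
    parts = []
    for f in fillers:
        if isinstance(f, SphereFiller):
            c = ",".join(_F % v for v in f.center)
            parts.append(f"sphere:{c}:{_F % f.diameter}")
        elif isinstance(f, CylinderFiller):
            a = ",".join(_F % v for v in f.anchor)
            parts.append(f"cylinder:{a}:{_F % f.diameter}:{f.axis}")
        else:
            raise ParseError(f"unknown filler {f!r}")
    return ";".join(parts) if parts else "none"


def _parse_fillers(s: str):
    if s == "none":
        return ()
    out = []
    for part in s.split(";"):
        bits = part.split(":")
        if bits[0] == "sphere":
            center = tuple(float(v) for v in bits[1].split(","))
            out.append(SphereFiller(center, float(bits[2])))
        elif bits[0] == "cylinder":
            anchor = tuple(float(v) for v in bits[1].split(","))
            out.append(CylinderFiller(anchor, float(bits[2]), int(bits[3])))
        else:
            raise ParseError(f"unknown filler spec {part!r}")
    return tuple(out)


def write_xyz(path, config: Configuration, append: bool = False) -> None:
    """Write a configuration (or append a trajectory frame)."""
    cell = config.cell
    dim = cell.dim
    chain_id, mono, species = config.topology.site_tables()
    lat = []
    for k in range(dim):
        row = ["0"] * dim
        row[k] = _F % cell.lengths[k]
        lat.extend(row)
    header = " ".join(
        [
            'Lattice="' + " ".join(lat) + '"',
            'pbc="' + " ".join("T" if p else "F" for p in cell.periodic) + '"',
            f"Properties=species:S:1:pos:R:{dim}:chain:I:1:mono:I:1",
            f"sigma={_F % config.sigma}",
            f"confinement={_fmt_conf(cell.confinement)}",
            f'fillers="{_fmt_fillers(config.fillers)}"',
        ]
    )
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{config.n_sites}\n{header}\n")
        for i in range(config.n_sites):
            xyz = " ".join(_F % v for v in config.coords[i])
            fh.write(f"{species[i]} {xyz} {chain_id[i]} {mono[i]}\n")


def _header_fields(line: str, lineno: int) -> dict:
    out = {}
    try:
        for tok in shlex.split(line):
            k, _, v = tok.partition("=")
            out[k] = v
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed header ({exc})") from None
    return out


def read_xyz(path) -> Configuration:
    """Read one configuration (the first frame) from an extended-XYZ file."""
    frames = read_xyz_frames(path, max_frames=1)
    if not frames:
        raise ParseError(f"{path}: empty file")
    return frames[0]


def read_xyz_frames(path, max_frames: int | None = None):
    """Read all (or the first ``max_frames``) frames of a trajectory."""
    lines = Path(path).read_text().splitlines()
    frames = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise ParseError(
                f"line {ln + 1}: expected a site count, got {lines[ln]!r}"
            ) from None
        if ln + 1 >= len(lines):
            raise ParseError(f"line {ln + 2}: missing header line")
        fields = _header_fields(lines[ln + 1], ln + 2)
        try:
            lat = [float(v) for v in fields["Lattice"].split()]
        except (KeyError, ValueError):
            raise ParseError(f"line {ln + 2}: bad or missing Lattice") from None
        dim = int(round(len(lat) ** 0.5))
        lengths = [lat[k * dim + k] for k in range(dim)]
        pbc = [v == "T" for v in fields.get("pbc", "").split()] or None
        conf = _parse_conf(fields.get("confinement", "none"))
        fillers = _parse_fillers(fields.get("fillers", "none"))
        sigma = float(fields.get("sigma", 1.0))
        cell = SimulationCell(
            lengths,
            confinement=conf,
            periodic=None if pbc is None else pbc,
        )
        body = lines[ln + 2: ln + 2 + n]
        if len(body) < n:
            raise ParseError(
                f"line {ln + 1}: count is {n} but only {len(body)} site "
                "lines follow"
            )
        coords = np.empty((n, dim))
        chain_id = np.empty(n, dtype=int)
        mono = np.empty(n, dtype=int)
        for i, raw in enumerate(body):
            toks = raw.split()
            if len(toks) != dim + 3:
                raise ParseError(
                    f"line {ln + 3 + i}: expected {dim + 3} columns, got "
                    f"{len(toks)}"
                )
            try:
                coords[i] = [float(v) for v in toks[1: 1 + dim]]
                chain_id[i] = int(toks[1 + dim])
                mono[i] = int(toks[2 + dim])
            except ValueError:
                raise ParseError(f"line {ln + 3 + i}: malformed site line") from None
        chains_d: dict[int, list] = {}
        singles = []
        for i in range(n):
            if chain_id[i] < 0:
                singles.append(i)
            else:
                chains_d.setdefault(int(chain_id[i]), []).append(i)
        chains = []
        for cid in sorted(chains_d):
            members = sorted(chains_d[cid], key=lambda s: mono[s])
            chains.append(members)
        topo = SpeciesTopology(chains, singles)
        frames.append(Configuration(coords, topo, cell, fillers, sigma))
        ln += 2 + n
        if max_frames is not None and len(frames) >= max_frames:
            break
    return frames
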