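"""Reading and writing multi-frame structures and metric tables.

Multi-model PDB (MODEL/ENDMDL) and concatenated-block XYZ files are read
through MDAnalysis, frame by frame, so arbitrarily long trajectories
never need whole-file residency.  Coordinates are Angstrom throughout
(XYZ files are assumed Angstrom).  Per-frame descriptor tables are
written as TSV with a units header line and 6 significant digits;
aggregate statistics as JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections.abc import Iterator
from pathlib import Path

import numpy as np
import pandas as pd

from .topology import CDTopology, Conformation, Ensemble, TopologySpec, TopologyError

logger = logging.getLogger(__name__)

#: Units of the metric-table columns, by column-name prefix.
COLUMN_UNITS = {
    "frame": "",
    "d1": "Angstrom",
    "d2": "Angstrom",
    "d3": "Angstrom",
    "theta": "degree",
    "d4": "Angstrom",
    "rg": "Angstrom",
    "circularity": "",
    "n_flips": "count",
    "n_inserted": "count",
}

#: Decimal places of a PDB coordinate field; round-trip precision bound.
PDB_COORD_DECIMALS = 3


class TrajectoryError(ValueError):
    """Raised when a coordinate file cannot be read against a topology."""


def _universe(path: str | Path, fmt: str | None = None):
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"{path}: no such file")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), format=fmt, topology_format=fmt)
    except (EOFError, StopIteration):
        raise TrajectoryError(f"{path}: no frames") from None
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        if path.stat().st_size == 0:
            raise TrajectoryError(f"{path}: no frames") from None
        raise TrajectoryError(f"{path}: unreadable ({exc})") from exc


def _altloc_mask(universe) -> np.ndarray:
    try:
        altlocs = universe.atoms.altLocs
    except AttributeError:
        return np.ones(len(universe.atoms), dtype=bool)
    mask = np.isin(altlocs, ("", "A"))
    if not mask.all():
        logger.warning(
            "dropping %d alternate-location atoms (keeping first altloc)", (~mask).sum()
        )
    return mask


def _elements(universe, mask: np.ndarray) -> list[str]:
    try:
        els = [str(e) for e in universe.atoms.elements[mask]]
        if all(els):
            return els
    except AttributeError:
        pass
    out = []
    for name in universe.atoms.names[mask]:
        sym = next((c for c in str(name) if c.isalpha()), "")
        if not sym:
            raise TrajectoryError(f"cannot infer element for atom named {name!r}")
        out.append(sym.upper())
    return out


def resolve_pdb_topology(path: str | Path, spec: TopologySpec) -> CDTopology:
    """Bind a name-based topology spec to the atom layout of a PDB file."""
    u = _universe(path)
    mask = _altloc_mask(u)
    names = [str(n) for n in u.atoms.names[mask]]
    resids = [int(r) for r in u.atoms.resids[mask]]
    return spec.resolve(names, resids, _elements(u, mask))


def _iter_universe_frames(path, u, mask, topology, temperature_label) -> Iterator[Conformation]:
    n_expected = topology.n_atoms
    n_file = int(mask.sum())
    if n_file != n_expected:
        raise TrajectoryError(
            f"{path}: file has {n_file} atoms, topology expects {n_expected}"
        )
    i = 0
    declared = len(u.trajectory)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                coords = np.array(ts.positions[mask], dtype=float)
                yield Conformation(coords=coords, frame_id=i, temperature_label=temperature_label)
                i += 1
    except TrajectoryError:
        raise
    except Exception as exc:  # noqa: BLE001 - reader inconsistency mid-file
        raise TrajectoryError(
            f"{path}: frame {i + 1} unreadable or has a wrong atom count ({exc})"
        ) from exc
    if i == 0:
        raise TrajectoryError(f"{path}: no frames")
    if i < declared:
        # some readers stop silently on a truncated/short final block
        raise TrajectoryError(
            f"{path}: frame {i + 1} truncated or has a wrong atom count "
            f"(read {i} of {declared} declared frames)"
        )


def iter_pdb_frames(
    path: str | Path,
    topology: CDTopology,
    temperature_label: float | None = None,
) -> Iterator[Conformation]:
    """Stream conformations from a multi-model PDB (constant memory)."""
    u = _universe(path, fmt="PDB")
    yield from _iter_universe_frames(path, u, _altloc_mask(u), topology, temperature_label)


def iter_xyz_frames(
    path: str | Path,
    topology: CDTopology,
    temperature_label: float | None = None,
) -> Iterator[Conformation]:
    """Stream conformations from a concatenated-block XYZ file."""
    u = _universe(path, fmt="XYZ")
    mask = np.ones(len(u.atoms), dtype=bool)
    yield from _iter_universe_frames(path, u, mask, topology, temperature_label)


def read_multimodel_pdb(
    path: str | Path,
    topology: CDTopology | TopologySpec,
    temperature: float = 300.0,
) -> Ensemble:
    """Read a multi-model PDB into an :class:`Ensemble`.

    ``topology`` may be an index-bound :class:`CDTopology` or a
    name-based :class:`TopologySpec`, which is resolved against the
    file's atom names and residue numbering first.  A file without MODEL
    records is a single-frame ensemble.
    """
    if isinstance(topology, TopologySpec):
        topology = resolve_pdb_topology(path, topology)
    frames = list(iter_pdb_frames(path, topology, temperature_label=temperature))
    return Ensemble(frames=frames, temperature=temperature, source=str(path))


def read_xyz_frames(
    path: str | Path,
    topology: CDTopology,
    temperature: float = 300.0,
) -> Ensemble:
    """Read a concatenated XYZ file (atom order positional) into an Ensemble."""
    if isinstance(topology, TopologySpec):
        raise TopologyError("XYZ files carry no residue info; use an index-based topology")
    frames = list(iter_xyz_frames(path, topology, temperature_label=temperature))
    return Ensemble(frames=frames, temperature=temperature, source=str(path))


def write_multimodel_pdb(
    path: str | Path,
    topology: CDTopology,
    frames: Ensemble | list[Conformation],
) -> None:
    """Write frames as a multi-model PDB, one residue per glucose unit."""
    import MDAnalysis as mda

    if topology.atom_names is None or topology.elements is None:
        raise TopologyError("topology needs atom_names and elements to write PDB")
    anchor = {a: g.anchor_unit for g in topology.hp_groups for a in g.atoms}
    resindex = np.array(
        [
            (topology.unit_membership[a] or anchor[a]) - 1
            for a in range(topology.n_atoms)
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            topology.n_atoms,
            n_residues=topology.n_units,
            atom_resindex=resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(topology.atom_names))
        u.add_TopologyAttr("elements", list(topology.elements))
        u.add_TopologyAttr("resids", list(range(1, topology.n_units + 1)))
        u.add_TopologyAttr("resnames", ["GLC"] * topology.n_units)
        with mda.Writer(str(path), multiframe=True, n_atoms=topology.n_atoms) as writer:
            for conf in frames:
                u.atoms.positions = conf.coords
                writer.write(u.atoms)


def _column_unit(column: str) -> str:
    return COLUMN_UNITS.get(column.rsplit("_", 1)[0], COLUMN_UNITS.get(column, ""))


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write a metrics table as TSV; the single header row carries units.

    Columns with a unit are written as ``name(unit)``, e.g.
    ``d1_1(Angstrom)``.  Values are printed with 6 significant digits;
    :func:`read_metrics` round-trips them at that precision.
    """
    renamed = table.rename(
        columns={c: f"{c}({u})" if (u := _column_unit(c)) else c for c in table.columns}
    )
    renamed.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read a TSV metrics table written by :func:`write_metrics`."""
    table = pd.read_csv(path, sep="\t")
    return table.rename(columns={c: c.split("(")[0] for c in table.columns})


def write_summary(summary: dict, path: str | Path) -> None:
    """Write an aggregate-statistics summary document as JSON."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_summary(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
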