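"""Molecular data model for cyclodextrin macrocycles.

A cyclodextrin (CD) is a cyclic oligosaccharide of glucopyranose units;
beta-cyclodextrin has seven.  Every shape descriptor in this package is
defined in terms of five role atoms per unit (O2, O3, O4, C2, C6) and,
for hydroxypropylated derivatives, the atom sets of the hydroxypropyl
(HP) substituents anchored at the O2 or O6 hydroxyls.  This module holds
that mapping (:class:`CDTopology`), the per-frame coordinate container
(:class:`Conformation`), the multi-frame container (:class:`Ensemble`),
cyclic unit indexing, and topology validation / (de)serialisation.

Unit indices are 1-based and cyclic: for a 7-unit CD the successor of
unit 7 is unit 1, so each adjacent-pair descriptor has exactly seven
values per frame.

Topology file format (YAML)
---------------------------
Index-based (atom order is positional, e.g. for XYZ input or files
written by the synthetic builder)::

    n_units: 7
    units:
      - roles: {O2: 0, O3: 1, O4: 2, C2: 3, C6: 4}
        atoms: [0, 1, 2, 3, 4, 5, 6]      # all macrocycle atoms of the unit
      - ...
    hp_groups:
      - {anchor_unit: 1, position: O6, atoms: [49, 50, 51, 52]}
    elements: [O, O, O, C, C, C, C, ...]  # per atom, for masses and PDB output
    atom_names: [O2, O3, O4, C2, C6, C1, C5, ...]   # optional
    masses: {O: 15.999}                   # optional overrides (element or name)

Name-based (resolved against the atom names / residue ids of a PDB
file): role and atom entries are atom-name strings instead of integers,
and each unit maps to one residue (unit i = i-th residue in file order).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import STANDARD_MASSES

REQUIRED_ROLES = ("O2", "O3", "O4", "C2", "C6")
HP_POSITIONS = ("O2", "O6")


class TopologyError(ValueError):
    """Raised when a topology specification cannot be built or resolved."""


def cyclic_next(i: int, offset: int, n_units: int) -> int:
    """Cyclic successor of 1-based unit ``i`` shifted by ``offset``.

    Realises the wrap-around subscripts i+1 and i+3 used by the
    adjacent-pair and cross-cavity descriptors: ``cyclic_next(7, 1, 7)``
    is 1.
    """
    if not isinstance(i, (int, np.integer)) or not isinstance(offset, (int, np.integer)):
        raise TypeError("unit index and offset must be integers")
    if not 1 <= i <= n_units:
        raise ValueError(f"unit index {i} outside 1..{n_units}")
    return (i - 1 + offset) % n_units + 1


@dataclass(frozen=True)
class HPGroup:
    """One hydroxypropyl substituent: anchor unit/position and its atoms."""

    anchor_unit: int
    position: str  # "O2" (secondary rim) or "O6" (primary rim)
    atoms: tuple[int, ...]


@dataclass(frozen=True)
class CDTopology:
    """Atom-role map for an ``n_units`` cyclodextrin, optionally HP-substituted.

    Attributes
    ----------
    n_units
        Number of glucopyranose units (>= 3; 7 for beta-CD).
    unit_atoms
        Per-unit mapping role -> 0-based atom index for the roles
        O2, O3, O4, C2, C6 (tuple of dicts, index 0 = unit 1).
    unit_membership
        Integer array of length ``n_atoms``: unit number (1-based) for
        macrocycle atoms, 0 for HP-substituent atoms.
    hp_groups
        One :class:`HPGroup` per hydroxypropyl substituent.
    masses
        Per-atom masses in amu.
    atom_names, elements
        Optional per-atom labels, kept for file output.
    """

    n_units: int
    unit_atoms: tuple[dict[str, int], ...]
    unit_membership: np.ndarray
    hp_groups: tuple[HPGroup, ...] = ()
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]
    atom_names: tuple[str, ...] | None = None
    elements: tuple[str, ...] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.unit_membership)

    @property
    def hp_atom_set(self) -> frozenset[int]:
        return frozenset(a for g in self.hp_groups for a in g.atoms)

    @property
    def ring_atom_set(self) -> np.ndarray:
        """Indices of all macrocycle atoms (every atom not in an HP group)."""
        hp = self.hp_atom_set
        return np.array([a for a in range(self.n_atoms) if a not in hp], dtype=int)

    def unit_ring_atoms(self, unit: int) -> np.ndarray:
        """Native (non-HP) atoms assigned to 1-based ``unit``."""
        return np.nonzero(self.unit_membership == unit)[0]

    def role_index(self, unit: int, role: str) -> int:
        return self.unit_atoms[unit - 1][role]


@dataclass(frozen=True)
class Conformation:
    """A single frame of Cartesian coordinates in Angstrom."""

    coords: np.ndarray  # (n_atoms, 3) float64, Angstrom
    frame_id: int = 0
    temperature_label: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"frame {self.frame_id}: non-finite coordinates")


@dataclass
class Ensemble:
    """Ordered conformations sharing one topology, with a temperature label."""

    frames: list[Conformation]
    temperature: float = 300.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def validate_topology(topology: CDTopology) -> list[str]:
    """Check every :class:`CDTopology` invariant; return violation messages.

    An empty list means the topology is well formed.  Violations are
    returned as data (not raised) so callers can report them all at once.
    """
    v: list[str] = []
    n = topology.n_units
    if n < 3:
        v.append(f"n_units must be >= 3, got {n}")
    if len(topology.unit_atoms) != n:
        v.append(f"unit_atoms has {len(topology.unit_atoms)} entries for {n} units")
    n_atoms = topology.n_atoms
    role_atoms: set[int] = set()
    for u, roles in enumerate(topology.unit_atoms, start=1):
        for role in REQUIRED_ROLES:
            if role not in roles:
                v.append(f"unit {u}: missing role {role}")
            else:
                idx = roles[role]
                if not 0 <= idx < n_atoms:
                    v.append(f"unit {u}: role {role} atom index {idx} out of range")
                else:
                    role_atoms.add(idx)
        extra = set(roles) - set(REQUIRED_ROLES)
        if extra:
            v.append(f"unit {u}: unknown roles {sorted(extra)}")
    seen: dict[int, int] = {}
    for gi, g in enumerate(topology.hp_groups):
        if not 1 <= g.anchor_unit <= n:
            v.append(f"hp_group {gi}: anchor unit {g.anchor_unit} out of range")
        if g.position not in HP_POSITIONS:
            v.append(f"hp_group {gi}: position {g.position!r} not in {HP_POSITIONS}")
        for a in g.atoms:
            if a in role_atoms:
                v.append(f"hp_group {gi}: atom {a} is a required-role atom")
            if a in seen:
                v.append(f"hp_group {gi}: atom {a} also in hp_group {seen[a]}")
            seen[a] = gi
    keys = [(g.anchor_unit, g.position) for g in topology.hp_groups]
    for key in sorted(set(k for k in keys if keys.count(k) > 1)):
        v.append(f"more than one HP group anchored at unit {key[0]} position {key[1]}")
    if topology.masses is None or len(topology.masses) != n_atoms:
        v.append("masses missing or wrong length")
    elif np.any(np.asarray(topology.masses) <= 0):
        bad = np.nonzero(np.asarray(topology.masses) <= 0)[0]
        v.append(f"non-positive masses at atoms {bad.tolist()}")
    hp = topology.hp_atom_set
    for a in range(n_atoms):
        in_unit = topology.unit_membership[a] != 0
        if in_unit and a in hp:
            v.append(f"atom {a}: assigned to unit {topology.unit_membership[a]} and an HP group")
        if not in_unit and a not in hp:
            v.append(f"atom {a}: neither macrocycle nor HP member")
    return v


def masses_from_elements(
    elements: Sequence[str],
    overrides: dict[str, float] | None = None,
    atom_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Standard atomic masses for ``elements``, with optional overrides.

    Overrides are keyed by atom name (checked first, when names are
    given) or element symbol.
    """
    overrides = overrides or {}
    masses = np.empty(len(elements))
    for i, el in enumerate(elements):
        if atom_names is not None and atom_names[i] in overrides:
            masses[i] = overrides[atom_names[i]]
        elif el in overrides:
            masses[i] = overrides[el]
        elif el in STANDARD_MASSES:
            masses[i] = STANDARD_MASSES[el]
        else:
            raise TopologyError(f"no standard mass for element {el!r} (atom {i}); add an override")
    return masses


@dataclass(frozen=True)
class TopologySpec:
    """Name-based topology declaration, resolved against a coordinate file.

    ``units[i]`` maps roles to atom *names* within the (i+1)-th residue;
    ``unit_atom_names[i]``, when given, lists all macrocycle atom names
    of that residue (defaults to every non-HP atom of the residue).
    """

    n_units: int
    units: tuple[dict[str, str], ...]
    unit_atom_names: tuple[tuple[str, ...] | None, ...]
    hp_groups: tuple[tuple[int, str, tuple[str, ...]], ...]
    mass_overrides: dict[str, float] = field(default_factory=dict)

    def resolve(
        self,
        atom_names: Sequence[str],
        resids: Sequence[int],
        elements: Sequence[str],
    ) -> CDTopology:
        """Bind atom names to indices using the residue layout of a file.

        Units are identified with residues in order of first appearance;
        the file must contain exactly ``n_units`` residues.
        """
        order: list[int] = []
        for r in resids:
            if r not in order:
                order.append(r)
        if len(order) != self.n_units:
            raise TopologyError(
                f"file has {len(order)} residues, topology declares {self.n_units} units"
            )
        by_unit: dict[int, dict[str, int]] = {u: {} for u in range(1, self.n_units + 1)}
        resid_to_unit = {r: u for u, r in enumerate(order, start=1)}
        for i, (name, resid) in enumerate(zip(atom_names, resids)):
            by_unit[resid_to_unit[resid]].setdefault(name, i)

        unit_atoms = []
        for u, roles in enumerate(self.units, start=1):
            resolved = {}
            for role, name in roles.items():
                if name not in by_unit[u]:
                    raise TopologyError(f"unit {u}: atom named {name!r} (role {role}) not found")
                resolved[role] = by_unit[u][name]
            unit_atoms.append(resolved)

        hp_groups = []
        hp_atoms: set[int] = set()
        for anchor, position, names in self.hp_groups:
            idxs = []
            for name in names:
                if name not in by_unit[anchor]:
                    raise TopologyError(
                        f"HP group at unit {anchor}/{position}: atom {name!r} not found"
                    )
                idxs.append(by_unit[anchor][name])
            hp_groups.append(HPGroup(anchor, position, tuple(idxs)))
            hp_atoms.update(idxs)

        membership = np.zeros(len(atom_names), dtype=int)
        for i, resid in enumerate(resids):
            if i not in hp_atoms:
                u = resid_to_unit[resid]
                wanted = self.unit_atom_names[u - 1]
                if wanted is None or atom_names[i] in wanted:
                    membership[i] = u
        topo = CDTopology(
            n_units=self.n_units,
            unit_atoms=tuple(unit_atoms),
            unit_membership=membership,
            hp_groups=tuple(hp_groups),
            masses=masses_from_elements(elements, self.mass_overrides, atom_names),
            atom_names=tuple(atom_names),
            elements=tuple(elements),
        )
        problems = validate_topology(topo)
        if problems:
            raise TopologyError("resolved topology invalid: " + "; ".join(problems))
        return topo


def load_topology(path: str | Path) -> CDTopology | TopologySpec:
    """Load a topology YAML file.

    Returns a fully bound :class:`CDTopology` for index-based files and a
    :class:`TopologySpec` (to be resolved against a PDB) for name-based
    files.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "n_units" not in doc or "units" not in doc:
        raise TopologyError(f"{path}: not a topology file (need n_units and units)")
    n_units = int(doc["n_units"])
    units = doc["units"]
    if len(units) != n_units:
        raise TopologyError(f"{path}: {len(units)} unit entries for n_units={n_units}")

    first_roles = units[0]["roles"] if isinstance(units[0], dict) and "roles" in units[0] else units[0]
    index_based = all(isinstance(x, (int, np.integer)) for x in first_roles.values())

    if index_based:
        if "elements" not in doc:
            raise TopologyError(f"{path}: index-based topology requires an elements list")
        elements = [str(e) for e in doc["elements"]]
        n_atoms = len(elements)
        membership = np.zeros(n_atoms, dtype=int)
        unit_atoms = []
        for u, entry in enumerate(units, start=1):
            roles = {k: int(v) for k, v in entry["roles"].items()}
            unit_atoms.append(roles)
            for a in entry.get("atoms", list(roles.values())):
                membership[int(a)] = u
        hp_groups = tuple(
            HPGroup(int(g["anchor_unit"]), str(g["position"]), tuple(int(a) for a in g["atoms"]))
            for g in doc.get("hp_groups", [])
        )
        names = tuple(str(n) for n in doc["atom_names"]) if "atom_names" in doc else None
        topo = CDTopology(
            n_units=n_units,
            unit_atoms=tuple(unit_atoms),
            unit_membership=membership,
            hp_groups=hp_groups,
            masses=masses_from_elements(elements, doc.get("masses"), names),
            atom_names=names,
            elements=tuple(elements),
        )
        problems = validate_topology(topo)
        if problems:
            raise TopologyError(f"{path}: " + "; ".join(problems))
        return topo

    unit_roles = []
    unit_atom_names = []
    for entry in units:
        roles = entry["roles"] if "roles" in entry else entry
        unit_roles.append({str(k): str(v) for k, v in roles.items()})
        atoms = entry.get("atoms") if isinstance(entry, dict) else None
        unit_atom_names.append(tuple(str(a) for a in atoms) if atoms else None)
    hp = tuple(
        (int(g["anchor_unit"]), str(g["position"]), tuple(str(a) for a in g["atoms"]))
        for g in doc.get("hp_groups", [])
    )
    return TopologySpec(
        n_units=n_units,
        units=tuple(unit_roles),
        unit_atom_names=tuple(unit_atom_names),
        hp_groups=hp,
        mass_overrides=doc.get("masses") or {},
    )


def save_topology(topology: CDTopology, path: str | Path) -> None:
    """Write an index-based topology YAML file (inverse of :func:`load_topology`)."""
    if topology.elements is None:
        raise TopologyError("cannot save a topology without element symbols")
    doc = {
        "n_units": topology.n_units,
        "units": [
            {
                "roles": {k: int(v) for k, v in topology.unit_atoms[u].items()},
                "atoms": [int(a) for a in topology.unit_ring_atoms(u + 1)],
            }
            for u in range(topology.n_units)
        ],
        "hp_groups": [
            {
                "anchor_unit": g.anchor_unit,
                "position": g.position,
                "atoms": [int(a) for a in g.atoms],
            }
            for g in topology.hp_groups
        ],
        "elements": list(topology.elements),
    }
    if topology.atom_names is not None:
        doc["atom_names"] = list(topology.atom_names)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
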