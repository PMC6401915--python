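"""Synthetic cyclodextrin conformers with exact, controllable ground truth.

Real hydroxypropyl-beta-cyclodextrin ensembles come from long
replica-exchange simulations; for testing the analysis pipeline we
instead build idealised pseudo-atom conformers whose state labels (flip
set, inserted-HP count, elliptical distortion) are known by
construction, then mix them into seeded stochastic ensembles.

Each glucose unit carries its five role atoms (O2, O3, O4, C2, C6) plus
two filler ring carbons (C1, C5) so centre-of-mass descriptors are
exercised with non-trivial mass weighting; each hydroxypropyl group is
four pseudo-atoms (3 C, 1 O).  The regular builder places the O4 atoms
on a regular n-gon and every unit in an identical local geometry, so
all adjacent-pair descriptors are exactly equal and circularity is
exactly 1.  The default rim offsets put unflipped flip-angles at ~60 deg
and flipped ones at ~120 deg — a ~30 deg margin on either side of the
90 deg classification threshold, so small coordinate noise cannot move
a frame across it.  Likewise HP placements target d4 well away from the
3 A insertion cutoff (exterior ~8 A, inserted ~1.5 A).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import STANDARD_MASSES
from .topology import (
    CDTopology,
    Conformation,
    Ensemble,
    HPGroup,
    TopologyError,
    masses_from_elements,
)

_RING_ATOM_NAMES = ("O2", "O3", "O4", "C2", "C6", "C1", "C5")
_RING_ELEMENTS = ("O", "O", "O", "C", "C", "C", "C")
_HP_NAMES = {"O6": ("C7", "C8", "C9", "O7"), "O2": ("C10", "C11", "C12", "O8")}
_HP_ELEMENTS = ("C", "C", "C", "O")

#: Atoms reflected by a glucose flip: the primary-rim C6 role atom plus
#: the primary-rim filler carbon.
_PRIMARY_RIM_NAMES = ("C6", "C5")


class BuilderError(ValueError):
    """Raised for invalid builder specifications."""


@dataclass(frozen=True)
class HPPlacement:
    """One hydroxypropyl substituent to attach: where and in which mode.

    ``mode`` is ``"exterior"`` (HP points away from the cavity, default
    target d4 = 8 A) or ``"inserted"`` (HP centre of mass inside the
    cavity, default target d4 = 1.5 A, well below the 3 A self-closure
    criterion).
    """

    anchor_unit: int
    position: str = "O6"  # O6 = primary rim, O2 = secondary rim
    mode: str = "exterior"
    target_d4: float | None = None

    @property
    def d4(self) -> float:
        if self.target_d4 is not None:
            return self.target_d4
        return 8.0 if self.mode == "exterior" else 1.5


@dataclass(frozen=True)
class BuilderSpec:
    """Parameters of one synthetic conformer state.

    Lengths in Angstrom.  Radii of the rim atoms are expressed as
    offsets from ``circumradius`` (the O4 n-gon radius) so that the
    whole ring scales coherently.  ``d1_target`` fixes the angular
    stagger of the secondary-rim O2/O3 atoms so that every adjacent
    O2(i)-O3(i+1) distance equals it exactly.
    """

    n_units: int = 7
    circumradius: float = 5.0
    d1_target: float = 3.5
    secondary_rim_radius_offset: float = 0.6
    secondary_rim_height: float = 1.2
    c2_radius_offset: float = -0.2
    c2_height: float = 0.0
    c6_radius_offset: float = -0.2
    c6_height: float = -2.4
    hp_placements: tuple[HPPlacement, ...] = ()
    flip_units: frozenset[int] = frozenset()
    ellipse_ratio: float = 1.0
    noise_sigma: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_units < 3:
            raise BuilderError("n_units must be >= 3")
        if self.circumradius <= 0:
            raise BuilderError("circumradius must be positive")
        if not 0 < self.ellipse_ratio <= 1:
            raise BuilderError("ellipse_ratio must be in (0, 1]")
        if self.noise_sigma < 0:
            raise BuilderError("noise_sigma must be >= 0")
        if not self.flip_units <= set(range(1, self.n_units + 1)):
            raise BuilderError(f"flip_units outside 1..{self.n_units}")
        r23 = self.circumradius + self.secondary_rim_radius_offset
        if not 0 < self.d1_target < 2 * r23 * np.sin(np.pi / self.n_units):
            raise BuilderError("d1_target unreachable on the secondary rim circle")
        keys = [(p.anchor_unit, p.position) for p in self.hp_placements]
        if len(keys) != len(set(keys)):
            raise BuilderError("duplicate HP placement (unit, position)")
        for p in self.hp_placements:
            if not 1 <= p.anchor_unit <= self.n_units:
                raise BuilderError(f"HP anchor unit {p.anchor_unit} out of range")
            if p.position not in ("O2", "O6"):
                raise BuilderError(f"HP position {p.position!r} must be O2 or O6")
            if p.mode not in ("exterior", "inserted"):
                raise BuilderError(f"HP mode {p.mode!r} must be exterior or inserted")
            if p.d4 <= 0:
                raise BuilderError("HP target d4 must be positive")

    @property
    def n_flipped_units(self) -> int:
        return len(self.flip_units)

    @property
    def n_flips(self) -> int:
        """Expected flip-angle count: adjacent pairs with exactly one flipped unit.

        Flipping a glucose unit sends *both* pair angles flanking it
        above 90 deg (its C6 is opposite each neighbour's), so an
        isolated flipped unit contributes two counted angles, while two
        adjacent flipped units share a same-side pair that does not
        count.  This is the value the flip classifier recovers on a
        noiseless built frame.
        """
        n = self.n_units
        return sum(
            1
            for i in range(1, n + 1)
            if (i in self.flip_units) != ((i % n) + 1 in self.flip_units)
        )

    @property
    def n_inserted(self) -> int:
        return sum(1 for p in self.hp_placements if p.mode == "inserted")


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame state labels of a generated ensemble, plus the mixture specs."""

    table: pd.DataFrame  # frame, state, n_flipped_units, n_flips, n_inserted, ellipse_ratio
    specs: tuple[BuilderSpec, ...]


# ---------------------------------------------------------------------------
# Ring construction
# ---------------------------------------------------------------------------

def _ring_topology(spec: BuilderSpec) -> CDTopology:
    n = spec.n_units
    per = len(_RING_ATOM_NAMES)
    unit_atoms = []
    membership = np.zeros(n * per, dtype=int)
    names: list[str] = []
    elements: list[str] = []
    for u in range(n):
        base = u * per
        roles = {role: base + k for k, role in enumerate(_RING_ATOM_NAMES[:5])}
        unit_atoms.append(roles)
        membership[base : base + per] = u + 1
        names.extend(_RING_ATOM_NAMES)
        elements.extend(_RING_ELEMENTS)
    return CDTopology(
        n_units=n,
        unit_atoms=tuple(unit_atoms),
        unit_membership=membership,
        hp_groups=(),
        masses=masses_from_elements(elements),
        atom_names=tuple(names),
        elements=tuple(elements),
    )


def _ring_coords(spec: BuilderSpec) -> np.ndarray:
    n, R = spec.n_units, spec.circumradius
    dphi = 2 * np.pi / n
    r23 = R + spec.secondary_rim_radius_offset
    delta = dphi / 2 - np.arcsin(spec.d1_target / (2 * r23))
    # (radius, angular offset, z) per atom of one unit, in _RING_ATOM_NAMES order
    local = {
        "O2": (r23, +delta, spec.secondary_rim_height),
        "O3": (r23, -delta, spec.secondary_rim_height),
        "O4": (R, 0.0, 0.0),
        "C2": (R + spec.c2_radius_offset, 0.0, spec.c2_height),
        "C6": (R + spec.c6_radius_offset, 0.0, spec.c6_height),
        "C1": (R - 0.2, -0.05, 0.3),
        "C5": (R - 0.4, +0.05, -0.6),
    }
    coords = np.empty((n * len(_RING_ATOM_NAMES), 3))
    for u in range(n):
        phi = u * dphi
        for k, name in enumerate(_RING_ATOM_NAMES):
            rad, off, z = local[name]
            a = phi + off
            coords[u * len(_RING_ATOM_NAMES) + k] = (rad * np.cos(a), rad * np.sin(a), z)
    return coords


def build_regular_cd(spec: BuilderSpec | None = None) -> tuple[Conformation, CDTopology]:
    """Build the undistorted reference conformer (no flips, no HP, circular).

    The O4 atoms sit on a regular ``n_units``-gon of radius
    ``circumradius``; every unit has identical local geometry, so all
    d1 equal ``d1_target``, all d2 equal the n-gon chord
    ``2 R sin(pi/n)``, all d3 are equal (circularity exactly 1 within
    floating point) and every flip angle is below 90 deg.
    """
    spec = spec or BuilderSpec()
    spec.validate()
    if spec.flip_units or spec.ellipse_ratio != 1.0 or spec.noise_sigma != 0.0:
        raise BuilderError(
            "build_regular_cd builds the undistorted reference; "
            "use build_conformation for flipped/elliptical/noisy states"
        )
    topology = _ring_topology(spec)
    conf = Conformation(coords=_ring_coords(spec))
    from .descriptors import flip_angles  # deferred: avoids import cycle at module load

    if np.any(flip_angles(conf, topology) >= 90.0):
        raise BuilderError("builder offsets produce flip angles >= 90 deg on the reference")
    return conf, topology


# ---------------------------------------------------------------------------
# State transformations
# ---------------------------------------------------------------------------

def _o4_plane(conf: Conformation, topology: CDTopology) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane of the O4 atoms."""
    o4 = conf.coords[[topology.role_index(i, "O4") for i in range(1, topology.n_units + 1)]]
    centroid = o4.mean(axis=0)
    _, _, vt = np.linalg.svd(o4 - centroid)
    return centroid, vt[2]


def apply_flip(conf: Conformation, topology: CDTopology, unit: int) -> Conformation:
    """Flip one glucose unit by reflecting its primary-rim atoms.

    The unit's C6 atom (and its primary-rim filler, when named) is
    reflected through the best-fit plane of the glycosidic O4 atoms.
    Because the O4 atoms are untouched, the operation is an exact
    involution, and the two adjacent-pair angles flanking the unit move
    from ~60 deg to ~120 deg on builder geometry.
    """
    if not 1 <= unit <= topology.n_units:
        raise BuilderError(f"flip unit {unit} outside 1..{topology.n_units}")
    centroid, normal = _o4_plane(conf, topology)
    targets = [topology.role_index(unit, "C6")]
    if topology.atom_names is not None:
        for a in topology.unit_ring_atoms(unit):
            if topology.atom_names[a] in _PRIMARY_RIM_NAMES and a not in targets:
                targets.append(a)
    coords = conf.coords.copy()
    for a in targets:
        coords[a] = coords[a] - 2 * np.dot(coords[a] - centroid, normal) * normal
    return dataclasses.replace(conf, coords=coords)


def apply_ellipse(conf: Conformation, topology: CDTopology, ratio: float) -> Conformation:
    """Squeeze the ring by scaling one in-plane axis by ``ratio`` <= 1.

    The axis is the in-plane direction through unit 1's O4 atom; scaling
    is about the O4 centroid.  ``ratio=1`` is the identity; smaller
    ratios make the cavity elliptical and strictly lower circularity.
    """
    if ratio <= 0:
        raise BuilderError("ellipse ratio must be positive")
    if ratio == 1.0:
        return conf
    centroid, normal = _o4_plane(conf, topology)
    axis = conf.coords[topology.role_index(1, "O4")] - centroid
    axis -= np.dot(axis, normal) * normal
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise BuilderError("cannot determine in-plane ellipse axis")
    axis /= norm
    rel = conf.coords - centroid
    coords = centroid + rel + (ratio - 1.0) * np.outer(rel @ axis, axis)
    return dataclasses.replace(conf, coords=coords)


def place_hp(
    conf: Conformation,
    topology: CDTopology,
    anchor_unit: int,
    position: str = "O6",
    mode: str = "exterior",
    target_d4: float | None = None,
) -> tuple[Conformation, CDTopology]:
    """Attach one 4-pseudo-atom hydroxypropyl group.

    The group's centre of mass is placed exactly ``target_d4`` from the
    macrocycle's centre of mass: radially outward through the anchor
    unit's O4 for ``exterior``, or along the ring axis on the anchoring
    rim's side for ``inserted`` (emulating an HP rotated into the
    cavity).  Returns the extended conformation and topology.
    """
    placement = HPPlacement(anchor_unit, position, mode, target_d4)
    if any(
        (g.anchor_unit, g.position) == (anchor_unit, position) for g in topology.hp_groups
    ):
        raise BuilderError(f"unit {anchor_unit} already has an HP at {position}")
    if not 1 <= anchor_unit <= topology.n_units:
        raise BuilderError(f"HP anchor unit {anchor_unit} out of range")
    if position not in _HP_NAMES:
        raise BuilderError(f"HP position {position!r} must be O2 or O6")
    if placement.d4 <= 0:
        raise BuilderError("HP target d4 must be positive")

    ring = topology.ring_atom_set
    from .descriptors import center_of_mass  # deferred import, avoids cycle

    ring_com = center_of_mass(conf.coords[ring], topology.masses[ring])
    if mode == "exterior":
        direction = conf.coords[topology.role_index(anchor_unit, "O4")] - ring_com
        direction = direction / np.linalg.norm(direction)
    elif mode == "inserted":
        centroid, normal = _o4_plane(conf, topology)
        c6 = conf.coords[[topology.role_index(i, "C6") for i in range(1, topology.n_units + 1)]]
        primary_sign = np.sign(np.dot(c6.mean(axis=0) - centroid, normal)) or 1.0
        direction = normal * (primary_sign if position == "O6" else -primary_sign)
    else:
        raise BuilderError(f"HP mode {mode!r} must be exterior or inserted")
    hp_com = ring_com + placement.d4 * direction

    # Offsets with zero mass-weighted mean, so the group COM is exact.
    m_c, m_o = STANDARD_MASSES["C"], STANDARD_MASSES["O"]
    offsets = np.array(
        [
            (0.6, 0.0, 0.0),
            (-0.6, 0.0, 0.0),
            (0.0, 0.5, 0.0),
            (0.0, -0.5 * m_c / m_o, 0.0),
        ]
    )
    coords = np.vstack([conf.coords, hp_com + offsets])
    start = topology.n_atoms
    group = HPGroup(anchor_unit, position, tuple(range(start, start + 4)))
    names = _HP_NAMES[position]
    new_topology = dataclasses.replace(
        topology,
        unit_membership=np.concatenate([topology.unit_membership, np.zeros(4, dtype=int)]),
        hp_groups=topology.hp_groups + (group,),
        masses=np.concatenate([topology.masses, [m_c, m_c, m_c, m_o]]),
        atom_names=(topology.atom_names + names) if topology.atom_names else None,
        elements=(topology.elements + _HP_ELEMENTS) if topology.elements else None,
    )
    return dataclasses.replace(conf, coords=coords), new_topology


def build_conformation(
    spec: BuilderSpec, rng: np.random.Generator | None = None
) -> tuple[Conformation, CDTopology]:
    """Build one conformer realising every field of ``spec``.

    Order of operations: regular ring, flips, elliptical squeeze, HP
    placement (d4 targets measured on the distorted ring), then optional
    isotropic Gaussian coordinate noise.
    """
    spec.validate()
    base = dataclasses.replace(
        spec, flip_units=frozenset(), ellipse_ratio=1.0, noise_sigma=0.0, hp_placements=()
    )
    conf, topology = build_regular_cd(base)
    for unit in sorted(spec.flip_units):
        conf = apply_flip(conf, topology, unit)
    conf = apply_ellipse(conf, topology, spec.ellipse_ratio)
    for p in spec.hp_placements:
        conf, topology = place_hp(conf, topology, p.anchor_unit, p.position, p.mode, p.d4)
    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        conf = dataclasses.replace(
            conf, coords=conf.coords + rng.normal(0.0, spec.noise_sigma, conf.coords.shape)
        )
    return conf, topology


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

def _state_signature(spec: BuilderSpec) -> tuple:
    return (spec.n_units, tuple((p.anchor_unit, p.position) for p in spec.hp_placements))


def generate_ensemble(
    state_mixture: Sequence[tuple[BuilderSpec, float]],
    n_frames: int,
    noise_sigma: float = 0.05,
    seed: int | None = None,
    temperature: float = 300.0,
) -> tuple[Ensemble, CDTopology, GroundTruth]:
    """Draw frames i.i.d. from a mixture of builder states.

    Every frame is one mixture state's noiseless conformer plus
    isotropic Gaussian coordinate noise of ``noise_sigma`` (A).  All
    states must share one topology (same unit count and HP anchors).
    The returned :class:`GroundTruth` labels every frame; the same seed
    reproduces the ensemble bit for bit.
    """
    if n_frames <= 0:
        raise BuilderError("n_frames must be positive")
    if not state_mixture:
        raise BuilderError("state mixture is empty")
    fractions = np.array([f for _, f in state_mixture], dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise BuilderError("mixture fractions must be >= 0 and sum to 1")
    specs = tuple(s for s, _ in state_mixture)
    signatures = {_state_signature(s) for s in specs}
    if len(signatures) != 1:
        raise BuilderError("mixture states must share one topology (units and HP anchors)")

    bases = []
    topology = None
    for s in specs:
        conf, topo = build_conformation(dataclasses.replace(s, noise_sigma=0.0))
        bases.append(conf.coords)
        topology = topo
    rng = np.random.default_rng(seed)
    states = rng.choice(len(specs), size=n_frames, p=fractions)
    frames = []
    for i, k in enumerate(states):
        coords = bases[k]
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
        frames.append(Conformation(coords=coords, frame_id=i, temperature_label=temperature))
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "frame": np.arange(n_frames),
                "state": states,
                "n_flipped_units": [specs[k].n_flipped_units for k in states],
                "n_flips": [specs[k].n_flips for k in states],
                "n_inserted": [specs[k].n_inserted for k in states],
                "ellipse_ratio": [specs[k].ellipse_ratio for k in states],
            }
        ),
        specs=specs,
    )
    ensemble = Ensemble(frames=frames, temperature=temperature, source=f"synthetic(seed={seed})")
    return ensemble, topology, truth


def random_conformations(
    n: int,
    seed: int | None = None,
    ellipse_range: tuple[float, float] = (0.5, 1.0),
    flip_probability: float = 0.2,
    noise_sigma: float = 0.1,
) -> Iterator[tuple[Conformation, CDTopology]]:
    """Yield randomly distorted conformers (random flip sets, ellipse, noise).

    Used to probe descriptor bounds over a broad, seeded state space
    rather than a fixed mixture.
    """
    rng = np.random.default_rng(seed)
    for _ in range(n):
        flips = frozenset(
            u for u in range(1, 8) if rng.random() < flip_probability
        )
        ratio = float(rng.uniform(*ellipse_range))
        spec = BuilderSpec(flip_units=flips, ellipse_ratio=ratio, noise_sigma=noise_sigma)
        yield build_conformation(spec, rng=rng)


# ---------------------------------------------------------------------------
# Named mixtures (qualitative analogues of observed conformational states)
# ---------------------------------------------------------------------------

def flip_mixture(
    no_flip: float = 0.58, one_flip: float = 0.35, two_flips: float = 0.07
) -> list[tuple[BuilderSpec, float]]:
    """Unsubstituted-CD mixture over 0/1/2-flip states.

    Defaults mirror the flip-state populations of an unsubstituted
    beta-CD ensemble at 300 K (58/35/7%).  The two-flip state flips two
    non-adjacent units.
    """
    return [
        (BuilderSpec(), no_flip),
        (BuilderSpec(flip_units=frozenset({1})), one_flip),
        (BuilderSpec(flip_units=frozenset({1, 4})), two_flips),
    ]


def closure_mixture(
    closure_fraction: float = 0.4,
    anchor_unit: int = 1,
    position: str = "O6",
) -> list[tuple[BuilderSpec, float]]:
    """Single-HP mixture of exterior (open) and inserted (self-closed) states."""
    exterior = BuilderSpec(hp_placements=(HPPlacement(anchor_unit, position, "exterior"),))
    inserted = BuilderSpec(hp_placements=(HPPlacement(anchor_unit, position, "inserted"),))
    return [(exterior, 1.0 - closure_fraction), (inserted, closure_fraction)]
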