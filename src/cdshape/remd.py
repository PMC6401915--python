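"""Toy replica-exchange Monte Carlo over the synthetic CD state space.

A deliberately minimal surrogate for temperature-structured sampling:
the state of one replica is a discrete conformational label (set of
flipped glucose units, per-HP exterior/inserted mode, and optionally a
continuous elliptical-distortion ratio), scored by a naive additive
energy model.  Replicas run Metropolis sweeps at a ladder of
temperatures and periodically attempt neighbour exchanges with the
standard acceptance min(1, exp[(bi - bj)(Ei - Ej)]).  Sampled states are
rendered into conformers through the synthetic builder, giving
temperature-demultiplexed ensembles on which the ensemble statistics
(flip populations, closure percentage vs temperature) can be exercised
end to end.

The energy model is *not* a molecular force field and makes no claim of
chemical realism; it exists to give the statistics layer input with a
controlled, known temperature dependence.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL_MOL_K
from .synthetic import BuilderSpec, build_conformation
from .topology import Conformation, Ensemble


class REMDError(ValueError):
    """Raised for invalid sampler configuration."""


@dataclass(frozen=True)
class ToyEnergyModel:
    """Additive surrogate energies, kcal/mol.

    * each flipped glucose unit costs ``flip_penalty``;
    * each inserted HP group gains ``-insertion_well`` (a favourable
      well for positive values, so self-closure becomes *less* likely
      as temperature rises);
    * ``insertion_barrier`` symmetrically damps HP mode-toggle
      acceptance by exp(-barrier/kBT) in both directions — it slows the
      insertion/ejection kinetics without changing the stationary
      distribution;
    * elliptical distortion costs ``ellipse_stiffness * n_units *
      (1 - ratio)^2``.
    """

    flip_penalty: float = 1.5
    insertion_well: float = 1.0
    insertion_barrier: float = 2.0
    ellipse_stiffness: float = 20.0

    def __post_init__(self) -> None:
        if min(self.flip_penalty, self.insertion_well, self.insertion_barrier) < 0:
            raise REMDError("energy-model penalties must be >= 0")

    def energy(self, state: "ReplicaState", n_units: int) -> float:
        e = self.flip_penalty * len(state.flips)
        e -= self.insertion_well * sum(1 for m in state.hp_modes if m == "inserted")
        e += self.ellipse_stiffness * n_units * (1.0 - state.ellipse_ratio) ** 2
        return e


@dataclass(frozen=True)
class ToyStateSpace:
    """What a replica state may vary: units, HP count, ellipse bounds."""

    n_units: int = 7
    n_hp: int = 0
    ellipse_enabled: bool = False
    ratio_bounds: tuple[float, float] = (0.5, 1.0)
    ellipse_step: float = 0.05


@dataclass(frozen=True)
class ReplicaState:
    """Discrete conformational state of one replica plus its energy."""

    flips: frozenset[int]
    hp_modes: tuple[str, ...]
    ellipse_ratio: float
    energy: float


def initial_state(space: ToyStateSpace, model: ToyEnergyModel) -> ReplicaState:
    """Ground-like starting state: no flips, all HP exterior, circular ring."""
    state = ReplicaState(frozenset(), ("exterior",) * space.n_hp, 1.0, 0.0)
    return dataclasses.replace(state, energy=model.energy(state, space.n_units))


@dataclass(frozen=True)
class ReplicaLadder:
    """Ascending replica temperatures and the exchange-attempt cadence.

    Temperatures must be non-decreasing with at least two replicas
    (equal temperatures are permitted; every exchange between them is
    accepted).
    """

    temperatures: tuple[float, ...]
    exchange_interval: int = 10  # MC sweeps between exchange attempts

    def __post_init__(self) -> None:
        t = self.temperatures
        if len(t) < 2:
            raise REMDError("ladder needs at least 2 replicas")
        if min(t) <= 0:
            raise REMDError("temperatures must be positive")
        if any(b < a for a, b in zip(t, t[1:])):
            raise REMDError("ladder temperatures must be ascending")
        if self.exchange_interval < 1:
            raise REMDError("exchange interval must be >= 1 sweep")

    def __len__(self) -> int:
        return len(self.temperatures)


def geometric_ladder(t_min: float, t_max: float, n: int) -> ReplicaLadder:
    """Geometrically spaced ladder t_min * r^k with r = (t_max/t_min)^(1/(n-1)).

    Geometric spacing is the standard equal-acceptance heuristic; the
    endpoints are hit exactly.  The conventional 8-replica ladder from
    269.5 K to 570.9 K has every adjacent gap inside 30-60 K.
    """
    if not 0 < t_min < t_max:
        raise REMDError("need 0 < t_min < t_max")
    if n < 2:
        raise REMDError("need at least 2 replicas")
    ratio = (t_max / t_min) ** (1.0 / (n - 1))
    temps = [t_min * ratio**k for k in range(n)]
    temps[0], temps[-1] = t_min, t_max
    return ReplicaLadder(temperatures=tuple(temps))


def exchange_probability(
    energy_i: float, energy_j: float, temp_i: float, temp_j: float
) -> float:
    """Metropolis acceptance for swapping configurations between replicas.

    p = min(1, exp[(bi - bj)(Ei - Ej)]) with b = 1/(kB T); symmetric
    under swapping the (i, j) labels, and 1 whenever the energies or the
    temperatures coincide.
    """
    if temp_i <= 0 or temp_j <= 0:
        raise REMDError("temperatures must be positive")
    beta_i = 1.0 / (KB_KCAL_MOL_K * temp_i)
    beta_j = 1.0 / (KB_KCAL_MOL_K * temp_j)
    log_p = (beta_i - beta_j) * (energy_i - energy_j)
    return 1.0 if log_p >= 0 else math.exp(log_p)


def _metropolis(delta_e: float, kt: float, rng: np.random.Generator, extra_log: float = 0.0) -> bool:
    log_p = extra_log + (0.0 if delta_e <= 0 else -delta_e / kt)
    return log_p >= 0 or rng.random() < math.exp(log_p)


def mc_sweep(
    state: ReplicaState,
    model: ToyEnergyModel,
    temperature: float,
    rng: np.random.Generator,
    space: ToyStateSpace,
) -> ReplicaState:
    """One Metropolis sweep: every flip toggle, every HP toggle, one ellipse move.

    Energies are kept incrementally; ``model.energy`` on the returned
    state reproduces the bookkept value to floating-point accuracy.
    """
    kt = KB_KCAL_MOL_K * temperature
    flips = set(state.flips)
    modes = list(state.hp_modes)
    ratio = state.ellipse_ratio
    energy = state.energy

    for unit in range(1, space.n_units + 1):
        delta = -model.flip_penalty if unit in flips else model.flip_penalty
        if _metropolis(delta, kt, rng):
            flips.symmetric_difference_update({unit})
            energy += delta

    barrier_log = -model.insertion_barrier / kt
    for j in range(space.n_hp):
        delta = model.insertion_well if modes[j] == "inserted" else -model.insertion_well
        if _metropolis(delta, kt, rng, extra_log=barrier_log):
            modes[j] = "exterior" if modes[j] == "inserted" else "inserted"
            energy += delta

    if space.ellipse_enabled:
        lo, hi = space.ratio_bounds
        proposal = ratio + rng.normal(0.0, space.ellipse_step)
        while proposal < lo or proposal > hi:  # reflect (keeps the proposal symmetric)
            if proposal > hi:
                proposal = 2 * hi - proposal
            if proposal < lo:
                proposal = 2 * lo - proposal
        stiff = model.ellipse_stiffness * space.n_units
        delta = stiff * ((1 - proposal) ** 2 - (1 - ratio) ** 2)
        if _metropolis(delta, kt, rng):
            ratio = proposal
            energy += delta

    return ReplicaState(frozenset(flips), tuple(modes), ratio, energy)


@dataclass
class ExchangeReport:
    """Attempt/acceptance counters for one neighbouring replica pair."""

    pair: tuple[int, int]
    temperatures: tuple[float, float]
    attempts: int = 0
    accepted: int = 0

    @property
    def rate(self) -> float:
        return self.accepted / self.attempts if self.attempts else float("nan")


@dataclass
class REMDResult:
    """Demultiplexed toy-REMD output: per-temperature ensembles and diagnostics."""

    ensembles: dict[float, Ensemble]
    states: dict[float, list[ReplicaState]]
    acceptance: list[ExchangeReport]
    topology: object  # CDTopology of the rendered conformers (None if not rendered)
    ladder: ReplicaLadder


def _render(state: ReplicaState, base_spec: BuilderSpec, cache: dict) -> tuple:
    key = (state.flips, state.hp_modes, round(state.ellipse_ratio, 6))
    if key not in cache:
        hp = tuple(
            dataclasses.replace(p, mode=state.hp_modes[j])
            for j, p in enumerate(base_spec.hp_placements)
        )
        spec = dataclasses.replace(
            base_spec,
            flip_units=state.flips,
            ellipse_ratio=state.ellipse_ratio,
            hp_placements=hp,
            noise_sigma=0.0,
        )
        cache[key] = build_conformation(spec)
    return cache[key]


def run_remd(
    model: ToyEnergyModel,
    ladder: ReplicaLadder,
    base_spec: BuilderSpec | None = None,
    n_sweeps: int = 2000,
    sample_interval: int = 10,
    burn_in: int = 0,
    seed: int | None = None,
    space: ToyStateSpace | None = None,
    render: bool = True,
) -> REMDResult:
    """Run the replica ladder: MC sweeps alternated with neighbour exchanges.

    Each temperature slot holds one walker; accepted exchanges swap the
    *configurations* of neighbouring slots (alternating even/odd pair
    parity across attempts), so the samples collected in slot k are
    already demultiplexed at temperature k.  After ``burn_in`` sweeps,
    every ``sample_interval``-th sweep contributes one sample per slot;
    with ``render=True`` samples are turned into conformers through the
    synthetic builder.  The same seed reproduces the run exactly.
    """
    if n_sweeps <= 0:
        raise REMDError("n_sweeps must be positive")
    base_spec = base_spec or BuilderSpec()
    if space is None:
        space = ToyStateSpace(
            n_units=base_spec.n_units,
            n_hp=len(base_spec.hp_placements),
            ellipse_enabled=False,
        )
    if space.n_hp != len(base_spec.hp_placements):
        raise REMDError("state space HP count must match base_spec placements")
    rng = np.random.default_rng(seed)
    temps = ladder.temperatures
    replicas = [initial_state(space, model) for _ in temps]
    samples: dict[float, list[ReplicaState]] = {t: [] for t in temps}
    reports = [
        ExchangeReport(pair=(k, k + 1), temperatures=(temps[k], temps[k + 1]))
        for k in range(len(temps) - 1)
    ]
    parity = 0
    for sweep in range(1, n_sweeps + 1):
        for k, t in enumerate(temps):
            replicas[k] = mc_sweep(replicas[k], model, t, rng, space)
        if sweep % ladder.exchange_interval == 0:
            for k in range(parity, len(temps) - 1, 2):
                p = exchange_probability(
                    replicas[k].energy, replicas[k + 1].energy, temps[k], temps[k + 1]
                )
                reports[k].attempts += 1
                if rng.random() < p:
                    reports[k].accepted += 1
                    replicas[k], replicas[k + 1] = replicas[k + 1], replicas[k]
            parity = 1 - parity
        if sweep > burn_in and (sweep - burn_in) % sample_interval == 0:
            for k, t in enumerate(temps):
                samples[t].append(replicas[k])

    ensembles: dict[float, Ensemble] = {}
    topology = None
    if render:
        cache: dict = {}
        for t in temps:
            frames = []
            for i, st in enumerate(samples[t]):
                conf, topology = _render(st, base_spec, cache)
                frames.append(
                    Conformation(coords=conf.coords, frame_id=i, temperature_label=t)
                )
            ensembles[t] = Ensemble(
                frames=frames, temperature=t, source=f"toy-remd(seed={seed})"
            )
    return REMDResult(
        ensembles=ensembles,
        states=samples,
        acceptance=reports,
        topology=topology,
        ladder=ladder,
    )
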