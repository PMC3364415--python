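"""Core domain types for the hierarchical ephemeral-speciation simulator.

The model has two levels. *Incipient lineages* are the atomic units: each
living lineage independently branches (producing a new incipient lineage in
the same species), is lost (local extinction or reabsorption into its
parental species), or converts into a new "full species". *Full species* are
the higher-level entities: a species is simply the set of its living
incipient lineages, and it persists for exactly as long as that set is
non-empty.

All times are in millions of years (Myr); all rates are per incipient
lineage per Myr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "BRANCH",
    "LOSS",
    "CONVERSION",
    "REABSORPTION",
    "SPECIES_EXTINCTION",
    "ModelParams",
    "BDParams",
    "LineageNode",
    "LineageTree",
    "Event",
    "EventLog",
    "SimResult",
    "LineageCapExceeded",
    "SurvivalConditioningError",
]

# Event kinds
BRANCH = "branch"
LOSS = "loss"
CONVERSION = "conversion"

# Loss labels
REABSORPTION = "reabsorption"
SPECIES_EXTINCTION = "species_extinction"


class LineageCapExceeded(RuntimeError):
    """Raised when the number of concurrently alive lineages exceeds the cap.

    The partially completed simulation is attached as ``.result`` (with
    ``capped=True``) so callers can inspect it; it is never returned as if
    it were a complete replicate.
    """

    def __init__(self, message: str, result: "SimResult"):
        super().__init__(message)
        self.result = result


class SurvivalConditioningError(RuntimeError):
    """Raised when rejection sampling fails to find a surviving replicate."""

    def __init__(self, message: str, attempts: int):
        super().__init__(message)
        self.attempts = attempts


def _check_rate(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the hierarchical ephemeral-speciation model.

    Parameters
    ----------
    lambda_i : float
        Incipient-speciation (branching) rate per incipient lineage per Myr.
    mu_i : float
        Incipient-loss rate per incipient lineage per Myr. A loss is
        recorded as reabsorption when the species retains at least one
        other living lineage, and as whole-species extinction otherwise.
    lambda_f : float
        Full-species-formation (conversion) rate per incipient lineage per
        Myr: the rate at which an incipient lineage attains independent
        species status.
    t_max : float
        Simulation horizon in Myr.
    max_lineages : int
        Hard cap on concurrently alive incipient lineages (memory guard).
        Exceeding it raises :class:`LineageCapExceeded`; growth is never
        silently truncated.
    seed : int
        Seed for the replicate's random number generator.
    """

    lambda_i: float
    mu_i: float
    lambda_f: float
    t_max: float
    max_lineages: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambda_i", _check_rate("lambda_i", self.lambda_i))
        object.__setattr__(self, "mu_i", _check_rate("mu_i", self.mu_i))
        object.__setattr__(self, "lambda_f", _check_rate("lambda_f", self.lambda_f))
        if not (math.isfinite(self.t_max) and self.t_max > 0):
            raise ValueError(f"t_max must be finite and > 0, got {self.t_max!r}")
        if self.max_lineages < 1:
            raise ValueError("max_lineages must be >= 1")


@dataclass(frozen=True)
class BDParams:
    """Parameters of the constant-rate ("high turnover") birth-death model.

    Every lineage is its own species: ``lambda_`` is the speciation rate and
    ``mu`` the extinction rate, both per lineage per Myr.
    """

    lambda_: float
    mu: float
    t_max: float
    max_lineages: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambda_", _check_rate("lambda", self.lambda_))
        object.__setattr__(self, "mu", _check_rate("mu", self.mu))
        if not (math.isfinite(self.t_max) and self.t_max > 0):
            raise ValueError(f"t_max must be finite and > 0, got {self.t_max!r}")
        if self.max_lineages < 1:
            raise ValueError("max_lineages must be >= 1")


@dataclass(slots=True)
class LineageNode:
    """One incipient lineage in the genealogy.

    ``species_id`` is the species the lineage belonged to at birth. Each
    time the lineage converts (founds a new full species) an entry
    ``(time, new_species_id)`` is appended to ``conversions``; a lineage
    may convert more than once. ``fate`` is ``"alive"`` (extant at the
    horizon) or ``"lost"`` (died); branching does not terminate a lineage
    in this bookkeeping — a lineage is a single path through time and may
    branch many times.
    """

    id: int
    parent_id: Optional[int]
    birth_time: float
    species_id: int
    death_time: Optional[float] = None
    conversions: list = field(default_factory=list)
    fate: str = "alive"

    def species_at(self, time: float) -> int:
        """Species membership of this lineage at a given time (conversion
        takes effect at the instant of the event)."""
        sp = self.species_id
        for conv_time, new_sp in self.conversions:
            if time >= conv_time:
                sp = new_sp
            else:
                break
        return sp


@dataclass
class LineageTree:
    """Full genealogy of incipient lineages from a single simulation."""

    nodes: list[LineageNode]
    origin_time: float = 0.0
    horizon: float = 0.0

    @property
    def root(self) -> LineageNode:
        return self.nodes[0]

    def node(self, lineage_id: int) -> LineageNode:
        return self.nodes[lineage_id]

    def n_alive(self) -> int:
        return sum(1 for nd in self.nodes if nd.death_time is None)


@dataclass(slots=True)
class Event:
    """One event in the simulation history.

    ``kind`` is one of ``branch`` / ``loss`` / ``conversion``. ``label`` is
    set only for loss events (``reabsorption`` or ``species_extinction``).
    For branch events ``child_id`` is the new lineage; for conversion events
    ``species_id`` is the newly founded species and ``parent_species_id``
    the species the converting lineage left.
    """

    time: float
    kind: str
    lineage_id: int
    species_id: int
    label: Optional[str] = None
    child_id: Optional[int] = None
    parent_species_id: Optional[int] = None


@dataclass
class EventLog:
    """Time-ordered record of every event, with the generating parameters."""

    events: list[Event]
    params: object
    n_alive_final: int = 0

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def running_lineage_count(self) -> list[tuple[float, int]]:
        """Lineage count after each event (branch +1, loss -1, conversion 0)."""
        n = 1
        out = []
        for ev in self.events:
            if ev.kind == BRANCH:
                n += 1
            elif ev.kind == LOSS:
                n -= 1
            if n < 0:
                raise AssertionError("negative lineage count in event log")
            out.append((ev.time, n))
        return out


@dataclass
class SimResult:
    """Output of one simulation replicate.

    ``surviving`` is true when at least one incipient lineage is alive at
    the horizon; ``n_species_extant`` counts species with >= 1 living
    lineage at the horizon. ``attempts`` is filled by survival
    conditioning (number of rejection-sampling tries).
    """

    lineage_tree: LineageTree
    event_log: EventLog
    surviving: bool
    n_species_extant: int
    capped: bool = False
    attempts: Optional[int] = None
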