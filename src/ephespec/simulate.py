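"""Event-driven (Gillespie) simulation of the hierarchical model and the
constant-rate birth-death baseline.

Both simulators start from a single lineage at time 0 and run to the
horizon ``t_max``, drawing exponentially distributed waiting times with
total rate ``n_alive * (sum of per-lineage rates)``, choosing the affected
lineage uniformly among the living and the event kind with probabilities
proportional to the per-lineage rates. Ties in time cannot occur with
continuous waiting times; event order is the order of occurrence.

In the hierarchical model a *conversion* gives the chosen lineage a fresh
species identity containing only itself; incipient lineages it spawned
earlier stay in the old species. A species whose last living lineage is
lost disappears by whole-species extinction; a species whose sole living
lineage converts is replaced anagenetically by the new species (no loss
event is involved).
"""

from __future__ import annotations

import numpy as np

from .model import (
    BRANCH,
    CONVERSION,
    LOSS,
    REABSORPTION,
    SPECIES_EXTINCTION,
    BDParams,
    Event,
    EventLog,
    LineageCapExceeded,
    LineageNode,
    LineageTree,
    ModelParams,
    SimResult,
    SurvivalConditioningError,
)

__all__ = [
    "simulate",
    "simulate_bd",
    "condition_on_survival",
    "expected_diversity",
]


def simulate(params: ModelParams) -> SimResult:
    """Run one replicate of the hierarchical ephemeral-speciation model.

    Returns the full incipient-lineage genealogy and event log. Raises
    :class:`ephespec.model.LineageCapExceeded` if the number of living
    lineages would exceed ``params.max_lineages``.
    """
    rng = np.random.default_rng(params.seed)
    lam_i, mu_i, lam_f = params.lambda_i, params.mu_i, params.lambda_f
    per_lineage = lam_i + mu_i + lam_f

    nodes = [LineageNode(id=0, parent_id=None, birth_time=0.0, species_id=0)]
    alive = [0]  # ids of living lineages; order irrelevant, swap-pop removal
    species_count = {0: 1}  # living lineages per species
    events: list[Event] = []
    next_species = 1
    t = 0.0
    capped = False

    while alive and per_lineage > 0.0:
        n = len(alive)
        t += rng.exponential(1.0 / (n * per_lineage))
        if t >= params.t_max:
            break
        idx = int(rng.integers(n))
        lid = alive[idx]
        node = nodes[lid]
        sp = node.species_at(t)
        u = rng.random() * per_lineage
        if u < lam_i:
            # branch: new incipient lineage in the same species
            if n + 1 > params.max_lineages:
                capped = True
                break
            cid = len(nodes)
            nodes.append(
                LineageNode(id=cid, parent_id=lid, birth_time=t, species_id=sp)
            )
            alive.append(cid)
            species_count[sp] += 1
            events.append(
                Event(time=t, kind=BRANCH, lineage_id=lid, species_id=sp, child_id=cid)
            )
        elif u < lam_i + mu_i:
            # loss: reabsorption if the species keeps other living lineages
            alive[idx] = alive[-1]
            alive.pop()
            node.death_time = t
            node.fate = "lost"
            species_count[sp] -= 1
            label = SPECIES_EXTINCTION if species_count[sp] == 0 else REABSORPTION
            if species_count[sp] == 0:
                del species_count[sp]
            events.append(
                Event(time=t, kind=LOSS, lineage_id=lid, species_id=sp, label=label)
            )
        else:
            # conversion: the lineage founds a new full species of itself
            new_sp = next_species
            next_species += 1
            node.conversions.append((t, new_sp))
            species_count[sp] -= 1
            if species_count[sp] == 0:
                del species_count[sp]  # anagenetic replacement, not extinction
            species_count[new_sp] = 1
            events.append(
                Event(
                    time=t,
                    kind=CONVERSION,
                    lineage_id=lid,
                    species_id=new_sp,
                    parent_species_id=sp,
                )
            )

    tree = LineageTree(nodes=nodes, origin_time=0.0, horizon=params.t_max)
    log = EventLog(events=events, params=params, n_alive_final=len(alive))
    result = SimResult(
        lineage_tree=tree,
        event_log=log,
        surviving=len(alive) >= 1,
        n_species_extant=len(species_count),
        capped=capped,
    )
    if capped:
        raise LineageCapExceeded(
            f"live lineage count exceeded max_lineages={params.max_lineages} "
            f"at t={t:.6g}",
            result,
        )
    return result


def simulate_bd(params: BDParams) -> SimResult:
    """Run one replicate of the constant-rate birth-death baseline.

    The output shares types with the hierarchical simulator: every lineage
    is its own species (``species_id == lineage_id``) and there are no
    conversion events, so all downstream summaries apply unchanged.
    """
    rng = np.random.default_rng(params.seed)
    lam, mu = params.lambda_, params.mu
    per_lineage = lam + mu

    nodes = [LineageNode(id=0, parent_id=None, birth_time=0.0, species_id=0)]
    alive = [0]
    events: list[Event] = []
    t = 0.0
    capped = False

    while alive and per_lineage > 0.0:
        n = len(alive)
        t += rng.exponential(1.0 / (n * per_lineage))
        if t >= params.t_max:
            break
        idx = int(rng.integers(n))
        lid = alive[idx]
        if rng.random() * per_lineage < lam:
            if n + 1 > params.max_lineages:
                capped = True
                break
            cid = len(nodes)
            nodes.append(
                LineageNode(id=cid, parent_id=lid, birth_time=t, species_id=cid)
            )
            alive.append(cid)
            events.append(
                Event(time=t, kind=BRANCH, lineage_id=lid, species_id=cid, child_id=cid)
            )
        else:
            alive[idx] = alive[-1]
            alive.pop()
            nodes[lid].death_time = t
            nodes[lid].fate = "lost"
            events.append(
                Event(
                    time=t,
                    kind=LOSS,
                    lineage_id=lid,
                    species_id=lid,
                    label=SPECIES_EXTINCTION,
                )
            )

    tree = LineageTree(nodes=nodes, origin_time=0.0, horizon=params.t_max)
    log = EventLog(events=events, params=params, n_alive_final=len(alive))
    result = SimResult(
        lineage_tree=tree,
        event_log=log,
        surviving=len(alive) >= 1,
        n_species_extant=len(alive),
        capped=capped,
    )
    if capped:
        raise LineageCapExceeded(
            f"live lineage count exceeded max_lineages={params.max_lineages} "
            f"at t={t:.6g}",
            result,
        )
    return result


def condition_on_survival(params, max_tries: int = 1000) -> SimResult:
    """Rejection-sample replicates until one survives to the horizon.

    Clades observed today are survivors; conditioning on survival is how
    the simulated trees acquire the survivorship bias that produces
    apparent early bursts. Attempt ``k`` (0-based) reseeds the generator
    with ``params.seed + k``. The returned result carries the number of
    attempts in ``result.attempts``. Works for both parameter types
    (:class:`ModelParams` and :class:`BDParams`).

    Raises
    ------
    SurvivalConditioningError
        If no surviving replicate is found within ``max_tries`` — a signal
        that the survival probability is too low for these parameters.
    """
    if max_tries < 1:
        raise ValueError("max_tries must be >= 1")
    sim = simulate_bd if isinstance(params, BDParams) else simulate
    for k in range(max_tries):
        p = _reseed(params, params.seed + k)
        result = sim(p)
        if result.surviving:
            result.attempts = k + 1
            return result
    raise SurvivalConditioningError(
        f"no surviving replicate in {max_tries} attempts "
        f"(survival probability too low for these parameters)",
        attempts=max_tries,
    )


def _reseed(params, seed: int):
    kwargs = {f: getattr(params, f) for f in params.__dataclass_fields__}
    kwargs["seed"] = seed
    return type(params)(**kwargs)


def expected_diversity(lambda_: float, mu: float, t: float, n0: int = 1) -> float:
    """Expected lineage count ``n0 * exp((lambda - mu) * t)`` under
    constant-rate birth-death growth. Depends on the rates only through
    the net diversification rate ``lambda - mu``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if lambda_ < 0 or mu < 0:
        raise ValueError("rates must be >= 0")
    return n0 * float(np.exp((lambda_ - mu) * t))
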