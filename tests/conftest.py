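"""Shared fixtures: a scripted builder for hand-made simulation results.

``build_result`` replays a hand-written list of actions into a consistent
``SimResult`` (nodes, events, labels, species bookkeeping), so tests can
state small genealogies exactly and derive expectations by hand.
"""

from __future__ import annotations

import pytest

from ephespec.model import (
    BRANCH,
    CONVERSION,
    LOSS,
    REABSORPTION,
    SPECIES_EXTINCTION,
    Event,
    EventLog,
    LineageNode,
    LineageTree,
    ModelParams,
    SimResult,
)


def build_result(horizon, actions, params=None):
    """Build a SimResult from a script of actions.

    Actions, in time order:
      ("branch", t, parent_lineage_id)   -> new lineage (next free id)
      ("loss", t, lineage_id)
      ("convert", t, lineage_id)         -> new species (next free id)
    Loss labels and species membership are derived by replay.
    """
    if params is None:
        params = ModelParams(lambda_i=1.0, mu_i=1.0, lambda_f=1.0, t_max=horizon)
    nodes = [LineageNode(id=0, parent_id=None, birth_time=0.0, species_id=0)]
    counts = {0: 1}
    events = []
    next_sp = 1
    for action in actions:
        kind, t, lid = action
        node = nodes[lid]
        sp = node.species_at(t)
        if kind == "branch":
            cid = len(nodes)
            nodes.append(LineageNode(id=cid, parent_id=lid, birth_time=t, species_id=sp))
            counts[sp] += 1
            events.append(Event(time=t, kind=BRANCH, lineage_id=lid, species_id=sp, child_id=cid))
        elif kind == "loss":
            node.death_time = t
            node.fate = "lost"
            counts[sp] -= 1
            label = SPECIES_EXTINCTION if counts[sp] == 0 else REABSORPTION
            if counts[sp] == 0:
                del counts[sp]
            events.append(Event(time=t, kind=LOSS, lineage_id=lid, species_id=sp, label=label))
        elif kind == "convert":
            new_sp = next_sp
            next_sp += 1
            node.conversions.append((t, new_sp))
            counts[sp] -= 1
            if counts[sp] == 0:
                del counts[sp]
            counts[new_sp] = 1
            events.append(Event(time=t, kind=CONVERSION, lineage_id=lid,
                                species_id=new_sp, parent_species_id=sp))
        else:
            raise ValueError(kind)
    tree = LineageTree(nodes=nodes, origin_time=0.0, horizon=horizon)
    n_alive = sum(1 for nd in nodes if nd.death_time is None)
    log = EventLog(events=events, params=params, n_alive_final=n_alive)
    return SimResult(
        lineage_tree=tree,
        event_log=log,
        surviving=n_alive >= 1,
        n_species_extant=len(counts),
    )


@pytest.fixture
def two_conversion_result():
    """Hand-built genealogy with exactly two conversions at t=1.0 and
    t=2.0 and all lineages surviving to horizon 3.0: collapsing gives a
    3-tip species tree with internal node times {1.0, 2.0}."""
    return build_result(
        3.0,
        [
            ("branch", 0.5, 0),   # lineage 1 in species 0
            ("convert", 1.0, 1),  # species 1, founded by lineage 1
            ("branch", 1.5, 0),   # lineage 2 in species 0
            ("convert", 2.0, 2),  # species 2, founded by lineage 2
        ],
    )


@pytest.fixture
def membership_fixture():
    """One branch at t=0.5 and one conversion at t=1.0, horizon 2."""
    return build_result(2.0, [("branch", 0.5, 0), ("convert", 1.0, 1)])
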