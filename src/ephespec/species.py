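"""Species-level views of a simulation: membership counts, species records,
and collapse of the incipient-lineage genealogy to a tree of full species.

A full species is born either at time 0 (the root species) or at a
conversion event, and it ends when its count of living incipient lineages
reaches zero — by a loss event (whole-species extinction) or, in the
special case where its sole living lineage converts, by anagenetic
replacement. The species tree places the split of species ``S`` from its
parent ``P`` either at the conversion time (default) or at the time the
founding lineage originated within ``P`` (``incipient_origin_time``
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy

from .model import (
    BRANCH,
    LOSS,
    REABSORPTION,
    SPECIES_EXTINCTION,
    BDParams,
    SimResult,
)

__all__ = [
    "SpeciesRecord",
    "species_records",
    "species_membership_counts",
    "collapse_to_species_tree",
    "lineage_tree_to_dendropy",
    "sampled_species_tree",
    "check_emergent_extinction",
]

END_EXTINCTION = "extinction"
END_REPLACED = "replaced"
END_EXTANT = "extant"


@dataclass(slots=True)
class SpeciesRecord:
    """Life history of one full species, reconstructed from the event log."""

    id: int
    parent_id: Optional[int]  # species of the founding lineage at conversion
    founder_lineage: int
    origin_time: float  # conversion time (0.0 for the root species)
    founder_membership_start: float  # when the founder entered the parent sp.
    end_time: Optional[float] = None
    end_cause: str = END_EXTANT
    n_incipient_final: int = 0  # living lineages at the horizon
    child_events: list = field(default_factory=list)  # (time, child_species_id)


def species_records(result: SimResult) -> dict[int, SpeciesRecord]:
    """Replay the event log into per-species life-history records."""
    nodes = result.lineage_tree.nodes
    records = {
        0: SpeciesRecord(
            id=0,
            parent_id=None,
            founder_lineage=0,
            origin_time=0.0,
            founder_membership_start=0.0,
        )
    }
    counts = {0: 1}
    for ev in result.event_log:
        if ev.kind == BRANCH:
            counts[ev.species_id] += 1
        elif ev.kind == LOSS:
            counts[ev.species_id] -= 1
            if counts[ev.species_id] == 0:
                rec = records[ev.species_id]
                rec.end_time = ev.time
                rec.end_cause = END_EXTINCTION
        else:  # conversion
            old = ev.parent_species_id
            counts[old] -= 1
            if counts[old] == 0:
                rec = records[old]
                rec.end_time = ev.time
                rec.end_cause = END_REPLACED
            founder = nodes[ev.lineage_id]
            start = founder.birth_time
            for conv_time, sp in founder.conversions:
                if conv_time < ev.time and sp == old:
                    start = conv_time  # repeat conversion: entered `old` then
            records[ev.species_id] = SpeciesRecord(
                id=ev.species_id,
                parent_id=old,
                founder_lineage=ev.lineage_id,
                origin_time=ev.time,
                founder_membership_start=start,
            )
            counts[ev.species_id] = 1
            records[old].child_events.append((ev.time, ev.species_id))
    for sp, n in counts.items():
        if n > 0:
            records[sp].n_incipient_final = n
    return records


def species_membership_counts(result: SimResult, at_time: float) -> dict[int, int]:
    """Living incipient lineages per species at ``at_time``, from a replay
    of the event log (events at exactly ``at_time`` included). Species with
    zero living lineages are omitted."""
    horizon = result.lineage_tree.horizon
    if not (0.0 <= at_time <= horizon):
        raise ValueError(f"at_time must be in [0, {horizon}], got {at_time}")
    counts = {0: 1}
    for ev in result.event_log:
        if ev.time > at_time:
            break
        if ev.kind == BRANCH:
            counts[ev.species_id] += 1
        elif ev.kind == LOSS:
            counts[ev.species_id] -= 1
            if counts[ev.species_id] == 0:
                del counts[ev.species_id]
        else:
            counts[ev.parent_species_id] -= 1
            if counts[ev.parent_species_id] == 0:
                del counts[ev.parent_species_id]
            counts[ev.species_id] = 1
    return counts


def check_emergent_extinction(result: SimResult) -> int:
    """Verify, by replaying the event log, that species extinction is an
    emergent property: a species goes extinct only when its last incipient
    lineage is lost.

    Checks that (i) every loss event that empties a species is labeled
    ``species_extinction`` and leaves zero members, (ii) every
    ``reabsorption`` loss leaves at least one member, (iii) membership
    counts never go negative, and (iv) a species disappears from the
    membership table only at a species-extinction loss or — anagenetic
    replacement — when its sole living lineage converts. Returns the number
    of species-extinction events; raises ``AssertionError`` otherwise.
    """
    counts = {0: 1}
    n_extinctions = 0
    for ev in result.event_log:
        if ev.kind == BRANCH:
            counts[ev.species_id] += 1
        elif ev.kind == LOSS:
            counts[ev.species_id] -= 1
            remaining = counts[ev.species_id]
            if remaining < 0:
                raise AssertionError("negative species membership count")
            if remaining == 0:
                if ev.label != SPECIES_EXTINCTION:
                    raise AssertionError(
                        f"species {ev.species_id} emptied by a loss labeled "
                        f"{ev.label!r} at t={ev.time}"
                    )
                n_extinctions += 1
                del counts[ev.species_id]
            elif ev.label != REABSORPTION:
                raise AssertionError(
                    f"loss leaving {remaining} members labeled {ev.label!r}"
                )
        else:  # conversion: allowed to empty a species (replacement)
            counts[ev.parent_species_id] -= 1
            if counts[ev.parent_species_id] < 0:
                raise AssertionError("negative species membership count")
            if counts[ev.parent_species_id] == 0:
                del counts[ev.parent_species_id]
            counts[ev.species_id] = 1
    if sum(counts.values()) != result.event_log.n_alive_final:
        raise AssertionError("replayed lineage count disagrees with n_alive_final")
    if len(counts) != result.n_species_extant:
        raise AssertionError("replayed species count disagrees with n_species_extant")
    return n_extinctions


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class _Seg:
    """A node of the intermediate (pre-dendropy) tree: an event time plus
    either two children (a split) or a terminal entity."""

    time: float
    children: list
    entity_id: Optional[int] = None  # set for tips
    extant: bool = False
    n_incipient: int = 0


def _build_subtree(entity_id, start_time, events, entities):
    """Recursively lay one entity's timeline (with its child-split events)
    into a binary tree of ``_Seg`` nodes."""
    end_time, extant, n_inc = entities[entity_id][:3]
    if not events:
        return _Seg(
            time=end_time,
            children=[],
            entity_id=entity_id,
            extant=extant,
            n_incipient=n_inc,
        )
    (t1, child_id) = events[0]
    left = _build_subtree(entity_id, t1, events[1:], entities)
    child_events = entities[child_id][3]
    right = _build_subtree(child_id, t1, child_events, entities)
    return _Seg(time=t1, children=[left, right])


def _prune_extant(seg):
    if not seg.children:
        return seg if seg.extant else None
    kept = [c for c in (_prune_extant(c) for c in seg.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]  # splice: edge lengths recomputed from absolute times
    seg.children = kept
    return seg


def _to_dendropy(root_seg, origin_time, label_prefix) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def convert(seg, parent_time):
        nd = dendropy.Node()
        nd.edge.length = seg.time - parent_time
        nd.age_from_origin = seg.time
        if not seg.children:
            nd.taxon = taxa.new_taxon(label=f"{label_prefix}{seg.entity_id}")
            nd.entity_id = seg.entity_id
            nd.extant = seg.extant
            nd.n_incipient = seg.n_incipient
        for child in seg.children:
            nd.add_child(convert(child, seg.time))
        return nd

    tree.seed_node = convert(root_seg, origin_time)
    return tree


def _entities_to_tree(entities, root_id, origin_time, label_prefix, extant_only):
    root_events = entities[root_id][3]
    seg = _build_subtree(root_id, origin_time, root_events, entities)
    if extant_only:
        seg = _prune_extant(seg)
        if seg is None:
            raise ValueError("no extant tips to build a reconstructed tree from")
    return _to_dendropy(seg, origin_time, label_prefix)


def collapse_to_species_tree(
    result: SimResult,
    node_time_convention: str = "conversion_time",
    extant_only: bool = False,
) -> dendropy.Tree:
    """Collapse the incipient-lineage genealogy into a tree of full species.

    Each full species becomes one tip; the parent of species ``S`` is the
    species its founding lineage belonged to at conversion. Internal node
    times follow ``node_time_convention``:

    - ``"conversion_time"`` (default): the moment the founding lineage
      became a full species;
    - ``"incipient_origin_time"``: the moment the founding lineage
      originated within the parent species.

    With ``extant_only``, species with no living lineage at the horizon are
    pruned and the result is ultrametric with every extant tip at age 0.
    Tips carry ``entity_id`` (species id), ``extant`` and ``n_incipient``
    attributes; for the birth-death baseline every lineage is its own
    species and the species tree equals the lineage tree.
    """
    if node_time_convention not in ("conversion_time", "incipient_origin_time"):
        raise ValueError(f"unknown node_time_convention {node_time_convention!r}")
    if isinstance(result.event_log.params, BDParams):
        return lineage_tree_to_dendropy(result, extant_only=extant_only, label_prefix="S")

    horizon = result.lineage_tree.horizon
    records = species_records(result)
    use_origin = node_time_convention == "incipient_origin_time"
    entities = {}
    for sp, rec in records.items():
        end = horizon if rec.end_time is None else rec.end_time
        events = []
        for t, child in rec.child_events:
            child_rec = records[child]
            node_time = child_rec.founder_membership_start if use_origin else t
            events.append((node_time, child))
        events.sort(key=lambda e: e[0])
        entities[sp] = (end, rec.end_time is None, rec.n_incipient_final, events)
    if extant_only and not any(e[1] for e in entities.values()):
        raise ValueError("extant_only requested but no species survives")
    return _entities_to_tree(entities, 0, 0.0, "S", extant_only)


def sampled_species_tree(result: SimResult) -> dendropy.Tree:
    """The species tree as it would be estimated from genetic data of the
    extant species: one sampled incipient lineage per extant species, with
    divergence times taken from the incipient genealogy.

    Unlike :func:`collapse_to_species_tree`, whose node times are
    conversion (or founder-origin) times along the species parentage, this
    tree is the incipient genealogy pruned to one representative living
    lineage per extant species — the quantity molecular phylogenies
    measure. Because recently branched lineages have rarely completed
    conversion yet, such trees show a deficit of recent divergences: the
    apparent early burst of surviving clades. The representative is the
    oldest living lineage of each species (smallest lineage id, ids being
    assigned in birth order). Always ultrametric; requires >= 1 extant
    species.
    """
    horizon = result.lineage_tree.horizon
    nodes = result.lineage_tree.nodes
    rep_of: dict[int, int] = {}  # species -> oldest living lineage
    for nd in nodes:
        if nd.death_time is None:
            sp = nd.species_at(horizon)
            if sp not in rep_of:  # nodes iterated in id (birth) order
                rep_of[sp] = nd.id
    if not rep_of:
        raise ValueError("no extant species to sample")
    sp_of_rep = {lid: sp for sp, lid in rep_of.items()}

    children: dict[int, list] = {nd.id: [] for nd in nodes}
    for nd in nodes:
        if nd.parent_id is not None:
            children[nd.parent_id].append((nd.birth_time, nd.id))
    entities = {}
    for nd in nodes:
        is_rep = nd.id in sp_of_rep
        end = horizon if is_rep else (nd.death_time if nd.death_time is not None else horizon)
        entities[nd.id] = (end, is_rep, 1, sorted(children[nd.id]))
    tree = _entities_to_tree(entities, 0, 0.0, "L", extant_only=True)
    counts = {sp: 0 for sp in rep_of}
    for nd in nodes:
        if nd.death_time is None:
            counts[nd.species_at(horizon)] += 1
    for leaf in tree.leaf_node_iter():
        sp = sp_of_rep[leaf.entity_id]
        leaf.entity_id = sp
        leaf.taxon.label = f"S{sp}"
        leaf.n_incipient = counts[sp]
        leaf.extant = True
    return tree


def lineage_tree_to_dendropy(
    result: SimResult, extant_only: bool = False, label_prefix: str = "L"
) -> dendropy.Tree:
    """Convert the incipient-lineage genealogy to a dendropy tree.

    Tips are individual lineages; internal nodes are branching events. With
    ``extant_only`` the tree is pruned to lineages alive at the horizon
    (the reconstructed genealogy).
    """
    horizon = result.lineage_tree.horizon
    nodes = result.lineage_tree.nodes
    children: dict[int, list] = {nd.id: [] for nd in nodes}
    for nd in nodes:
        if nd.parent_id is not None:
            children[nd.parent_id].append((nd.birth_time, nd.id))
    entities = {}
    for nd in nodes:
        alive = nd.death_time is None
        end = horizon if alive else nd.death_time
        entities[nd.id] = (end, alive, 1 if alive else 0, sorted(children[nd.id]))
    if extant_only and not any(e[1] for e in entities.values()):
        raise ValueError("extant_only requested but no lineage survives")
    return _entities_to_tree(entities, 0, 0.0, label_prefix, extant_only)
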