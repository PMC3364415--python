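"""Readers and writers: annotated Newick trees, TSV event logs, and JSON
metadata sidecars.

Trees are written in Newick with NHX-style comment blocks
(``[&&NHX:key=value:...]``) carrying per-node annotations such as species
id, extant flag and incipient-lineage count. Reading goes through
dendropy, which parses NHX comments into node annotations; unknown keys
are kept as strings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import dendropy

from .model import Event, EventLog

__all__ = [
    "tree_to_newick",
    "write_newick",
    "read_newick",
    "node_annotations",
    "write_event_log",
    "read_event_log",
    "write_metadata",
]

log = logging.getLogger("ephespec")

_KNOWN_KEYS = {"entity_id", "extant", "n_incipient", "fate", "species_id"}

# branch lengths printed with enough digits for lossless float round-trip
_FMT = "%.17g"


def _nhx_comment(nd) -> str:
    items = []
    if getattr(nd, "entity_id", None) is not None:
        items.append(f"entity_id={nd.entity_id}")
    if getattr(nd, "extant", None) is not None:
        items.append(f"extant={int(nd.extant)}")
    if getattr(nd, "n_incipient", None) is not None:
        items.append(f"n_incipient={nd.n_incipient}")
    if getattr(nd, "fate", None) is not None:
        items.append(f"fate={nd.fate}")
    if not items:
        return ""
    return "[&&NHX:" + ":".join(items) + "]"


def _node_str(nd, annotations: bool) -> str:
    kids = nd.child_nodes()
    if kids:
        body = "(" + ",".join(_node_str(c, annotations) for c in kids) + ")"
    else:
        body = ""
    label = nd.taxon.label if nd.taxon is not None else ""
    # quote labels containing newick-reserved characters
    if label and any(ch in label for ch in " (),:;[]'"):
        label = "'" + label.replace("'", "''") + "'"
    out = body + label
    if annotations:
        out += _nhx_comment(nd)
    if nd.edge.length is not None:
        out += ":" + _FMT % nd.edge.length
    return out


def tree_to_newick(tree: dendropy.Tree, annotations: bool = True) -> str:
    """Serialize a tree to a Newick string with optional NHX annotations."""
    return _node_str(tree.seed_node, annotations) + ";"


def write_newick(tree: dendropy.Tree, path, annotations: bool = True) -> None:
    Path(path).write_text(tree_to_newick(tree, annotations=annotations) + "\n")


def read_newick(path_or_str, is_string: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree; NHX comments become typed node attributes
    (``entity_id``, ``extant``, ``n_incipient``, ``fate``) where recognized
    and remain available as dendropy annotations otherwise. Malformed input
    raises a parse error with position information."""
    src = {"data": str(path_or_str)} if is_string else {"path": str(path_or_str)}
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            extract_comment_metadata=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            **src,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed newick input: {exc}") from exc
    for nd in tree.preorder_node_iter():
        for ann in nd.annotations:
            if ann.name == "entity_id":
                nd.entity_id = int(ann.value)
            elif ann.name == "extant":
                nd.extant = bool(int(ann.value))
            elif ann.name == "n_incipient":
                nd.n_incipient = int(ann.value)
            elif ann.name == "fate":
                nd.fate = str(ann.value)
            elif ann.name not in _KNOWN_KEYS:
                log.warning("ignoring unknown newick annotation key %r", ann.name)
    return tree


def node_annotations(nd) -> dict:
    """Recognized annotations of a node as a plain dict."""
    out = {}
    for key in ("entity_id", "extant", "n_incipient", "fate"):
        if getattr(nd, key, None) is not None:
            out[key] = getattr(nd, key)
    return out


# ---------------------------------------------------------------------------
# Event log TSV
# ---------------------------------------------------------------------------

_LOG_COLUMNS = ("time", "kind", "lineage_id", "species_id", "label",
                "child_id", "parent_species_id")


def write_event_log(event_log: EventLog, path) -> None:
    """Write the event log as TSV (one event per row, time-ordered).

    Times are printed with 17 significant digits so reloading reproduces
    the exact float values.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_LOG_COLUMNS) + "\n")
        for ev in event_log:
            row = (
                _FMT % ev.time,
                ev.kind,
                str(ev.lineage_id),
                str(ev.species_id),
                ev.label or "",
                "" if ev.child_id is None else str(ev.child_id),
                "" if ev.parent_species_id is None else str(ev.parent_species_id),
            )
            fh.write("\t".join(row) + "\n")


def read_event_log(path) -> list[Event]:
    """Read an event-log TSV back into a list of events."""
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _LOG_COLUMNS:
            raise ValueError(f"unexpected event-log header: {header}")
        for line in fh:
            t, kind, lid, sid, label, cid, psid = line.rstrip("\n").split("\t")
            events.append(
                Event(
                    time=float(t),
                    kind=kind,
                    lineage_id=int(lid),
                    species_id=int(sid),
                    label=label or None,
                    child_id=int(cid) if cid else None,
                    parent_species_id=int(psid) if psid else None,
                )
            )
    return events


def write_metadata(path, **fields) -> None:
    """Write a JSON metadata sidecar (params, seed, counts, provenance)."""

    def default(obj):
        if is_dataclass(obj):
            return asdict(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(fields, indent=2, default=default) + "\n")
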