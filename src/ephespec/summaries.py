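"""Tree and simulation summary statistics.

These operationalize the model's three qualitative predictions: (i) an
uneven distribution of incipient forms within species (histogram and
skewness), (ii) differences in effective speciation and extinction rates
across species driven by membership size, and (iii) an apparent early
burst of branching (negative Pybus–Harvey gamma) in reconstructed trees of
surviving clades, contrasted with the log-linear lineage-through-time
curve of a constant-rate birth-death process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
from scipy import stats as _stats

from .model import BRANCH, LOSS, SimResult
from .species import species_membership_counts

__all__ = [
    "LTTCurve",
    "IncipientHistogram",
    "EffectiveRates",
    "node_depths",
    "compute_ltt",
    "gamma_statistic",
    "gamma_from_branching_ages",
    "colless_index",
    "incipient_distribution",
    "effective_rates",
]


@dataclass
class LTTCurve:
    """Lineage count through time, from the origin to the horizon.

    ``pairs`` lists ``(time, n_lineages)`` with the count in effect from
    that time until the next entry; the curve starts at ``(origin, 1)``.
    """

    pairs: list

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.pairs])

    @property
    def counts(self) -> np.ndarray:
        return np.array([n for _, n in self.pairs])

    def __iter__(self):
        return iter(self.pairs)


def node_depths(tree: dendropy.Tree) -> dict:
    """Depth (time from the origin, including the root edge) of every node.

    Raises on negative branch lengths.
    """
    depths = {}
    for nd in tree.preorder_node_iter():
        edge = nd.edge.length if nd.edge.length is not None else 0.0
        if edge < 0:
            raise ValueError("negative branch length")
        parent_depth = depths[nd.parent_node] if nd.parent_node else 0.0
        depths[nd] = parent_depth + edge
    return depths


def compute_ltt(tree: dendropy.Tree, extant_only: bool = False) -> LTTCurve:
    """Lineage-through-time curve of a rooted tree.

    The count steps +1 at each branching time (+c-1 at a c-furcation) and,
    for trees containing extinct tips, -1 at each tip that ends before the
    horizon (the maximum tip depth). With ``extant_only`` the input is
    expected to be a reconstructed (pruned) tree and the curve is monotone
    nondecreasing; extinct tips then raise.
    """
    if tree.seed_node is None or not tree.seed_node.child_nodes() and tree.seed_node.taxon is None:
        raise ValueError("empty tree")
    depths = node_depths(tree)
    leaves = [nd for nd in tree.leaf_node_iter()]
    horizon = max(depths[nd] for nd in leaves)
    tol = 1e-9 * max(horizon, 1.0)
    changes = []
    for nd in tree.preorder_node_iter():
        nchild = len(nd.child_nodes())
        if nchild >= 2:
            changes.append((depths[nd], nchild - 1))
        elif nchild == 0 and depths[nd] < horizon - tol:
            if extant_only:
                raise ValueError("extant_only LTT requested on a tree with extinct tips")
            changes.append((depths[nd], -1))
    changes.sort(key=lambda c: c[0])
    pairs = [(0.0, 1)]
    n = 1
    for t, delta in changes:
        n += delta
        if pairs and abs(pairs[-1][0] - t) <= tol and len(pairs) > 1:
            pairs[-1] = (t, n)
        else:
            pairs.append((t, n))
    return LTTCurve(pairs=pairs)


def _branching_ages(tree: dendropy.Tree):
    """Ages (before the present) of all splits of an ultrametric tree,
    sorted descending, plus tip count and tree height above the crown."""
    depths = node_depths(tree)
    leaf_depths = [depths[nd] for nd in tree.leaf_node_iter()]
    height = max(leaf_depths)
    tol = 1e-9 * max(height, 1.0)
    if max(leaf_depths) - min(leaf_depths) > tol:
        raise ValueError("tree is not ultrametric")
    ages = []
    n_tips = len(leaf_depths)
    for nd in tree.preorder_internal_node_iter():
        c = len(nd.child_nodes())
        if c >= 2:
            ages.extend([height - depths[nd]] * (c - 1))
    ages.sort(reverse=True)
    return ages, n_tips, height


def gamma_statistic(tree: dendropy.Tree) -> float:
    """Pybus–Harvey gamma of an ultrametric tree (>= 3 tips).

    Negative values indicate branching concentrated early in the clade's
    history ("early burst"); for pure-birth trees of fixed tip count gamma
    has mean 0 and is asymptotically standard normal. Invariant to
    rescaling all branch lengths.
    """
    ages, n, _height = _branching_ages(tree)
    return gamma_from_branching_ages(ages)


def gamma_from_branching_ages(ages) -> float:
    """Gamma computed directly from branching ages (before the present,
    descending; crown age first). ``len(ages) + 1`` is the tip count."""
    ages = sorted((float(a) for a in ages), reverse=True)
    n = len(ages) + 1
    if n < 3:
        raise ValueError("gamma statistic requires >= 3 tips")
    # internode intervals g_k = duration with exactly k lineages, k = 2..n
    ages = ages + [0.0]  # crown age first, present last
    g = [ages[k - 2] - ages[k - 1] for k in range(2, n + 1)]
    kg = [k * gk for k, gk in zip(range(2, n + 1), g)]
    total = math.fsum(kg)
    partial = np.cumsum(kg)  # partial[i-2] = T_i = sum_{k=2}^{i} k g_k
    mean_partial = float(np.mean(partial[: n - 2]))  # i = 2..n-1
    return (mean_partial - total / 2.0) / (total * math.sqrt(1.0 / (12.0 * (n - 2))))


def _tip_counts(nd, counts):
    kids = nd.child_nodes()
    if not kids:
        counts[nd] = 1
        return 1
    if len(kids) != 2:
        raise ValueError("colless index requires a strictly binary tree")
    total = sum(_tip_counts(c, counts) for c in kids)
    counts[nd] = total
    return total


def colless_index(tree: dendropy.Tree) -> int:
    """Colless imbalance: sum over internal nodes of the absolute
    difference in descendant tip counts. Polytomies are rejected."""
    counts: dict = {}
    _tip_counts(tree.seed_node, counts)
    total = 0
    for nd in tree.preorder_internal_node_iter():
        left, right = nd.child_nodes()
        total += abs(counts[left] - counts[right])
    return total


@dataclass
class IncipientHistogram:
    """Distribution of incipient forms per living species at one time."""

    histogram: dict  # k (members) -> number of species
    mean: float
    median: float
    skewness: Optional[float]  # adjusted Fisher-Pearson; None if undefined

    @property
    def n_species(self) -> int:
        return sum(self.histogram.values())


def incipient_distribution(result: SimResult, at_time: float) -> IncipientHistogram:
    """Histogram of incipient-lineage counts per species alive at
    ``at_time``. Raw integer bins; skewness is the adjusted Fisher-Pearson
    sample estimator (``scipy.stats.skew(..., bias=False)``), reported as
    None when fewer than three species are alive or all counts are equal.
    """
    counts = species_membership_counts(result, at_time)
    if not counts:
        raise ValueError(f"no species alive at t={at_time}")
    values = np.array(sorted(counts.values()))
    hist: dict[int, int] = {}
    for v in counts.values():
        hist[v] = hist.get(v, 0) + 1
    skew = None
    if len(values) >= 3 and values.std() > 0:
        skew = float(_stats.skew(values, bias=False))
    return IncipientHistogram(
        histogram=hist,
        mean=float(values.mean()),
        median=float(np.median(values)),
        skewness=skew,
    )


@dataclass(slots=True)
class EffectiveRates:
    """Per-species effective rates.

    ``speciation_rate`` is the number of conversions that originated from
    the species' lineages divided by the species' lineage-time exposure
    (lineage-Myr). ``extinction_exposure`` is the reciprocal of the
    expected time for all current members to be lost under the incipient
    loss rate alone (``mu_i / H_k`` with ``H_k`` the k-th harmonic number);
    it decreases with membership and is None for species with no living
    members at the horizon.
    """

    species_id: int
    exposure: float
    n_conversions_from: int
    speciation_rate: float
    n_members_final: int
    extinction_exposure: Optional[float]


def effective_rates(result: SimResult) -> list[EffectiveRates]:
    """Effective speciation and extinction rates per species.

    Species with many incipient forms speciate more (more lineages at risk
    of conversion) and are harder to extinguish (all members must be lost);
    this function measures both from one replicate's event log.
    """
    if len(result.event_log) == 0 and result.lineage_tree.horizon <= 0:
        raise ValueError("empty event log")
    params = result.event_log.params
    mu_i = getattr(params, "mu_i", getattr(params, "mu", 0.0))
    horizon = result.lineage_tree.horizon

    count = {0: 1}
    last_t = {0: 0.0}
    exposure = {0: 0.0}
    conv_from: dict[int, int] = {0: 0}

    def advance(sp, t):
        exposure[sp] += count[sp] * (t - last_t[sp])
        last_t[sp] = t

    for ev in result.event_log:
        if ev.kind == BRANCH:
            advance(ev.species_id, ev.time)
            count[ev.species_id] += 1
        elif ev.kind == LOSS:
            advance(ev.species_id, ev.time)
            count[ev.species_id] -= 1
        else:
            advance(ev.parent_species_id, ev.time)
            count[ev.parent_species_id] -= 1
            conv_from[ev.parent_species_id] += 1
            count[ev.species_id] = 1
            last_t[ev.species_id] = ev.time
            exposure[ev.species_id] = 0.0
            conv_from.setdefault(ev.species_id, 0)
    for sp in count:
        advance(sp, horizon)

    out = []
    for sp in sorted(count):
        expo = exposure[sp]
        if expo <= 0.0:
            raise ValueError(f"species {sp} has zero lineage-time exposure")
        k = count[sp]
        ext = None
        if k >= 1:
            harmonic = math.fsum(1.0 / j for j in range(1, k + 1))
            ext = mu_i / harmonic
        out.append(
            EffectiveRates(
                species_id=sp,
                exposure=expo,
                n_conversions_from=conv_from[sp],
                speciation_rate=conv_from[sp] / expo,
                n_members_final=k,
                extinction_exposure=ext,
            )
        )
    return out
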