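"""Cross-lineage comparison of ITS sites and ancestral-gain parsimony.

Two questions are answered here.  First, which additional-ITS sites in
different lineages occupy the same homologous position (the same
inter-anchor region of the structure-based alignment)?  Second, can the
presence pattern of a fragmentation character across the taxa of a tree
be explained by a single ancestral gain — or does it require independent
origins?  The latter is made machine-checkable: a character needing two
or more gains under a no-loss model (and two or more changes under
Fitch parsimony) cannot be traced to the common ancestor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .its_caller import ItsCall, ItsSiteRegistry

_INF = float("inf")


@dataclass(frozen=True)
class SharedPair:
    site_a: str
    site_b: str
    region_id: tuple[str, str]


def shared_sites(registry: ItsSiteRegistry) -> list[SharedPair]:
    """All cross-lineage pairs of registry sites with identical region id.

    Deterministic order: pairs sorted by region id; within a pair, the
    site from the alphabetically earlier lineage comes first.
    """
    pairs = []
    by_region: dict[tuple[str, str], list] = {}
    for e in registry.entries:
        by_region.setdefault(e.region_id, []).append(e)
    for rid in sorted(by_region):
        sites = by_region[rid]
        for a, b in itertools.combinations(sorted(sites, key=lambda s: (s.lineage, s.site_id)), 2):
            if a.lineage != b.lineage:
                pairs.append(SharedPair(site_a=a.site_id, site_b=b.site_id, region_id=rid))
    return pairs


def shared_sites_by_window(
    sites_a: Mapping[str, tuple[int, int]],
    sites_b: Mapping[str, tuple[int, int]],
    window: int = 10,
) -> list[tuple[str, str]]:
    """Registry-free tolerance mode: sites from two lineages are shared
    when their alignment-column windows overlap within ``window`` columns."""
    out = []
    for a, (a0, a1) in sorted(sites_a.items()):
        for b, (b0, b1) in sorted(sites_b.items()):
            if a0 - window < b1 and b0 - window < a1:
                out.append((a, b))
    return out


def presence_matrix(
    calls: Sequence[ItsCall],
    taxa: Sequence[str],
    columns: str = "site",
) -> pd.DataFrame:
    """Boolean taxa x sites (or taxa x regions) matrix of ITS presence."""
    if columns == "site":
        keys = sorted({c.site_id for c in calls if c.site_id is not None})
        get = lambda c: c.site_id
    elif columns == "region":
        # joined region labels keep the frame friendly to pandas indexing
        keys = sorted({"%s-%s" % c.region_id for c in calls})
        get = lambda c: "%s-%s" % c.region_id
    else:
        raise ValueError("columns must be 'site' or 'region'")
    mat = pd.DataFrame(False, index=list(taxa), columns=keys)
    for c in calls:
        key = get(c)
        if key in mat.columns and c.species in mat.index:
            mat.loc[c.species, key] = True
    return mat


def any_28s_character(calls: Sequence[ItsCall], taxa: Sequence[str]) -> dict[str, bool]:
    """The headline single character: does a taxon carry any 28S-domain ITS?"""
    present = {
        c.species
        for c in calls
        if c.domain == "LSU" and c.classification in ("known_ITS", "novel_candidate")
    }
    return {t: t in present for t in taxa}


# ---------------------------------------------------------------------------
# Parsimony

def _leaf_states(tree: dendropy.Tree, presence: Mapping[str, bool]) -> None:
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in presence:
            raise KeyError(f"leaf {label!r} has no character state")


def min_state_changes(tree: dendropy.Tree, presence: Mapping[str, bool]) -> int:
    """Fitch small-parsimony count of binary state changes.

    Implemented as a symmetric-cost Sankoff dynamic programme so
    polytomies are scored exactly; with a symmetric unit cost the count
    is invariant to root placement, i.e. it is a statement about the
    unrooted tree.
    """
    _leaf_states(tree, presence)
    cost: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = presence[node.taxon.label]
            cost[id(node)] = np.array(
                [0.0 if not state else _INF, 0.0 if state else _INF]
            )
        else:
            total = np.zeros(2)
            for child in node.child_nodes():
                c = cost[id(child)]
                total += np.minimum(c, c[::-1] + 1.0)
            cost[id(node)] = total
    return int(min(cost[id(tree.seed_node)]))


@dataclass(frozen=True)
class GainScenarios:
    fitch_changes: int
    gains_no_loss: int
    dollo_losses_single_gain: int


def gain_scenarios(
    tree: dendropy.Tree,
    presence: Mapping[str, bool],
    outgroup: str | None = None,
) -> GainScenarios:
    """Three parsimony readings of a binary presence character.

    ``gains_no_loss``: minimum number of gains when loss is forbidden —
    the number of maximal clades whose leaves are all present.  A value
    >= 2 means the character cannot be traced to the common ancestor.
    ``dollo_losses_single_gain``: losses required if the character arose
    once at the MRCA of the present leaves (Dollo reading).
    ``fitch_changes``: unconstrained minimum changes.
    """
    _leaf_states(tree, presence)
    tree.is_rooted = True  # gains/losses are statements about the rooted tree
    if outgroup is not None:
        tree = tree.clone(depth=1)
        node = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == outgroup
        )
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    present_leaves = [
        lf for lf in tree.leaf_node_iter() if presence[lf.taxon.label]
    ]
    if not present_leaves:
        return GainScenarios(0, 0, 0)
    fitch = min_state_changes(tree, presence)

    all_present: dict[int, bool] = {}
    all_absent: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = presence[node.taxon.label]
            all_present[id(node)] = state
            all_absent[id(node)] = not state
        else:
            kids = node.child_nodes()
            all_present[id(node)] = all(all_present[id(k)] for k in kids)
            all_absent[id(node)] = all(all_absent[id(k)] for k in kids)
    gains = 0
    for node in tree.preorder_node_iter():
        if all_present[id(node)]:
            parent = node.parent_node
            if parent is None or not all_present[id(parent)]:
                gains += 1

    mrca = tree.mrca(taxa=[lf.taxon for lf in present_leaves])
    losses = 0
    for node in mrca.preorder_iter():
        if node is mrca:
            continue
        if all_absent[id(node)]:
            parent = node.parent_node
            if parent is mrca or not all_absent[id(parent)]:
                losses += 1
    return GainScenarios(
        fitch_changes=fitch,
        gains_no_loss=gains,
        dollo_losses_single_gain=losses,
    )
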