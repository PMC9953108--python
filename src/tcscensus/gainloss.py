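"""UPGMA tree from an ANI matrix and minimum-cost gain/loss inference.

The genome tree is built by UPGMA on the dissimilarity 100 - ANI (node
heights are half the merge distance, so the tree is ultrametric by
construction).  Per-family presence/absence vectors are then explained by a
Sankoff dynamic program over binary ancestral states with asymmetric costs:
a gain (absent -> present) costs ``gain_penalty`` (default 2), a loss costs
1.  The root prior is *absent*, so every family carries at least one gain —
core families a single gain on the root branch, accessory families whatever
combination of later gains and losses is cheapest (multiple independent
gains are allowed when cheaper).  Ties resolve toward fewer gains, then
toward events nearer the root; the procedure is fully deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .model import AniMatrix, Event, EventSet

__all__ = [
    "Node",
    "parse_newick",
    "upgma",
    "infer_events",
    "replay_events",
    "events_summary",
]


@dataclass
class Node:
    """A rooted-tree node; ``length`` is the branch to its parent."""

    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    height: float = 0.0  # ultrametric height above the leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.leaves())

    @property
    def label(self) -> str:
        """Branch label: the leaf name, or sorted leaf names joined by '|'."""
        return self.name if self.is_leaf else "|".join(self.leaf_names())

    def postorder(self) -> list["Node"]:
        out = []
        for c in self.children:
            out.extend(c.postorder())
        out.append(self)
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:g}"
        kids = sorted(self.children, key=lambda c: c.leaf_names()[0])
        inner = ",".join(c._newick() for c in kids)
        return f"({inner}):{self.length:g}"

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = {}

        def walk(node: Node, d: float) -> None:
            d += node.length
            if node.is_leaf:
                depths[node.name] = d
            for c in node.children:
                walk(c, d)

        walk(self, -self.length)  # root branch does not count toward depth
        vals = list(depths.values())
        return max(vals) - min(vals) <= tol


def parse_newick(newick: str) -> Node:
    """Parse a Newick string into a :class:`Node` tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")

    def convert(dn) -> Node:
        name = dn.taxon.label if dn.taxon is not None else dn.label
        node = Node(
            name=name,
            length=float(dn.edge.length) if dn.edge.length is not None else 0.0,
            children=[convert(c) for c in dn.child_nodes()],
        )
        return node

    return convert(tree.seed_node)


def upgma(ani: AniMatrix) -> Node:
    """UPGMA agglomeration on d = 100 - ANI.

    Arithmetic-mean linkage weighted by cluster sizes; the merged node sits
    at height d/2.  When several pairs tie at the minimum distance, the pair
    whose combined member list is lexicographically smallest merges first,
    making the topology independent of input order.
    """
    n = len(ani)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 genomes")
    d = ani.distance()
    # cluster key: sorted tuple of member genome ids
    clusters: dict[tuple[str, ...], Node] = {}
    sizes: dict[tuple[str, ...], int] = {}
    dist: dict[frozenset, float] = {}
    keys = []
    for i, g in enumerate(ani.genome_ids):
        key = (g,)
        clusters[key] = Node(name=g, height=0.0)
        sizes[key] = 1
        keys.append(key)
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((keys[i], keys[j]))] = float(d[i, j])

    while len(clusters) > 1:
        active = sorted(clusters)
        best = None
        for a, b in itertools.combinations(active, 2):
            key = frozenset((a, b))
            cand = (dist[key], tuple(sorted(a + b)))
            if best is None or cand < best[0]:
                best = (cand, a, b)
        (_, _), a, b = best[0], best[1], best[2]
        dmerge = dist[frozenset((a, b))]
        height = dmerge / 2.0
        na, nb = clusters.pop(a), clusters.pop(b)
        na.length = height - na.height
        nb.length = height - nb.height
        merged_key = tuple(sorted(a + b))
        merged = Node(children=[na, nb], height=height)
        size_a, size_b = sizes.pop(a), sizes.pop(b)
        for other in clusters:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged_key, other))] = (
                size_a * da + size_b * db
            ) / (size_a + size_b)
        dist.pop(frozenset((a, b)))
        clusters[merged_key] = merged
        sizes[merged_key] = size_a + size_b
    root = next(iter(clusters.values()))
    root.length = 0.0
    return root


_INF = (float("inf"), 0, 0)


def _vec_add(x, y):
    return (x[0] + y[0], x[1] + y[1], x[2] + y[2])


def _transition(parent_state: int, child_state: int, depth: int, gain: float, loss: float):
    """Cost vector (cost, n_gains, sum of event depths) for one branch."""
    if parent_state == child_state:
        return (0.0, 0, 0)
    if parent_state == 0:  # gain
        return (gain, 1, depth)
    return (loss, 0, depth)  # loss


def infer_events(
    tree: Node,
    presence: dict[str, int],
    gain_penalty: float = 2.0,
    loss_penalty: float = 1.0,
    family_id: str = "",
) -> EventSet:
    """Minimum-cost gain/loss scenario for one presence/absence vector.

    Sankoff DP over binary states with the root's parent fixed absent (the
    branch above the root is a real branch: a family present everywhere is
    one gain on it).  The optimized objective is the lexicographic vector
    (total cost, number of gains, sum of event depths), which implements the
    documented tie-breaking exactly.
    """
    leaves = tree.leaf_names()
    if set(leaves) != set(presence):
        raise ValueError(
            f"presence vector leaves {sorted(presence)} do not match tree leaves {leaves}"
        )
    if not any(presence.values()):
        raise ValueError("presence vector is all-zero")

    depth: dict[int, int] = {}

    def set_depth(node: Node, d: int) -> None:
        depth[id(node)] = d
        for c in node.children:
            set_depth(c, d + 1)

    set_depth(tree, 0)

    cost: dict[int, dict[int, tuple]] = {}
    choice: dict[int, dict[int, dict[int, int]]] = {}
    for node in tree.postorder():
        nid = id(node)
        if node.is_leaf:
            state = int(presence[node.name])
            cost[nid] = {state: (0.0, 0, 0), 1 - state: _INF}
        else:
            cost[nid] = {}
            choice[nid] = {}
            for s in (0, 1):
                total = (0.0, 0, 0)
                picks = {}
                for child in node.children:
                    cid = id(child)
                    best_vec, best_state = None, None
                    # cstate 0 first, so an exact vector tie keeps state 0
                    for cstate in (0, 1):
                        if cost[cid][cstate][0] == float("inf"):
                            continue
                        vec = _vec_add(
                            _transition(s, cstate, depth[cid], gain_penalty, loss_penalty),
                            cost[cid][cstate],
                        )
                        if best_vec is None or vec < best_vec:
                            best_vec, best_state = vec, cstate
                    total = _vec_add(total, best_vec)
                    picks[cid] = best_state
                cost[nid][s] = total
                choice[nid][s] = picks

    root_id = id(tree)
    best_root, best_vec = None, None
    for s in (0, 1):  # s=0 first keeps state 0 on an exact vector tie
        if cost[root_id][s][0] == float("inf"):
            continue
        vec = _vec_add(
            _transition(0, s, 0, gain_penalty, loss_penalty), cost[root_id][s]
        )
        if best_vec is None or vec < best_vec:
            best_vec, best_root = vec, s

    events: list[Event] = []

    def backtrack(node: Node, state: int, parent_state: int) -> None:
        if state != parent_state:
            events.append(
                Event(branch=node.label, type="GAIN" if state == 1 else "LOSS")
            )
        if node.is_leaf:
            return
        picks = choice[id(node)][state]
        for child in node.children:
            backtrack(child, picks[id(child)], state)

    backtrack(tree, best_root, 0)
    total_cost = sum(
        gain_penalty if e.type == "GAIN" else loss_penalty for e in events
    )
    result = EventSet(family_id=family_id, events=events, cost=total_cost)
    # hard invariant: replaying the events reproduces the leaf presences
    replayed = replay_events(tree, result.events)
    if replayed != {k: int(v) for k, v in presence.items()}:
        raise AssertionError("event replay does not reproduce leaf presences")
    return result


def replay_events(tree: Node, events: list[Event]) -> dict[str, int]:
    """Apply events along the tree from an absent root state; returns the
    implied leaf presence vector."""
    by_branch: dict[str, str] = {}
    for e in events:
        if e.branch in by_branch:
            raise ValueError(f"multiple events on branch {e.branch}")
        by_branch[e.branch] = e.type

    out: dict[str, int] = {}

    def walk(node: Node, parent_state: int) -> None:
        state = parent_state
        ev = by_branch.get(node.label)
        if ev == "GAIN":
            if state == 1:
                raise ValueError(f"gain of a present family on {node.label}")
            state = 1
        elif ev == "LOSS":
            if state == 0:
                raise ValueError(f"loss of an absent family on {node.label}")
            state = 0
        if node.is_leaf:
            out[node.name] = state
        for c in node.children:
            walk(c, state)

    walk(tree, 0)
    return out


def events_summary(event_sets: list[EventSet]) -> pd.DataFrame:
    """Per-branch gain/loss counts over a collection of family scenarios."""
    rows: dict[str, dict[str, int]] = {}
    for es in event_sets:
        for e in es.events:
            rec = rows.setdefault(e.branch, {"gains": 0, "losses": 0})
            rec["gains" if e.type == "GAIN" else "losses"] += 1
    records = [
        {"branch": b, "gains": v["gains"], "losses": v["losses"]}
        for b, v in sorted(rows.items())
    ]
    return pd.DataFrame(records, columns=["branch", "gains", "losses"])
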