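"""Memory-compressed k-best decoding via an online-pruned traceback tree.

Instead of the full ``(n+1) x m x k`` backpointer matrix, this engine keeps
only the backpointers that still lie on a path from the root (the silent
start) to the current frontier, organised in two layers:

* **path nodes** — one per live ``(position, state, rank)`` triple, holding a
  parent pointer, a child counter and the log-score of that ranked path;
* **state nodes** — one per live ``(position-run, state-run)``, aggregating
  the <= k path nodes at a position and, after merging, a *run* of states
  spanning several consecutive positions.

After each position is incorporated the tree is pruned (path nodes no longer
reachable from the new frontier are removed transitively, and a state node
with no path nodes left is deleted) and compressed (a state node is merged
into its parent whenever that parent is its only parent and it is the
parent's only child, concatenating the state runs and splicing the path-node
chains).  The frontier's k x m sorted score lists live outside the tree; the
tree stores structure and backpointers only.

The recovered paths, ranks and log-probabilities are identical to the naive
matrix engine, including the package-wide lexicographic tie rule.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .kbest import DecoderStats, KBestResult, merge_candidates
from .model import NEG_INF, Hmm, ScoredPath, Sequence


class TreeConsistencyError(RuntimeError):
    """Raised when a structural self-check of the compressed tree fails."""


class PathNode:
    """One live (position, state, rank) backpointer cell."""

    __slots__ = ("pos", "state", "rank", "parent", "child_count", "owner", "log_score")

    def __init__(self, pos, state, rank, parent, owner, log_score):
        self.pos = pos
        self.state = state
        self.rank = rank
        self.parent: Optional[PathNode] = parent
        self.child_count = 0
        self.owner: StateNode = owner
        self.log_score = log_score

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PathNode(i={self.pos}, j={self.state}, a={self.rank})"


class StateNode:
    """All live ranks at one (position, state), merged into runs of states.

    ``run`` lists one state index per position, covering positions
    ``start .. start+len(run)-1``; the path nodes always sit at the run's
    last position.  ``parent_edges`` counts, per parent state node, how many
    of this node's path nodes have their parent path node there.
    """

    __slots__ = ("start", "run", "path_nodes", "children", "parent_edges")

    def __init__(self, start: int, run: list[int]):
        self.start = start
        self.run = run
        self.path_nodes: list[PathNode] = []
        self.children: dict["StateNode", None] = {}
        self.parent_edges: dict["StateNode", int] = {}

    @property
    def end(self) -> int:
        return self.start + len(self.run) - 1

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"StateNode([{self.start},{self.end}], run={self.run}, |a|={len(self.path_nodes)})"


def path_state_indices(pn: PathNode) -> tuple[int, ...]:
    """State-index sequence pi_1..pi_i of the path ending at ``pn``,
    expanded from the state runs along the parent chain (start excluded)."""
    segs = []
    while pn.parent is not None:
        segs.append(pn.owner.run)
        pn = pn.parent
    out: list[int] = []
    for run in reversed(segs):
        out.extend(run)
    return tuple(out)


class CompressedTree:
    """The live path-node/state-node structure maintained during decoding."""

    def __init__(self, start_index: int):
        self.root = StateNode(start=0, run=[start_index])
        self.root_pn = PathNode(
            pos=0, state=start_index, rank=1, parent=None, owner=self.root, log_score=0.0
        )
        self.root.path_nodes.append(self.root_pn)
        # insertion-ordered registry of live state nodes (dict used as an
        # ordered set) so every traversal is deterministic
        self.state_nodes: dict[StateNode, None] = {self.root: None}
        self.live_path_nodes = 1
        self.peak_path_nodes = 1
        self.peak_state_nodes = 1
        self.merges_performed = 0
        self.prunes_performed = 0

    # -- construction -----------------------------------------------------

    def attach_frontier(
        self, pos: int, level: dict[int, list[tuple[float, PathNode]]]
    ) -> dict[int, list[PathNode]]:
        """Link the merge results for position ``pos`` into the tree.

        ``level`` maps each state index to its ranked ``(log_score, parent
        path node)`` entries.  Returns the new frontier path nodes per state.
        """
        new_nodes: dict[int, list[PathNode]] = {}
        for j, entries in level.items():
            sn = StateNode(start=pos, run=[j])
            self.state_nodes[sn] = None
            nodes = []
            for rank0, (score, parent) in enumerate(entries):
                if parent.owner not in self.state_nodes:
                    raise TreeConsistencyError(
                        f"parent of new node ({pos},{j},{rank0 + 1}) is not live"
                    )
                pn = PathNode(pos=pos, state=j, rank=rank0 + 1, parent=parent, owner=sn, log_score=score)
                parent.child_count += 1
                sn.path_nodes.append(pn)
                po = parent.owner
                sn.parent_edges[po] = sn.parent_edges.get(po, 0) + 1
                po.children[sn] = None
                nodes.append(pn)
            self.live_path_nodes += len(nodes)
            new_nodes[j] = nodes
        self.peak_path_nodes = max(self.peak_path_nodes, self.live_path_nodes)
        self.peak_state_nodes = max(self.peak_state_nodes, len(self.state_nodes))
        return new_nodes

    # -- pruning ----------------------------------------------------------

    def prune_level(self, removal_seed: list[PathNode]) -> None:
        """Transitively remove path nodes with no children, starting from the
        old-frontier nodes the new level no longer references; delete state
        nodes left without path nodes."""
        queue = [pn for pn in removal_seed if pn.child_count == 0 and pn is not self.root_pn]
        while queue:
            pn = queue.pop()
            sn = pn.owner
            sn.path_nodes.remove(pn)
            self.live_path_nodes -= 1
            self.prunes_performed += 1
            parent = pn.parent
            if parent is not None:
                po = parent.owner
                cnt = sn.parent_edges[po] - 1
                if cnt:
                    sn.parent_edges[po] = cnt
                else:
                    del sn.parent_edges[po]
                    po.children.pop(sn, None)
                parent.child_count -= 1
                if parent.child_count == 0 and parent is not self.root_pn:
                    queue.append(parent)
            if not sn.path_nodes:
                if sn.children:  # a childless path node cascade cannot leave children
                    raise TreeConsistencyError("emptied state node still has children")
                del self.state_nodes[sn]

    # -- compression ------------------------------------------------------

    def compress_merge(self) -> None:
        """Merge every (parent, child) state-node pair where the parent is
        the child's only parent and the child is the parent's only child;
        repeats until no pair qualifies (idempotent afterwards).  The virtual
        root is never merged."""
        changed = True
        while changed:
            changed = False
            for v in list(self.state_nodes):
                if v is self.root or v not in self.state_nodes:
                    continue
                if len(v.parent_edges) != 1:
                    continue
                p = next(iter(v.parent_edges))
                if p is self.root or len(p.children) != 1:
                    continue
                self._merge_pair(p, v)
                changed = True

    def _merge_pair(self, p: StateNode, v: StateNode) -> None:
        """Merge child ``v`` into parent ``p``: concatenate runs, keep v's
        path nodes, and splice p's path nodes out of the parent chains."""
        if v.start != p.end + 1:
            raise TreeConsistencyError("merge of non-adjacent state nodes")
        p.run.extend(v.run)
        spliced = p.path_nodes
        for pn in v.path_nodes:
            q = pn.parent
            pn.parent = q.parent
            pn.owner = p
        for q in spliced:
            # grandparent loses q but adopts q's children
            q.parent.child_count += q.child_count - 1
        self.live_path_nodes -= len(spliced)
        p.path_nodes = v.path_nodes
        p.children = v.children
        for ch in p.children:
            ch.parent_edges[p] = ch.parent_edges.pop(v)
        new_pe: dict[StateNode, int] = {}
        for pn in p.path_nodes:
            po = pn.parent.owner
            new_pe[po] = new_pe.get(po, 0) + 1
        p.parent_edges = new_pe
        del self.state_nodes[v]
        self.merges_performed += 1

    # -- auditing ---------------------------------------------------------

    def audit(self, frontier_nodes: list[PathNode]) -> None:
        """Recount every counter and recompute reachability from scratch;
        raise :class:`TreeConsistencyError` on any discrepancy.  O(live) —
        intended for instrumented runs, not production decodes."""
        problems: list[str] = []
        live = [pn for sn in self.state_nodes for pn in sn.path_nodes]
        live_set = set(map(id, live))
        if len(live_set) != len(live):
            problems.append("a path node is owned by two state nodes")

        # reachability: exactly the ancestors of the frontier (plus the root)
        reach: set[int] = {id(self.root_pn)}
        for pn in frontier_nodes:
            q: Optional[PathNode] = pn
            while q is not None and id(q) not in reach:
                reach.add(id(q))
                q = q.parent
        if reach != live_set:
            problems.append(
                f"live path nodes ({len(live_set)}) != reachable from frontier ({len(reach)})"
            )

        # child counters
        counts: dict[int, int] = {}
        by_id = {id(pn): pn for pn in live}
        for pn in live:
            if pn.parent is not None:
                counts[id(pn.parent)] = counts.get(id(pn.parent), 0) + 1
        for pn in live:
            if pn.child_count != counts.get(id(pn), 0):
                problems.append(f"child_count mismatch at {pn!r}")

        for sn in self.state_nodes:
            for pn in sn.path_nodes:
                if pn.owner is not sn:
                    problems.append(f"owner mismatch at {pn!r}")
                if pn.pos != sn.end:
                    problems.append(f"path node {pn!r} not at the end of its run")
                if pn.parent is not None and pn.parent.pos != sn.start - 1:
                    problems.append(f"parent of {pn!r} not adjacent to run start")
            if sn is self.root:
                continue
            pe: dict[StateNode, int] = {}
            for pn in sn.path_nodes:
                po = pn.parent.owner
                pe[po] = pe.get(po, 0) + 1
            if pe != sn.parent_edges:
                problems.append(f"parent_edges mismatch at {sn!r}")
            for po in pe:
                if sn not in po.children:
                    problems.append(f"{sn!r} missing from children of its parent")
            # merge condition must not hold for any live pair
            if len(sn.parent_edges) == 1:
                p = next(iter(sn.parent_edges))
                if p is not self.root and len(p.children) == 1:
                    problems.append(f"mergeable pair left after compression: {p!r} -> {sn!r}")
        for sn in self.state_nodes:
            for ch in sn.children:
                if ch not in self.state_nodes:
                    problems.append(f"{sn!r} lists a dead child")
        if problems:
            raise TreeConsistencyError("; ".join(problems))


def recover_paths(
    hmm: Hmm,
    frontier: dict[int, tuple[list[float], list[PathNode]]],
    k: int,
) -> list[ScoredPath]:
    """Select the global top-k from the <= k x m frontier candidates (the
    first k steps of an m-way mergesort, applying terminal weights), then
    expand each winner's state runs by walking parent pointers."""
    pred_lists = {j: scores for j, (scores, _) in frontier.items()}
    if hmm.log_end is not None:
        factors = {j: float(hmm.log_end[j]) for j in frontier}
    else:
        factors = {j: 0.0 for j in frontier}

    def tie_key(j: int, rank: int) -> tuple:
        return path_state_indices(frontier[j][1][rank - 1])

    triples = merge_candidates(pred_lists, factors, k, tie_key=tie_key)
    paths = []
    for rank0, (score, j, r) in enumerate(triples):
        pn = frontier[j][1][r - 1]
        idx = path_state_indices(pn)
        paths.append(
            ScoredPath(
                states=tuple(hmm.states[s] for s in idx),
                log_joint=float(score),
                rank=rank0 + 1,
            )
        )
    return paths


def kbest_tree(hmm: Hmm, seq: Sequence, k: int, audit: bool = False) -> KBestResult:
    """The k' <= k most probable paths via the compressed-tree engine.

    Processes the sequence strictly left to right, keeping only the live
    compressed tree plus the current frontier's sorted score lists.  With
    ``audit=True`` a full structural self-check runs after every position.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) == 0:
        raise ValueError("cannot decode an empty sequence")
    x = seq.encode(hmm)
    n, m = len(x), hmm.m
    lt, le = hmm.log_trans, hmm.log_emit

    tree = CompressedTree(start_index=m)
    # frontier: state index -> (sorted score list, path nodes in rank order);
    # position 0 is the silent start, keyed -1
    frontier: dict[int, tuple[list[float], list[PathNode]]] = {
        -1: ([0.0], [tree.root_pn])
    }

    def make_stats() -> DecoderStats:
        return DecoderStats(
            peak_path_nodes=tree.peak_path_nodes,
            peak_state_nodes=tree.peak_state_nodes,
            naive_cells=k * m * (n + 1),
            merges_performed=tree.merges_performed,
            prunes_performed=tree.prunes_performed,
        )

    for i in range(1, n + 1):
        sym = x[i - 1]
        level: dict[int, list[tuple[float, PathNode]]] = {}
        new_scores: dict[int, list[float]] = {}
        for j in range(m):
            lej = le[j, sym]
            if lej == NEG_INF:
                continue
            pred_lists: dict[int, list[float]] = {}
            factors: dict[int, float] = {}
            if i == 1:
                pred_lists[-1] = frontier[-1][0]
                factors[-1] = float(lt[m, j] + lej)
            else:
                for c in hmm.predecessors[j]:
                    c = int(c)
                    if c in frontier:
                        pred_lists[c] = frontier[c][0]
                        factors[c] = float(lt[c, j] + lej)
            if not pred_lists:
                continue

            def tie_key(c: int, rank: int) -> tuple:
                return path_state_indices(frontier[c][1][rank - 1])

            triples = merge_candidates(pred_lists, factors, k, tie_key=tie_key)
            if triples:
                level[j] = [(s, frontier[c][1][r - 1]) for s, c, r in triples]
                new_scores[j] = [s for s, _, _ in triples]

        if not level:  # no positive-probability path survives
            return KBestResult(paths=[], k_requested=k, stats=make_stats())

        new_nodes = tree.attach_frontier(i, level)
        old_frontier = [pn for _, nodes in frontier.values() for pn in nodes]
        tree.prune_level([pn for pn in old_frontier if pn.child_count == 0])
        tree.compress_merge()
        frontier = {j: (new_scores[j], new_nodes[j]) for j in level}
        if audit:
            tree.audit([pn for _, nodes in frontier.values() for pn in nodes])

    paths = recover_paths(hmm, frontier, k)
    return KBestResult(paths=paths, k_requested=k, stats=make_stats())
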