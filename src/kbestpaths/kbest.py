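"""k-best Viterbi decoding: shared result types, the list-merge primitive and
the naive matrix-backtracking engine.

The naive engine generalises Viterbi by storing, for every (position, state)
cell, the k highest-scoring paths into that cell together with backpointers
(predecessor state, predecessor rank).  It retains the full
``(n+1) x m x k`` backpointer matrix and serves as the reference decoder for
the memory-compressed tree engine in :mod:`kbestpaths.tree`.

Tie rule (package-wide): paths of exactly equal log-probability are ordered
by lexicographic comparison of their state-index sequences — the path whose
first differing state has the lower index in ``Hmm.states`` ranks earlier.
Both engines apply this rule identically so their outputs are comparable
element by element.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Optional, Sequence as TySequence

import numpy as np

from .model import NEG_INF, Hmm, ScoredPath, Sequence

TieKey = Callable[[Hashable, int], tuple]


@dataclass
class DecoderStats:
    """Instrumentation counters for one decode.

    Memory is reported as live node counts rather than bytes; ``naive_cells``
    is the ``k * m * (n+1)`` cell count of the full matrix for comparison.
    """

    peak_path_nodes: int = 0
    peak_state_nodes: int = 0
    naive_cells: int = 0
    merges_performed: int = 0
    prunes_performed: int = 0


@dataclass
class KBestResult:
    """The k' <= k globally best paths, sorted by non-increasing log_joint
    (ties by the package tie rule), plus decoder statistics."""

    paths: list[ScoredPath]
    k_requested: int
    stats: DecoderStats = field(default_factory=DecoderStats)

    def __len__(self) -> int:
        return len(self.paths)


def merge_candidates(
    pred_lists: Mapping[Hashable, TySequence[float]],
    factors: Mapping[Hashable, float],
    k: int,
    tie_key: Optional[TieKey] = None,
) -> list[tuple[float, Hashable, int]]:
    """Select the k largest ``pred_lists[c][r] + factors[c]`` as the first k
    steps of a |Pred|-way mergesort.

    Each predecessor list must be sorted non-increasing.  Returns
    ``(score, predecessor, source_rank)`` triples with 1-based source ranks,
    in non-increasing score order.  Candidates of probability zero (``-inf``)
    are never produced; if everything is ``-inf`` the result is empty.

    ``tie_key(pred, rank0)`` maps a candidate to a sortable key used to order
    exact score ties (ascending); when omitted, ties keep the predecessor
    iteration order.  Only O(k + |Pred|) candidates are touched, plus any
    candidates tied with the k-th score.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    keys = list(pred_lists.keys())
    heap: list[tuple[float, int, int]] = []  # (-score, pred_order, rank0)
    for oi, c in enumerate(keys):
        f = factors.get(c, NEG_INF)
        lst = pred_lists[c]
        if f == NEG_INF or len(lst) == 0:
            continue
        s = lst[0] + f
        if s == NEG_INF:
            continue
        heap.append((-s, oi, 0))
    heapq.heapify(heap)

    out: list[tuple[float, int, int]] = []  # (score, pred_order, rank0)

    def _pop() -> None:
        negs, oi, r = heapq.heappop(heap)
        out.append((-negs, oi, r))
        lst = pred_lists[keys[oi]]
        if r + 1 < len(lst):
            s2 = lst[r + 1] + factors[keys[oi]]
            if s2 != NEG_INF:
                heapq.heappush(heap, (-s2, oi, r + 1))

    while heap and len(out) < k:
        _pop()
    # pull candidates tied with the k-th score so the tie rule can see them
    if out:
        kth = out[-1][0]
        while heap and -heap[0][0] == kth:
            _pop()

    internal_key = None if tie_key is None else (lambda oi, r0: tie_key(keys[oi], r0 + 1))
    out = _resolve_ties(out, internal_key)
    return [(s, keys[oi], r + 1) for s, oi, r in out[:k]]


def _resolve_ties(
    cands: list[tuple[float, int, int]], tie_key: Optional[TieKey]
) -> list[tuple[float, int, int]]:
    """Reorder runs of exactly equal scores by the tie key (ascending)."""
    if len(cands) < 2:
        return cands
    out: list[tuple[float, int, int]] = []
    i = 0
    while i < len(cands):
        j = i + 1
        while j < len(cands) and cands[j][0] == cands[i][0]:
            j += 1
        run = cands[i:j]
        if len(run) > 1:
            if tie_key is not None:
                run.sort(key=lambda t: tie_key(t[1], t[2]))
            else:
                run.sort(key=lambda t: (t[1], t[2]))
        out.extend(run)
        i = j
    return out


# ---------------------------------------------------------------------------
# naive matrix engine
# ---------------------------------------------------------------------------


class _Matrix:
    """Full (n+1) x m x k backpointer storage: for every cell the
    (predecessor state, predecessor rank) of each ranked path into it."""

    __slots__ = ("bp",)

    def __init__(self, n: int, m: int, k: int):
        self.bp = np.full((n + 1, m, k, 2), -1, dtype=np.int32)

    def backtrack(self, i: int, j: int, r: int) -> tuple[int, ...]:
        """State-index sequence pi_1..pi_i of the r-th best path to (i, j)."""
        path = [0] * i
        bp = self.bp
        while i >= 1:
            path[i - 1] = j
            j, r = int(bp[i, j, r, 0]), int(bp[i, j, r, 1])
            i -= 1
        return tuple(path)


def _select_topk(
    cand_s: np.ndarray,
    k: int,
    path_key: Callable[[int], tuple],
) -> np.ndarray:
    """Indices of the top-k candidates by (score desc, path key asc).

    ``path_key(idx)`` is consulted only for exact score ties, which are rare
    for generic real-valued parameters but systematic in symmetric models.
    """
    order = np.argsort(-cand_s, kind="stable")
    take = min(k, len(order))
    # widen the window to cover everything tied with the k-th score
    if take < len(order):
        kth = cand_s[order[take - 1]]
        while take < len(order) and cand_s[order[take]] == kth:
            take += 1
    window = list(order[:take])
    # reorder exact-tie runs by the lexicographic path rule
    i = 0
    resolved: list[int] = []
    while i < len(window):
        j = i + 1
        while j < len(window) and cand_s[window[j]] == cand_s[window[i]]:
            j += 1
        run = window[i:j]
        if len(run) > 1:
            run.sort(key=path_key)
        resolved.extend(run)
        i = j
    return np.asarray(resolved[:k], dtype=np.int64)


def kbest_naive(hmm: Hmm, seq: Sequence, k: int) -> KBestResult:
    """The k' <= k most probable paths via the full-matrix DP.

    Runs in Theta(k m n) space: every cell of the (n+1) x m grid keeps up to
    k ranked scores and backpointers (``stats.peak_path_nodes`` therefore
    equals ``stats.naive_cells``).  Each position is processed as one
    vectorised candidate-matrix update; exact score ties fall back to a
    per-state path comparison implementing the lexicographic tie rule.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) == 0:
        raise ValueError("cannot decode an empty sequence")
    x = seq.encode(hmm)
    n, m = len(x), hmm.m
    lt, le = hmm.log_trans, hmm.log_emit
    mat = _Matrix(n, m, k)

    # scores of the current frontier: (state, rank), -inf padded, sorted
    # non-increasing along ranks.  Position 1's only predecessor is the start.
    prev = np.full((m, k), NEG_INF)
    prev[:, 0] = lt[m, :] + le[:, x[0]]
    mat.bp[1, :, 0, 1] = 0

    # materialised state-index prefixes of the frontier paths, so the
    # lexicographic tie rule costs one bytes comparison instead of a
    # backpointer walk (ties are systematic in models with repeated modules)
    if m > 255:
        raise ValueError("the naive engine supports at most 255 states")
    prefix = np.zeros((m, k, n), dtype=np.uint8)
    prefix[:, 0, 0] = np.arange(m, dtype=np.uint8)

    ltm = lt[:m]
    for i in range(2, n + 1):
        # candidate scores: prev[c, r] + (a_cj * b_j(x_i)), flattened c-major
        cand = (prev[:, None, :] + (ltm + le[:, x[i - 1]][None, :])[:, :, None])
        cand = cand.transpose(1, 0, 2).reshape(m, m * k)
        order = np.argsort(-cand, axis=1, kind="stable")
        w = min(k, m * k)
        top = order[:, : w + 1] if m * k > w else order
        sorted_top = np.take_along_axis(cand, top, axis=1)
        finite = sorted_top > NEG_INF
        # rows needing the tie rule: equal adjacent scores within the top
        # w+1 finite candidates (covers ties inside and at the k boundary)
        with np.errstate(invalid="ignore"):
            ties = (np.diff(sorted_top, axis=1) == 0.0) & finite[:, 1:]
        tie_rows = np.flatnonzero(ties.any(axis=1))
        sel = top[:, :w]
        ok = finite[:, :w]
        new = np.full((m, k), NEG_INF)
        new[:, :w] = np.where(ok, sorted_top[:, :w], NEG_INF)
        bp_i = mat.bp[i]
        bp_i[:, :w, 0] = np.where(ok, sel // k, -1)
        bp_i[:, :w, 1] = np.where(ok, sel % k, -1)
        flat_prefix = prefix.reshape(m * k, n)
        for j in tie_rows:
            row = cand[j]
            cand_idx = np.flatnonzero(row > NEG_INF)

            def path_key(ci: int, _ci=cand_idx) -> bytes:
                return flat_prefix[int(_ci[ci]), : i - 1].tobytes()

            chosen = cand_idx[_select_topk(row[cand_idx], k, path_key)]
            cnt = len(chosen)
            new[j, :cnt] = row[chosen]
            new[j, cnt:] = NEG_INF
            bp_i[j, :cnt, 0] = chosen // k
            bp_i[j, :cnt, 1] = chosen % k
            bp_i[j, cnt:, :] = -1
        # advance the materialised prefixes (fancy indexing copies, so the
        # gather is safe against in-place aliasing)
        src = (bp_i[:, :, 0].astype(np.int64) * k + bp_i[:, :, 1]).clip(min=0)
        prefix[:, :, : i - 1] = flat_prefix[src.ravel(), : i - 1].reshape(m, k, i - 1)
        prefix[:, :, i - 1] = np.arange(m, dtype=np.uint8)[:, None]
        prev = new

    stats = DecoderStats(naive_cells=k * m * (n + 1), peak_state_nodes=m * (n + 1))
    stats.peak_path_nodes = stats.naive_cells

    # final selection over the k x m frontier, applying end weights if any
    final = prev if hmm.log_end is None else prev + hmm.log_end[:, None]
    flat = final.ravel()
    cand_idx = np.flatnonzero(flat > NEG_INF)
    if len(cand_idx) == 0:
        return KBestResult(paths=[], k_requested=k, stats=stats)
    flat_prefix = prefix.reshape(m * k, n)

    def final_key(ci: int) -> bytes:
        return flat_prefix[int(cand_idx[ci])].tobytes()

    chosen = cand_idx[_select_topk(flat[cand_idx], k, final_key)]
    paths = []
    for rank0, f in enumerate(chosen):
        paths.append(
            ScoredPath(
                states=tuple(hmm.states[s] for s in flat_prefix[int(f)]),
                log_joint=float(flat[f]),
                rank=rank0 + 1,
            )
        )
    return KBestResult(paths=paths, k_requested=k, stats=stats)


def kbest(
    hmm: Hmm, seq: Sequence, k: int, engine: str = "tree", audit: bool = False
) -> KBestResult:
    """Decode with the chosen engine (``"naive"`` or ``"tree"``).

    Both engines return identical paths, ranks and log-probabilities; they
    differ only in memory behaviour and in the statistics they report.
    ``audit`` enables per-position structural self-checks of the tree engine
    (ignored by the naive engine; changes asymptotic cost, default off).
    """
    if engine == "naive":
        return kbest_naive(hmm, seq, k)
    if engine == "tree":
        from .tree import kbest_tree

        return kbest_tree(hmm, seq, k, audit=audit)
    raise ValueError(f"unknown engine {engine!r}; expected 'naive' or 'tree'")
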