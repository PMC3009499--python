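"""Hidden Markov model data model, validation, forward algorithm and Viterbi.

The model is the classic discrete-emission HMM used for sequence labelling:
a silent start state ``I``, transition probabilities ``a_ij``, and per-state
emission distributions ``b_i(c)`` over a finite symbol alphabet.  A path
``pi_0 = I, pi_1, ..., pi_n`` emits a sequence ``x_1 ... x_n`` with joint
probability ``prod_t a_{pi_{t-1} pi_t} * b_{pi_t}(x_t)`` (optionally times a
terminal weight for ``pi_n``).

All probabilities are handled in natural-log space; impossible events are
``-inf``.  Sequence positions are 1..n in user-facing coordinates (position 0
is the silent start); internally everything is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence as TySequence

import numpy as np

NEG_INF = float("-inf")

#: Tolerance for probability-normalisation checks in :func:`validate`.
NORM_TOL = 1e-9


@dataclass(eq=False)
class Hmm:
    """A discrete-emission HMM with one silent start state.

    Parameters are stored as dense log-probability arrays:

    ``log_trans``
        shape ``(m+1, m)``; row ``m`` holds transitions out of the start
        state, rows ``0..m-1`` transitions between emitting states.  A
        forbidden transition is ``-inf``.
    ``log_emit``
        shape ``(m, A)`` over the alphabet.
    ``log_end``
        optional shape ``(m,)`` terminal weights; ``None`` means every state
        may end a path with weight 1.
    """

    states: tuple[str, ...]
    start_state: str
    alphabet: tuple[str, ...]
    labels: tuple[str, ...]
    log_trans: np.ndarray
    log_emit: np.ndarray
    log_end: Optional[np.ndarray] = None
    construction_issues: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        """Number of emitting states."""
        return len(self.states)

    @cached_property
    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}

    @cached_property
    def symbol_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.alphabet)}

    @cached_property
    def predecessors(self) -> tuple[np.ndarray, ...]:
        """For each state j, the emitting states c with ``a_cj > 0``."""
        lt = self.log_trans[: self.m]
        return tuple(np.flatnonzero(lt[:, j] > NEG_INF) for j in range(self.m))

    def label_of(self, state: str) -> str:
        return self.labels[self.state_index[state]]

    @classmethod
    def from_tables(
        cls,
        states: TySequence[str],
        start_state: str,
        alphabet: TySequence[str],
        transitions: Mapping[tuple[str, str], float],
        emissions: Mapping[tuple[str, str], float],
        labels: Mapping[str, str],
        end_weights: Optional[Mapping[str, float]] = None,
    ) -> "Hmm":
        """Build an :class:`Hmm` from sparse probability tables.

        Structural problems that cannot be represented in the dense arrays
        (a transition into the start state, an emission from the start state)
        are recorded on ``construction_issues`` and surface as diagnostics
        from :func:`validate` rather than raising.
        """
        states = tuple(states)
        alphabet = tuple(alphabet)
        if start_state in states:
            raise ValueError(f"start state {start_state!r} must not be an emitting state")
        sidx = {s: i for i, s in enumerate(states)}
        aidx = {c: i for i, c in enumerate(alphabet)}
        m, na = len(states), len(alphabet)
        issues: list[str] = []

        trans = np.zeros((m + 1, m))
        for (src, dst), p in transitions.items():
            if dst == start_state:
                issues.append(f"start state {start_state!r} has an incoming transition from {src!r}")
                continue
            if dst not in sidx:
                raise ValueError(f"unknown transition target {dst!r}")
            row = m if src == start_state else sidx.get(src)
            if row is None:
                raise ValueError(f"unknown transition source {src!r}")
            trans[row, sidx[dst]] = p

        emit = np.zeros((m, na))
        for (st, sym), p in emissions.items():
            if st == start_state:
                issues.append(f"start state {start_state!r} has an emission for {sym!r}")
                continue
            if st not in sidx:
                raise ValueError(f"unknown emitting state {st!r}")
            if sym not in aidx:
                raise ValueError(f"unknown symbol {sym!r}")
            emit[sidx[st], aidx[sym]] = p

        end = None
        if end_weights is not None:
            end = np.zeros(m)
            for st, p in end_weights.items():
                end[sidx[st]] = p

        lab = tuple(labels[s] for s in states)
        with np.errstate(divide="ignore"):
            return cls(
                states=states,
                start_state=start_state,
                alphabet=alphabet,
                labels=lab,
                log_trans=np.log(trans),
                log_emit=np.log(emit),
                log_end=None if end is None else np.log(end),
                construction_issues=tuple(issues),
            )

    def transition(self, src: str, dst: str) -> float:
        """Probability ``a_{src,dst}`` (linear scale)."""
        row = self.m if src == self.start_state else self.state_index[src]
        return float(np.exp(self.log_trans[row, self.state_index[dst]]))

    def emission(self, state: str, symbol: str) -> float:
        return float(np.exp(self.log_emit[self.state_index[state], self.symbol_index[symbol]]))


@dataclass(frozen=True)
class Sequence:
    """An observed symbol sequence; ``symbols`` is a string of single-character symbols."""

    id: str
    symbols: str

    def __len__(self) -> int:
        return len(self.symbols)

    def encode(self, hmm: Hmm) -> np.ndarray:
        try:
            return np.fromiter(
                (hmm.symbol_index[c] for c in self.symbols), dtype=np.int64, count=len(self.symbols)
            )
        except KeyError as exc:
            raise ValueError(
                f"sequence {self.id!r} contains symbol {exc.args[0]!r} not in the model alphabet"
            ) from None


@dataclass(frozen=True)
class ScoredPath:
    """A state path with its joint log-probability and 1-based rank."""

    states: tuple[str, ...]
    log_joint: float
    rank: int = 1


def validate(hmm: Hmm) -> list[str]:
    """Check the model invariants; return a list of human-readable violations.

    An empty list means the model is well formed: each transition row sums to
    one (including the terminal weight when present), each emission row sums
    to one, the start state is silent with no incoming edges, and every
    emitting state is reachable from the start.
    """
    out: list[str] = list(hmm.construction_issues)
    m = hmm.m
    with np.errstate(over="ignore"):
        trans = np.exp(hmm.log_trans)
        emit = np.exp(hmm.log_emit)
        end = None if hmm.log_end is None else np.exp(hmm.log_end)

    row_sums = trans.sum(axis=1)
    if end is not None:
        row_sums[:m] = row_sums[:m] + end
    names = list(hmm.states) + [hmm.start_state]
    for i, s in enumerate(row_sums):
        if abs(s - 1.0) > NORM_TOL:
            out.append(f"transition row of state {names[i]!r} sums to {s!r}, not 1")

    for i, s in enumerate(emit.sum(axis=1)):
        if abs(s - 1.0) > NORM_TOL:
            out.append(f"emission row of state {hmm.states[i]!r} sums to {s!r}, not 1")

    # reachability from the start state over positive-probability edges
    reach: set[int] = set()
    frontier = set(np.flatnonzero(trans[m] > 0.0).tolist())
    while frontier:
        reach |= frontier
        nxt: set[int] = set()
        for c in frontier:
            nxt |= set(np.flatnonzero(trans[c] > 0.0).tolist())
        frontier = nxt - reach
    for j in range(m):
        if j not in reach:
            out.append(f"state {hmm.states[j]!r} is not reachable from the start state")
    return out


def _encode_path(hmm: Hmm, states: Iterable[str]) -> list[int]:
    try:
        return [hmm.state_index[s] for s in states]
    except KeyError as exc:
        raise ValueError(f"unknown state {exc.args[0]!r} in path") from None


def path_log_prob(hmm: Hmm, seq: Sequence, states: TySequence[str]) -> float:
    """log P(path, sequence): sum of log a and log b factors along the path.

    Includes the terminal weight of the last state when the model defines end
    weights.  Returns ``-inf`` if any factor is zero.  Raises ``ValueError``
    on a length mismatch or unknown state/symbol.
    """
    if len(states) != len(seq):
        raise ValueError(
            f"path length {len(states)} does not match sequence length {len(seq)}"
        )
    x = seq.encode(hmm)
    idx = _encode_path(hmm, states)
    lt, le = hmm.log_trans, hmm.log_emit
    prev = hmm.m  # start state row
    score = 0.0
    for t, j in enumerate(idx):
        score = score + (lt[prev, j] + le[j, x[t]])
        prev = j
    if hmm.log_end is not None and idx:
        score = score + hmm.log_end[idx[-1]]
    return float(score)


def forward_log_prob(hmm: Hmm, seq: Sequence) -> float:
    """log P(sequence) = log of the total probability summed over all paths.

    Computed in log space with log-sum-exp; ``-inf`` when no path can emit
    the sequence.
    """
    from scipy.special import logsumexp

    if len(seq) == 0:
        raise ValueError("cannot compute forward probability of an empty sequence")
    x = seq.encode(hmm)
    lt, le = hmm.log_trans, hmm.log_emit
    f = lt[hmm.m, :] + le[:, x[0]]
    with np.errstate(invalid="ignore"):
        for t in range(1, len(x)):
            f = logsumexp(f[:, None] + lt[: hmm.m, :], axis=0) + le[:, x[t]]
        if hmm.log_end is not None:
            f = f + hmm.log_end
        return float(logsumexp(f))


def viterbi(hmm: Hmm, seq: Sequence) -> Optional[ScoredPath]:
    """The single most probable path, or ``None`` when no path has positive
    probability.

    Ties are broken by the package-wide rule (lexicographically smallest
    state-index sequence wins), shared with the k-best decoders.
    """
    from .kbest import kbest_naive

    result = kbest_naive(hmm, seq, 1)
    return result.paths[0] if result.paths else None
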