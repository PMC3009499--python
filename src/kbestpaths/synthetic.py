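"""Seeded generators: random HMMs, sampled sequences with known generating
paths, and purpose-built labelled fixtures.

The membrane fixtures use a reduced 4-symbol residue alphabet —
``h`` (hydrophobic), ``p`` (polar), ``c`` (charged), ``g`` (small/glycine) —
with hydrophobic-biased helix emissions, charged-biased inside loops and
polar-biased outside loops.  Helix runs pass through a fixed entry state,
two self-looping dwell states and a fixed exit state, giving a length
distribution with minimum 4 and an expected run of ~22 residues — the
typical length of a membrane-spanning alpha helix.  Loops pass through two
self-looping states, so degenerate one-residue loops (which no decoder
could recover) cannot occur.

All generators draw from a single ``numpy.random.default_rng`` stream and
are fully determined by their seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .model import Hmm, ScoredPath, Sequence, path_log_prob

#: Self-loop probabilities of the two helix dwell states per direction.  A
#: helix run is entry + dwell + dwell + exit: minimum length 4, expected
#: length 2 + (mean dwells) = 22 for both directions, with far less mass at
#: short lengths than a single geometric state of the same mean — matching
#: the narrow length distribution of real membrane-spanning helices.
#: in->out dwell means: 9.5 + 10.5; out->in: 9 + 11.
_HELIX_DWELL = {
    "mio": (1.0 - 1.0 / 9.5, 1.0 - 1.0 / 10.5),
    "moi": (1.0 - 1.0 / 9.0, 1.0 - 1.0 / 11.0),
}
#: Loop dwell self-loop probabilities (two serial states per loop, so the
#: minimum loop length is 2 and one-residue loops — which no decoder could
#: recover — cannot occur).  Inside loops are shorter (mean 5 + 6 = 11)
#: than outside loops (mean 6.5 + 7.5 = 14), as in real membrane proteins.  All
#: eight dwell probabilities are pairwise distinct so that moving a dwell
#: residue between states never leaves the path probability exactly
#: unchanged: distinct explanations essentially never tie.
_LOOP_DWELL = {
    "i": (1.0 - 1.0 / 5.0, 1.0 - 1.0 / 6.0),
    "o": (1.0 - 1.0 / 6.5, 1.0 - 1.0 / 7.5),
}

TOY_ALPHABET = ("h", "p", "c", "g")
_HELIX_EMIT = {"h": 0.80, "p": 0.06, "c": 0.03, "g": 0.11}
_INSIDE_EMIT = {"h": 0.04, "p": 0.12, "c": 0.66, "g": 0.18}
_OUTSIDE_EMIT = {"h": 0.05, "p": 0.64, "c": 0.10, "g": 0.21}


@dataclass(frozen=True)
class GenSpec:
    """Parameters of the random-HMM generator.

    ``sparsity`` is the density of extra transition edges in [0, 1] beyond
    the spanning edges that guarantee reachability; ``label_scheme`` is one
    of ``per-state`` (each state its own label), ``membrane`` (random i/M/o)
    or ``uniform``.
    """

    m: int
    alphabet_size: int = 4
    label_scheme: str = "per-state"
    sparsity: float = 0.3
    seed: int = 0
    n: int = 30


def random_hmm(spec: GenSpec) -> Hmm:
    """A valid random HMM, fully determined by ``spec.seed``.

    Reachability is guaranteed by giving every state an incoming edge from
    the start or an earlier state, and every state at least one outgoing
    edge; extra edges are added with probability ``spec.sparsity`` and all
    row weights are Dirichlet-distributed.
    """
    if spec.m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= spec.sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    if spec.alphabet_size < 1:
        raise ValueError("alphabet_size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    m = spec.m
    states = tuple(f"S{i}" for i in range(m))
    alphabet = tuple(string.ascii_lowercase[: spec.alphabet_size])

    support = np.zeros((m + 1, m), dtype=bool)
    support[m, 0] = True  # start -> S0
    for j in range(1, m):
        src = int(rng.integers(-1, j))  # -1 means the start state
        support[m if src < 0 else src, j] = True
    for c in range(m):
        if not support[c].any():
            support[c, int(rng.integers(0, m))] = True
    support |= rng.random((m + 1, m)) < spec.sparsity

    trans = np.zeros((m + 1, m))
    for row in range(m + 1):
        cols = np.flatnonzero(support[row])
        trans[row, cols] = rng.dirichlet(np.ones(len(cols)))
    emit = rng.dirichlet(np.ones(spec.alphabet_size), size=m)

    if spec.label_scheme == "per-state":
        labels = states
    elif spec.label_scheme == "membrane":
        labels = tuple(rng.choice(["i", "M", "o"]) for _ in range(m))
    elif spec.label_scheme == "uniform":
        labels = ("x",) * m
    else:
        raise ValueError(f"unknown label scheme {spec.label_scheme!r}")

    with np.errstate(divide="ignore"):
        return Hmm(
            states=states,
            start_state="I",
            alphabet=alphabet,
            labels=labels,
            log_trans=np.log(trans),
            log_emit=np.log(emit),
        )


def sample_sequence(hmm: Hmm, n: int, seed: int) -> tuple[Sequence, ScoredPath]:
    """Sample an n-symbol sequence by a stochastic walk from the start state,
    returning the sequence and the generating path with its log-probability.

    When the model carries terminal weights the walk renormalises each row's
    continuation probabilities, so sampling at a fixed length stays defined.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    with np.errstate(over="ignore"):
        trans = np.exp(hmm.log_trans)
        emit = np.exp(hmm.log_emit)
    m = hmm.m
    cur = m  # start row
    states_idx: list[int] = []
    symbols: list[str] = []
    for _ in range(n):
        row = trans[cur]
        total = row.sum()
        if total <= 0.0:
            name = hmm.start_state if cur == m else hmm.states[cur]
            raise ValueError(f"state {name!r} has no outgoing transitions")
        cur = int(rng.choice(m, p=row / total))
        states_idx.append(cur)
        symbols.append(hmm.alphabet[int(rng.choice(len(hmm.alphabet), p=emit[cur]))])
    seq = Sequence(id=f"sample-{seed}", symbols="".join(symbols))
    path_states = tuple(hmm.states[j] for j in states_idx)
    lp = path_log_prob(hmm, seq, path_states)
    return seq, ScoredPath(states=path_states, log_joint=lp, rank=1)


def _toy_tables() -> tuple[list[str], dict, dict, dict]:
    """States, transitions, emissions and labels of the 12-state membrane
    model: inside loop, two directed helix modules (in->out and out->in),
    outside loop."""
    states = [
        "i1", "i2",
        "mio1", "mio2", "mio3", "mio4",
        "o1", "o2",
        "moi1", "moi2", "moi3", "moi4",
    ]
    transitions = {("I", "i1"): 0.5, ("I", "o1"): 0.5}
    for side, helix in (("i", "mio"), ("o", "moi")):
        p1, p2 = _LOOP_DWELL[side]
        transitions[(f"{side}1", f"{side}1")] = p1
        transitions[(f"{side}1", f"{side}2")] = 1.0 - p1
        transitions[(f"{side}2", f"{side}2")] = p2
        transitions[(f"{side}2", f"{helix}1")] = 1.0 - p2
    for mod, exit_state in (("mio", "o1"), ("moi", "i1")):
        q1, q2 = _HELIX_DWELL[mod]
        transitions[(f"{mod}1", f"{mod}2")] = 1.0
        transitions[(f"{mod}2", f"{mod}2")] = q1
        transitions[(f"{mod}2", f"{mod}3")] = 1.0 - q1
        transitions[(f"{mod}3", f"{mod}3")] = q2
        transitions[(f"{mod}3", f"{mod}4")] = 1.0 - q2
        transitions[(f"{mod}4", exit_state)] = 1.0
    emissions = {}
    labels = {}
    for st in states:
        if st.startswith("i"):
            table, labels[st] = _INSIDE_EMIT, "i"
        elif st.startswith("o"):
            table, labels[st] = _OUTSIDE_EMIT, "o"
        else:
            table, labels[st] = _HELIX_EMIT, "M"
        for sym, p in table.items():
            emissions[(st, sym)] = p
    return states, transitions, emissions, labels


def toy_membrane_hmm() -> Hmm:
    """A 12-state labelled membrane-protein model over the reduced alphabet.

    Helices are entry/dwell/dwell/exit runs of expected length 22 (minimum
    4); loops pass through two dwell states (minimum length 2), inside
    loops shorter (mean 11) and charged-biased, outside loops longer (mean
    14) and polar-biased, so sidedness is recoverable from sequence alone.
    """
    states, transitions, emissions, labels = _toy_tables()
    return Hmm.from_tables(
        states=states,
        start_state="I",
        alphabet=TOY_ALPHABET,
        transitions=transitions,
        emissions=emissions,
        labels=labels,
    )


def mirror_hmm() -> Hmm:
    """The toy membrane model duplicated into two side-symmetric branches.

    Copy ``a`` is entered on the inside, copy ``b`` is the identical model
    with the ``i``/``o`` labels exchanged and is entered on the outside; the
    entry probabilities are equal.  Every path therefore has a mirror path
    of exactly equal probability and opposite sidedness — the dual-topology
    situation in miniature.
    """
    states, transitions, emissions, labels = _toy_tables()
    swap = {"i": "o", "o": "i", "M": "M"}
    all_states = [f"a.{s}" for s in states] + [f"b.{s}" for s in states]
    trans = {("I", "a.i1"): 0.5, ("I", "b.i1"): 0.5}
    emis = {}
    lab = {}
    for prefix in ("a", "b"):
        for (src, dst), p in transitions.items():
            if src == "I":
                continue
            trans[(f"{prefix}.{src}", f"{prefix}.{dst}")] = p
        for (st, sym), p in emissions.items():
            emis[(f"{prefix}.{st}", sym)] = p
        for st, l in labels.items():
            lab[f"{prefix}.{st}"] = l if prefix == "a" else swap[l]
    return Hmm.from_tables(
        states=all_states,
        start_state="I",
        alphabet=TOY_ALPHABET,
        transitions=trans,
        emissions=emis,
        labels=lab,
    )
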