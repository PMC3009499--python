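"""Shared fixtures and the brute-force enumeration oracle.

The oracle scores every possible state path by explicit enumeration and is
kept deliberately independent of the decoders it checks: it never touches
the DP machinery, only the model's log-parameter arrays.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from kbestpaths import GenSpec, Hmm, Sequence, mirror_hmm, random_hmm, toy_membrane_hmm

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def enumerate_paths(hmm: Hmm, seq: Sequence) -> list[tuple[float, tuple[int, ...]]]:
    """All positive-probability paths as (log_joint, state-index tuple),
    sorted by score descending then lexicographically ascending."""
    x = seq.encode(hmm)
    m = hmm.m
    lt, le = hmm.log_trans, hmm.log_emit
    scores = np.zeros(1)
    last = np.array([m])
    paths = np.zeros((1, 0), dtype=int)
    for t in range(len(x)):
        step = lt[last][:, :] + le[:, x[t]][None, :]
        scores = (scores[:, None] + step).ravel()
        paths = np.concatenate(
            [np.repeat(paths, m, axis=0), np.tile(np.arange(m), len(last))[:, None]], axis=1
        )
        keep = scores > -np.inf
        scores, paths = scores[keep], paths[keep]
        last = paths[:, -1]
    if hmm.log_end is not None and len(scores):
        scores = scores + hmm.log_end[last]
        keep = scores > -np.inf
        scores, paths = scores[keep], paths[keep]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], tuple(paths[i])))
    return [(float(scores[i]), tuple(int(v) for v in paths[i])) for i in order]


def path_tuples(hmm: Hmm, result) -> list[tuple[float, tuple[int, ...]]]:
    """Decoder output in the oracle's (log_joint, index-tuple) form."""
    idx = hmm.state_index
    return [(p.log_joint, tuple(idx[s] for s in p.states)) for p in result.paths]


def random_instance(rng: np.random.Generator, max_m=8, max_n=50, max_k=64):
    """One random (hmm, seq, k) decoding instance."""
    from kbestpaths import sample_sequence

    spec = GenSpec(
        m=int(rng.integers(2, max_m + 1)),
        alphabet_size=int(rng.integers(2, 5)),
        sparsity=float(rng.uniform(0.1, 0.9)),
        seed=int(rng.integers(2**31)),
    )
    hmm = random_hmm(spec)
    seq, _ = sample_sequence(hmm, int(rng.integers(3, max_n + 1)), seed=int(rng.integers(2**31)))
    return hmm, seq, int(rng.integers(1, max_k + 1))


@pytest.fixture(scope="session")
def toy() -> Hmm:
    return toy_membrane_hmm()


@pytest.fixture(scope="session")
def mirror() -> Hmm:
    return mirror_hmm()


@pytest.fixture(scope="session")
def two_state() -> Hmm:
    """A hand-specified 2-state model used for hand-computed oracles."""
    return Hmm.from_tables(
        states=["A", "B"],
        start_state="I",
        alphabet=["x", "y", "z"],
        transitions={
            ("I", "A"): 0.7,
            ("I", "B"): 0.3,
            ("A", "A"): 0.6,
            ("A", "B"): 0.4,
            ("B", "A"): 0.5,
            ("B", "B"): 0.5,
        },
        emissions={
            ("A", "x"): 0.5,
            ("A", "y"): 0.3,
            ("A", "z"): 0.2,
            ("B", "x"): 0.1,
            ("B", "y"): 0.2,
            ("B", "z"): 0.7,
        },
        labels={"A": "a", "B": "b"},
    )


@pytest.fixture(scope="session")
def chain() -> Hmm:
    """A deterministic single-path model: I -> C1 -> C2 -> C1 -> ..."""
    return Hmm.from_tables(
        states=["C1", "C2"],
        start_state="I",
        alphabet=["u"],
        transitions={("I", "C1"): 1.0, ("C1", "C2"): 1.0, ("C2", "C1"): 1.0},
        emissions={("C1", "u"): 1.0, ("C2", "u"): 1.0},
        labels={"C1": "c", "C2": "c"},
    )
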