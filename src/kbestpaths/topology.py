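"""Labellings, membrane-protein topologies, and the two correctness measures.

A *labelling* maps each sequence position to the label of the state that
produced it — for the membrane application the three-letter alphabet
``i`` (inside/cytoplasmic), ``M`` (membrane-spanning helix) and ``o``
(outside).  The *topology* of a labelling is its number of membrane helices
together with the sidedness of the first residue; helix boundary positions
are deliberately not part of the topology, which acts as the equivalence key
when grouping alternative paths.

Helix intervals are stored 0-based half-open internally and reported 1-based
inclusive in all user-facing output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import Hmm, ScoredPath

#: Sidedness value for a labelling that begins inside a membrane run; never
#: equal to either side label.
MEMBRANE_START = "membrane-start"

DEFAULT_MEMBRANE_LABEL = "M"
MEMBRANE_ALPHABET = frozenset("iMo")


@dataclass(frozen=True)
class Topology:
    """Ordered membrane-helix intervals plus the sidedness of position 1."""

    helices: tuple[tuple[int, int], ...]  # 0-based half-open, sorted, disjoint
    sidedness: str

    @property
    def helix_count(self) -> int:
        return len(self.helices)


def labelling_of(hmm: Hmm, path: ScoredPath) -> str:
    """Positionwise substitution of each path state by its label."""
    idx = hmm.state_index
    return "".join(hmm.labels[idx[s]] for s in path.states)


def segments(labels: str) -> list[tuple[int, int, str]]:
    """Maximal runs of one label as (start, end, label), 0-based half-open."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


def topology_of(labels: str, membrane_label: str = DEFAULT_MEMBRANE_LABEL) -> Topology:
    """Extract the topology: maximal membrane runs become helices, the
    sidedness is the first label (or ``membrane-start`` for a labelling that
    begins mid-helix)."""
    if not labels:
        raise ValueError("cannot extract a topology from an empty labelling")
    helices = tuple((s, e) for s, e, lab in segments(labels) if lab == membrane_label)
    side = MEMBRANE_START if labels[0] == membrane_label else labels[0]
    return Topology(helices=helices, sidedness=side)


def sides_alternate(labels: str, membrane_label: str = DEFAULT_MEMBRANE_LABEL) -> bool:
    """True iff consecutive non-membrane segments alternate their label.

    Meaningful for the three-letter membrane alphabet, where a helix must
    carry the path from one side of the membrane to the other.
    """
    sides = [lab for _, _, lab in segments(labels) if lab != membrane_label]
    return all(a != b for a, b in zip(sides, sides[1:]))


def same_topology(a: Topology, b: Topology) -> bool:
    """Equivalence used for grouping: helix count and sidedness both match;
    boundary positions are ignored."""
    return a.helix_count == b.helix_count and a.sidedness == b.sidedness


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def phobius_correct(pred: Topology, truth: Topology, min_overlap: int = 5) -> bool:
    """The lenient measure: correct topology, and each true helix overlaps
    its ordinally corresponding predicted helix in at least ``min_overlap``
    positions."""
    if not same_topology(pred, truth):
        return False
    return all(_overlap(p, t) >= min_overlap for p, t in zip(pred.helices, truth.helices))


def tau_correct(pred: Topology, truth: Topology, tau: int) -> bool:
    """The stringent measure: correct topology, and every predicted helix
    boundary within ``tau`` residues of the true boundary."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not same_topology(pred, truth):
        return False
    return all(
        abs(p[0] - t[0]) <= tau and abs(p[1] - t[1]) <= tau
        for p, t in zip(pred.helices, truth.helices)
    )


def labelling_to_gff3(
    seq_id: str, labels: str, membrane_label: str = DEFAULT_MEMBRANE_LABEL
) -> list[str]:
    """GFF3-style segment records (1-based inclusive coordinates)."""
    feature_names = {membrane_label: "helix", "i": "inside", "o": "outside"}
    lines = []
    for s, e, lab in segments(labels):
        feat = feature_names.get(lab, f"segment-{lab}")
        lines.append(
            "\t".join(
                [seq_id, "kbestpaths", feat, str(s + 1), str(e), ".", ".", ".", f"label={lab}"]
            )
        )
    return lines
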