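"""From k paths to one answer: grouping, consensus, confidence, dual topologies.

The k decoded paths are partitioned into *groups* of identical topology
(helix count + sidedness).  Each group is weighted by the summed conditional
probabilities P(path | sequence) of its members, with the forward total
probability as the denominator.  The heaviest group is summarised into a
single labelling by one of three consensus procedures:

``boundary-average``
    average each helix's start and end over the group members (round half
    away from zero on 1-based coordinates) — guaranteed to reproduce the
    group's topology, with a minimal right-shift repair if rounding makes
    averaged helices collide;
``position-vote``
    per position, the label with the largest summed conditional probability —
    may be inconsistent with the model, which is flagged, not repaired;
``helix-vote``
    per helix ordinal, the modal (start, length) pair — same flag.

A confidence report classifies the total conditional probability of the top
k paths into three bands (< 0.01, 0.01-0.5, 0.5-1) and records whether all
paths agree on the helix count; both are empirically strong predictors of a
trustworthy consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .kbest import KBestResult
from .model import NEG_INF, Hmm, ScoredPath, Sequence, forward_log_prob
from .topology import (
    DEFAULT_MEMBRANE_LABEL,
    MEMBRANE_START,
    Topology,
    labelling_of,
    topology_of,
)

PROBABILITY_BANDS = ("< 0.01", "0.01 - 0.5", "0.5 - 1")


@dataclass(frozen=True)
class GroupMember:
    path: ScoredPath
    labelling: str
    topology: Topology
    cond_prob: float


@dataclass
class TopologyGroup:
    """All decoded paths predicting one topology, with their summed
    conditional probability as the group weight."""

    topology_key: tuple[int, str]  # (helix_count, sidedness)
    members: list[GroupMember]
    weight: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Consensus:
    """A consensus labelling; ``consistent`` is True when the labelling can
    be produced by a positive-probability state path of the model (always
    True for the boundary-average method by construction)."""

    labels: str
    method: str
    consistent: bool


@dataclass
class ConfidenceReport:
    k: int
    total_conditional_prob: float
    band: str
    helix_counts_agree: bool
    group_table: pd.DataFrame
    groups: list[TopologyGroup]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def probability_band(total: float) -> str:
    if total < 0.01:
        return PROBABILITY_BANDS[0]
    if total < 0.5:
        return PROBABILITY_BANDS[1]
    return PROBABILITY_BANDS[2]


def group_paths(
    hmm: Hmm,
    seq: Sequence,
    result: KBestResult,
    membrane_label: str = DEFAULT_MEMBRANE_LABEL,
) -> list[TopologyGroup]:
    """Partition the decoded paths by (helix_count, sidedness), weight each
    group by its summed conditional probability, and sort by weight
    descending (ties by topology key)."""
    if not result.paths:
        raise ValueError("cannot group an empty decode result")
    log_z = forward_log_prob(hmm, seq)
    buckets: dict[tuple[int, str], list[GroupMember]] = {}
    for path in result.paths:
        lab = labelling_of(hmm, path)
        topo = topology_of(lab, membrane_label)
        key = (topo.helix_count, topo.sidedness)
        member = GroupMember(
            path=path,
            labelling=lab,
            topology=topo,
            cond_prob=float(np.exp(path.log_joint - log_z)),
        )
        buckets.setdefault(key, []).append(member)
    groups = [
        TopologyGroup(topology_key=key, members=members, weight=sum(m.cond_prob for m in members))
        for key, members in buckets.items()
    ]
    groups.sort(key=lambda g: (-g.weight, g.topology_key))
    return groups


def heaviest_group(groups: list[TopologyGroup]) -> TopologyGroup:
    """The maximum-weight group (ties already resolved by the sort order)."""
    if not groups:
        raise ValueError("no groups to choose from")
    return groups[0]


# ---------------------------------------------------------------------------
# consensus construction
# ---------------------------------------------------------------------------


def _member_segment_labels(group: TopologyGroup, membrane_label: str) -> list[str]:
    """Label of each of the helix_count+1 non-membrane segments, taken from
    the first member whose segment is non-empty; missing segments fall back
    to alternating with the previous side."""
    h = group.topology_key[0]
    labels: list[Optional[str]] = [None] * (h + 1)
    for member in group.members:
        hel = member.topology.helices
        bounds = [0] + [b for s, e in hel for b in (s, e)] + [len(member.labelling)]
        for t in range(h + 1):
            if labels[t] is None:
                s, e = bounds[2 * t], bounds[2 * t + 1]
                if e > s:
                    labels[t] = member.labelling[s]
        if all(lab is not None for lab in labels):
            break
    # fallback: alternate i/o from a known neighbour
    flip = {"i": "o", "o": "i"}
    for t in range(h + 1):
        if labels[t] is None:
            prev = labels[t - 1] if t else None
            labels[t] = flip.get(prev, prev or "i")
    return labels  # type: ignore[return-value]


def consensus_boundary_average(
    group: TopologyGroup, membrane_label: str = DEFAULT_MEMBRANE_LABEL
) -> Consensus:
    """Average helix start/end positions over the group members.

    Coordinates are averaged 1-based inclusive and rounded half away from
    zero.  If rounding makes consecutive helices collide (or a helix touch
    position 1 when the group does not start mid-helix), boundaries are
    shifted right by the minimal amount; the helix count and sidedness of
    the output always equal the group's topology key.
    """
    h, sidedness = group.topology_key
    if any(m.topology.helix_count != h for m in group.members):
        raise ValueError("group members disagree on helix count")
    n = len(group.members[0].labelling)
    if h == 0:
        return Consensus("".join([sidedness]) * n, "boundary-average", True)

    starts = [
        _round_half_away(sum(m.topology.helices[t][0] + 1 for m in group.members) / group.size)
        for t in range(h)
    ]
    ends = [
        _round_half_away(sum(m.topology.helices[t][1] for m in group.members) / group.size)
        for t in range(h)
    ]

    # forward repair: enforce ordering, a >=1 gap between helices, and a
    # leading side segment unless the group starts mid-helix
    prev_end = 0
    for t in range(h):
        min_start = 1 if (t == 0 and sidedness == MEMBRANE_START) else prev_end + 2
        starts[t] = max(starts[t], min_start)
        ends[t] = max(ends[t], starts[t])
        prev_end = ends[t]
    # backward repair: pull everything inside the sequence if needed
    limit = n
    for t in range(h - 1, -1, -1):
        ends[t] = min(ends[t], limit)
        starts[t] = min(starts[t], ends[t])
        limit = starts[t] - 2
    if starts[0] < 1 or (sidedness != MEMBRANE_START and starts[0] < 2):
        raise ValueError("averaged helices cannot be repaired within the sequence")

    sides = _member_segment_labels(group, membrane_label)
    out = [""] * n
    pos = 0
    for t in range(h):
        for p in range(pos, starts[t] - 1):
            out[p] = sides[t]
        for p in range(starts[t] - 1, ends[t]):
            out[p] = membrane_label
        pos = ends[t]
    for p in range(pos, n):
        out[p] = sides[h]
    return Consensus("".join(out), "boundary-average", True)


def labelling_feasible(hmm: Hmm, seq: Sequence, labels: str) -> bool:
    """True iff some positive-probability state path of the model produces
    this labelling for this sequence (constrained reachability sweep)."""
    if len(labels) != len(seq):
        raise ValueError("labelling length does not match sequence length")
    x = seq.encode(hmm)
    state_labels = np.asarray(hmm.labels)
    lt, le = hmm.log_trans, hmm.log_emit
    adj = lt[: hmm.m] > NEG_INF
    ok = (state_labels == labels[0]) & (lt[hmm.m] > NEG_INF) & (le[:, x[0]] > NEG_INF)
    for t in range(1, len(x)):
        ok = (state_labels == labels[t]) & (le[:, x[t]] > NEG_INF) & (ok @ adj)
        if not ok.any():
            return False
    if hmm.log_end is not None:
        ok = ok & (hmm.log_end > NEG_INF)
    return bool(ok.any())


def _members_of(
    hmm: Hmm, seq: Sequence, source: Union[TopologyGroup, KBestResult], membrane_label: str
) -> list[GroupMember]:
    if isinstance(source, TopologyGroup):
        return source.members
    log_z = forward_log_prob(hmm, seq)
    out = []
    for path in source.paths:
        lab = labelling_of(hmm, path)
        out.append(
            GroupMember(
                path=path,
                labelling=lab,
                topology=topology_of(lab, membrane_label),
                cond_prob=float(np.exp(path.log_joint - log_z)),
            )
        )
    return out


def consensus_position_vote(
    hmm: Hmm,
    seq: Sequence,
    source: Union[TopologyGroup, KBestResult],
    membrane_label: str = DEFAULT_MEMBRANE_LABEL,
) -> Consensus:
    """Per-position vote: at every position the label with the largest
    summed conditional probability wins (ties by label order).  The result
    may not correspond to any feasible state path; the ``consistent`` flag
    reports whether it does."""
    members = _members_of(hmm, seq, source, membrane_label)
    if not members:
        raise ValueError("nothing to vote over")
    n = len(members[0].labelling)
    out = []
    for t in range(n):
        tally: dict[str, float] = {}
        for m in members:
            tally[m.labelling[t]] = tally.get(m.labelling[t], 0.0) + m.cond_prob
        out.append(min(tally, key=lambda lab: (-tally[lab], lab)))
    labels = "".join(out)
    return Consensus(labels, "position-vote", labelling_feasible(hmm, seq, labels))


def consensus_helix_vote(
    hmm: Hmm,
    seq: Sequence,
    group: TopologyGroup,
    membrane_label: str = DEFAULT_MEMBRANE_LABEL,
) -> Consensus:
    """Per-helix vote on (start, length): the modal pair by summed
    conditional probability wins each helix ordinal (ties by the smaller
    pair).  Flagged, not repaired, when the result is infeasible."""
    h, sidedness = group.topology_key
    if any(m.topology.helix_count != h for m in group.members):
        raise ValueError("group members disagree on helix count")
    n = len(group.members[0].labelling)
    sides = _member_segment_labels(group, membrane_label)
    out = [""] * n
    pos_fill = sides[0] if sidedness != MEMBRANE_START else sides[0]
    chosen: list[tuple[int, int]] = []
    for t in range(h):
        tally: dict[tuple[int, int], float] = {}
        for m in group.members:
            s, e = m.topology.helices[t]
            key = (s, e - s)
            tally[key] = tally.get(key, 0.0) + m.cond_prob
        chosen.append(min(tally, key=lambda p: (-tally[p], p)))
    # paint sides then helices (later helices overwrite on collision)
    seg = 0
    pos = 0
    for t, (s, length) in enumerate(chosen):
        for p in range(pos, min(s, n)):
            out[p] = sides[t]
        for p in range(s, min(s + length, n)):
            out[p] = membrane_label
        pos = min(s + length, n)
    for p in range(pos, n):
        out[p] = sides[h]
    for p in range(n):  # collisions can leave gaps behind an overwritten helix
        if not out[p]:
            out[p] = membrane_label
    labels = "".join(out)
    return Consensus(labels, "helix-vote", labelling_feasible(hmm, seq, labels))


CONSENSUS_METHODS = {
    "boundary-average": "consensus_boundary_average",
    "position-vote": "consensus_position_vote",
    "helix-vote": "consensus_helix_vote",
}


def consensus(
    hmm: Hmm,
    seq: Sequence,
    group: TopologyGroup,
    method: str = "boundary-average",
    membrane_label: str = DEFAULT_MEMBRANE_LABEL,
) -> Consensus:
    """Dispatch to one of the three consensus procedures by name."""
    if method == "boundary-average":
        return consensus_boundary_average(group, membrane_label)
    if method == "position-vote":
        return consensus_position_vote(hmm, seq, group, membrane_label)
    if method == "helix-vote":
        return consensus_helix_vote(hmm, seq, group, membrane_label)
    raise ValueError(f"unknown consensus method {method!r}")


def confidence_report(
    hmm: Hmm,
    seq: Sequence,
    result: KBestResult,
    membrane_label: str = DEFAULT_MEMBRANE_LABEL,
) -> ConfidenceReport:
    """Summarise how much of the conditional probability space the top k
    paths occupy and whether they agree on the helix count."""
    if not result.paths:
        raise ValueError("cannot build a confidence report from an empty result")
    groups = group_paths(hmm, seq, result, membrane_label)
    total = sum(g.weight for g in groups)
    counts = {g.topology_key[0] for g in groups}
    table = pd.DataFrame(
        {
            "helix_count": [g.topology_key[0] for g in groups],
            "sidedness": [g.topology_key[1] for g in groups],
            "weight": [g.weight for g in groups],
            "size": [g.size for g in groups],
        }
    )
    return ConfidenceReport(
        k=result.k_requested,
        total_conditional_prob=total,
        band=probability_band(total),
        helix_counts_agree=len(counts) == 1,
        group_table=table,
        groups=groups,
    )


@dataclass
class TopGroups:
    """The g heaviest groups with their boundary-average consensus; used to
    surface dual-topology candidates (g=2 by default)."""

    pairs: list[tuple[TopologyGroup, Consensus]]
    requested: int

    @property
    def fewer_than_requested(self) -> bool:
        return len(self.pairs) < self.requested


def top_groups(
    groups: list[TopologyGroup],
    g: int = 2,
    membrane_label: str = DEFAULT_MEMBRANE_LABEL,
) -> TopGroups:
    if g < 1:
        raise ValueError("g must be >= 1")
    pairs = [
        (grp, consensus_boundary_average(grp, membrane_label)) for grp in groups[:g]
    ]
    return TopGroups(pairs=pairs, requested=g)
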