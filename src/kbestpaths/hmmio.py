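"""Plain-text I/O: the HMM definition format, FASTA sequences, and result
serialisation.

HMM definition format (version 1)
---------------------------------

A line-oriented key/value format.  Blank lines and lines starting with ``#``
are ignored.  Sections::

    ALPHABET <sym> <sym> ...          # one line, single-character symbols
    START <state-id>                  # the silent start state
    STATES                            # one "<id> <label>" row per state,
    <id> <label>                      #   in model order
    ...
    TRANSITIONS                       # sparse "<src> <dst> <prob>" triplets;
    <src> <dst> <prob>                #   omitted pairs are probability 0
    ...
    EMISSIONS                         # sparse "<state> <symbol> <prob>"
    <state> <symbol> <prob>
    ...
    ENDS                              # optional "<state> <weight>" terminal
    <state> <weight>                  #   weights

Probabilities are written with ``repr`` so that read(write(model)) restores
the file byte-identically.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np
from Bio import SeqIO

from .kbest import KBestResult
from .model import Hmm, Sequence, forward_log_prob

FORMAT_VERSION = "kbestpaths-hmm-v1"

_SECTIONS = {"STATES", "TRANSITIONS", "EMISSIONS", "ENDS"}


class HmmFormatError(ValueError):
    """A parse failure, carrying file/line diagnostics in the message."""


def _open(path_or_handle, mode: str):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode), True


def read_hmm(source: Union[str, Path, TextIO]) -> Hmm:
    """Parse an HMM definition file; raises :class:`HmmFormatError` with the
    offending line number on malformed input."""
    handle, close = _open(source, "r")
    name = getattr(handle, "name", "<hmm>")
    try:
        alphabet: list[str] = []
        start: str | None = None
        states: list[str] = []
        labels: dict[str, str] = {}
        transitions: dict[tuple[str, str], float] = {}
        emissions: dict[tuple[str, str], float] = {}
        ends: dict[str, float] = {}
        saw_ends = False
        section: str | None = None

        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            head = fields[0]

            def err(msg: str) -> HmmFormatError:
                return HmmFormatError(f"{name}:{lineno}: {msg}")

            if head == "ALPHABET":
                alphabet = fields[1:]
                if not alphabet:
                    raise err("ALPHABET line lists no symbols")
                if any(len(s) != 1 for s in alphabet):
                    raise err("alphabet symbols must be single characters")
                section = None
            elif head == "START":
                if len(fields) != 2:
                    raise err("START expects exactly one state id")
                start = fields[1]
                section = None
            elif head in _SECTIONS:
                section = head
                if head == "ENDS":
                    saw_ends = True
            elif section == "STATES":
                if len(fields) != 2:
                    raise err("state rows are '<id> <label>'")
                states.append(fields[0])
                labels[fields[0]] = fields[1]
            elif section == "TRANSITIONS":
                if len(fields) != 3:
                    raise err("transition rows are '<src> <dst> <prob>'")
                try:
                    transitions[(fields[0], fields[1])] = float(fields[2])
                except ValueError:
                    raise err(f"bad probability {fields[2]!r}") from None
            elif section == "EMISSIONS":
                if len(fields) != 3:
                    raise err("emission rows are '<state> <symbol> <prob>'")
                try:
                    emissions[(fields[0], fields[1])] = float(fields[2])
                except ValueError:
                    raise err(f"bad probability {fields[2]!r}") from None
            elif section == "ENDS":
                if len(fields) != 2:
                    raise err("end rows are '<state> <weight>'")
                try:
                    ends[fields[0]] = float(fields[1])
                except ValueError:
                    raise err(f"bad weight {fields[1]!r}") from None
            else:
                raise err(f"unexpected line {line!r} outside any section")

        if start is None:
            raise HmmFormatError(f"{name}: missing START line")
        if not states:
            raise HmmFormatError(f"{name}: missing STATES section")
        if not alphabet:
            raise HmmFormatError(f"{name}: missing ALPHABET line")
        return Hmm.from_tables(
            states=states,
            start_state=start,
            alphabet=alphabet,
            transitions=transitions,
            emissions=emissions,
            labels=labels,
            end_weights=ends if saw_ends else None,
        )
    finally:
        if close:
            handle.close()


def write_hmm(hmm: Hmm, dest: Union[str, Path, TextIO]) -> None:
    """Write the definition in canonical order (round-trips exactly)."""
    handle, close = _open(dest, "w")
    try:
        w = handle.write
        w(f"# {FORMAT_VERSION}\n")
        w("ALPHABET " + " ".join(hmm.alphabet) + "\n")
        w(f"START {hmm.start_state}\n")
        w("STATES\n")
        for s, lab in zip(hmm.states, hmm.labels):
            w(f"{s} {lab}\n")
        w("TRANSITIONS\n")
        with np.errstate(over="ignore"):
            trans = np.exp(hmm.log_trans)
            emit = np.exp(hmm.log_emit)
        names = list(hmm.states)
        for row in range(hmm.m + 1):
            src = hmm.start_state if row == hmm.m else names[row]
            for col in np.flatnonzero(trans[row] > 0.0):
                w(f"{src} {names[col]} {float(trans[row, col])!r}\n")
        w("EMISSIONS\n")
        for i, s in enumerate(names):
            for a in np.flatnonzero(emit[i] > 0.0):
                w(f"{s} {hmm.alphabet[a]} {float(emit[i, a])!r}\n")
        if hmm.log_end is not None:
            w("ENDS\n")
            with np.errstate(over="ignore"):
                end = np.exp(hmm.log_end)
            for i, s in enumerate(names):
                if end[i] > 0.0:
                    w(f"{s} {float(end[i])!r}\n")
    finally:
        if close:
            handle.close()


def hmm_to_text(hmm: Hmm) -> str:
    buf = io.StringIO()
    write_hmm(hmm, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(source: Union[str, Path, TextIO]) -> list[Sequence]:
    """Read sequences from FASTA; the id is the first whitespace-delimited
    token of the header, the rest of the description is ignored."""
    handle, close = _open(source, "r")
    try:
        return [Sequence(id=rec.id, symbols=str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()


def write_fasta(seqs: Iterable[Sequence], dest: Union[str, Path, TextIO]) -> None:
    handle, close = _open(dest, "w")
    try:
        for s in seqs:
            handle.write(f">{s.id}\n")
            for i in range(0, len(s.symbols), 60):
                handle.write(s.symbols[i : i + 60] + "\n")
    finally:
        if close:
            handle.close()


def read_labellings(source: Union[str, Path, TextIO]) -> dict[str, str]:
    """Reference labellings in FASTA dialect: one record per sequence id,
    the 'sequence' being the label string."""
    return {s.id: s.symbols for s in read_fasta(source)}


# ---------------------------------------------------------------------------
# result serialisation
# ---------------------------------------------------------------------------


def result_to_tsv(hmm: Hmm, seq: Sequence, result: KBestResult) -> str:
    """TSV of the decoded paths: rank, log_joint, conditional_prob, state
    string (comma-joined ids), labelling.  Formatted with ``repr`` so that
    both engines produce byte-identical files."""
    from .topology import labelling_of

    log_z = forward_log_prob(hmm, seq)
    lines = ["rank\tlog_joint\tconditional_prob\tstates\tlabelling"]
    for p in result.paths:
        cond = float(np.exp(p.log_joint - log_z))
        lines.append(
            f"{p.rank}\t{p.log_joint!r}\t{cond!r}\t{','.join(p.states)}\t{labelling_of(hmm, p)}"
        )
    return "\n".join(lines) + "\n"


def stats_to_text(result: KBestResult) -> str:
    """Structured-text block of the decoder statistics."""
    s = result.stats
    return (
        f"k_requested\t{result.k_requested}\n"
        f"paths_returned\t{len(result.paths)}\n"
        f"peak_path_nodes\t{s.peak_path_nodes}\n"
        f"peak_state_nodes\t{s.peak_state_nodes}\n"
        f"naive_cells\t{s.naive_cells}\n"
        f"merges_performed\t{s.merges_performed}\n"
        f"prunes_performed\t{s.prunes_performed}\n"
    )
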