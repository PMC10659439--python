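"""Ribosome decision graphs.

A ribosome decision graph (RDG) represents the translation of one mRNA as
a directed acyclic graph of scanning and elongation states. Edges are the
moves of a single small-subunit-containing complex; nodes with two
outgoing edges are *branching points* — places where the outcome is
stochastic: initiate vs scan through at a leaky start, read through vs
terminate at a readthrough-permissive stop, shift vs stay in frame at a
frameshift site. Stop codons are otherwise deterministic ends of
translons.

A *translon* is the region translated by one elongating ribosome from its
initiation codon through termination; it may span several frames (via
shift sites) or extend through readthrough stops, so one annotated start
can give rise to several translons — one per combination of elongation
decisions.

Termination of a short, re-initiation-competent translon returns the small
subunit to the scanning state strictly 3' of the stop; whether it actually
re-initiates is decided at the next downstream start it reaches after
covering the recharge distance, so that node is shared with the primary
scanning route. Termination of long translons releases the ribosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from .errors import AnnotationError, PolicyError, UnsupportedShiftError
from .notation import BranchAnnotation, ShiftSite, validate_annotation
from .transcript import STOP_CODONS, Transcript

# --------------------------------------------------------------------------
# shift classification


@dataclass(frozen=True)
class ShiftClass:
    offset: int
    label: str


def classify_shift(i: int, s: int) -> ShiftClass:
    """Classify a shift branch point by the signed offset ``s - i``.

    The offset is the direct coordinate difference between the first codon
    of the shifted frame (s) and the last codon of the incoming frame (i):
    +1 is +1 frameshifting, -1 is -1 frameshifting, and offsets above 3
    are translational bypassing (T4 gene 60 style, offset 50). Backward
    jumps of 4 nt or more are not a frameshift and are rejected.
    """
    offset = s - i
    if offset == 0:
        raise AnnotationError("shift with s == i is not a branch point")
    if offset <= -4:
        raise UnsupportedShiftError(
            f"backward jump of {offset} nt is not interpretable as frameshifting"
        )
    if offset > 3:
        label = f"bypass({offset})"
    else:
        label = f"{offset:+d} frameshifting"
    return ShiftClass(offset, label)


# --------------------------------------------------------------------------
# translons


@dataclass(frozen=True)
class Segment:
    """A contiguous nucleotide interval decoded in one frame."""

    begin: int
    end: int  # inclusive
    frame: int

    def __post_init__(self):
        if (self.end - self.begin + 1) % 3:
            raise ValueError("segment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return (self.end - self.begin + 1) // 3

    def codon_starts(self) -> range:
        return range(self.begin, self.end, 3)


@dataclass(frozen=True)
class ReadthroughEvent:
    kind = "readthrough"
    pos: int

    def token(self):
        return ("rt", self.pos)


@dataclass(frozen=True)
class ShiftEvent:
    kind = "shift"
    take_off: int
    landing: int

    def token(self):
        return ("shift", self.take_off, self.landing)


Event = Union[ReadthroughEvent, ShiftEvent]


@dataclass(frozen=True)
class Translon:
    """One translated region: initiation through termination.

    ``end_pos`` is the last nucleotide of the terminating stop codon, or
    the last complete codon before the 3' end for unbounded translons
    (``stop_terminated`` False). ``events`` lists the non-deterministic
    elongation events this translon consumed, in traversal order.
    """

    id: str
    start_pos: int
    end_pos: int
    segments: tuple[Segment, ...]
    events: tuple[Event, ...] = ()
    stop_terminated: bool = True
    reinit_competent: bool = False

    @property
    def n_codons(self) -> int:
        return sum(seg.n_codons for seg in self.segments)

    @property
    def unbounded(self) -> bool:
        return not self.stop_terminated

    def codon_starts(self) -> list[int]:
        """First-nucleotide positions of the codons in traversal order."""
        out: list[int] = []
        for seg in self.segments:
            out.extend(seg.codon_starts())
        return out

    def span(self) -> tuple[int, int]:
        return (
            min(s.begin for s in self.segments),
            max(s.end for s in self.segments),
        )


@dataclass(frozen=True)
class _Outcome:
    """One elongation outcome from a start: the decisions taken and the
    resulting translon geometry (id assigned later)."""

    start: int
    decisions: tuple[tuple, ...]  # tokens of consumed/declined events in order
    segments: tuple[Segment, ...]
    events: tuple[Event, ...]
    end_pos: int
    stop_terminated: bool


def _elongation_outcomes(
    transcript: Transcript, start: int, annotation: BranchAnnotation
) -> list[_Outcome]:
    """Enumerate every elongation outcome from ``start``.

    The walker advances codon by codon; an in-frame stop listed in secs
    branches (terminate / read through), a shift take-off reached in frame
    branches (stay / shift). Events apply only when the ribosome arrives
    exactly at the annotated codon position, i.e. in the annotated frame.
    """
    seq = transcript.seq
    secs = set(annotation.secs)
    shifts = {sh.take_off: sh for sh in annotation.shifts}
    outcomes: list[_Outcome] = []

    def walk(pos, seg_begin, done_segments, events, decisions, consumed):
        c = pos
        while True:
            if c + 2 > len(seq):
                # ran off the 3' end: close at the last complete codon
                end = c - 1
                segs = tuple(done_segments) + (
                    (Segment(seg_begin, end, (seg_begin - 1) % 3),)
                    if end >= seg_begin
                    else ()
                )
                outcomes.append(
                    _Outcome(start, tuple(decisions), segs, tuple(events), end, False)
                )
                return
            codon = seq[c - 1 : c + 2]
            if codon in STOP_CODONS:
                if c in secs and ("rt", c) not in consumed:
                    # branch: terminate here ...
                    segs = tuple(done_segments) + (
                        Segment(seg_begin, c + 2, (seg_begin - 1) % 3),
                    )
                    outcomes.append(
                        _Outcome(
                            start,
                            tuple(decisions) + (("term_at", c),),
                            segs,
                            tuple(events),
                            c + 2,
                            True,
                        )
                    )
                    # ... or read through (stop codon closes the segment)
                    walk(
                        c + 3,
                        c + 3,
                        list(done_segments) + [Segment(seg_begin, c + 2, (seg_begin - 1) % 3)],
                        events + [ReadthroughEvent(c)],
                        decisions + [("rt", c)],
                        consumed | {("rt", c)},
                    )
                    return
                segs = tuple(done_segments) + (
                    Segment(seg_begin, c + 2, (seg_begin - 1) % 3),
                )
                outcomes.append(
                    _Outcome(
                        start,
                        tuple(decisions) + (("term_at", c),),
                        segs,
                        tuple(events),
                        c + 2,
                        True,
                    )
                )
                return
            if c in shifts and ("shift", c) not in consumed:
                sh = shifts[c]
                # the codon at the take-off is decoded in the incoming frame
                seg_incoming = Segment(seg_begin, c + 2, (seg_begin - 1) % 3)
                # branch 1: stay in frame
                walk(
                    c + 3,
                    seg_begin,
                    list(done_segments),
                    list(events),
                    decisions + [("stay", c)],
                    consumed | {("shift", c)},
                )
                # branch 2: shift to the landing codon
                walk(
                    sh.landing,
                    sh.landing,
                    list(done_segments) + [seg_incoming],
                    list(events) + [ShiftEvent(c, sh.landing)],
                    decisions + [("shift", c, sh.landing)],
                    consumed | {("shift", c)},
                )
                return
            c += 3

    walk(start, start, [], [], [], frozenset())
    return outcomes


def derive_translon(
    transcript: Transcript,
    start: int,
    annotation: BranchAnnotation,
    *,
    _check: bool = True,
) -> Translon:
    """Derive the maximal translon from ``start``: the elongation outcome
    that consumes every readthrough and shift event it encounters."""
    if _check:
        if start not in annotation.starts:
            raise AnnotationError(f"position {start} is not an annotated start")
        validate_annotation(transcript, annotation)
    best = None
    for out in _elongation_outcomes(transcript, start, annotation):
        key = (len(out.events), out.end_pos)
        if best is None or key > (len(best.events), best.end_pos):
            best = out
    return _outcome_to_translon(best, annotation, tid="T?")


def _outcome_to_translon(
    out: _Outcome, annotation: BranchAnnotation, tid: str
) -> Translon:
    n_codons = sum(seg.n_codons for seg in out.segments)
    competent = out.stop_terminated and n_codons <= annotation.reinit_max_codons
    return Translon(
        id=tid,
        start_pos=out.start,
        end_pos=out.end_pos,
        segments=out.segments,
        events=out.events,
        stop_terminated=out.stop_terminated,
        reinit_competent=competent,
    )


# --------------------------------------------------------------------------
# graph construction

CAP = ("cap",)
END3 = ("end3",)  # 3' runoff of a scanning subunit (or unbounded elongation)
DISSOC = ("dissoc",)  # dissociation after termination

#: outgoing-edge kinds considered the "event" choice at a branch node; the
#: probability value assigned to a branch is the probability of this edge.
EVENT_EDGE = {"start": "initiate", "sec": "readthrough", "shift": "shift"}
PASS_EDGE = {"start": "scan_through", "sec": "terminate", "shift": "elongate"}


class RDG:
    """A ribosome decision graph over one transcript.

    The graph is a :class:`networkx.DiGraph`; node keys are tuples whose
    first element is the node kind (``cap``, ``start``, ``sec``,
    ``shift``, ``elong``, ``term``, ``end3``, ``dissoc``). ``translons``
    maps T-ids to :class:`Translon` objects; the edge that completes a
    translon carries its id in the ``translon`` attribute.
    """

    def __init__(
        self,
        transcript: Transcript,
        annotation: BranchAnnotation,
        graph: nx.DiGraph,
        translons: dict[str, Translon],
    ):
        self.transcript = transcript
        self.annotation = annotation
        self.graph = graph
        self.translons = translons

    # -- structure queries ------------------------------------------------

    def branch_nodes(self) -> list[tuple]:
        """Nodes with two or more outgoing edges, in deterministic order
        (position, then kind)."""
        nodes = [n for n in self.graph.nodes if self.graph.out_degree(n) >= 2]
        return sorted(nodes, key=_node_sort_key)

    def branch_points(self) -> list[tuple[str, int]]:
        """Branch events deduplicated by (kind, position)."""
        seen = []
        for n in self.branch_nodes():
            bp = (n[0], n[1])
            if bp not in seen:
                seen.append(bp)
        return seen

    def start_nodes(self) -> list[tuple]:
        return sorted(
            (n for n in self.graph.nodes if n[0] == "start"), key=lambda n: n[1]
        )

    def termination_nodes(self) -> list[tuple]:
        return sorted(
            (n for n in self.graph.nodes if n[0] == "term"), key=_node_sort_key
        )

    def node_label(self, node: tuple) -> str:
        return _node_label(node)

    def resolve_node(self, ref) -> tuple:
        """Accept a node key, a ``kind@pos`` label, or a bare start position."""
        if isinstance(ref, tuple) and ref in self.graph:
            return ref
        if isinstance(ref, int):
            ref = f"start@{ref}"
        for n in self.graph.nodes:
            if _node_label(n) == ref:
                return n
        raise KeyError(f"no node {ref!r} in graph")

    # -- probabilities ----------------------------------------------------

    def set_branch_probabilities(self, p: Mapping) -> None:
        """Assign the probability of the event edge at each branch node.

        Keys may be node tuples, ``kind@pos`` labels, or bare start
        positions; values must lie in [0, 1]. The complementary pass edge
        receives 1 - p.
        """
        for ref, value in p.items():
            node = self.resolve_node(ref)
            if self.graph.out_degree(node) < 2:
                raise PolicyError(f"{_node_label(node)} is not a branch node")
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"probability {value} outside [0, 1]")
            ev, ps = EVENT_EDGE[node[0]], PASS_EDGE[node[0]]
            for _, v, data in self.graph.out_edges(node, data=True):
                if data["kind"] == ev:
                    data["p"] = float(value)
                elif data["kind"] == ps:
                    data["p"] = 1.0 - float(value)

    def branch_probabilities(self) -> dict[tuple, float]:
        out = {}
        for node in self.branch_nodes():
            for _, _, data in self.graph.out_edges(node, data=True):
                if data["kind"] == EVENT_EDGE[node[0]] and "p" in data:
                    out[node] = data["p"]
        return out

    def probabilities_complete(self) -> bool:
        return all(n in self.branch_probabilities() for n in self.branch_nodes())

    # -- misc -------------------------------------------------------------

    def translon_by_role(self, start_pos: int, n_events: int = 0) -> Translon:
        """Look up a translon by its start position (and event count)."""
        for t in self.translons.values():
            if t.start_pos == start_pos and len(t.events) == n_events:
                return t
        raise KeyError(f"no translon starting at {start_pos} with {n_events} events")

    def completing_edge(self, translon_id: str) -> tuple:
        for u, v, data in self.graph.edges(data=True):
            if data.get("translon") == translon_id:
                return (u, v)
        raise KeyError(translon_id)


def _node_sort_key(n: tuple):
    pos = n[1] if len(n) > 1 and isinstance(n[1], int) else -1
    return (pos, n[0], tuple(map(str, n)))


def _node_label(n: tuple) -> str:
    kind = n[0]
    if kind in ("cap", "end3", "dissoc"):
        return kind
    if kind == "start":
        return f"start@{n[1]}"
    if kind == "sec":
        return f"sec@{n[1]}"
    if kind == "shift":
        return f"shift@{n[1]}>{n[2]}"
    if kind == "term":
        return f"term@{n[1]}"
    if kind == "runoff":
        return f"runoff@{n[1]}"
    if kind == "elong":
        return f"elong@{n[1]}-{n[2]}"
    return str(n)


def build_rdg(
    transcript: Transcript,
    annotation: BranchAnnotation,
    *,
    validate: bool = True,
) -> RDG:
    """Construct the ribosome decision graph for one annotated transcript.

    The scanner enters at the 5' cap, decides at each annotated start
    (unless marked deterministic), and runs off the 3' end if it never
    initiates — the unproductive path always exists. Initiation spawns the
    elongation outcomes of :func:`derive_translon`'s event tree; short
    stop-terminated translons return the subunit to scanning 3' of the
    stop, constrained by the annotation's recharge distance.
    """
    if validate:
        validate_annotation(transcript, annotation)

    g = nx.DiGraph()
    g.add_node(CAP, kind="cap")
    starts = list(annotation.starts)
    det = annotation.deterministic_starts

    # translon registry: (start, decisions) -> outcome; ids assigned at the end
    outcome_key: dict[tuple, _Outcome] = {}

    def scan_target(from_pos: int, min_init: int) -> tuple:
        """First start node reachable by a scanner located at ``from_pos``
        that becomes initiation-competent at ``min_init``."""
        for x in starts:
            if x >= from_pos and x >= min_init:
                return ("start", x)
        return END3

    pending: list[tuple] = []
    visited_starts: set[int] = set()

    def add_edge(u, v, kind, **attrs):
        for n in (u, v):
            if n not in g:
                g.add_node(n, kind=n[0])
        g.add_edge(u, v, kind=kind, **attrs)

    def expand_start(x: int):
        if x in visited_starts:
            return
        visited_starts.add(x)
        node = ("start", x)
        # elongation outcomes from this start
        for out in _elongation_outcomes(transcript, x, annotation):
            _wire_outcome(node, out)
        # leaky starts also allow scanning through
        if x not in det:
            tgt = scan_target(x + 1, 0)
            add_edge(node, tgt, "scan_through")
            if tgt[0] == "start":
                pending.append(tgt[1])

    secs_set = set(annotation.secs)

    def _wire_outcome(start_node: tuple, out: _Outcome):
        """Create the decision chain for one elongation outcome; shared
        prefixes between outcomes of the same start merge on node keys."""
        x = out.start
        prev = start_node
        prev_kind = "initiate"
        history: tuple = ()
        for dec in out.decisions:
            if dec[0] == "term_at":
                # termination at a readthrough-permissive stop is the
                # declining choice at the shared sec branch node
                if dec[1] in secs_set:
                    node = ("sec", dec[1], x, history)
                    add_edge(prev, node, prev_kind)
                    prev, prev_kind = node, "terminate"
                break
            if dec[0] == "rt":
                node = ("sec", dec[1], x, history)
                add_edge(prev, node, prev_kind)
                prev, prev_kind = node, "readthrough"
            elif dec[0] in ("stay", "shift"):
                sh = next(s for s in annotation.shifts if s.take_off == dec[1])
                node = ("shift", sh.take_off, sh.landing, x, history)
                add_edge(prev, node, prev_kind)
                prev_kind = "shift" if dec[0] == "shift" else "elongate"
                prev = node
            history = history + (dec,)
        key = (out.start, out.decisions)
        outcome_key[key] = out
        if out.stop_terminated:
            n_codons = sum(s.n_codons for s in out.segments)
            competent = n_codons <= annotation.reinit_max_codons
            term = ("term", out.end_pos, x, out.decisions)
            add_edge(prev, term, prev_kind, translon_key=key)
            g.nodes[term]["reinit_competent"] = competent
            if competent:
                min_init = out.end_pos + max(annotation.recharge_distance, 1)
                tgt = scan_target(out.end_pos + 1, min_init)
                add_edge(term, tgt, "terminate_reinitiate")
                if tgt[0] == "start":
                    pending.append(tgt[1])
            else:
                add_edge(term, DISSOC, "terminate_dissociate")
        else:
            # unbounded elongation: a distinct runoff state per outcome so
            # sibling choices never collapse onto one edge into the sink
            runoff = ("runoff", out.end_pos, x, out.decisions)
            add_edge(prev, runoff, prev_kind, translon_key=key, runoff=True)
            add_edge(runoff, END3, "elongate")

    first = scan_target(1, 0)
    add_edge(CAP, first, "scan")
    if first[0] == "start":
        pending.append(first[1])
    while pending:
        expand_start(pending.pop())

    # assign translon ids ordered by start position, then span/events
    outs = sorted(
        outcome_key.items(),
        key=lambda kv: (kv[1].start, kv[1].end_pos, len(kv[1].events), kv[0]),
    )
    translons: dict[str, Translon] = {}
    key_to_id: dict[tuple, str] = {}
    for i, (key, out) in enumerate(outs, 1):
        tid = f"T{i}"
        translons[tid] = _outcome_to_translon(out, annotation, tid)
        key_to_id[key] = tid
    for u, v, data in g.edges(data=True):
        if "translon_key" in data:
            data["translon"] = key_to_id[data.pop("translon_key")]

    rdg = RDG(transcript, annotation, g, translons)
    assert nx.is_directed_acyclic_graph(g), "RDG construction produced a cycle"
    return rdg


# --------------------------------------------------------------------------
# re-initiation eligibility


def reinitiation_eligible_starts(
    rdg: RDG,
    termination,
    recharge_distance: Optional[int] = None,
) -> list[tuple]:
    """Downstream start nodes a post-terminating subunit can reach.

    ``termination`` is a termination node (or its label) of a
    re-initiation-competent translon; eligibility requires scanning at
    least ``recharge_distance`` nucleotides past the stop before the
    subunit can rebind the ternary complex and initiate. Defaults to the
    annotation's recharge distance.
    """
    node = rdg.resolve_node(termination)
    if node[0] != "term":
        raise PolicyError(f"{_node_label(node)} is not a termination node")
    if not rdg.graph.nodes[node].get("reinit_competent", False):
        raise PolicyError(
            f"{_node_label(node)} terminates a translon that is not "
            "re-initiation competent"
        )
    if recharge_distance is None:
        recharge_distance = rdg.annotation.recharge_distance
    end = node[1]
    return [
        ("start", x)
        for x in rdg.annotation.starts
        if x > end and x - end >= recharge_distance and ("start", x) in rdg.graph
    ]
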