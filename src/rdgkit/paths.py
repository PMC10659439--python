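"""Ribosome paths through a decision graph.

A RiboPath is one complete passage of a small-subunit-containing complex
from cap loading to its final departure from the mRNA (dissociation after
termination, or 3' runoff of a scanning subunit). Enumeration is
deterministic: at every branch node the declining choice (scan through,
terminate, stay in frame) is explored before the event choice, so path
ids are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Optional

import networkx as nx
from Bio.Data import CodonTable

from .errors import PathExplosionError, UnknownTranslonError
from .graph import CAP, RDG, _node_label
from .transcript import STOP_CODONS

DEFAULT_PATH_LIMIT = 10_000

#: deterministic out-edge order: declining choice before event choice
_EDGE_ORDER = {
    "scan": 0,
    "scan_through": 0,
    "terminate": 0,
    "elongate": 0,
    "terminate_dissociate": 0,
    "terminate_reinitiate": 0,
    "initiate": 1,
    "readthrough": 1,
    "shift": 1,
}


@dataclass(frozen=True)
class RiboPath:
    """One source-to-sink path with its ordered translon list."""

    id: int
    events: tuple[tuple[str, str], ...]  # (branch node label, chosen edge kind)
    translons: tuple[str, ...]
    productive: bool
    probability: Optional[float] = None
    nodes: tuple = ()


def _ordered_out_edges(graph: nx.DiGraph, node):
    edges = list(graph.out_edges(node, data=True))
    edges.sort(key=lambda e: (_EDGE_ORDER.get(e[2]["kind"], 0), str(e[1])))
    return edges


def count_paths(rdg: RDG) -> int:
    """Number of source-to-sink paths, by topological-order dynamic
    programming (linear in edges; never materializes paths)."""
    g = rdg.graph
    n_to_sink: dict = {}
    for node in reversed(list(nx.topological_sort(g))):
        succ = list(g.successors(node))
        n_to_sink[node] = 1 if not succ else sum(n_to_sink[v] for v in succ)
    return n_to_sink[CAP]


def enumerate_paths(rdg: RDG, limit: int = DEFAULT_PATH_LIMIT) -> list[RiboPath]:
    """All RiboPaths in deterministic order.

    Raises :class:`PathExplosionError` (naming the count) when the graph
    holds more than ``limit`` paths.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    n = count_paths(rdg)
    if n > limit:
        raise PathExplosionError(n, limit)
    g = rdg.graph
    paths: list[RiboPath] = []

    def dfs(node, events, translons, prob, nodes):
        out = _ordered_out_edges(g, node)
        if not out:
            paths.append(
                RiboPath(
                    id=len(paths),
                    events=tuple(events),
                    translons=tuple(translons),
                    productive=bool(translons),
                    probability=prob,
                    nodes=tuple(nodes),
                )
            )
            return
        branching = len(out) >= 2
        for _, v, data in out:
            ev = events + [(_node_label(node), data["kind"])] if branching else events
            tr = translons + [data["translon"]] if "translon" in data else translons
            p = None
            if prob is not None:
                if branching:
                    p = prob * data["p"] if "p" in data else None
                else:
                    p = prob
            dfs(v, ev, tr, p, nodes + [v])

    dfs(CAP, [], [], 1.0, [CAP])
    return paths


def unproductive_paths(paths: list[RiboPath]) -> list[RiboPath]:
    return [p for p in paths if not p.productive]


def mutually_exclusive(rdg: RDG, a: str, b: str) -> bool:
    """True iff no single ribosome path contains both translons.

    Uses reachability between the translon-completing edges rather than
    path enumeration, so it is safe on combinatorially large graphs. A
    translon always co-occurs with itself.
    """
    for tid in (a, b):
        if tid not in rdg.translons:
            raise UnknownTranslonError(tid)
    if a == b:
        return False
    ua, va = rdg.completing_edge(a)
    ub, vb = rdg.completing_edge(b)
    g = rdg.graph
    return not (nx.has_path(g, va, ub) or nx.has_path(g, vb, ua))


# ---------------------------------------------------------------------------
# proteoforms


@dataclass(frozen=True)
class ProteoformRecord:
    translon_id: str
    sequence: str
    description: str


def proteoform_sequences(
    rdg: RDG,
    table: str = "Standard",
    readthrough_symbol: Optional[str] = None,
) -> list[ProteoformRecord]:
    """Amino-acid sequence of every translon (one record each).

    Readthrough stops are decoded as the annotation's per-site symbol
    ('U' for selenocysteine sites, 'X' otherwise) unless
    ``readthrough_symbol`` overrides it; shift translons concatenate the
    translations of their segments into the trans-frame fusion. The
    terminating stop is not included; unbounded translons are translated
    to the 3' end and flagged in the description.
    """
    code = CodonTable.unambiguous_rna_by_name[table].forward_table
    seq = rdg.transcript.seq
    records = []
    for tid in sorted(rdg.translons, key=lambda t: int(t[1:])):
        t = rdg.translons[tid]
        rt_positions = {e.pos for e in t.events if e.kind == "readthrough"}
        codon_positions = t.codon_starts()
        aa = []
        for idx, p in enumerate(codon_positions):
            codon = seq[p - 1 : p + 2]
            if codon in STOP_CODONS:
                if p in rt_positions:
                    aa.append(
                        readthrough_symbol
                        if readthrough_symbol is not None
                        else rdg.annotation.sec_symbol(p)
                    )
                elif t.stop_terminated and idx == len(codon_positions) - 1:
                    pass  # terminating stop: not part of the product
                else:  # pragma: no cover - excluded by translon invariants
                    raise AssertionError(
                        f"unexpected in-frame stop at {p} inside {tid}"
                    )
            else:
                aa.append(code[codon])
        desc_parts = [f"start={t.start_pos}"]
        if t.events:
            desc_parts.append(
                "events=" + ",".join(_event_str(e) for e in t.events)
            )
        if t.unbounded:
            desc_parts.append("unbounded=3p")
        records.append(ProteoformRecord(tid, "".join(aa), " ".join(desc_parts)))
    return records


def _event_str(e) -> str:
    if e.kind == "readthrough":
        return f"readthrough@{e.pos}"
    return f"shift@{e.take_off}>{e.landing}"
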