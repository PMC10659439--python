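"""Serialization of decision graphs and their derived tables.

Formats: JSON (full round-trippable dump, schema-versioned), DOT (for
graphviz rendering; branch nodes are diamonds), GFF3 (1-based inclusive)
and BED12 (0-based half-open, multi-segment translons as blocks), plus a
proteoform FASTA writer and a RiboPath TSV table.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional

import networkx as nx

from .graph import (
    RDG,
    ReadthroughEvent,
    Segment,
    ShiftEvent,
    Translon,
    _node_label,
)
from .notation import BranchAnnotation, ShiftSite, format_branch_notation
from .paths import ProteoformRecord, RiboPath
from .transcript import Transcript

JSON_SCHEMA_VERSION = 1


def _node_key_str(node: tuple) -> str:
    return "|".join(map(str, node))


def export_rdg_json(rdg: RDG) -> dict:
    """Full JSON document: transcript, annotation echo, nodes, edges,
    translons. Importable by :func:`import_rdg_json`."""
    nodes = []
    for n, data in rdg.graph.nodes(data=True):
        nodes.append(
            {
                "key": _node_key_str(n),
                "kind": data.get("kind", n[0]),
                "label": _node_label(n),
                **(
                    {"reinit_competent": data["reinit_competent"]}
                    if "reinit_competent" in data
                    else {}
                ),
            }
        )
    edges = []
    for u, v, data in rdg.graph.edges(data=True):
        e = {
            "from": _node_key_str(u),
            "to": _node_key_str(v),
            "kind": data["kind"],
        }
        if "p" in data:
            e["probability"] = data["p"]
        if "translon" in data:
            e["translon"] = data["translon"]
        edges.append(e)
    translons = []
    for tid in sorted(rdg.translons, key=lambda t: int(t[1:])):
        t = rdg.translons[tid]
        translons.append(
            {
                "id": tid,
                "start": t.start_pos,
                "end": t.end_pos,
                "segments": [[s.begin, s.end, s.frame] for s in t.segments],
                "events": [
                    {"kind": "readthrough", "pos": e.pos}
                    if e.kind == "readthrough"
                    else {"kind": "shift", "i": e.take_off, "s": e.landing}
                    for e in t.events
                ],
                "stop_terminated": t.stop_terminated,
                "reinit_competent": t.reinit_competent,
            }
        )
    a = rdg.annotation
    return {
        "schema_version": JSON_SCHEMA_VERSION,
        "transcript": {
            "id": rdg.transcript.id,
            "seq": rdg.transcript.seq,
            "cds_start": rdg.transcript.cds_start,
        },
        "annotation": {
            "notation": format_branch_notation(a),
            "reinit_max_codons": a.reinit_max_codons,
            "recharge_distance": a.recharge_distance,
            "start_set": sorted(a.start_set),
            "deterministic_starts": sorted(a.deterministic_starts),
            "sec_aa": {str(k): v for k, v in a.sec_aa},
        },
        "nodes": nodes,
        "edges": edges,
        "translons": translons,
    }


def import_rdg_json(doc: dict) -> RDG:
    """Rebuild an RDG (structure-preserving) from a JSON export."""
    if doc.get("schema_version") != JSON_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {doc.get('schema_version')}")
    t = Transcript(
        doc["transcript"]["id"],
        doc["transcript"]["seq"],
        cds_start=doc["transcript"]["cds_start"],
    )
    from .notation import parse_branch_notation

    ann_doc = doc["annotation"]
    policy = dict(
        reinit_max_codons=ann_doc["reinit_max_codons"],
        recharge_distance=ann_doc["recharge_distance"],
        start_set=frozenset(ann_doc["start_set"]),
        deterministic_starts=frozenset(ann_doc["deterministic_starts"]),
        sec_aa={int(k): v for k, v in ann_doc["sec_aa"].items()},
    )
    if ann_doc["notation"]:
        annotation = parse_branch_notation(ann_doc["notation"], t, **policy)
    else:  # annotation with no branch points has an empty notation
        annotation = BranchAnnotation(**policy)
    g = nx.DiGraph()
    key_of = {}
    for nd in doc["nodes"]:
        key = tuple(
            int(p) if p.lstrip("-").isdigit() else p
            for p in nd["key"].split("|")
        )
        key_of[nd["key"]] = key
        attrs = {"kind": nd["kind"]}
        if "reinit_competent" in nd:
            attrs["reinit_competent"] = nd["reinit_competent"]
        g.add_node(key, **attrs)
    for ed in doc["edges"]:
        attrs = {"kind": ed["kind"]}
        if "probability" in ed:
            attrs["p"] = ed["probability"]
        if "translon" in ed:
            attrs["translon"] = ed["translon"]
        g.add_edge(key_of[ed["from"]], key_of[ed["to"]], **attrs)
    translons = {}
    for td in doc["translons"]:
        events = tuple(
            ReadthroughEvent(e["pos"])
            if e["kind"] == "readthrough"
            else ShiftEvent(e["i"], e["s"])
            for e in td["events"]
        )
        translons[td["id"]] = Translon(
            id=td["id"],
            start_pos=td["start"],
            end_pos=td["end"],
            segments=tuple(Segment(*s) for s in td["segments"]),
            events=events,
            stop_terminated=td["stop_terminated"],
            reinit_competent=td["reinit_competent"],
        )
    return RDG(t, annotation, g, translons)


# ---------------------------------------------------------------------------
# DOT


def export_rdg_dot(rdg: RDG, quant=None) -> str:
    """Graphviz DOT text. Branch nodes render as diamonds, termination
    nodes as circles; edge labels carry the event kind and probability.
    ``quant`` (a QuantResult) adds relative synthesis percentages to the
    translon-completing edges, mirroring a heatmap-annotated graph."""
    lines = [
        "digraph RDG {",
        "  rankdir=LR;",
        f'  label="{rdg.transcript.id}";',
    ]
    branch = set(rdg.branch_nodes())
    for n in nx.topological_sort(rdg.graph):
        label = _node_label(n)
        if n in branch:
            shape = "diamond"
        elif n[0] in ("cap", "end3", "dissoc"):
            shape = "plaintext"
        elif n[0] == "term":
            shape = "circle"
        else:
            shape = "box"
        lines.append(f'  "{_node_key_str(n)}" [label="{label}", shape={shape}];')
    for u, v, data in rdg.graph.edges(data=True):
        label = data["kind"]
        if "p" in data:
            label += f"\\np={data['p']:.3g}"
        if "translon" in data:
            label += f"\\n{data['translon']}"
            if quant is not None and data["translon"] in quant.rel_synthesis:
                label += f" ({quant.rel_synthesis[data['translon']]:.1f}%)"
        lines.append(
            f'  "{_node_key_str(u)}" -> "{_node_key_str(v)}" [label="{label}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GFF3 / BED


def export_translons_gff(rdg: RDG) -> str:
    """GFF3: one ``translon`` feature per translon with ``translon_segment``
    children for multi-frame translons (1-based inclusive)."""
    lines = ["##gff-version 3"]
    tid = rdg.transcript.id
    for t_id in sorted(rdg.translons, key=lambda t: int(t[1:])):
        t = rdg.translons[t_id]
        lo, hi = t.span()
        attrs = (
            f"ID={t_id};reinit_competent={str(t.reinit_competent).lower()}"
            f";stop_terminated={str(t.stop_terminated).lower()}"
        )
        if t.events:
            attrs += ";events=" + ",".join(
                f"readthrough@{e.pos}" if e.kind == "readthrough"
                else f"shift@{e.take_off}>{e.landing}"
                for e in t.events
            )
        lines.append(
            "\t".join(
                [tid, "rdgkit", "translon", str(lo), str(hi), ".", "+", ".", attrs]
            )
        )
        for i, seg in enumerate(t.segments, 1):
            lines.append(
                "\t".join(
                    [
                        tid,
                        "rdgkit",
                        "translon_segment",
                        str(seg.begin),
                        str(seg.end),
                        ".",
                        "+",
                        str(seg.frame),
                        f"ID={t_id}.seg{i};Parent={t_id}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def export_translons_bed(rdg: RDG) -> str:
    """BED12 with one record per translon; segments become blocks
    (0-based half-open). Blocks of a -1 frameshift overlap by one base,
    which strict BED consumers may reject; the GFF3 export is lossless."""
    rows = []
    tid = rdg.transcript.id
    for t_id in sorted(rdg.translons, key=lambda t: int(t[1:])):
        t = rdg.translons[t_id]
        lo, hi = t.span()
        chrom_start = lo - 1
        segs = sorted(t.segments, key=lambda s: s.begin)
        sizes = ",".join(str(s.end - s.begin + 1) for s in segs)
        offsets = ",".join(str(s.begin - 1 - chrom_start) for s in segs)
        rows.append(
            "\t".join(
                [
                    tid,
                    str(chrom_start),
                    str(hi),
                    t_id,
                    "0",
                    "+",
                    str(chrom_start),
                    str(hi),
                    "0,0,0",
                    str(len(segs)),
                    sizes,
                    offsets,
                ]
            )
        )
    return "\n".join(rows) + ("\n" if rows else "")


def bed_interval_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def gff_interval_to_bed(first1: int, last1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return first1 - 1, last1


# ---------------------------------------------------------------------------
# proteoform FASTA and path table


def write_proteoform_fasta(
    records: Iterable[ProteoformRecord], transcript: Transcript
) -> str:
    out = []
    for r in records:
        out.append(f">{transcript.id}|{r.translon_id} {r.description}")
        for i in range(0, len(r.sequence), 60):
            out.append(r.sequence[i : i + 60])
    return "\n".join(out) + "\n"


def write_path_table(paths: Iterable[RiboPath]) -> str:
    """TSV: path id, decision list, translon list, productive flag and
    probability (blank when branch probabilities are unset)."""
    lines = ["path_id\tdecisions\ttranslons\tproductive\tprobability"]
    for p in paths:
        decisions = ";".join(f"{node}:{kind}" for node, kind in p.events) or "-"
        translons = ",".join(p.translons) or "-"
        prob = "" if p.probability is None else f"{p.probability:.10g}"
        lines.append(
            f"{p.id}\t{decisions}\t{translons}\t{int(p.productive)}\t{prob}"
        )
    return "\n".join(lines) + "\n"
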