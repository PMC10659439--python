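"""Quantifying branch probabilities from ribosome footprint densities.

Translation efficiency (TE) of a translon is the number of footprints
uniquely assigned to it divided by the number of codons used for the
mapping, with the first five codons excluded to avoid the high initiation
peaks. For two translons competing by leaky scanning, the initiation
probability at the upstream start is p = Ru / (Ru + Rd), where Ru and Rd
are the upstream and downstream TEs; for general graphs the probabilities
are recovered by propagating scanning flux through the graph and matching
predicted translon fluxes to observed TEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    IdentifiabilityError,
    TooShortError,
    UndefinedProbabilityError,
)
from .graph import CAP, RDG, Translon, _node_label
from .paths import DEFAULT_PATH_LIMIT, enumerate_paths

DEFAULT_TRIM_CODONS = 5


@dataclass
class FootprintTrack:
    """Per-nucleotide ribosome A-site footprint counts on one transcript.

    Counts are indexed by 1-based transcript position; simulated
    noise-free tracks may hold fractional expectations.
    """

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("footprint counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    def at(self, pos: int) -> float:
        return float(self.counts[pos - 1])


def read_track(path: str | Path, transcript_id: Optional[str] = None,
               length: Optional[int] = None) -> FootprintTrack:
    """Read a footprint track from bedGraph (0-based half-open intervals)
    or two-column TSV (1-based position, count); format is sniffed from
    the column count."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"empty track file: {path}")
    is_bedgraph = len(rows[0]) >= 4
    tid = transcript_id or (rows[0][0] if is_bedgraph else "track")
    if is_bedgraph:
        rows = [r for r in rows if r[0] == tid]
        n = length or max(int(r[2]) for r in rows)
        counts = np.zeros(n)
        for r in rows:
            counts[int(r[1]) : int(r[2])] = float(r[3])
    else:
        n = length or max(int(r[0]) for r in rows)
        counts = np.zeros(n)
        for r in rows:
            counts[int(r[0]) - 1] = float(r[1])
    return FootprintTrack(tid, counts)


def write_track_bedgraph(track: FootprintTrack, path: str | Path) -> None:
    """Write as bedGraph, merging runs of equal counts; zero runs omitted."""
    with open(path, "w") as fh:
        start = None
        for i, v in enumerate(track.counts):
            if start is not None and v != track.counts[start]:
                if track.counts[start]:
                    fh.write(
                        f"{track.transcript_id}\t{start}\t{i}\t"
                        f"{_fmt(track.counts[start])}\n"
                    )
                start = i
            elif start is None:
                start = i
        if start is not None and track.counts[start]:
            fh.write(
                f"{track.transcript_id}\t{start}\t{len(track.counts)}\t"
                f"{_fmt(track.counts[start])}\n"
            )


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# translation efficiency


def translation_efficiency(
    track: FootprintTrack,
    translon: Translon,
    *,
    rdg: Optional[RDG] = None,
    others: Optional[Iterable[Translon]] = None,
    trim_codons: int = DEFAULT_TRIM_CODONS,
    exclusive_only: bool = True,
    frame_aware: bool = False,
) -> float:
    """Footprints per codon over the translon's uniquely mapping span.

    The first ``trim_codons`` codons are excluded (initiation peak); with
    ``exclusive_only`` any position lying inside another translon of the
    graph (or of ``others``) is also excluded, implementing "uniquely
    aligning" footprints. ``frame_aware`` additionally restricts counting
    to positions that are the first nucleotide of one of the translon's
    codons (A-site codon frame match).
    """
    if translon.n_codons <= trim_codons:
        raise TooShortError(
            f"translon {translon.id} has {translon.n_codons} codons; "
            f"needs more than trim_codons={trim_codons}"
        )
    excluded = np.zeros(len(track), dtype=bool)
    if exclusive_only:
        if others is None and rdg is not None:
            others = [t for t in rdg.translons.values() if t.id != translon.id]
        for other in others or ():
            if other.id == translon.id:
                continue
            for seg in other.segments:
                excluded[seg.begin - 1 : seg.end] = True
    total = 0.0
    codons_used = 0
    for k, cpos in enumerate(translon.codon_starts()):
        if k < trim_codons:
            continue
        positions = (cpos,) if frame_aware else (cpos, cpos + 1, cpos + 2)
        kept = [p for p in positions if not excluded[p - 1]]
        if not kept:
            continue
        codons_used += 1
        total += sum(track.at(p) for p in kept)
    if codons_used == 0:
        return 0.0
    return total / codons_used


def infer_initiation_probability(te_upstream: float, te_downstream: float) -> float:
    """p = Ru / (Ru + Rd) for an upstream/downstream translon pair."""
    if te_upstream < 0 or te_downstream < 0:
        raise ValueError("translation efficiencies must be non-negative")
    if te_upstream == 0 and te_downstream == 0:
        raise UndefinedProbabilityError(
            "no flux observed on either translon; probability undefined"
        )
    return te_upstream / (te_upstream + te_downstream)


# ---------------------------------------------------------------------------
# flux propagation


@dataclass
class QuantResult:
    """Per-translon efficiencies, branch probabilities, path probabilities
    and relative synthesis rates (percent of productive output)."""

    te: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)  # branch label -> prob
    path_prob: dict[int, float] = field(default_factory=dict)
    rel_synthesis: dict[str, float] = field(default_factory=dict)
    translon_flux: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def node_flux(rdg: RDG) -> dict:
    """Scanning/elongation flux through every node for unit cap input.

    Requires a complete probability assignment; edge flux is the source
    node's flux times the edge probability (1 for deterministic edges).
    """
    import networkx as nx

    g = rdg.graph
    missing = [
        _node_label(n)
        for n in rdg.branch_nodes()
        if n not in rdg.branch_probabilities()
    ]
    if missing:
        raise ValueError(f"branch nodes without probabilities: {missing}")
    flux = {n: 0.0 for n in g.nodes}
    flux[CAP] = 1.0
    for node in nx.topological_sort(g):
        out = list(g.out_edges(node, data=True))
        branching = len(out) >= 2
        for _, v, data in out:
            p = data.get("p", 1.0) if branching else 1.0
            data["flux"] = flux[node] * p
            flux[v] += data["flux"]
    return flux


def propagate_flux(
    rdg: RDG,
    p: Optional[Mapping] = None,
    *,
    path_limit: int = DEFAULT_PATH_LIMIT,
    with_paths: bool = True,
) -> QuantResult:
    """Propagate unit scanning flux from the cap through the graph.

    Returns per-translon synthesis fluxes (flux through the edge that
    completes each translon), relative synthesis rates in percent, and —
    when the graph is small enough to enumerate — per-path probabilities.
    """
    if p is not None:
        rdg.set_branch_probabilities(p)
    node_flux(rdg)
    g = rdg.graph
    result = QuantResult()
    for u, v, data in g.edges(data=True):
        if "translon" in data:
            result.translon_flux[data["translon"]] = data["flux"]
    total = sum(result.translon_flux.values())
    if total > 0:
        result.rel_synthesis = {
            tid: 100.0 * f / total for tid, f in result.translon_flux.items()
        }
    result.p = {
        _node_label(n): v for n, v in rdg.branch_probabilities().items()
    }
    if with_paths:
        paths = enumerate_paths(rdg, limit=path_limit)
        result.path_prob = {pp.id: pp.probability for pp in paths}
    result.metadata["assumes_no_leak_past_last_start"] = True
    return result


# ---------------------------------------------------------------------------
# fitting branch probabilities from observed efficiencies


def _is_pure_leaky_chain(rdg: RDG) -> bool:
    """True when every branch node is a start, no termination re-feeds the
    scanning queue, every translon is event-free, and starts/translons are
    in bijection — the geometry with a closed-form solution."""
    if any(n[0] != "start" for n in rdg.branch_nodes()):
        return False
    for _, v, data in rdg.graph.edges(data=True):
        if data["kind"] == "terminate_reinitiate" and v[0] == "start":
            return False
    if any(t.events for t in rdg.translons.values()):
        return False
    start_positions = sorted(n[1] for n in rdg.start_nodes())
    translon_starts = sorted(t.start_pos for t in rdg.translons.values())
    return start_positions == translon_starts


def fit_branch_probabilities(
    rdg: RDG,
    te: Mapping[str, float],
    *,
    fix_terminal: bool = True,
    scale: Optional[float] = None,
) -> dict[str, float]:
    """Branch probabilities that best explain observed translon TEs.

    For a pure leaky-scanning chain the closed form applies: the last
    start initiates with probability 1 (no unproductive leakage past it)
    and each upstream start with p_k = TE_k / sum of TEs from k on. For
    other graphs the probabilities minimize the squared error between
    normalized observed TEs and the translon fluxes predicted by
    :func:`propagate_flux`, with probabilities bounded to [0, 1].

    ``fix_terminal`` pins the 3'-most start branch at probability 1;
    ``scale`` fixes the TE-per-unit-flux factor instead of fitting it
    (pass 1.0 when the TEs *are* fluxes). Keys of the result are branch
    node labels (``start@x``, ...). Deterministic for fixed inputs.
    """
    if any(v < 0 for v in te.values()):
        raise ValueError("translation efficiencies must be non-negative")
    if not any(v > 0 for v in te.values()):
        raise ValueError("at least one translation efficiency must be positive")

    if _is_pure_leaky_chain(rdg) and fix_terminal and scale is None:
        start_of = {t.start_pos: tid for tid, t in rdg.translons.items()}
        xs = sorted(n[1] for n in rdg.start_nodes())
        tes = [float(te[start_of[x]]) for x in xs]
        out = {}
        for k, x in enumerate(xs):
            if ("start", x) not in set(rdg.branch_nodes()):
                continue  # deterministic start, p fixed at 1
            denom = sum(tes[k:])
            if denom <= 0:
                raise UndefinedProbabilityError(
                    f"no flux observed at or downstream of start {x}"
                )
            out[f"start@{x}"] = tes[k] / denom
        return out

    branch = rdg.branch_nodes()
    free = list(branch)
    fixed: dict = {}
    if fix_terminal:
        start_branches = [n for n in branch if n[0] == "start"]
        if start_branches:
            terminal = max(start_branches, key=lambda n: n[1])
            free = [n for n in free if n != terminal]
            fixed[terminal] = 1.0
    tids = sorted(rdg.translons, key=lambda t: int(t[1:]))
    observed = np.array([float(te[t]) for t in tids])
    n_obs = len(tids)
    n_free = len(free) + (1 if scale is None else 0)
    if n_free > n_obs:
        raise IdentifiabilityError([_node_label(n) for n in free], n_obs)

    def predicted_flux(pvec) -> np.ndarray:
        probs = dict(fixed)
        probs.update({n: v for n, v in zip(free, pvec)})
        rdg.set_branch_probabilities(probs)
        node_flux(rdg)
        flux = {
            data["translon"]: data["flux"]
            for _, _, data in rdg.graph.edges(data=True)
            if "translon" in data
        }
        return np.array([flux[t] for t in tids])

    fit_scale = scale is None

    def residuals(x):
        pvec = x[: len(free)]
        c = x[len(free)] if fit_scale else scale
        return c * predicted_flux(pvec) - observed

    x0 = np.full(len(free), 0.5)
    lo = np.zeros(len(free))
    hi = np.ones(len(free))
    if fit_scale:
        c0 = max(observed.sum(), 1e-9)
        x0 = np.append(x0, c0)
        lo = np.append(lo, 0.0)
        hi = np.append(hi, np.inf)
    best = None
    for start_p in (0.5, 0.25, 0.75):
        x_init = x0.copy()
        x_init[: len(free)] = start_p
        sol = least_squares(
            residuals, x_init, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-20:
            break
    result = {_node_label(n): float(v) for n, v in zip(free, best.x)}
    for n, v in fixed.items():
        result[_node_label(n)] = v
    return result
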