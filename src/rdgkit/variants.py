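"""Transcript variants and their effect on decision-graph topology.

Variants are applied in mature-transcript coordinates; HGVS-like ``c.``
strings with negative 5'-leader offsets are accepted when the transcript
has an annotated CDS start (``c.-1`` is the nucleotide immediately 5' of
the CDS AUG). The supported subset is SNVs (``c.Xr>a``), insertions
(``c.X_X+1insSEQ``) and deletions (``c.X_YdelSEQ``).

Because single-nucleotide edits create and destroy start and stop codons,
the comparison between alleles re-derives the branch annotation on each
sequence under one policy rather than lifting the reference annotation
across; positions of non-sequence origin (externally evidenced shift or
readthrough sites) are lifted through the edit's coordinate map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    CdsAnchorError,
    RefMismatchError,
    UnsupportedVariantError,
)
from .graph import RDG, build_rdg
from .notation import BranchAnnotation, ShiftSite
from .transcript import DEFAULT_START_CODONS, Transcript, normalize_rna, scan_codons

import re


@dataclass(frozen=True)
class Variant:
    """A transcript-space edit.

    ``pos`` is 1-based; for substitutions/deletions it is the first
    edited nucleotide and ``ref`` the replaced bases; for pure insertions
    ``ref`` is empty and the inserted bases follow position ``pos``.
    """

    pos: int
    ref: str
    alt: str
    hgvs: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "ref", normalize_rna(self.ref) if self.ref else "")
        object.__setattr__(self, "alt", normalize_rna(self.alt) if self.alt else "")

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def map_position(self, pos: int) -> Optional[int]:
        """Reference position → alternate position (None if deleted)."""
        if not self.ref:  # insertion after self.pos
            return pos if pos <= self.pos else pos + len(self.alt)
        last = self.pos + len(self.ref) - 1
        if pos < self.pos:
            return pos
        if pos <= last:
            if len(self.ref) == len(self.alt):  # substitution keeps coords
                return pos
            return None
        return pos + self.length_change

    def inverse(self) -> "Variant":
        """The edit that restores the reference (coordinates on the alt)."""
        if not self.ref:  # insertion -> delete the inserted bases
            return Variant(self.pos + 1, self.alt, "")
        if not self.alt:  # deletion -> re-insert after the preceding base
            return Variant(self.pos - 1, "", self.ref)
        return Variant(self.pos, self.alt, self.ref)


_SNV_RE = re.compile(r"(?:c\.)?(-?\d+)([ACGTUacgtu])>([ACGTUacgtu])$")
_INS_RE = re.compile(r"(?:c\.)?(-?\d+)_(-?\d+)ins([ACGTUacgtu]+)$")
_DEL_RE = re.compile(r"(?:c\.)?(-?\d+)(?:_(-?\d+))?del([ACGTUacgtu]*)$")


def parse_variant(spec, transcript: Transcript) -> Variant:
    """Parse a (pos, ref, alt) triple or an HGVS-like ``c.`` string.

    ``c.`` coordinates (including negative 5'-leader offsets) require the
    transcript's ``cds_start``. The reference allele is always checked
    against the sequence.
    """
    if isinstance(spec, (tuple, list)):
        pos, ref, alt = spec
        v = Variant(int(pos), ref, alt)
        return _check_ref(v, transcript)
    text = spec.strip()
    m = _SNV_RE.match(text)
    if m:
        pos = _c2t(int(m.group(1)), transcript)
        v = Variant(pos, m.group(2), m.group(3), hgvs=text)
        return _check_ref(v, transcript)
    m = _INS_RE.match(text)
    if m:
        left, right = int(m.group(1)), int(m.group(2))
        lp, rp = _c2t(left, transcript), _c2t(right, transcript)
        if rp != lp + 1:
            raise UnsupportedVariantError(
                f"insertion flanks {left}_{right} are not adjacent"
            )
        return Variant(lp, "", m.group(3), hgvs=text)
    m = _DEL_RE.match(text)
    if m:
        first = _c2t(int(m.group(1)), transcript)
        last = _c2t(int(m.group(2)), transcript) if m.group(2) else first
        if last < first:
            raise UnsupportedVariantError("deletion range reversed")
        ref = transcript.seq[first - 1 : last]
        stated = m.group(3)
        if stated and normalize_rna(stated) != ref:
            raise RefMismatchError(first, normalize_rna(stated), ref)
        return _check_ref(Variant(first, ref, "", hgvs=text), transcript)
    raise UnsupportedVariantError(
        f"unsupported variant form {text!r} (supported: SNV, ins, del)"
    )


def _c2t(c: int, transcript: Transcript) -> int:
    # plain transcript coordinates are only reachable via the triple form;
    # strings always use the c. frame so -N offsets work
    return transcript.from_cds_coordinate(c)


def _check_ref(v: Variant, transcript: Transcript) -> Variant:
    if v.ref:
        if v.pos < 1 or v.pos + len(v.ref) - 1 > len(transcript):
            raise ValueError(f"edit at {v.pos} out of bounds")
        found = transcript.seq[v.pos - 1 : v.pos - 1 + len(v.ref)]
        if found != v.ref:
            raise RefMismatchError(v.pos, v.ref, found)
    elif not 0 <= v.pos <= len(transcript):
        raise ValueError(f"insertion point {v.pos} out of bounds")
    return v


def apply_variant(transcript: Transcript, v: Variant) -> Transcript:
    """Apply an edit, shifting ``cds_start`` when the edit lies 5' of it.

    A deletion overlapping the CDS anchor raises — the coordinate anchor
    would be destroyed.
    """
    _check_ref(v, transcript)
    seq = transcript.seq
    if not v.ref:
        new_seq = seq[: v.pos] + v.alt + seq[v.pos :]
    else:
        new_seq = seq[: v.pos - 1] + v.alt + seq[v.pos - 1 + len(v.ref) :]
    cds = transcript.cds_start
    if cds is not None:
        if v.ref and v.pos <= cds <= v.pos + len(v.ref) - 1 and len(v.ref) != len(v.alt):
            raise CdsAnchorError(
                f"edit at {v.pos} overlaps the CDS anchor at {cds}"
            )
        mapped = v.map_position(cds)
        cds = mapped if mapped is not None else cds
    label = v.hgvs or f"{v.pos}{v.ref or '-'}>{v.alt or '-'}"
    return Transcript(f"{transcript.id}|{label}", new_seq, cds_start=cds)


# ---------------------------------------------------------------------------
# allele comparison


@dataclass
class AnnotationPolicy:
    """How to derive a branch annotation from a bare sequence.

    Starts are re-scanned on each allele from ``start_set``;
    ``deterministic_starts`` (reference coordinates) and the lift-only
    events ``secs``/``shifts`` are carried across the edit through its
    coordinate map.
    """

    start_set: frozenset = DEFAULT_START_CODONS
    reinit_max_codons: int = 30
    recharge_distance: int = 0
    deterministic_starts: frozenset = frozenset()
    secs: tuple = ()
    shifts: tuple = ()

    @classmethod
    def from_annotation(cls, a: BranchAnnotation) -> "AnnotationPolicy":
        return cls(
            start_set=a.start_set,
            reinit_max_codons=a.reinit_max_codons,
            recharge_distance=a.recharge_distance,
            deterministic_starts=a.deterministic_starts,
            secs=a.secs,
            shifts=a.shifts,
        )

    def derive(self, transcript: Transcript, variant: Optional[Variant] = None
               ) -> BranchAnnotation:
        """Annotation for one allele; ``variant`` maps the policy's
        reference-coordinate fields onto the alternate allele."""
        mapper = variant.map_position if variant else (lambda p: p)
        starts = tuple(
            s.pos
            for s in scan_codons(transcript, self.start_set)
            if s.kind == "start"
        )
        det = {mapper(x) for x in self.deterministic_starts}
        det = {x for x in det if x in starts}
        secs = tuple(y for y in (mapper(y) for y in self.secs) if y is not None)
        shifts = tuple(
            ShiftSite(i, s)
            for i, s in (
                (mapper(sh.take_off), mapper(sh.landing))
                for sh in (ShiftSite(*s) if not isinstance(s, ShiftSite) else s
                           for s in self.shifts)
            )
            if i is not None and s is not None
        )
        return BranchAnnotation(
            starts=starts,
            secs=secs,
            shifts=shifts,
            reinit_max_codons=self.reinit_max_codons,
            recharge_distance=self.recharge_distance,
            start_set=self.start_set,
            deterministic_starts=frozenset(det),
        )


@dataclass
class TranslonChange:
    ref_id: str
    alt_id: str
    ref_bounds: tuple[int, int]
    alt_bounds: tuple[int, int]
    change: str  # "extended" | "truncated" | "rearranged"


@dataclass
class RdgDiff:
    """Topology differences between the graphs of two alleles.

    Translons are matched when the reference start maps through the edit
    to an alternate translon's start (frame relative to the start is then
    preserved by construction); branch points are compared as annotated
    (kind, position) events through the same coordinate map.
    """

    translons_lost: list[str] = field(default_factory=list)
    translons_gained: list[str] = field(default_factory=list)
    translons_modified: list[TranslonChange] = field(default_factory=list)
    branch_points_lost: list[tuple] = field(default_factory=list)
    branch_points_gained: list[tuple] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.translons_lost
            or self.translons_gained
            or self.translons_modified
            or self.branch_points_lost
            or self.branch_points_gained
        )

    def summary(self) -> str:
        if self.is_empty():
            return "no topology change"
        lines = []
        for tid in self.translons_lost:
            lines.append(f"translon lost: {tid}")
        for tid in self.translons_gained:
            lines.append(f"translon gained: {tid}")
        for ch in self.translons_modified:
            lines.append(
                f"translon {ch.change}: {ch.ref_id} "
                f"{ch.ref_bounds[0]}-{ch.ref_bounds[1]} -> "
                f"{ch.alt_id} {ch.alt_bounds[0]}-{ch.alt_bounds[1]}"
            )
        for bp in self.branch_points_lost:
            lines.append(f"branch point lost: {bp[0]}@{bp[1]}")
        for bp in self.branch_points_gained:
            lines.append(f"branch point gained: {bp[0]}@{bp[1]}")
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "translons_lost": self.translons_lost,
            "translons_gained": self.translons_gained,
            "translons_modified": [
                {
                    "ref_id": c.ref_id,
                    "alt_id": c.alt_id,
                    "ref_bounds": list(c.ref_bounds),
                    "alt_bounds": list(c.alt_bounds),
                    "change": c.change,
                }
                for c in self.translons_modified
            ],
            "branch_points_lost": [list(b) for b in self.branch_points_lost],
            "branch_points_gained": [list(b) for b in self.branch_points_gained],
        }


def _annotated_branch_events(a: BranchAnnotation) -> set[tuple]:
    events = {
        ("start", x) for x in a.starts if x not in a.deterministic_starts
    }
    events |= {("sec", y) for y in a.secs}
    events |= {("shift", sh.take_off, sh.landing) for sh in a.shifts}
    return events


def diff_rdg(
    transcript_ref: Transcript,
    transcript_alt: Transcript,
    policy: AnnotationPolicy,
    variant: Optional[Variant] = None,
) -> tuple[RdgDiff, RDG, RDG]:
    """Compare decision-graph topology between two alleles.

    Annotations are re-derived per allele under ``policy`` and graphs are
    rebuilt, so the diff reflects which translated regions actually
    remain reachable. Returns the diff together with both graphs.
    """
    if variant is None and transcript_ref.seq != transcript_alt.seq:
        raise ValueError("alleles differ: a Variant is needed to map coordinates")
    ann_ref = policy.derive(transcript_ref)
    ann_alt = policy.derive(transcript_alt, variant)
    rdg_ref = build_rdg(transcript_ref, ann_ref)
    rdg_alt = build_rdg(transcript_alt, ann_alt)
    mapper = variant.map_position if variant else (lambda p: p)

    diff = RdgDiff()

    # translon matching keyed on mapped start position
    alt_by_start: dict[int, list] = {}
    for t in rdg_alt.translons.values():
        alt_by_start.setdefault(t.start_pos, []).append(t)
    matched_alt = set()
    for tid in sorted(rdg_ref.translons, key=lambda t: int(t[1:])):
        t_ref = rdg_ref.translons[tid]
        mapped = mapper(t_ref.start_pos)
        candidates = alt_by_start.get(mapped, []) if mapped is not None else []
        candidates = [c for c in candidates if c.id not in matched_alt]
        if not candidates:
            diff.translons_lost.append(tid)
            continue
        # prefer the candidate with the same event signature, then nearest end
        sig = tuple(e.kind for e in t_ref.events)
        candidates.sort(
            key=lambda c: (
                tuple(e.kind for e in c.events) != sig,
                abs(c.end_pos - (mapper(t_ref.end_pos) or -1)),
            )
        )
        t_alt = candidates[0]
        matched_alt.add(t_alt.id)
        mapped_end = mapper(t_ref.end_pos)
        if mapped_end is not None and mapped_end == t_alt.end_pos:
            continue  # unchanged
        ref_len = t_ref.end_pos - t_ref.start_pos
        alt_len = t_alt.end_pos - t_alt.start_pos
        change = (
            "extended"
            if alt_len > ref_len
            else "truncated" if alt_len < ref_len else "rearranged"
        )
        diff.translons_modified.append(
            TranslonChange(
                tid,
                t_alt.id,
                (t_ref.start_pos, t_ref.end_pos),
                (t_alt.start_pos, t_alt.end_pos),
                change,
            )
        )
    diff.translons_gained = [
        t.id
        for t in rdg_alt.translons.values()
        if t.id not in matched_alt
    ]

    # branch points from the annotations (not reachability-filtered)
    ref_events = _annotated_branch_events(ann_ref)
    alt_events = _annotated_branch_events(ann_alt)
    mapped_ref = {}
    for ev in ref_events:
        coords = tuple(mapper(c) for c in ev[1:])
        mapped_ref[ev] = None if None in coords else (ev[0], *coords)
    diff.branch_points_lost = sorted(
        ev for ev, m in mapped_ref.items() if m is None or m not in alt_events
    )
    hit = {m for m in mapped_ref.values() if m is not None}
    diff.branch_points_gained = sorted(ev for ev in alt_events if ev not in hit)
    return diff, rdg_ref, rdg_alt
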