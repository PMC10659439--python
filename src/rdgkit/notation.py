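"""Branch-point annotations and their compact text notation.

The non-deterministic events on one transcript are written as a short
array of clauses::

    starts(x1;x2;...);secs(y1;...);shifts(i1,s1;...)

* ``starts`` — 1-based positions of initiation codons (leaky unless the
  annotation marks them deterministic);
* ``secs`` — positions of readthrough-permissive stop codons
  (selenocysteine insertion or generic stop-codon readthrough);
* ``shifts`` — pairs (i, s): the last codon decoded in the incoming frame
  and the first codon decoded in the shifted frame. ``s - i = +1`` is +1
  frameshifting, ``s - i = -1`` is -1 frameshifting, and large positive
  offsets encode translational bypassing.

The canonical form uses parentheses and ';' between clauses; the bare
form without parentheses (``starts1;13;secs25``) is accepted on input.
Unknown clause names are preserved but ignored with a warning, so readers
of the notation stay forward-compatible with new branch-point types.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .errors import AnnotationError, NotationParseError
from .transcript import (
    DEFAULT_START_CODONS,
    STOP_CODONS,
    Transcript,
    normalize_rna,
)

#: default limit on translon length (in codons, stop included) below which a
#: post-terminating small subunit is considered re-initiation competent.
DEFAULT_REINIT_MAX_CODONS = 30


@dataclass(frozen=True)
class ShiftSite:
    """A frameshift / bypass branch point: take_off = i, landing = s."""

    take_off: int
    landing: int

    def __post_init__(self):
        if self.landing == self.take_off:
            raise AnnotationError("shift landing s must differ from take-off i")


@dataclass(frozen=True)
class BranchAnnotation:
    """The set of non-deterministic events on one transcript.

    ``starts``/``secs``/``shifts`` carry the branch-point coordinates of
    the compact notation; the remaining fields are the re-initiation and
    initiation policy that the notation does not encode.

    Attributes
    ----------
    starts : tuple of int
        Initiation-codon positions, strictly increasing.
    secs : tuple of int
        Readthrough-permissive stop codon positions.
    shifts : tuple of ShiftSite
        Frameshift sites (i, s).
    reinit_max_codons : int
        Translons at most this many codons long (stop included) leave the
        post-terminating small subunit competent to resume scanning.
    recharge_distance : int
        Scanning distance (nt) a post-terminating subunit must cover
        before it can initiate again (ternary-complex recharge; grows
        under stress).
    start_set : frozenset of str
        Codons accepted as initiation sites.
    deterministic_starts : frozenset of int
        Starts treated as 100%-efficient (no branch node) — typically CDS
        starts in a strong context.
    sec_aa : mapping pos -> str
        Amino-acid symbol inserted at a readthrough stop ('U' for
        selenocysteine); defaults to 'X' for unlisted positions.
    unknown_clauses : tuple of (name, args)
        Clauses of unrecognized type, preserved verbatim.
    """

    starts: tuple[int, ...] = ()
    secs: tuple[int, ...] = ()
    shifts: tuple[ShiftSite, ...] = ()
    reinit_max_codons: int = DEFAULT_REINIT_MAX_CODONS
    recharge_distance: int = 0
    start_set: frozenset[str] = DEFAULT_START_CODONS
    deterministic_starts: frozenset[int] = frozenset()
    sec_aa: tuple[tuple[int, str], ...] = ()
    unknown_clauses: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "starts", tuple(int(x) for x in self.starts))
        object.__setattr__(self, "secs", tuple(sorted(int(y) for y in self.secs)))
        shifts = tuple(
            s if isinstance(s, ShiftSite) else ShiftSite(*s) for s in self.shifts
        )
        object.__setattr__(self, "shifts", tuple(sorted(shifts, key=lambda s: s.take_off)))
        object.__setattr__(
            self, "start_set", frozenset(normalize_rna(c) for c in self.start_set)
        )
        object.__setattr__(
            self, "deterministic_starts", frozenset(self.deterministic_starts)
        )
        if isinstance(self.sec_aa, Mapping):
            object.__setattr__(self, "sec_aa", tuple(sorted(self.sec_aa.items())))
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise AnnotationError("start positions must be strictly increasing")
        if self.reinit_max_codons < 0 or self.recharge_distance < 0:
            raise AnnotationError("policy distances must be non-negative")

    def sec_symbol(self, pos: int) -> str:
        return dict(self.sec_aa).get(pos, "X")

    def with_(self, **changes) -> "BranchAnnotation":
        return replace(self, **changes)


def validate_annotation(
    transcript: Transcript, annotation: BranchAnnotation
) -> None:
    """Check every annotated position against the transcript sequence.

    Raises :class:`AnnotationError` when a position is out of bounds, a
    start does not begin a codon of the start set, or a secs position is
    not a stop codon.
    """
    n = len(transcript)

    def _in_bounds(pos: int, what: str):
        if not 1 <= pos <= n - 2:
            raise AnnotationError(f"{what} position {pos} outside [1, {n - 2}]")

    for x in annotation.starts:
        _in_bounds(x, "start")
        codon = transcript.codon(x)
        if codon not in annotation.start_set:
            raise AnnotationError(
                f"start at {x} is {codon}, not in start set "
                f"{sorted(annotation.start_set)}"
            )
    for y in annotation.secs:
        _in_bounds(y, "secs")
        codon = transcript.codon(y)
        if codon not in STOP_CODONS:
            raise AnnotationError(f"secs position {y} is {codon}, not a stop")
    for sh in annotation.shifts:
        _in_bounds(sh.take_off, "shift take-off")
        _in_bounds(sh.landing, "shift landing")
    extra = annotation.deterministic_starts - set(annotation.starts)
    if extra:
        raise AnnotationError(
            f"deterministic starts {sorted(extra)} are not annotated starts"
        )


# ---------------------------------------------------------------------------
# parsing / formatting

_CLAUSE_RE = re.compile(r"\s*([A-Za-z_]\w*)\s*\(([^)]*)\)\s*")
_BARE_PIECE_RE = re.compile(r"\s*([A-Za-z_]+)?\s*(-?\d+(?:\s*,\s*-?\d+)?)\s*$")

_KNOWN_CLAUSES = ("starts", "secs", "shifts")


def _parse_int_list(args: str, offset: int) -> list[int]:
    vals = []
    for piece in args.split(";"):
        piece = piece.strip()
        if not piece:
            continue
        try:
            vals.append(int(piece))
        except ValueError:
            raise NotationParseError(f"expected integer, got {piece!r}", offset)
    return vals


def _parse_pair_list(args: str, offset: int) -> list[ShiftSite]:
    pairs = []
    for piece in args.split(";"):
        piece = piece.strip()
        if not piece:
            continue
        parts = [p.strip() for p in piece.split(",")]
        if len(parts) != 2:
            raise NotationParseError(
                f"shift clause needs 'i,s' pairs, got {piece!r}", offset
            )
        try:
            pairs.append(ShiftSite(int(parts[0]), int(parts[1])))
        except ValueError:
            raise NotationParseError(f"expected integer pair, got {piece!r}", offset)
    return pairs


def _split_clauses(text: str) -> list[tuple[str, str, int]]:
    """Split notation into (name, args, offset) triples.

    Accepts the canonical parenthesized form and the bare form in which a
    clause name is directly followed by its arguments.
    """
    clauses: list[tuple[str, str, int]] = []
    pos = 0
    if "(" in text:
        while pos < len(text):
            m = _CLAUSE_RE.match(text, pos)
            if not m:
                raise NotationParseError("malformed clause", pos)
            clauses.append((m.group(1).lower(), m.group(2), m.start(1)))
            pos = m.end()
            if pos < len(text):
                if text[pos] != ";":
                    raise NotationParseError("expected ';' between clauses", pos)
                pos += 1
        return clauses
    # bare form: clause name glued to its first argument
    current: Optional[list] = None
    for piece in text.split(";"):
        m = _BARE_PIECE_RE.match(piece)
        if not m:
            raise NotationParseError(f"malformed token {piece!r}", pos)
        name, args = m.group(1), m.group(2)
        if name:
            if current is not None:
                clauses.append(tuple(current))
            current = [name.lower(), args, pos]
        elif current is None:
            raise NotationParseError("arguments before any clause name", pos)
        else:
            current[1] += ";" + args
        pos += len(piece) + 1
    if current is not None:
        clauses.append(tuple(current))
    return clauses


def parse_branch_notation(
    text: str,
    transcript: Optional[Transcript] = None,
    **policy,
) -> BranchAnnotation:
    """Parse compact branch notation into a :class:`BranchAnnotation`.

    When a transcript is supplied the positions are validated against its
    sequence. Unknown clause names are kept in ``unknown_clauses`` and
    trigger a warning. Extra keyword arguments (``reinit_max_codons``,
    ``recharge_distance``, ``start_set``, ...) set the policy fields the
    notation itself does not carry.
    """
    if not text or not text.strip():
        raise NotationParseError("empty notation string", 0)
    starts: list[int] = []
    secs: list[int] = []
    shifts: list[ShiftSite] = []
    unknown: list[tuple[str, str]] = []
    for name, args, offset in _split_clauses(text.strip()):
        if name == "starts":
            starts.extend(_parse_int_list(args, offset))
        elif name == "secs":
            secs.extend(_parse_int_list(args, offset))
        elif name == "shifts":
            shifts.extend(_parse_pair_list(args, offset))
        else:
            warnings.warn(
                f"unknown clause {name!r} ignored (forward compatibility)",
                stacklevel=2,
            )
            unknown.append((name, args))
    annotation = BranchAnnotation(
        starts=tuple(sorted(starts)),
        secs=tuple(secs),
        shifts=tuple(shifts),
        unknown_clauses=tuple(unknown),
        **policy,
    )
    if transcript is not None:
        validate_annotation(transcript, annotation)
    return annotation


def format_branch_notation(annotation: BranchAnnotation) -> str:
    """Canonical notation string: clauses in starts/secs/shifts order,
    positions ascending, unknown clauses appended verbatim."""
    clauses = []
    if annotation.starts:
        clauses.append("starts(" + ";".join(map(str, annotation.starts)) + ")")
    if annotation.secs:
        clauses.append("secs(" + ";".join(map(str, annotation.secs)) + ")")
    if annotation.shifts:
        clauses.append(
            "shifts("
            + ";".join(f"{s.take_off},{s.landing}" for s in annotation.shifts)
            + ")"
        )
    for name, args in annotation.unknown_clauses:
        clauses.append(f"{name}({args})")
    return ";".join(clauses)
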