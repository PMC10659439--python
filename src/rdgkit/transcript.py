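"""Transcripts and open reading frames.

An mRNA is modelled in mature-transcript coordinates: 1-based, inclusive,
5'→3'. Two classical ORF definitions are provided — start-to-stop
(``start_stop``) and stop-to-stop (``stop_stop``) — in all three reading
frames, where frame ``f`` of a codon starting at position ``p`` is
``(p - 1) % 3``. Start-stop ORF spans include the terminating stop codon.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

from .errors import AlphabetError

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
DEFAULT_START_CODONS = frozenset({"AUG"})
#: near-cognate codons commonly used for non-AUG initiation (e.g. CUG starts)
NEAR_COGNATE_START_CODONS = frozenset(
    {"AUG", "CUG", "GUG", "UUG", "ACG", "AUA", "AUU", "AUC", "AAG", "AGG"}
)

_RNA_ALPHABET = frozenset("ACGU")


def normalize_rna(seq: str) -> str:
    """Uppercase, convert T to U and validate the 4-letter RNA alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"sequence contains non-ACGU characters after normalization: "
            f"{sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class Transcript:
    """An mRNA sequence with 1-based coordinates.

    Parameters
    ----------
    id : str
        Transcript identifier (first whitespace token of a FASTA header).
    seq : str
        Nucleotide sequence; T is accepted and normalized to U.
    cds_start : int, optional
        1-based position of the A of the annotated CDS AUG; anchors
        HGVS-like ``c.`` coordinates (``c.-1`` is the nucleotide 5' of it).
    """

    id: str
    seq: str
    cds_start: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if not self.seq:
            raise AlphabetError("transcript sequence is empty")
        if self.cds_start is not None and not (
            1 <= self.cds_start <= len(self.seq) - 2
        ):
            raise ValueError(
                f"cds_start {self.cds_start} outside [1, {len(self.seq) - 2}]"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def codon(self, pos: int) -> str:
        """3-mer starting at 1-based ``pos`` (must fit in the sequence)."""
        if not 1 <= pos <= len(self.seq) - 2:
            raise IndexError(f"codon position {pos} out of range")
        return self.seq[pos - 1 : pos + 2]

    def to_cds_coordinate(self, pos: int) -> int:
        """Transcript position → HGVS-like c. coordinate (requires cds_start)."""
        if self.cds_start is None:
            raise ValueError("transcript has no annotated cds_start")
        return pos - self.cds_start + (1 if pos >= self.cds_start else 0)

    def from_cds_coordinate(self, c: int) -> int:
        """HGVS-like c. coordinate → transcript position (c.-1 is 5' of AUG)."""
        if self.cds_start is None:
            raise ValueError("transcript has no annotated cds_start")
        if c == 0:
            raise ValueError("c.0 does not exist")
        return self.cds_start + c - (1 if c > 0 else 0)


@dataclass(frozen=True)
class CodonSite:
    """A start or stop codon located on the transcript."""

    pos: int  # 1-based position of the first codon nucleotide
    frame: int  # (pos - 1) % 3
    kind: str  # "start" | "stop"
    codon: str

    def __post_init__(self):
        if self.frame != (self.pos - 1) % 3:
            raise ValueError("frame inconsistent with position")


@dataclass(frozen=True)
class Orf:
    """A Start-Stop or Stop-Stop open reading frame.

    ``first``/``last`` are 1-based inclusive; the terminating stop codon is
    part of the span. ``unbounded`` flags runs truncated by a transcript
    boundary instead of a stop codon: "5p" (no upstream stop, stop_stop
    only), "3p" (no terminating stop) or "5p3p".
    """

    mode: str  # "start_stop" | "stop_stop"
    first: int
    last: int
    frame: int
    unbounded: str = ""

    def __post_init__(self):
        if (self.last - self.first + 1) % 3:
            raise ValueError("ORF length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return (self.last - self.first + 1) // 3

    def cds_frame(self, transcript: Transcript) -> Optional[int]:
        """Frame relative to the annotated CDS start, if one is set."""
        if transcript.cds_start is None:
            return None
        return (self.first - transcript.cds_start) % 3


def scan_codons(
    transcript: Transcript,
    start_set: Iterable[str] = DEFAULT_START_CODONS,
) -> list[CodonSite]:
    """Locate all start and stop codons in the three reading frames.

    Returns sites in ascending position; stop codons are always the fixed
    set {UAA, UAG, UGA}.
    """
    starts = frozenset(normalize_rna(c) for c in start_set)
    if not starts:
        raise ValueError("start_set is empty")
    seq = transcript.seq
    sites: list[CodonSite] = []
    for pos in range(1, len(seq) - 1):
        codon = seq[pos - 1 : pos + 2]
        if codon in starts:
            sites.append(CodonSite(pos, (pos - 1) % 3, "start", codon))
        if codon in STOP_CODONS:
            sites.append(CodonSite(pos, (pos - 1) % 3, "stop", codon))
    return sites


def _stops_by_frame(transcript: Transcript) -> dict[int, list[int]]:
    by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for site in scan_codons(transcript, start_set={"AUG"}):
        if site.kind == "stop":
            by_frame[site.frame].append(site.pos)
    return by_frame


def next_inframe_stop(transcript: Transcript, pos: int) -> Optional[int]:
    """Position of the nearest in-frame stop codon strictly 3' of ``pos``."""
    stops = _stops_by_frame(transcript)[(pos - 1) % 3]
    i = bisect_right(stops, pos)
    return stops[i] if i < len(stops) else None


def find_start_stop_orfs(
    transcript: Transcript,
    start_set: Iterable[str] = DEFAULT_START_CODONS,
) -> list[Orf]:
    """One ORF per start codon with a downstream in-frame stop.

    Nested in-frame starts yield nested ORFs sharing the stop. Starts with
    no downstream in-frame stop yield no ORF.
    """
    orfs = []
    for site in scan_codons(transcript, start_set):
        if site.kind != "start":
            continue
        stop = next_inframe_stop(transcript, site.pos)
        if stop is None:
            continue
        orfs.append(Orf("start_stop", site.pos, stop + 2, site.frame))
    return orfs


def find_stop_stop_orfs(transcript: Transcript) -> list[Orf]:
    """Maximal stop-free codon runs per frame, bounded by stop codons.

    The span begins at the first codon after the bounding upstream stop
    (or the first full codon of the frame) and ends at the last nucleotide
    of the terminating stop (or the last full in-frame codon, flagged
    "3p"-unbounded). Empty runs between adjacent stops are omitted.
    """
    n = len(transcript)
    orfs = []
    stops = _stops_by_frame(transcript)
    for frame in range(3):
        frame_first = frame + 1
        last_codon_start = frame_first + 3 * ((n - frame_first - 2) // 3)
        if last_codon_start < frame_first:
            continue  # frame has no full codon
        run_first = frame_first
        bounded_5p = False
        for stop in stops[frame]:
            if stop + 2 > run_first + 2:  # at least one codon incl. the stop
                orfs.append(
                    Orf(
                        "stop_stop",
                        run_first,
                        stop + 2,
                        frame,
                        unbounded="" if bounded_5p else "5p",
                    )
                )
            elif stop == run_first:
                pass  # adjacent stops: empty run
            run_first = stop + 3
            bounded_5p = True
        if run_first <= last_codon_start:
            orfs.append(
                Orf(
                    "stop_stop",
                    run_first,
                    last_codon_start + 2,
                    frame,
                    unbounded=("" if bounded_5p else "5p") + "3p",
                )
            )
    orfs.sort(key=lambda o: (o.first, o.frame))
    return orfs


# ---------------------------------------------------------------------------
# FASTA I/O and ORF table export


def read_fasta(
    path: str | Path,
    cds_starts: Optional[Mapping[str, int]] = None,
) -> list[Transcript]:
    """Read a (multi-record) FASTA file into Transcripts.

    The record id is the first whitespace-delimited header token. A
    ``cds_start=N`` token in the description, or an entry in ``cds_starts``,
    sets the CDS anchor.
    """
    transcripts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cds = None
        for token in rec.description.split():
            if token.startswith("cds_start="):
                cds = int(token.split("=", 1)[1])
        if cds_starts and rec.id in cds_starts:
            cds = cds_starts[rec.id]
        transcripts.append(Transcript(rec.id, str(rec.seq), cds_start=cds))
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            header = t.id
            if t.cds_start is not None:
                header += f" cds_start={t.cds_start}"
            fh.write(f">{header}\n")
            for i in range(0, len(t.seq), 60):
                fh.write(t.seq[i : i + 60] + "\n")


def orfs_to_bed(orfs: Iterable[Orf], transcript: Transcript) -> str:
    """BED6 (0-based half-open) lines for an ORF table."""
    lines = []
    for o in orfs:
        name = f"{o.mode}:f{o.frame}" + (f":{o.unbounded}" if o.unbounded else "")
        lines.append(
            "\t".join(
                [transcript.id, str(o.first - 1), str(o.last), name, "0", "+"]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def orfs_to_gff3(orfs: Iterable[Orf], transcript: Transcript) -> str:
    """GFF3 (1-based inclusive) lines with mode/frame/unbounded attributes."""
    lines = ["##gff-version 3"]
    for i, o in enumerate(orfs, 1):
        attrs = f"ID=orf{i};mode={o.mode};frame={o.frame}"
        if o.unbounded:
            attrs += f";unbounded={o.unbounded}"
        lines.append(
            "\t".join(
                [
                    transcript.id,
                    "rdgkit",
                    "ORF",
                    str(o.first),
                    str(o.last),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"
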