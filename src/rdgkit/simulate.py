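"""Simulated footprint tracks and the built-in model transcripts.

Simulation closes the inference loop: a graph with known branch
probabilities generates a synthetic ribosome-profiling track, and
comparing tracks predicted under candidate graphs with observed data is
how branch probabilities (and ultimately branch points) are inferred.

The model is deliberately simple: elongation is uniform (no codon
dwell-time structure), each translon deposits ``flux x depth`` expected
footprints per codon at the codon's first (A-site) nucleotide, the first
five codons carry a configurable initiation peak, and counts are drawn
from a Poisson distribution (or left as exact expectations).

``make_fixture`` builds small synthetic transcripts realizing the
recurring regulatory topologies: a three-start/two-frame leader with
re-initiation, a 5' leader whose single-base insertion silences the CDS,
a selenoprotein-style readthrough stop, a -1 frameshift cassette, the
delayed re-initiation arrangement (short uORF, long uORF, CDS) and
leaky-scanning chains. All fixture sequences are deterministic.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import UnknownFixtureError
from .graph import RDG, build_rdg
from .notation import BranchAnnotation, ShiftSite, validate_annotation
from .quantify import FootprintTrack, propagate_flux
from .transcript import Transcript

#: the documented pathogenic-style single-base insertion of the nf2_like
#: fixture (transcript-relative HGVS; creates an AUG and shifts the uORF frame)
NF2_LIKE_INSERTION = "-12_-11insT"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    depth
        Expected footprints per codon for a translon carrying unit flux.
    seed
        RNG seed; streams are derived per transcript id so multi-fixture
        runs reproduce regardless of generation order.
    start_peak_fold
        Multiplier applied to the first five codons of every translon,
        emulating the high initiation peaks of real profiles.
    noise
        "poisson" for counts, "none" for exact expectations.
    """

    depth: float = 50.0
    seed: Optional[int] = None
    start_peak_fold: float = 5.0
    noise: str = "poisson"

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.start_peak_fold < 1:
            raise ValueError("start_peak_fold must be >= 1")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")

    def rng_for(self, transcript_id: str) -> np.random.Generator:
        stream = zlib.crc32(transcript_id.encode())
        return np.random.default_rng(
            np.random.SeedSequence(self.seed or 0, spawn_key=(stream,))
        )


PEAK_CODONS = 5


def simulate_track(
    rdg: RDG,
    p: Optional[Mapping] = None,
    cfg: SimConfig = SimConfig(),
) -> FootprintTrack:
    """Generate a per-nucleotide footprint track from an RDG.

    Expected count at each codon equals the translon's flux times
    ``cfg.depth`` (times ``start_peak_fold`` on its first five codons),
    deposited at the codon's first nucleotide; overlapping translons add.
    """
    result = propagate_flux(rdg, p, with_paths=False)
    expected = np.zeros(len(rdg.transcript.seq))
    for tid, flux in result.translon_flux.items():
        translon = rdg.translons[tid]
        for k, cpos in enumerate(translon.codon_starts()):
            lam = flux * cfg.depth
            if k < PEAK_CODONS:
                lam *= cfg.start_peak_fold
            expected[cpos - 1] += lam
    if cfg.noise == "poisson":
        counts = cfg.rng_for(rdg.transcript.id).poisson(expected).astype(float)
    else:
        counts = expected
    return FootprintTrack(rdg.transcript.id, counts)


# ---------------------------------------------------------------------------
# fixtures

_F = "GCC"  # filler codon: GCCGCC... contains no start or stop in any frame


def _fig3() -> tuple[Transcript, BranchAnnotation]:
    """Three starts in two frames: uAUG (frame 1) whose short uORF allows
    re-initiation, and CUG + in-frame AUG (frame 0) encoding N-terminally
    distinct proteoforms of the same CDS. The CUG lies inside the uORF's
    span, so post-termination scanning can only re-initiate at the AUG."""
    seq = (
        "G"            # 1
        "AUG"          # 2-4   uORF start (frame 1)
        "GCC"          # 5-7
        "GC"           # 8-9
        "CUG"          # 10-12 extended proteoform start (frame 0)
        "C"            # 13
        "UAA"          # 14-16 uORF stop (frame 1)
        "GC"           # 17-18
        "AUG"          # 19-21 CDS start (frame 0)
        + _F * 33      # 22-120
        + "UAA"        # 121-123 shared stop (frame 0)
        + _F * 2       # 124-129 trailer
    )
    t = Transcript("fig3_like", seq)
    a = BranchAnnotation(
        starts=(2, 10, 19),
        start_set=frozenset({"AUG", "CUG"}),
    )
    return t, a


def _nf2_like() -> tuple[Transcript, BranchAnnotation]:
    """A 5' leader with an AUG followed by an in-frame AUG in strong
    context (deterministic), whose short uORF feeds the CDS by
    re-initiation. Inserting U between positions 16 and 17 (c.-12_-11insT,
    see NF2_LIKE_INSERTION) creates a new AUG, shifts the uORF frame so
    both upstream translons extend past the CDS start, and thereby
    abolishes CDS translation."""
    seq = (
        _F             # 1-3
        + "AUG"        # 4-6   uAUG1 (leaky)
        + _F * 2       # 7-12
        + "AUG"        # 13-15 uAUG2, strong context (deterministic)
        + "AGC"        # 16-18 insertion site: A|GC -> AUG after insT
        + "UAA"        # 19-21 uORF stop
        + _F * 2       # 22-27
        + "AUG"        # 28-30 CDS start (deterministic)
        + _F * 40      # 31-150
        + "UGA"        # 151-153 CDS stop
        + "GCUAAC"     # 154-159 trailer with the shifted-frame stop
        + _F           # 160-162
    )
    t = Transcript("nf2_like", seq, cds_start=28)
    a = BranchAnnotation(
        starts=(4, 13, 28),
        deterministic_starts=frozenset({13, 28}),
    )
    return t, a


def _gpx4_like() -> tuple[Transcript, BranchAnnotation]:
    """Selenoprotein-style transcript: one AUG and one in-frame UGA that
    is read through by selenocysteine (U) insertion."""
    seq = (
        _F             # 1-3
        + "AUG"        # 4-6
        + _F * 10      # 7-36
        + "UGA"        # 37-39 Sec readthrough stop
        + _F * 8       # 40-63
        + "UAA"        # 64-66
        + _F * 2       # 67-72
    )
    t = Transcript("gpx4_like", seq)
    a = BranchAnnotation(starts=(4,), secs=(37,), sec_aa={37: "U"})
    return t, a


def _peg10_like() -> tuple[Transcript, BranchAnnotation]:
    """-1 programmed frameshift cassette: shift site (i, s) with
    s - i = -1 producing a trans-frame fusion alongside the short
    in-frame product."""
    body = _F * 12
    seq = (
        _F             # 1-3
        + "AUG"        # 4-6
        + _F * 6       # 7-24
        + "AAA"        # 25-27 take-off codon i=25 (slippery-style)
        + _F           # 28-30
        + "UAG"        # 31-33 in-frame (frame 0) stop
        + body[: 63 - 34]  # 34-62 filler
        + "UAA"        # 63-65 shifted-frame (frame 2) stop
        + _F * 2       # 66-71 trailer
    )
    t = Transcript("peg10_like", seq)
    a = BranchAnnotation(starts=(4,), shifts=(ShiftSite(25, 24),))
    return t, a


def _delayed_reinit(
    short_to_long: int = 31, short_to_cds: int = 181, recharge_distance: int = 0
) -> tuple[Transcript, BranchAnnotation]:
    """Minimal delayed re-initiation arrangement: a short uORF, a long
    uORF and the CDS. After the short uORF terminates, the distance the
    subunit must scan before it can rebind the ternary complex decides
    whether it re-initiates at the long uORF (normal conditions) or only
    at the more distal CDS (stress)."""
    if short_to_long % 3 != 1 or short_to_cds % 3 != 1:
        raise ValueError("spacings must be ≡ 1 (mod 3) to keep frame 0")
    if not 12 < short_to_long < short_to_cds - 120:
        raise ValueError("long uORF must fit between short uORF and CDS")
    lu = 12 + short_to_long
    cds = 12 + short_to_cds
    gap1 = lu - 13          # nt between short-uORF stop and long uORF
    gap2 = cds - (lu + 120)  # long uORF is 40 codons = 120 nt
    seq = (
        _F                      # 1-3
        + "AUG" + _F + "UAA"    # 4-12 short uORF (3 codons)
        + _F * (gap1 // 3) + "G" * (gap1 % 3)
        + "AUG" + _F * 38 + "UAA"   # long uORF (40 codons)
        + _F * (gap2 // 3) + "G" * (gap2 % 3)
        + "AUG" + _F * 40 + "UGA"   # CDS (42 codons)
        + _F * 2
    )
    t = Transcript("delayed_reinit", seq)
    a = BranchAnnotation(
        starts=(4, lu, cds), recharge_distance=recharge_distance
    )
    return t, a


def _leaky_chain(k: int = 2) -> tuple[Transcript, BranchAnnotation]:
    """k sequential leaky starts, each heading its own 35-codon translon
    (too long for re-initiation) separated by short spacers: every pair
    of translons is mutually exclusive and each translon's footprint
    density is proportional to its own initiation flux."""
    if k < 1:
        raise ValueError("leaky_chain needs k >= 1")
    parts = [_F]
    starts = []
    pos = 4
    for _ in range(k):
        starts.append(pos)
        parts.append("AUG" + _F * 33 + "UAA")  # 35 codons = 105 nt
        parts.append(_F * 2)                   # 6 nt spacer
        pos += 105 + 6
    t = Transcript(f"leaky_chain_{k}", "".join(parts))
    a = BranchAnnotation(starts=tuple(starts))
    return t, a


_FIXTURES = {
    "fig3": _fig3,
    "nf2_like": _nf2_like,
    "gpx4_like": _gpx4_like,
    "peg10_like": _peg10_like,
    "delayed_reinit": _delayed_reinit,
    "leaky_chain": _leaky_chain,
}


def make_fixture(name: str, seed: int = 0, **kwargs) -> tuple[Transcript, BranchAnnotation]:
    """Build a named model transcript and its branch annotation.

    ``leaky_chain(k)`` may be written literally, or passed as
    ``make_fixture("leaky_chain", k=3)``; ``delayed_reinit`` accepts
    spacing keywords. The ``seed`` argument is accepted for interface
    symmetry — the named fixtures are fully deterministic.
    """
    m = re.fullmatch(r"leaky_chain\((\d+)\)", name.strip())
    if m:
        name, kwargs = "leaky_chain", {"k": int(m.group(1)), **kwargs}
    try:
        builder = _FIXTURES[name.strip()]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None
    transcript, annotation = builder(**kwargs)
    validate_annotation(transcript, annotation)
    return transcript, annotation


def fixture_rdg(name: str, **kwargs) -> RDG:
    """Convenience: build_rdg(*make_fixture(name))."""
    t, a = make_fixture(name, **kwargs)
    return build_rdg(t, a)
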