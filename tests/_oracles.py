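"""Independent reference implementations used only by the tests.

These deliberately avoid the library's graph machinery: the codon
scanner compares 3-mers position by position, the ORF oracle enumerates
(start, stop) pairs exhaustively, and the ribosome walker recursively
simulates a single scanning complex over the raw sequence, branching at
every decision. Tests compare library output against these.
"""

from __future__ import annotations

import random

STOPS = {"UAA", "UAG", "UGA"}


def naive_codon_sites(seq: str, start_set):
    """Position-by-position 3-mer comparison."""
    sites = []
    for pos in range(1, len(seq) - 1):
        mer = seq[pos - 1 : pos + 2]
        if mer in start_set:
            sites.append((pos, (pos - 1) % 3, "start", mer))
        if mer in STOPS:
            sites.append((pos, (pos - 1) % 3, "stop", mer))
    return sites


def naive_start_stop_orfs(seq: str, start_set):
    """Every (start, stop) pair; keep the nearest in-frame stop per start."""
    orfs = set()
    for start in range(1, len(seq) - 1):
        if seq[start - 1 : start + 2] not in start_set:
            continue
        for stop in range(start + 3, len(seq) - 1, 3):
            if seq[stop - 1 : stop + 2] in STOPS:
                orfs.add((start, stop + 2))
                break
    return orfs


def naive_stop_stop_orfs(seq: str):
    """Exhaustive per-frame scan for stop-bounded codon runs."""
    out = set()
    for frame in range(3):
        codon_positions = list(range(frame + 1, len(seq) - 1, 3))
        run_first = frame + 1
        bounded_5p = False
        for pos in codon_positions:
            if seq[pos - 1 : pos + 2] in STOPS:
                if pos > run_first:
                    out.add((run_first, pos + 2, frame, "" if bounded_5p else "5p"))
                run_first = pos + 3
                bounded_5p = True
        if codon_positions and run_first <= codon_positions[-1]:
            out.add(
                (
                    run_first,
                    codon_positions[-1] + 2,
                    frame,
                    ("" if bounded_5p else "5p") + "3p",
                )
            )
    return out


# ---------------------------------------------------------------------------
# recursive single-ribosome walker


def ribosome_walk(transcript, annotation):
    """All trajectories of one scanning complex, as
    (decisions, translated) pairs where ``translated`` is the ordered
    tuple of translated regions, each a tuple of (begin, end) segments.
    """
    seq = transcript.seq
    starts = sorted(annotation.starts)
    det = set(annotation.deterministic_starts)
    secs = set(annotation.secs)
    shifts = {sh.take_off: sh.landing for sh in annotation.shifts}
    reinit_max = annotation.reinit_max_codons
    recharge = annotation.recharge_distance
    trajectories = []

    def scan(pos, min_init, decisions, translated):
        nxt = next((x for x in starts if x >= pos and x >= min_init), None)
        if nxt is None:
            trajectories.append((tuple(decisions), tuple(translated)))
            return
        if nxt not in det:
            scan(nxt + 1, 0, decisions + [("skip", nxt)], translated)
        elongate_from(nxt, decisions + [("init", nxt)], translated)

    def elongate_from(start, decisions, translated):
        def walk(c, seg_begin, segs, consumed, decs):
            while True:
                if c + 2 > len(seq):
                    final = segs + (
                        [(seg_begin, c - 1)] if c - 1 >= seg_begin else []
                    )
                    trajectories.append(
                        (tuple(decs), tuple(translated) + (tuple(final),))
                    )
                    return
                codon = seq[c - 1 : c + 2]
                if codon in STOPS:
                    if c in secs and ("rt", c) not in consumed:
                        finish(c + 2, segs + [(seg_begin, c + 2)],
                               decs + [("sec_term", c)])
                        walk(c + 3, c + 3, segs + [(seg_begin, c + 2)],
                             consumed | {("rt", c)}, decs + [("sec_rt", c)])
                        return
                    finish(c + 2, segs + [(seg_begin, c + 2)], decs)
                    return
                if c in shifts and ("sh", c) not in consumed:
                    landing = shifts[c]
                    walk(c + 3, seg_begin, segs, consumed | {("sh", c)},
                         decs + [("stay", c)])
                    walk(landing, landing, segs + [(seg_begin, c + 2)],
                         consumed | {("sh", c)}, decs + [("shift", c)])
                    return
                c += 3

        def finish(end, segs, decs):
            n_codons = sum(b - a + 1 for a, b in segs) // 3
            new_translated = translated + [tuple(segs)]
            if n_codons <= reinit_max:
                scan(end + 1, end + max(recharge, 1), decs, new_translated)
            else:
                trajectories.append((tuple(decs), tuple(new_translated)))

        walk(start, start, [], frozenset(), decisions)

    scan(1, 0, [], [])
    return trajectories


# ---------------------------------------------------------------------------
# random test-case generation


def random_transcript_and_annotation(rng: random.Random):
    """A random small transcript with a random valid annotation."""
    from rdgkit import BranchAnnotation, Transcript

    n = rng.randrange(120, 400, 3)
    seq = "".join(rng.choice("ACGU") for _ in range(n))
    t = Transcript(f"rand{rng.randrange(1 << 30)}", seq)
    aug_positions = [
        pos for pos in range(1, n - 1) if seq[pos - 1 : pos + 2] == "AUG"
    ]
    stop_positions = [
        pos for pos in range(1, n - 1) if seq[pos - 1 : pos + 2] in STOPS
    ]
    k = min(len(aug_positions), rng.randint(0, 4))
    starts = tuple(sorted(rng.sample(aug_positions, k)))
    secs = ()
    if stop_positions and rng.random() < 0.4:
        secs = tuple(sorted(rng.sample(stop_positions, 1)))
    shifts = ()
    if starts and rng.random() < 0.3:
        i = rng.randrange(starts[0] + 3, min(starts[0] + 60, n - 6))
        s = i + rng.choice([-1, 1, 2, 6])
        if 1 <= s <= n - 2:
            shifts = ((i, s),)
    det = frozenset(
        x for x in starts if rng.random() < 0.2 and x != starts[-1]
    ) if starts else frozenset()
    a = BranchAnnotation(
        starts=starts,
        secs=secs,
        shifts=shifts,
        reinit_max_codons=rng.choice([0, 5, 30, 10_000]),
        recharge_distance=rng.choice([0, 0, 10, 60]),
        deterministic_starts=det,
    )
    return t, a
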