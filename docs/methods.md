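# Methods

## The graph model

`rdgkit` represents the translation of a single mature mRNA as a directed
acyclic graph over the states of one small-subunit-containing complex.
Coordinates are 1-based and inclusive throughout the public interface; the
reading frame of a codon starting at position `p` is `(p − 1) % 3`, and
frames relative to an annotated CDS start are reported additionally where a
CDS anchor is set.

Node kinds:

* `cap` — the unique source (cap loading / pre-initiation assembly);
* `start@x` — the decision state at an annotated initiation codon;
* `sec@y` — the decision state at a readthrough-permissive stop;
* `shift@i>s` — the decision state at a frameshift/bypass site;
* `term@e` — termination at the stop codon ending at nucleotide `e`;
* `runoff` — an elongating ribosome reaching the 3' end without a stop;
* `end3`, `dissoc` — the sinks: 3'-end runoff of a scanning subunit, and
  dissociation after termination.

Edges carry a kind (`scan`, `scan_through`, `initiate`, `elongate`,
`readthrough`, `terminate`, `shift`, `terminate_reinitiate`,
`terminate_dissociate`) and, once assigned, a probability. A node with two
outgoing edges is a branching point; the probability value of a branch is by
convention the probability of its *event* edge (initiate, readthrough,
shift), with the complementary pass edge receiving `1 − p`. Elongation
between decisions is represented by the edges themselves; the edge that
completes a translon carries its id, which keeps per-path translon
attribution unambiguous even when decision histories reconverge.

Two identity rules matter:

* **Start nodes are keyed by position alone.** A start reached by primary
  scanning and by post-termination scanning is the same node, so the
  graph reconverges there. This is what makes the three-start worked
  example come out as 3 branch points / 5 paths with exactly one
  unproductive path.
* **Readthrough, shift and termination nodes are keyed by position plus
  the initiating start and decision history.** Re-initiation competence
  and translon identity depend on the elongation history (two nested
  in-frame starts can share a stop yet differ in competence), so merging
  those states across histories would be unsound. For reporting and
  variant diffs, branch points are deduplicated back to (kind, position).

## Decision semantics

* **Leaky initiation.** Each annotated start branches initiate /
  scan-through unless marked *deterministic* (probability 1, no branch
  node) — used for CDS starts in strong context.
* **Termination.** A stop codon in frame deterministically ends the
  translon. If the translon is at most `reinit_max_codons` long (default
  30, stop codon included) and stop-terminated, the small subunit resumes
  scanning strictly 3' of the stop (no 3'→5' scanning); the *decision* to
  re-initiate happens at the next eligible downstream start. Longer or
  unbounded translons dissociate.
* **Recharge distance.** A post-terminating subunit can only initiate at
  starts at least `recharge_distance` nucleotides past the stop; closer
  starts are scanned through deterministically. Increasing this distance
  reproduces delayed re-initiation: the proximal (long-uORF) start drops
  out and only the distal CDS start remains eligible.
* **Readthrough and shifts.** A `secs` stop branches terminate /
  readthrough; a shift site `(i, s)` reached exactly in its annotated
  frame branches stay / shift, decoding the codon at `i` before jumping to
  `s`. Events encountered in another frame are ignored on that path. Each
  combination of elongation decisions from one start is its own translon,
  so translon identity is path-independent.
* **Starts inside translons.** An elongating ribosome never initiates, so
  a start inside another translon's span is reachable only on paths that
  did not initiate upstream — overlapping translons are therefore mutually
  exclusive per ribosome, which the reachability-based
  `mutually_exclusive` query answers without enumerating paths.

Path enumeration is deterministic (declining choice before event choice at
every branch), guarded by a 10,000-path default limit because conceptual
graphs with many starts explode combinatorially; `count_paths` uses a
topological dynamic program and is always safe. Whenever all branch
probabilities are set, path probabilities are products of branch choices and
sum to 1 (property-tested to 1e-12).

## Quantification

Translation efficiency of a translon is computed as footprints per codon
over its *uniquely mapping* span: the first `trim_codons` codons (default 5)
are discarded to avoid initiation peaks, and with `exclusive_only` (default)
any nucleotide inside another translon's span is excluded. "Uniquely
aligning" is not operationally defined in the field's usage, so two
interpretations are implemented: exclusive positions (default) and an
additional frame-aware mode that counts only positions matching the
translon's A-site codon frame. Units are footprints per codon; lengths are
measured in codons.

`infer_initiation_probability` is the two-translon closed form
`p = Ru / (Ru + Rd)`. `fit_branch_probabilities` generalizes it: for a pure
leaky-scanning chain (every branch a start, one translon per start, no
re-initiation) the closed form `p_k = TE_k / Σ_{j≥k} TE_j` applies exactly,
with the 3'-most start pinned at probability 1 — leakage past the last start
is assumed zero, otherwise the system is not identifiable from TEs alone
(stated in the result metadata). Other graphs are fitted by bounded least
squares (scipy, multi-start from fixed initial points, hence deterministic)
matching flux-predicted to observed TEs, with an optional free scale factor
for the unknown sequencing depth and an identifiability guard comparing free
parameters against observations.

## Simulation and the model transcripts

`simulate_track` deposits `flux × depth` expected footprints per codon at
each codon's first nucleotide (A-site assignment), multiplies the first five
codons by `start_peak_fold` (default 5) to emulate initiation peaks, and
draws Poisson counts (or returns exact expectations with `noise="none"`).
Defaults: depth 50 footprints per codon at unit flux. Elongation is uniform —
no codon dwell-time structure, no coverage gaps, no multimapping ambiguity —
so recovery tests demonstrate correctness of the inference arithmetic, not
robustness to real library artifacts. RNG streams are derived from the seed
and a CRC of the transcript id, so multi-transcript runs reproduce
regardless of order.

The named fixtures are deterministic synthetic sequences built from a
GCC filler (stop- and start-free in every frame) with signal codons planted
at designed positions, each validated against its own annotation at build
time:

* `fig3` — uORF in frame 1 plus CUG and in-frame AUG in frame 0; the CUG
  lies inside the uORF span so re-initiation can only target the AUG.
* `nf2_like` — leaky uAUG, deterministic in-frame uAUG, CDS fed by
  re-initiation; inserting U between positions 16 and 17
  (`c.-12_-11insT`) creates an AUG and frameshifts the uORF so both
  upstream translons extend past the CDS start and the CDS translon
  disappears from the graph.
* `gpx4_like` — one start, one selenocysteine (U) readthrough stop.
* `peg10_like` — one start and a `(i, s)` shift with `s − i = −1`
  producing a two-segment trans-frame translon.
* `delayed_reinit` — 3-codon uORF, 40-codon uORF and CDS with spacings 31
  and 181 nt from the short uORF's stop (configurable), the minimal
  delayed re-initiation arrangement.
* `leaky_chain(k)` — k sequential 35-codon translons (too long to
  re-initiate) with their own stops: mutually exclusive products whose
  densities identify every initiation probability via the chain closed
  form. Used for parameter-recovery tests at depth 50.

## Variant analysis

Supported edits are SNVs, insertions and deletions in transcript
coordinates, with an HGVS-like `c.` syntax (negative offsets for the 5'
leader) anchored at the CDS start; reference alleles are always checked.
Because single-base edits create and destroy codons, allele comparison
re-derives starts per allele from the start set under one policy
(deterministic-start positions and externally evidenced secs/shift sites are
lifted through the edit's coordinate map). Translons are matched across
alleles by mapped start position (ties broken by event signature), and a
matched translon with a different mapped end is reported extended or
truncated; branch points are compared as annotated (kind, position) events.
A translon is *lost* when no ribosome path on the alternate allele reaches
it — the graph-level statement of "this variant silences the CDS".

## Numerical and formatting choices

* Start-to-stop spans include the terminating stop codon; codon counts
  include it. Stop-to-stop runs start after the bounding upstream stop and
  include the terminating stop; runs truncated by transcript ends are
  flagged unbounded rather than clipped.
* T is normalized to U on input; mixed case accepted. Default start set is
  {AUG}; near-cognate sets are provided as a constant.
* Readthrough residues translate to the annotation's per-site symbol
  ('U' for selenocysteine sites, 'X' generic), overridable per call.
* BED exports are 0-based half-open with translon segments as blocks; the
  two blocks of a −1 frameshift overlap by one base, which some strict BED
  consumers reject — the GFF3 export (1-based, segment children) is the
  lossless form. JSON exports are schema-versioned and re-importable; the
  compact notation round-trips (`parse(format(a)) == a`).
* The bare notation of the array form (`starts1;13`) is accepted on input;
  the canonical output always uses parentheses, which disambiguates the
  comma pairs of shift clauses. The notation does not carry a transcript
  id or the re-initiation policy; the JSON annotation document does.

## Known limitations

* Single-isoform only: graphs live in mature-transcript coordinates; no
  splice graphs, genome projection or multi-isoform loci.
* No kinetic modelling — decisions are probabilities, not mechanisms; no
  Kozak-strength priors, IRES entry, or StopGo/2A.
* Branch-point *locations* are taken as given; only their probabilities
  are inferred. Model comparison to discover branch points from data is
  future work.
* The simulator's uniform-elongation assumption means passing recovery
  tests bounds arithmetic correctness, not performance on real libraries
  with dwell-time structure, ligation bias or ambiguous mapping.
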