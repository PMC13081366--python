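# Methods

This note records the models, rules and numerical choices behind `satarch`,
and what the synthetic-data tests do and do not establish about real data.

## Coordinates, determinism, formats

All internal coordinates are 0-based half-open; GFF3 is written 1-based
inclusive and BED stays 0-based half-open. Every sort uses the key (contig,
start, end, strand with '+' < '−' < '.'), so all outputs are byte-stable
across runs. Non-ACGTN input characters collapse to N and never count as
matches anywhere downstream.

## Monomer annotation

The search contract is "every local alignment of a consensus, either
strand, passing the identity and query-coverage filters". The engine is
NCBI `blastn -task blastn` with `-dust no -soft_masking false` (the targets
are low-complexity tandem repeats; default masking would delete them),
`-evalue 1e-5` and one thread. Filtering — percent identity ≥ 70 and query
coverage ≥ 70% of the consensus length (qcovhsp semantics, computed in our
code from the raw HSP fields) — is the normative part; engine internals
(word size, penalties) are deliberately not part of the contract.
Consensuses shorter than 20 bp are rejected: seeding is unreliable there.

Overlap resolution is greedy by descending bitscore (ties: higher identity,
then leftmost, then '+'): a hit is kept iff its overlap with every accepted
hit is ≤ 10% of the shorter of the two. The 10% bound admits the 1–7 bp of
end fuzz that alignment trimming produces in tandem context while
forbidding nested or phase-shifted duplicates. On tandem arrays this
matters: because a window out of register with the planted copies matches
the consensus only at chance level, the surviving hits are phase-locked to
the true monomers, which is why monomer-level recovery on synthetic arrays
is essentially exact.

## Arrays and the gap rule

Monomers of one family join an array when their gap is at most one
consensus monomer length, strands ignored. This single-linkage rule is
provably the fixed point of the iterative procedure "expand the region by
one monomer length, absorb any monomer found there, repeat", and the test
suite checks that equivalence against an explicit iterative implementation
on random inputs. The boundary case gap = L merges. Array intervals span
first monomer start to last monomer end (expansion margins are scaffolding,
not sequence claims). A family counts as a satellite when some array holds
at least five tandem monomers. Array-length KDEs use a Gaussian kernel with
Scott's bandwidth; they are exports for plotting and feed no decision.

## Subarrays, inversion points, macro-dyad metrics

Within each array the gap rule is re-applied per strand; the resulting
blocks, clipped to the array span and ordered, are the subarrays, and
strands must alternate (same-strand neighbours are merged defensively). An
inversion point sits at the midpoint of the gap between adjacent
opposite-strand blocks — the midpoint is the only choice symmetric under
reverse complementation of the contig, and in the generator the planted
variant element fills that gap, so the midpoint coincides with the variant
centre. Macro-dyad metrics report the signed left-minus-right length
difference per inversion point and the largest flanking-pair total
(symmetry span). One-directional arrays are reported with n_subarrays = 1
and excluded from difference statistics.

Inversion-site windows default to radius 200 bp: wide enough to span the
degenerate subunit found at inversion points (~110–200 bp in the systems
this models), narrow enough to stay inside the flanking monomers.

## Pairwise identity and clustering

All identity computations use one pinned scheme: global alignment with
match +1, mismatch −1, gap open −5, gap extend −1; identity =
matches / alignment columns, so gap columns count as differences.
Single-linkage clustering at an identity threshold (default 90%) is exactly
the connected components of the thresholded pairwise-identity graph; two
exact shortcuts (identity can never exceed min(len)/max(len), and pairs
already connected need no alignment) keep it near-linear on clustered
inputs without changing the result. Cluster consensus is majority rule over
columns after anchoring every member to the longest one; clusters with
fewer than three members are reported but flagged minor. Mean pairwise
identity uses all pairs, or a seeded subsample of 2000 pairs above that.

## Junctions, breakpoints, cassettes

Adjacencies pair arrays of two families that are genomic neighbours (no
third array between them) with gap ≤ 1 kb, matching the observation that
most inter-array distances in such systems fall under a kilobase. Junctions
are extracted with 250 bp pads into each flanking array — a window choice,
flagged as such; the element lengths themselves (e.g. 389 bp and 124 bp in
the planted architecture) are properties of the data, not of the window.

Chimeric breakpoint detection follows the definition directly: the split
maximizing (local score of the prefix vs family-A material) + (suffix vs
family-B material), donors tiled into tandem context and tried in both
orientations; the split is found on a 16 bp grid and refined at 1 bp, ties
to the left. The duplicated motif is the longest string (4–20 bp) that both
terminates the aligned A-donor segment and begins the aligned B-donor
segment; the deletion length is the largest donor-side gap run in the
prefix alignment. Junction sides scoring below 20 give an "unclassified"
result rather than an exception.

Cassette typing is structural, not sequence-literal: junction clusters
whose median adjacency gap is below 20 bp are plain abutments and get no
type; element-bearing clusters are typed by which side of the minor-family
array they occupy (entry = TRANS_1-like, exit = TRANS_2-like), and several
clusters may share a type — e.g. orientation variants of the same element
context. The census then marks each minor array for entry transition, exit
transition and internal inversion point, and the Venn counts partition the
array set exactly.

Array-edge refinement scans outward in 1 bp steps, testing the 4k-bp window
on the array side of each position against the family's consensus k-mer set
(tandem context, both strands, k = 12). Against a sharp edge the last
passing position overshoots by (1 − threshold) × (window − k + 1) bp, a
bias that follows directly from the window geometry, so the estimate is
debiased by exactly that amount: at threshold 1.0 the boundary lands on the
last consensus base; at the default 0.5 it is an unbiased edge estimate
with a few bp of noise.

## Microsatellite runs and linkage

A run is a maximal alternating substring of the two motif bases — i.e. a
substring of the infinite motif repetition starting at either rotation —
with the unit count floored to whole motif copies; detection is exact (zero
mismatches), default n ≥ 5 units. Anchoring the pattern to one rotation
would split runs arbitrarily at phase boundaries. Runs are first trimmed
against the satellite family's monomer annotation, then labelled linked
when within 100 bp of a family monomer. The 100 bp linkage gap is a
documented knob: no numeric rule exists in the literature this models; the
value is conservative relative to reported spacer medians (~42 bp) and
should be varied in sensitivity analyses on real data.

## Comparative scanning and geometry

The approximate k-mer scan computes, for every text position, the exact
minimal edit distance of each 16-mer against windows ending there (Myers
bit-parallel semi-global algorithm, one machine word per pattern, compiled
with numba). This is complete for every locus at distance ≤ 3 by
construction — no seeding heuristic, hence no completeness argument needed;
a pigeonhole-seeded design was considered and rejected because 4 bp exact
seed parts match essentially everywhere, making verification the bottleneck.
End positions within ±3 bp reporting comparable matches collapse to the
best (minimal distance, leftmost, lexicographic k-mer).

F81 distances use d = −E·ln(1 − p/E) with E = 1 − Σπᵢ²; p is computed with
pairwise deletion over columns where both rows carry A/C/G/T, and base
frequencies are estimated once from the whole input (the common behaviour
of reference implementations, and more stable for small samples than
per-pair estimates). Saturated pairs (p ≥ E), where the formula is
undefined, return infinity, are flagged, and are imputed with 1.5× the
largest finite distance for PCA and graph construction. Sequences enter a
common column set by pairwise anchoring to the longest sequence (insertions
relative to the anchor are dropped); this replaces a full MSA and is pinned
so results are reproducible. PCA operates on the distance-matrix rows,
column-centred — the distance matrix, not a one-hot sequence encoding, is
the object the downstream analyses share — and the choice is isolated in
one function. k-NN graphs link each sequence to its 5 nearest by F81
distance, ties by label order, mutual selections deduplicated.

## The synthetic architecture

The generator's defaults are the reference study conditions, chosen once:

* 5 Mb single contig, background i.i.d. at 70% A+T (A=T, C=G).
* **MajSat**: 340 bp monomer = two 170 bp subunits at 20% mutual
  divergence. **MinSat**: 700 bp monomer = seven 100 bp subunits at 25%
  divergence, with subunits E–F replaced by the reverse complement of B–C
  (an intra-monomer inverted block ~200 bp). **AcSat**: 180 bp monomer with
  G/T-forced termini so (AC)n spacers never extend into monomers.
* 40 array loci: 10 major arrays (1–4 oriented blocks, block copy number
  log-normal with median 20, probabilities 0.30/0.45/0.15/0.10 for 1–4
  blocks — two subarrays predominate), 4 standalone minor arrays, 6 AcSat
  arrays (12–25 copies, spacer units 4 + Geometric(0.042), capped below the
  monomer length so the gap rule always holds; median spacer ≈ 42 bp), and
  20 cassettes; plus 40 background (AC)n decoys (units 4 + Geometric(0.35),
  median ≈ 12 bp). Loci are placed with ≥ 2 kb of background between them
  so truth arrays are unambiguous under the gap merge.
* Per-copy substitution divergence 5% (exercises clustering, far from the
  30% annotation limit); planted elements drift 1% per instance (their
  within-type conservation mirrors the ~98–99% reported for real inversion
  site families).
* Inversion variants: major-family boundaries carry one of two conserved
  variants of the distal subunit at 23.5% or 10.7% divergence; minor-family
  boundaries carry a variant of the terminal two subunits differing at
  exactly 12 positions.
* Transition elements: TRANS_1 is 389 bp of major-satellite material with a
  60 bp internal deletion, built from a donor window starting mid-monomer
  (offset 97) so its two segments occupy overlapping monomer phases — no
  colinear alignment of the consensus can reach the coverage filter across
  it, keeping the element out of the monomer annotation (its real
  counterpart is likewise too degenerate to annotate). TRANS_2 is a 124 bp
  chimera whose minor part ends with TTCAAT and whose major part begins
  with it, each part continuing its neighbour's tandem register.
* Cassette layout: major block (+), TRANS_1, minor array (entry block '−'
  when an inversion is present, exit block always '+'), TRANS_2, major
  block (+). Element presence uses probabilities 0.90 (entry), 0.82 (exit)
  and 0.80 (inversion), realized by largest-remainder allocation over the
  eight joint cells and seed-shuffled: the planted population carries
  exactly the implied composition, in particular a triple-element rate of
  round(n × 0.59)/n — 59% at n = 200 — rather than a Bernoulli-sampled
  approximation of it. This makes population-level rates properties of the
  design, not of sampling luck.
* Microsatellite truth is obtained by scanning the *finished* genome with
  an independent regex and applying the same trim-and-link definition
  against the planted monomers, so background sequence that extends a
  planted run, or spontaneous background runs, are labelled correctly.

Identical spec + seed give byte-identical genomes and truth (one numpy
Generator in a fixed draw order).

**What passing these tests shows — and does not.** Recovery is measured
against i.i.d.-substitution copies on a clean single-contig background with
non-overlapping, well-separated arrays. Real satellite regions add indels,
higher-order repeats, nested insertions (transposons), assembly collapse
and contig breaks mid-array; none of these are simulated, so exact recovery
here demonstrates the correctness of the rules and their implementations,
not annotation completeness on real assemblies. Real-genome runs should
treat the published thresholds as the defaults they are and inspect the
flagged/minor clusters.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the 5 Mb
reference spec (~1,200 planted monomers), the cassette census additionally
on a 4.5 Mb, 200-cassette population, oracle comparisons on 10³ random
interval cases, a 100 kb microsatellite scan, a 2 kb approximate-scan
brute-force comparison, and 36-sequence distance/PCA problems. These sizes
were chosen as the smallest at which every rule is exercised with
comfortable statistical margins.

## Known limitations

* The annotation engine is an external dependency (BLAST+); the filtering
  semantics are pinned here but alignment end-trimming (±a few bp) is not,
  which is why boundary assertions carry small tolerances.
* Only substitution divergence is simulated by default (an indel knob
  exists at the copy level but is off); edit-distance-based stages are
  nevertheless exercised directly in unit tests.
* F81 is the only substitution model; saturated pairs are imputed, not
  modelled.
* Microsatellite detection is limited to perfect dinucleotide runs by
  design; interrupted-run models are out of scope.
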