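# satarch

Satellite DNA annotation and long-range architecture analysis.

Satellite DNAs (satDNAs) are tandemly repeated sequences that can occupy a
third or more of an animal genome, concentrated in (peri)centromeric
heterochromatin. With long-read assemblies it has become possible to ask not
just *how much* satellite a genome carries but *how its arrays are built*:
monomers flip orientation inside arrays, producing kilobase-scale
palindrome-like arrangements (**macro-dyad symmetries**) with conserved
sequence variants at the inversion points; a minor satellite can be embedded
in a major one as a stereotyped **cassette** delimited by conserved
transition elements; and satellite monomers can alternate with
microsatellite spacers such as (AC)n. `satarch` is a library and CLI for
beetle-satellitome-style analyses of this kind, aimed at researchers
studying repeat organization in assembled genomes.

## What it computes

* **Monomer annotation** — local alignments of consensus monomers against a
  genome (NCBI blastn as the engine, low-complexity filtering off), retained
  at ≥70% identity and ≥70% query coverage, with best-score-per-locus
  overlap resolution. A family is a *satellite* if some array holds ≥5
  tandem monomers.
* **Arrays** — single-linkage grouping of same-family monomers with gap ≤
  one monomer length *L* (the fixed point of iteratively expanding each
  annotation by *L* and absorbing neighbours), strand-agnostic.
* **Macro-dyad symmetry** — per-strand re-application of the gap rule
  splits each array into oriented subarrays; each boundary between
  opposite-strand blocks is an inversion point (midpoint of the inter-block
  gap). Windows around inversion points are clustered by global-alignment
  identity (match +1, mismatch −1, gap open −5, extend −1; identity =
  matches/columns) and their consensus compared against canonical subunits.
* **Junction grammar** — adjacencies between arrays of two families,
  junction extraction and identity clustering, chimeric-breakpoint
  detection (the split maximizing prefix-vs-donor-A plus suffix-vs-donor-B
  local scores, reporting duplicated breakpoint motifs and internal
  deletions), k-mer–based array edge refinement, and a cassette census: per
  minor-family array, presence of an entry transition, an exit transition
  and an internal inversion, summarized as Venn counts.
* **Microsatellite conjunction** — maximal perfect dinucleotide runs
  (phase-agnostic, n ≥ 5 units), trimmed against satellite annotations and
  classified as satellite-linked (within 100 bp of a monomer) or unlinked,
  with length statistics per class.
* **Comparative geometry** — 16-mer sets from consensus sequences scanned
  against other genomes under Levenshtein distance ≤ 3 (a complete
  bit-parallel semi-global scan, no seeding heuristic); F81 genetic
  distances d = −E·ln(1 − p/E), E = 1 − Σπᵢ²; PCA of distance-matrix rows;
  5-nearest-neighbour sequence graphs.
* **Synthetic genomes** — `satarch.simulate` plants the whole architecture
  (subunit-structured families, oriented subarrays, inversion-site
  variants, transition elements with a 60 bp deletion and a duplicated
  TTCAAT breakpoint motif, cassettes, (AC)n spacers and decoys) into an
  A+T-rich background and emits complete ground truth, so every stage is
  verifiable without downloading anything.

## Worked example

Generate a 1.2 Mb synthetic genome with the default planted architecture
and run the full pipeline on it:

```bash
satarch simulate --out-dir sim --seed 42 --genome-length 1200000
satarch all --genome sim/genome.fa --library sim/library.fa \
            --out-dir out --seed 42
```

`out/annotation_summary.tsv` reports the annotated copies per family:

```
family_id  copy_count  total_bp  genome_fraction
AcSat      128         22982     1.92
MajSat     1025        348090    29.01
MinSat     79          55271     4.61
```

i.e. the major satellite alone covers 29% of this genome. The array stage
(`out/array_stats.tsv`) finds 50 MajSat arrays (median 3.1 kb, up to
42.5 kb) and 24 MinSat arrays (median 1.85 kb); both families pass the
≥5-tandem-copies satellite criterion. `out/cassette_report.json` shows the
junction clusters between the two families — two prevalent types, one on
the entry side of the minor arrays (15+4 junctions) and one on the exit
side (16) — and the cassette census over the 24 minor arrays:

```
"venn": {"T1&T2&INV": 12, "T1&INV": 3, "T1&T2": 3, "INV": 3,
         "T2&INV": 1, "T1": 1, "none": 1}
```

so 12 minor arrays carry all three cassette elements (both transitions plus
an internal inversion point; 37 inversion points were found in total, in
clusters with 92–94% mean within-cluster identity). Finally
`out/microsat_stats.tsv` separates the (AC)n census into satellite-linked
and unlinked runs:

```
          count  total_bp  median_length
linked    122    6898      44
unlinked  40     560       12
```

— linked spacer runs are markedly longer (median 44 bp) than background
runs (median 12 bp), the signature of a genuine satellite/microsatellite
conjunction.

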