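# Methods

This note documents the models and procedures implemented in `metaprof`,
the parameters that matter, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Taxonomy model

The reference taxonomy is a rooted tree with an ordered official rank
vocabulary: root, superkingdom, phylum, class, order, family, genus,
species. NCBI's "superkingdom" and GTDB's "domain" occupy the same slot so
profiles built against either taxonomy live on one rank axis; GTDB's two
domains are attached below a single synthetic root so LCA queries across
domains are defined. Non-official nodes ("no rank", strains, genome
accessions below species) are retained in the tree but skipped by rank
projection, since evaluation happens only at the six ranks phylum through
species. Retired (merged) taxon ids are remapped transparently at lookup;
ids absent from both the node set and the merged map raise a lookup error
rather than being silently dropped — hit tables built against an older
taxonomy release should fail loudly, not lose hits.

## Annotation

**r-window LCA.** For a query with hits, hits with
`bitscore ≥ (1 − r) · top` are kept (boundary inclusive: ties with the top
hit must never be dropped) and the query is assigned the LCA of their
subject taxa. Default r = 0.10. Widening the window can only move the call
rootward (checked as a property).

**Bit-score voting.** Each annotated ORF contributes its *top* bit-score to
every taxon on the lineage of its LCA call; supports are normalised by the
summed top scores over annotated ORFs, so the root always has support 1 and
supports are non-increasing along any lineage. The assigned taxon is the
deepest with support **strictly** greater than f. With f ≥ 0.5 at most one
child per node can qualify, so the winner is found by a single root-to-leaf
descent; an exact 50/50 species split escalates to the shared ancestor. Two
conventions are deliberate and worth noting:

* the per-ORF contribution is the top-hit bit-score, not the sum over the
  ORF's retained hits — the simplest rule consistent with per-rank supports
  summing to ≤ 1;
* ORFs without hits are excluded from the denominator, so a sequence with
  one annotated ORF has support 1.0 rather than being diluted by hitless
  ORFs.

Voting is invariant to uniform scaling of all bit-scores, and raising f can
only move the call rootward (both checked as properties; the descent is
also cross-checked against a brute-force evaluator that scores every tree
node independently).

Bins (MAGs) are voted over the pooled ORF annotations of all member
contigs. Contigs that the voting stage cannot annotate (no ORF hits) can
fall back to a direct whole-contig r-window LCA over a contig-level hit
table.

## Read integration

Mappings are filtered to primary records with MAPQ ≥ 2 (a minimum
acceptable score; the boundary value is kept). Among a read's surviving
mappings the highest MAPQ wins; equal-MAPQ ties are broken by a seeded
random draw over a sorted candidate list, making the step reproducible.
Filtering precedes tie-breaking. Paired reads are treated as independent
records, so profile denominators are unambiguous read counts.

The cascade assigns, per read, the first available of: MAG annotation (if
its contig is binned and the bin is annotated), contig voting annotation,
direct contig annotation, direct read annotation, else unclassified. An
annotation whose taxon is absent falls through to the next signal rather
than blocking the read. Mode `mc` skips both direct signals; mode `cr`
skips MAG annotations; `mcr` uses everything.

## Profiling

At each official rank a read contributes to the projection of its taxon
onto that rank; reads annotated above the rank contribute to neither a
taxon nor the unclassified bucket there, so classified mass is
non-increasing with depth. Fractions are over the total number of
sequenced reads. The minimum-abundance cut-off (default 0.001 % = 1e-5)
removes taxa independently at each rank; it is idempotent and monotone.
Genome-size normalisation divides each fraction by the taxon's weighted
mean genome size — falling back to the nearest ancestor with a size entry —
and rescales so retained per-rank mass is unchanged; it is invariant to
uniform size scaling. Profiles are written in CAMI-profiling-style columns
(taxon id, rank, lineage id path, lineage name path, percentage) with
extra header lines (total reads, per-rank unclassified percentages) so the
round-trip is lossless.

## Evaluation metrics

* **Per-read scoring**: at each rank, correct / incorrect / unannotated by
  comparing rank projections of prediction and truth; TPR = correct /
  (correct + incorrect), defined as 0 when nothing is annotated at the
  rank. Overall accuracy (correct / total) is reported alongside as a
  convenience.
* **L1** over the union of taxa at one rank; range [0, 2], 2 iff supports
  are disjoint and both profiles carry full mass.
* **Precision / sensitivity** from binary detection counts under an
  abundance cut-off applied to the predicted profile.
* **Weighted UniFrac**: mass annotated at internal ranks stays on the
  internal node (it is not spread to leaves); both distributions are
  renormalised over their classified mass (EMD requires equal totals, and
  unclassified fractions differ between profiles), numerical residual
  balancing at the root. Edge lengths are 1 per official-rank step —
  non-official intermediate nodes do not add length; when a lineage skips
  a rank the edge spans the corresponding number of rank steps. The
  distance is computed by the bottom-up push-to-parent scheme (traverse
  levels deepest first, push each node's signed surplus to its nearest
  shallower official-rank ancestor, accumulate |pushed| × steps), which on
  a tree equals the exact transport optimum; the test-suite verifies this
  against a min-cost-flow linear program on random small instances to
  1e-9.
* **Rarefaction**: fractions 1–100 % of reads, 10 repeats each,
  subsampled **without replacement** (the standard rarefaction
  convention), profile rebuilt on the subsample's own denominator before
  the optional cut-off.

## Synthetic-data generator

The generator emulates a simulated-benchmark evaluation setting: a random
rank-complete taxonomy (species grouped bottom-up with fanout 2–4), a
log-normal species abundance distribution (μ = 0, σ = 1; σ = 0 degenerates
to uniform), reads drawn from it, a configurable assembled share of reads
mapped (primary, MAPQ 30) to pure per-species contigs, a binned share of
contigs placed in single-species bins (an optional contamination knob
mis-assigns contigs to foreign bins), and hit tables for ORFs, contigs and
reads. The ground-truth profile is the *realised* per-read profile, so a
noiseless run can recover it exactly. Defaults are chosen to resemble a
moderately well-assembled benchmark sample at desk scale: 100 species,
20,000 reads, assembled_fraction 0.8, binned_fraction 0.9 (so ~72 % of
reads are MAG-mapped), hit_noise 0.3, novel_fraction 0.1. Bit-scores are
synthetic (ORF/contig hits ~100, read hits ~50–70, decoys scaled inside or
outside the r-window as needed) since only relative scores enter the
algorithms.

Noise has two channels. `hit_noise` corrupts a direct read hit's subject
to a species outside the true genus. `novel_fraction` marks species as
absent from the reference: their queries hit 2–3 sister species (under the
nearest ancestor with other species descendants) with scores inside the
r-window, so LCA lands at genus rank or above — the behaviour expected of
novel lineages.

**What the generator does not emulate:** sequences and their error models
(no bases are generated — every stage consumes mappings and hit tables),
chimeric contigs and mis-assemblies, uneven coverage within genomes,
paired-end structure, and reference databases with mis-annotated entries.
Passing tests therefore demonstrate the correctness of the integration and
profiling logic under planted signals, not profiler performance on real
data.

## Problem sizes and numerical choices

Tests and the acceptance script run on communities of 8–50 species and
600–10,000 reads — large enough for stable fraction estimates while the
full suite completes in seconds. Fractions use double precision
throughout; profile-sum invariants allow 1e-9 slack; exclusive UniFrac
node masses below 1e-12 are treated as zero. Tie-breaks: equal-MAPQ
mappings via a seeded draw over sorted candidates; equal-support voting
children (possible only at support = f exactly) resolve by score then id,
though the strict > f rule makes this unreachable for f ≥ 0.5.

## Known limitations

* Abundances are sequence abundances (read fractions); no coverage- or
  base-weighted variant.
* The voting contribution rule (top-hit bit-score per ORF) is one of two
  defensible readings of bit-score voting; the alternative (summed
  retained scores per ORF) would change supports but not the normalisation
  structure.
* The per-rank abundance cut-off is a pure percentage rule; no
  read-count-based variant is provided.
* Deleted taxon ids are surfaced as errors, not remapped; users with stale
  hit tables must supply the matching merged-id map.
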