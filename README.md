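# metaprof

Integrated taxonomic profiling of shotgun metagenomes from MAG, contig and
read signals.

## The problem

Direct homology annotation of short metagenomic reads is noisy: conserved
regions, horizontal gene transfer and missing reference taxa all produce
spurious species-level calls. Assembled contigs — and bins of contigs
(metagenome-assembled genomes, MAGs) — carry far more taxonomic signal and
can be annotated much more reliably, but they rarely cover all of the data.
`metaprof` resolves this trade-off the way an integrated profiler does:
every read inherits the **most reliable taxonomic signal available to it**

```
MAG  >  contig (ORF voting)  >  contig (direct)  >  read (direct)  >  unclassified
```

and the per-read calls are summed into per-rank relative-abundance
profiles. The package is aimed at microbiome researchers who already have
read→contig mappings (e.g. from BWA-MEM) and protein-space homology hit
tables (e.g. DIAMOND tabular output) and want integrated, per-rank
sequence-abundance profiles plus the standard benchmark metrics.

## The model

Two primitives drive every annotation:

* **r-window LCA.** For one query with hits `(taxon_i, bitscore_i)`, keep
  the hits with `bitscore ≥ (1 − r) · max_i bitscore` (default r = 0.10)
  and assign the lowest common ancestor of the retained subject taxa.
  Queries matching several related organisms land on the ancestor they
  share — novel sequences are annotated at an appropriately high rank.

* **Bit-score voting.** Each ORF on a contig (or in a bin) pushes its top
  bit-score onto every taxon along the lineage of its LCA call. Supports
  are normalised by the summed top scores, so at any rank competing taxa
  sum to ≤ 1. The sequence is assigned the deepest taxon with support
  strictly greater than f (default 0.5, i.e. a majority); a 50/50 species
  split escalates to the shared genus. Values f < 0.5 (multiple winners)
  are not supported.

Mappings are restricted to primary records with MAPQ ≥ 2 (configurable);
equal-MAPQ ties are broken by a seeded random draw. Profiles report
*sequence abundance* (fraction of sequenced reads); an optional
genome-size table converts them to taxonomic abundance (genome copies).
Profiles are compared with per-rank L1 distance (range 0–2), binary
detection precision TP/(TP+FP) and sensitivity TP/(TP+FN) under a per-rank
minimum-abundance cut-off (default 0.001 %), and the weighted UniFrac
distance — the earth-mover's distance on the taxonomy tree with an edge
length of 1 per official-rank step.

## Worked example

Simulate a 20-species community (2,000 reads, 80 % assembled, 90 % of
contigs binned, 30 % noisy direct hits), run the integrated workflow, and
score it against the planted truth:

```python
import metaprof as mp

config = mp.SimulationConfig(seed=1, n_species=20, n_reads=2000)
ds = mp.simulate_dataset(config)
result = mp.run_on_dataset(ds, mode="mcr")

for source, n in sorted(result.source_counts.items()):
    print(f"{source:>12}: {n:5d} reads ({100 * n / config.n_reads:.1f}%)")

scores = mp.score_read_annotations(result.read_annotations, ds.truth.read_taxa, ds.tree)
print(scores.to_frame().to_string(index=False))

for rank in ("genus", "species"):
    print(f"L1 at {rank}: {mp.l1_distance(result.profile, ds.truth.profile, rank):.4f}")
print(f"weighted UniFrac: {mp.weighted_unifrac(result.profile, ds.truth.profile, ds.tree):.4f}")
```

prints

```
  contig_cat:   113 reads (5.7%)
         mag:  1443 reads (72.2%)
 read_direct:   444 reads (22.2%)
   rank  correct  incorrect  unannotated      tpr  accuracy
 phylum     2000          0            0 1.000000    1.0000
  class     2000          0            0 1.000000    1.0000
  order     2000          0            0 1.000000    1.0000
 family     1925         75            0 0.962500    0.9625
  genus     1864        136            0 0.932000    0.9320
species     1608        136          256 0.922018    0.8040
L1 at genus: 0.0200
L1 at species: 0.1570
weighted UniFrac: 0.1930
```

72 % of reads were annotated via MAGs and another 6 % via contigs; only the
22 % unassembled reads fell back to noisy direct annotation, which is why
the species-rank true-positive rate (correct / annotated) stays at 0.92
even though 30 % of direct hits point at the wrong clade. Running the same
dataset with direct read annotation alone drops species TPR to 0.68.

The same stages are available from the shell:

```sh
metaprof simulate --seed 1 --n-species 20 --n-reads 2000 --out sim/
metaprof annotate --nodes sim/taxonomy/nodes.dmp --mappings sim/mappings.tsv \
    --contig2bin sim/contig2bin.tsv --orf-hits sim/orf_hits.tsv \
    --orf2contig sim/orf2contig.tsv --contig-hits sim/contig_hits.tsv \
    --read-hits sim/read_hits.tsv --mode mcr --out run/
metaprof evaluate --nodes sim/taxonomy/nodes.dmp --predicted run/profile.tsv \
    --reference sim/truth_profile.tsv --out metrics.tsv
metaprof rarefy --nodes sim/taxonomy/nodes.dmp \
    --annotations run/read_annotations.tsv --rank species --out rarefaction.tsv
```

Every run writes a `manifest.json` with its parameters, seed and input
checksums.

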