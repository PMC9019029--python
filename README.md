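# betapipe

Alignment-free phylogenomics for large panels of closely related genomes
sequenced at low coverage — the workflow used to resolve relationships among
wild and cultivated beets, rebuilt as a tested, reusable Python package.

## Who this is for

Population genomicists and germplasm curators who have shallow (~5-fold)
whole-genome sequencing for hundreds of accessions and want pairwise genomic
distances, distance-based phylogenies, and a reproducible way to propose
(sub-)species assignments for unlabeled accessions — without read mapping,
variant calling, or a reference genome.

## The method

Each accession's reads are reduced to a **bottom-s MinHash sketch**: the
`s = 10000` smallest 64-bit hashes over its canonical 21-mers, ignoring
k-mers seen fewer than `m = 2` times (singletons are dominated by sequencing
errors at low coverage). Comparing two sketches estimates the Jaccard index
`j` of the underlying k-mer sets, which the **Mash distance**

```
D = -ln( 2j / (1 + j) ) / k
```

converts into a per-base mutation-distance proxy. The matrix of all pairwise
`D` feeds a **Fitch–Margoliash least-squares tree** (weighted criterion
`sum (d_ij - p_ij)^2 / d_ij^2`, non-negative branch lengths, randomized
addition orders plus NNI and global SPR rearrangements). Supporting
machinery includes Trimmomatic-style quality trimming, coverage estimation
and fragment downsampling, k-mer-based organelle read removal, **Rogers'
genetic distance** on SNP-array genotypes, the **Mantel permutation test**
for comparing distance matrices, and **quartet distance** for comparing tree
topologies.

Because the real panel is hundreds of deposited sequencing runs, the package
ships a first-class synthetic-data generator (`betapipe.simdata`): diploid
Mbp-scale genomes evolved on a known tree (two deep sea-beet-like clades
with a shallow cultivar clade nested inside one of them, plus an outgroup),
2x125 nt paired reads with errors, within-accession duplicates that differ
only at resampled heterozygous sites, organelle spike-ins, and
tree-consistent biallelic genotypes. Every validation experiment is scored
against that known truth.

## Worked example

```python
import betapipe as bp

# a 13-accession synthetic panel: 3 groups x 4 accessions + outgroup
truth = bp.make_scenario("beet-mini-wide", seed=42)

sketches = []
for i, name in enumerate(truth.taxa):
    reads = bp.simulate_reads(truth.haplotypes[name], coverage=5.5, seed=100 + i)
    reads = bp.trim_reads(reads)                      # LEADING/TRAILING 28, window 5:15, MINLEN 50
    sketches.append(bp.build_sketch(reads, name=name))  # k=21, s=10000, m=2

dm = bp.pairwise_mash(sketches)
print(f"mean pairwise Mash distance: {dm.mean_offdiagonal():.4f}")

tree = bp.fitch_margoliash(dm, bp.SearchConfig(jumbles=5, seed=42))
rooted = bp.root_with_outgroup(tree, ["outgroup"])
print(bp.quartet_distance(tree, truth.tree), "quartets differ from the truth tree")
```

prints

```
mean pairwise Mash distance: 0.0803
0 quartets differ from the truth tree
```

i.e. the sketch distances sit in the few-percent range typical of
within-species beet comparisons, and the 13-taxon topology is recovered
exactly. A `betapipe` console script exposes the same steps for files on
disk (`betapipe simulate | trim | downsample | sketch | dist | fitch |
qdist | mantel | run-titration | run-duplicates | run-crossval`).

## Layout

| module | contents |
| --- | --- |
| `betapipe.simdata` | scenario/truth generation, genome evolution, read simulation, genotypes |
| `betapipe.readqc` | quality trimming, coverage, downsampling, organelle k-mer filter |
| `betapipe.sketch` | canonical k-mers, bottom-s MinHash, Jaccard, Mash distance, sketch I/O |
| `betapipe.distance` | distance matrices, Rogers' distance, Mantel test, PHYLIP I/O |
| `betapipe.tree` | Fitch–Margoliash search, NJ, rooting, quartet distance, Newick I/O |
| `betapipe.experiments` | seeded validation experiments and the unknown-accession classifier |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
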