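# tetrasig

K-mer based diagnosis of polyploid origin, plus companion analyses, as a
tested, reusable pipeline:

1. **Chromosome-enriched k-mer signature** — count canonical 13-mers per
   chromosome of a haplotype-resolved assembly, keep k-mers that occur often
   globally and are concentrated on one chromosome, cluster chromosomes
   (UPGMA on Bray–Curtis profile distances) and test whether every homologous
   group's haplotypes form a clade (auto-polyploidy) or chromosomes co-cluster
   by subgenome instead (allo-polyploidy), with a seeded permutation null.
2. **Smudge analysis** — extract heterozygous k-mer pairs (two k-mers
   differing at the middle position, orientation-canonicalized) from read
   k-mer tables, estimate the 1× coverage, and assign each pair to a copy
   number pattern (AB, AAB, AAAB, AABB, …); the dominant pattern is the
   ploidy signature.
3. **SNP hard-filter cascade** — optional two-call-set intersection, then
   depth bounds (5–1000), biallelic, missing rate (≤40%), repeat-region mask,
   and proximity (<5 bp to any other input variant removes both neighbours),
   with per-rule accounting.
4. **Tandem gene-cluster calling** — maximal runs of ≥3 family genes with
   inter-gene gaps ≤0.8 Mb.
5. **Synthetic data** — seeded simulators for auto-/allo-tetraploid and
   diploid genomes (group- or subgenome-private repeat families, tunable
   haplotype/subgenome divergence), uniform short reads, and VCFs with a
   constructed per-rule filter truth table. Everything downstream is testable
   offline.

## CLI

All stages are subcommands of `tetrasig` (or `python -m tetrasig.cli`);
run any with `--help` for the full option list.

```sh
# simulate an auto-tetraploid (3 groups x 4 haplotypes x 50 kb by default)
tetrasig simulate-genome --mode auto --seed 1 --out-fasta g.fa --out-map g.tsv

# full chromosome-enriched k-mer signature -> verdict JSON + newick tree
tetrasig classify-ploidy --genome g.fa --labels g.tsv --seed 1 \
    --out-json call.json --out-newick tree.nwk

# intermediate stages are available separately
tetrasig count-kmers --fasta g.fa -k 13 --out table.tsv
tetrasig select-enriched --table table.tsv --min-global 200 --baseline mean_other \
    --out-entries enriched.tsv --out-profile profile.tsv
tetrasig cluster-chroms --profile profile.tsv --out-newick tree.nwk --out-dist dist.tsv

# smudge analysis from reads
tetrasig simulate-reads --genome g.fa --labels g.tsv --coverage 25 --seed 2 --out reads.fq
tetrasig smudge --fastq reads.fq --out-json smudge.json --out-pairs pairs.tsv

# variant filtering and gene clusters
tetrasig simulate-vcf --n-records 1000 --seed 7 --out-vcf v.vcf \
    --out-truth truth.tsv --out-bed repeats.bed
tetrasig filter-vcf --vcf v.vcf --repeat-bed repeats.bed \
    --out-vcf filtered.vcf --out-json filter.json
tetrasig find-clusters --gff3 genes.gff3 --family family.tsv --out-tsv clusters.tsv
```

Notes on defaults:

* `select-enriched` defaults to the strict `max_other` baseline (a k-mer must
  beat the *maximum* of the other chromosomes); the `classify-ploidy`
  pipeline defaults to `mean_other`, since in an auto-polyploid the
  diagnostic repeats are shared by all haplotypes of a group.
* `--min-global` (default 1000) is calibrated for multi-Gb assemblies; scale
  it down proportionally for small genomes/simulations.
* The smudge report's `c_hat` is on the k-mer coverage scale; `c_hat_base`
  rescales it to per-copy read depth using the read length.

Exit codes: 0 success, 2 validation/input error, 1 runtime error.

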