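# enhins

Small-insertion discovery in enhancer ChIP-seq data.

H3K27ac ChIP-seq enriches for active-enhancer DNA, but standard gapless
aligners silently discard reads that carry small insertions relative to the
reference. `enhins` rescues those reads: it re-aligns initially unmapped
reads (and contigs greedily assembled from them) with an insertion-aware
aligner, verifies each candidate with an independent exhaustive zero-mismatch
realignment, restricts calls to enhancer peaks, catalogues them by a
left-normalized `chrom:pos:sequence` key, deprioritizes likely-germline
entries (dbSNP key match or recurrence in >2 samples), scores allele-specific
coverage bias with per-variant mini-genomes, assigns insertions to genes
sharing an insulated neighbourhood (smallest containing CTCF/cohesin loop),
and confirms predictions from amplicon reads against per-allele custom
genomes. A synthetic-data module generates genomes, peaks, planted insertions
with known zygosity, and ChIP-like/amplicon-like reads, and serves as the
planted-truth test bed for every stage.

## Conventions

- All coordinates are 0-based, half-open.
- An insertion is anchored at the index of the reference base immediately
  **left** of the insertion point and is left-normalized (shifted to the
  leftmost equivalent anchor through repeats) before any keying or matching.
- Alignment scoring: match +1, mismatch −1, gap of length L costs 2 + L.
- The rescue aligner permits at most one gap run (a single insertion or a
  single deletion); downstream verification accepts only single-insertion,
  zero-mismatch placements (deletion calls analogously demand a single
  M-D-M alignment from contigs only).

## CLI

```sh
# synthetic data with planted truth
enhins simulate --seed 7 --genome-out g.fa --peaks-out p.bed \
    --reads-out r.fq --truth-out truth.tsv

# per-sample discovery (peaks optional; a built-in Poisson caller is the fallback)
enhins call --reads r.fq --genome g.fa --peaks p.bed --sample s1 \
    --out catalogue.tsv [--max-insertion 20] [--emit-sam rescued.sam] \
    [--deletions dels.tsv] [--stats-out stats.json]

# germline deprioritization (dbSNP as a key file or an insertion-only VCF)
enhins germline --catalogue catalogue.tsv --dbsnp keys.tsv --out annotated.tsv

# allele-specific coverage bias (twofold filter)
enhins bias --catalogue annotated.tsv --reads r.fq --genome g.fa \
    --read-len 40 --min-ratio 2 --out bias.tsv

# insulated-neighbourhood gene assignment + permutation enrichment test
enhins assign --catalogue bias.tsv --loops loops.bedpe --genes genes.tsv \
    --enhancers union.bed --perms 10000 --seed 7 --out assigned.tsv

# amplicon confirmation of one prediction
enhins confirm --key chr1:1234:ACG --genome g.fa --reads amplicon.fq \
    --flank 250 --out result.tsv
```

Formats: FASTA/FASTQ, BED (peaks), BEDPE + two extra columns (loops: FDR and
`ctcf1,ctcf2` flags), TSV catalogue with documented header, gene TSV
(`name chrom tss strand active oncogene`), optional VCF 4.2 export and SAM
export of rescued alignments.

## Layout

| module | role |
| --- | --- |
| `enhins.core_io` | data model (genome, reads, peaks, variant keys, loops, catalogue entries) and format I/O |
| `enhins.align` | gapless first-pass mapper, single-gap rescue aligner, exhaustive verification, deletion check |
| `enhins.assemble` | greedy exact-overlap contig assembly of unmapped reads |
| `enhins.call_insertions` | per-sample pipeline: peaks, rescue, filtering, cataloguing, deletion calls |
| `enhins.germline` | dbSNP/recurrence flagging, somatic partitioning, external-catalogue intersection |
| `enhins.allelic_bias` | per-variant mini-genomes, allele-informative read counting, bias filter |
| `enhins.neighbourhoods` | loop filtering, smallest-loop gene assignment, permutation enrichment test |
| `enhins.confirm` | amplicon assembly and zero-mismatch allele-presence / zygosity calls |
| `enhins.simulate` | synthetic genomes, planted insertions, read simulators, loop/gene fixtures |
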