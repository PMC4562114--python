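# tentacle

Gene quantification for shotgun metagenomes: stream reads and read-mapper
output, filter alignments, and compute per-gene read counts and coverage
statistics with a linear-time algorithm — with a dynamic master-worker
scheduler that spreads independent per-sample jobs over however many workers
happen to be available.

It is aimed at people quantifying annotated genes (or any annotated regions)
across many metagenome samples, where each sample is an independent job:
reads, a reference database, and an annotation table in, a results table out.

## The core computation

For every retained alignment of a read to reference sequence *r* on the
half-open interval [*s*, *e*), the coverage of *r* is accumulated in a
difference array:

```
d_r[s] += 1,   d_r[e] -= 1,        then   depth_r = cumsum(d_r)
```

With *n* total reference bases and *N* mapped reads this costs O(*n* + *N*)
elementary writes — independent of read length *M* — versus O(*n* + *N*·*M*)
for incrementing every covered base. Per annotated region the pipeline then
reports the read **count** (alignments overlapping the region under a
configurable overlap rule), and the **median**, **mean** and population
**standard deviation** of per-base depth over exactly the region's bases.

Ambiguously mapped reads are handled by either of two policies: keep all
hits passing the matching criteria (minimum percent identity and alignment
length), or keep only the *best* hit per read, defined as the first one
listed in the mapper output. Mapper output is accepted in 12-column BLAST
tabular ("blast8"/"blast6out") or SAM; reads in FASTA/FASTQ, optionally
gzipped. No aligner is bundled — adapters invoke external mappers, and a
`precomputed` adapter consumes an existing mapping file.

Distribution follows a dynamic master-worker scheme: the master holds a FIFO
job queue and exchanges only small control messages; workers register
whenever they come online, pull jobs, fetch inputs and write results
themselves, and failed jobs are requeued up to a retry limit.

## Worked example

Generate a small synthetic sample with a known answer, then quantify it:

```
tentacle-synth contigs -n 20 --min-len 2500 --max-len 5000 --seed 11 \
    --fasta contigs.fasta --annotations annotations.tsv
tentacle-synth spike --contigs contigs.fasta --coverage 10 --seed 12 \
    --select-fraction 0.5 --fastq reads.fastq --mapping mapping.blast8 \
    --truth truth.tsv
tentacle run-single --reads reads.fastq --reference contigs.fasta \
    --annotations annotations.tsv --mapping mapping.blast8 --out results.tsv
```

`contigs` prints `wrote 20 contigs (75532 bases)`; `spike` fragments half of
them into error-free 45 nt reads at 10× fold-coverage and prints
`spiked 10 contigs with 8971 reads at 10x`. `results.tsv` then holds one row
per annotated region:

```
#ref_id      start  end    strand  label             count  median_cov  mean_cov  sd_cov
contig00001  1      2834   +       contig00001_gene  630    10.0000     10.0035   3.3371
contig00002  1      3912   +       contig00002_gene  0      0.0000      0.0000    0.0000
contig00003  1      3755   +       contig00003_gene  0      0.0000      0.0000    0.0000
...
```

Spiked contigs come out with a median depth of 10 — the spiked fold-coverage
— while unspiked contigs stay at zero; `count` is the number of retained
alignments overlapping the region, and the coverage columns summarize
per-base depth across it. The same quantification runs across many samples
with `tentacle run-local --jobs jobs.tsv -N 4` (a TSV of reads / reference /
annotations / output / mapping per line), or across machines with
`tentacle-master`, `tentacle-worker` and `tentacle-status`.

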