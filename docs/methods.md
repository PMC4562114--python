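# Methods

## Problem and model

Shotgun metagenome quantification asks, for each annotated region of a
reference database (typically genes on assembled contigs), how many reads
from a sample align there and how deeply the region is covered. The package
treats each sample as an independent job — reads, reference FASTA,
annotation table — and produces one results row per annotation: read count,
median, mean and standard deviation of per-base coverage depth.

Coverage is computed by interval accumulation on a difference array. Every
reference sequence is an integer array; a retained alignment on the
half-open interval [s, e) contributes +1 at slot s and −1 at slot e, and the
per-base depth is the cumulative sum. The decrement deliberately lands on
the *exclusive* end: decrementing at the last covered base would strip one
base from every alignment and break the exact conservation law the test
suite asserts (total depth mass = summed alignment lengths). Cost is
2 writes per alignment plus one per reference base, O(n + N) for n reference
bases and N alignments, independent of read length; the per-base
"increment every covered slot" implementation, O(n + N·M) for read length M,
is retained as `naive_coverage` strictly as a test oracle. Both carry an
instrumented write counter so the complexity claim is checked on operation
counts rather than wall-clock time.

All internal coordinates are 0-based half-open; on-disk formats (annotation
TSV, BLAST tabular, SAM) use their native 1-based inclusive conventions and
are converted only at file boundaries.

## Filtering semantics

Quality filtering keeps a read iff at least p % of its bases have Phred
quality ≥ q (defaults q = 20, p = 90; Phred+33 encoding assumed, as modern
instruments emit). Trimming and adapter removal are deliberately out of
scope. Because the rule needs qualities, filtering necessarily precedes
FASTA conversion. The parameter domain requires p > 0; the degenerate
keep-everything configuration is expressed as q = 0 (every Phred score
passes), which is also the tested invariant.

Hit filtering applies matching criteria first — minimum percent identity and
minimum alignment length, the two measures available in every supported
mapper dialect — and only then the optional best-hit policy (smallest
file-order record per query). Criteria-first means a failing first-listed
hit cannot shadow a passing later one. Strand is not retained on hits:
quantification is strand-agnostic, and reverse-strand BLAST coordinates
(sstart > send) are normalized by min/max at parse time.

Counting is per retained alignment: a hit contributes to every region whose
intersection satisfies the overlap rule (default: ≥ 1 base; optionally also
a minimum fraction of the hit's own length). There is no fractional
assignment — ambiguity between reads is resolved upstream by the best-hit
policy, and overlapping annotations each receive the hit. Median uses
midpoint averaging for even-length regions; the standard deviation is the
population form (the region's slots are the entire population, not a
sample). Either counts or coverage can be disabled; disabled fields are
written as `NA`, and with both disabled the pipeline performs no array
writes at all and reduces to a parallel mapping harness.

Hits extending past their reference's end are clipped and logged rather
than dropped (mappers soft-clip inconsistently); hits naming an unknown
reference are skipped and logged, or abort under the strict policy.
Malformed mapper-output lines follow the same skip-and-log default with a
strict option, since third-party mapper output is heterogeneous.

## Master-worker distribution

The master holds a FIFO queue and a status record per job
(queued / running / done / failed / abandoned; the five states always
partition the job set). Workers register at any time, receive a job, and
report done or failed; a failure requeues the job until the retry limit
(default 3 reruns after the first attempt) is exhausted, after which the
job is abandoned with its last error. Reports for a job not currently
running on that worker are rejected, making success exactly-once. A worker
that goes silent while holding a job loses it after a heartbeat timeout
(default 60 s) — liveness on unreliable hardware requires some such
invention, as failure detection cannot rely on the worker reporting.

Transport is request-reply over one TCP socket using
`multiprocessing.connection` (Listener/Client); each connection carries a
single small control message — register, job, done, failed, status,
shutdown — and never file contents. The master is never involved in data
transfer: workers read inputs and write results themselves. After the last
job reaches a terminal state the master answers remaining workers with
shutdown and exits once none are left (bounded by a drain timeout).
`run_local` runs the same machinery on one machine: a master thread plus N
worker processes, and because each job is deterministic given its inputs,
results are byte-identical for any worker count. Cluster schedulers,
authentication and data caching are out of scope.

## Synthetic data and the validation study

The generator emulates the minimal structure quantification accuracy
depends on: reference contigs are i.i.d. uniform A/C/G/T (lengths uniform in
a range), and spiking fragments a selected contig of length L into
round(C·L/r) reads of fixed length r = 45 whose starts are uniform on
[0, L − r] — with replacement, fully inside the contig, error-free, at
constant Q40. Each interior base is then covered Binomial(round(C·L/r),
r/(L − r + 1))-many times, mean ≈ C·L/(L − r + 1), so the median depth
estimates the spiked fold-coverage C with a small upward bias of order r/L
(0.5–2 % for these contig lengths) and edge ramps over the first and last
r bases. It does not emulate abundance profiles, sequencing errors, paired
ends, GC bias or repeats — so passing tests demonstrate the correctness of
the quantification arithmetic, not robustness to real-sequencer artifacts.

The validation study generates 100 contigs of 2500–10000 nt per replicate,
selects 10 % of those ≥ 2500 nt, spikes the same selected contigs at 1×,
10×, 100× and 1000×, runs each spiked sample through the full pipeline with
the precomputed ground-truth mapping, and reports per level the mean over
spiked contigs of |median_depth − C| / C × 100, with its standard error
across contigs (an averaging interpretation consistent with reporting
standard errors; a max-deviation reading would admit none). Theoretical
coverage is taken as C itself, not the edge-corrected expectation — edge
effects and the r/L bias are precisely why the study asserts tolerances
rather than equalities. Three replicates at 100 contigs give ≈ 30 spiked
contigs per level, enough that the study completes in about a minute on a
single CPU while the standard errors stay well below the tolerances. At
these scales the measured mean deviations are ≈ 0 % at 1× and 10× (the
median snaps to the integer C), ≈ 0.4 % at 100× and ≈ 0.7 % at 1000×. Note
the deviation *grows* with C: at small C integer snapping hides the r/L
bias entirely, while at large C the median resolves it. The per-contig
median is therefore a consistent estimator of C only up to that bias; the
high-coverage sanity test (10⁴× on a 2500 nt contig stays within 3 %)
bounds it.

## Numerical and design choices

- Reproducibility: every stochastic component takes an explicit seed;
  per-replicate and per-level streams are derived via `SeedSequence` so the
  whole study is byte-reproducible from one integer.
- Read counts per spiked contig use banker's rounding of C·L/r (Python
  `round`), recorded because it is visible in ground-truth read totals.
- Results are written with fixed 4-decimal floats; write-then-read is the
  identity at that precision.
- SAM parsing derives percent identity from the NM tag over alignment
  columns (M/I/D/=/X), defaulting to 100 when absent; reference span sums
  M/D/N/=/X. Records with flag 0x4 or CIGAR `*` never become hits.
- The pipeline touches the read stream only when a stage consumes it
  (quality filter or a real mapper); with a precomputed mapping and no
  filtering the reads file is validated for existence but not parsed, which
  changes no output byte.
- FASTQ writing exists only to serve the synthetic generator; BAM, GEM and
  RazerS native dialects are future parser plug-ins, not supported formats.

## Known limitations

- Quantification is strand-agnostic and unnormalized (no RPKM/TPM); counts
  are per alignment, so paired-end mates count separately.
- The best-hit definition is positional (first listed), inheriting whatever
  ordering the mapper emits.
- The heartbeat cannot distinguish a slow job from a dead worker; jobs
  slower than the timeout need it raised.
- The synthetic generator's uniform, error-free reads make the validation a
  correctness check of the quantification path, not a benchmark of mapper
  sensitivity or of behaviour under sequencing error.
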