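"""The per-worker processing workflow and the local multi-core launcher.

A job flows through: stream + decompress reads -> optional quality filter ->
optional FASTA conversion -> read mapper (an external aligner invoked through
an adapter, or a precomputed mapping file) -> hit filtering -> coverage /
counts -> per-region statistics -> results TSV. Each job writes its own
processing log; the results file appears atomically, so a failed job never
leaves a partial output behind.

``run_local`` wires the same workflow into the master-worker machinery on a
single machine: one master thread plus N worker processes.
"""

from __future__ import annotations

import logging
import multiprocessing
import os
import shlex
import shutil
import subprocess
import tempfile
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from threading import Thread
from typing import Callable, Optional

from . import dmw, filtering, formats, quantify
from .dmw import Job, RunSummary
from .filtering import ConfigurationError, HitCriteria, QualityFilterParams
from .quantify import OverlapRule

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class MapperAdapter:
    """How to obtain mapping output for a job.

    ``command`` is a shell template with ``{reads}``, ``{reference}`` and
    ``{output}`` placeholders. The special adapter name "precomputed"
    bypasses execution and reads an existing mapping file instead — the only
    adapter the test suite ever uses. ``parser`` selects the output dialect.
    """

    name: str
    command: Optional[str] = None
    parser: str = "blast8"  # blast8 | sam

    def __post_init__(self):
        if self.parser not in ("blast8", "sam"):
            raise ValueError(f"unknown mapping parser {self.parser!r}")
        if self.name != "precomputed" and not self.command:
            raise ValueError(f"adapter {self.name!r} needs a command template")


#: Command templates for the supported external aligners; documented
#: examples only — no aligner is bundled, and tests never execute one.
ADAPTERS: dict[str, MapperAdapter] = {
    "precomputed": MapperAdapter("precomputed"),
    "pblat": MapperAdapter(
        "pblat", "pblat -threads=1 -minIdentity=90 -out=blast8 "
        "{reference} {reads} {output}", "blast8"),
    "usearch": MapperAdapter(
        "usearch", "usearch -usearch_local {reads} -db {reference} "
        "-id 0.9 -query_cov 1.0 -blast6out {output}", "blast8"),
    "bowtie2": MapperAdapter(
        "bowtie2", "bowtie2 -x {reference} -U {reads} -S {output}", "sam"),
}


@dataclass(frozen=True, slots=True)
class PipelineOptions:
    """Everything a worker needs to process one job.

    At least one of counts, coverage, or keep_mapping_output must be enabled,
    otherwise the job would produce nothing. With counts and coverage both
    disabled the pipeline degenerates into a parallel mapping framework:
    the quantification stage performs zero array writes.
    """

    quality_filter: Optional[QualityFilterParams] = None
    criteria: HitCriteria = field(default_factory=HitCriteria)
    overlap: OverlapRule = field(default_factory=OverlapRule)
    compute_counts: bool = True
    compute_coverage: bool = True
    keep_mapping_output: bool = False
    mapper: str = "precomputed"
    mapper_args: str = ""
    mapping_path: Optional[str] = None  # required by the precomputed adapter
    mapping_format: str = "blast8"      # dialect of the precomputed mapping
    exclude_ids_path: Optional[str] = None
    log_level: str = "info"  # info | verbose
    scratch_dir: Optional[str] = None

    def __post_init__(self):
        if not (self.compute_counts or self.compute_coverage
                or self.keep_mapping_output):
            raise ConfigurationError(
                "counts, coverage and keep-mapping-output are all disabled; "
                "the job would produce nothing")
        if self.log_level not in ("info", "verbose"):
            raise ValueError(f"unknown log level {self.log_level!r}")
        if self.mapping_format not in ("blast8", "sam"):
            raise ValueError(f"unknown mapping format {self.mapping_format!r}")

    def adapter(self) -> MapperAdapter:
        try:
            return ADAPTERS[self.mapper]
        except KeyError:
            raise ConfigurationError(
                f"unknown mapper adapter {self.mapper!r}; known: "
                f"{', '.join(sorted(ADAPTERS))}") from None


class JobError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class JobLog:
    """Per-job processing log with two output levels.

    info lines are always written; verbose additionally records summary
    statistics (records in/out) around the individual steps.
    """

    def __init__(self, path: Optional[Path], level: str = "info",
                 mirror: bool = False):
        self.path = path
        self.level = level
        self.mirror = mirror
        self.lines: list[str] = []

    def event(self, level: str, stage: str, message: str,
              stats: Optional[dict] = None) -> None:
        if level == "verbose" and self.level != "verbose":
            return
        line = f"{time.strftime('%Y-%m-%d %H:%M:%S')} [{stage}] {message}"
        if stats:
            line += " | " + " ".join(f"{k}={v}" for k, v in stats.items())
        self.lines.append(line)
        if self.mirror:
            logger.info("%s", line)

    def flush(self) -> None:
        if self.path is not None:
            with open(self.path, "a") as out:
                out.writelines(line + "\n" for line in self.lines)
            self.lines.clear()


def log_event(log: JobLog, level: str, stage: str, message: str,
              stats: Optional[dict] = None) -> None:
    """Module-level convenience wrapper around :meth:`JobLog.event`."""
    log.event(level, stage, message, stats)


def reference_lengths(reference_path: str) -> dict[str, int]:
    """Sequence id -> length from the reference FASTA."""
    return {rec.id: len(rec.sequence)
            for rec in formats.stream_reads(reference_path)}


def _preprocess_reads(job: Job, options: PipelineOptions, scratch: Path,
                      log: JobLog) -> str:
    """Stream, quality-filter and convert reads; returns the mapper input path."""
    reads = formats.stream_reads(job.reads_path)
    if options.exclude_ids_path:
        exclude = filtering.load_exclude_ids(options.exclude_ids_path)
        reads = filtering.exclude_reads(reads, exclude)
        log.event("verbose", "preprocess", "host-read exclusion enabled",
                  {"exclude_ids": len(exclude)})
    if options.quality_filter is not None:
        reads = list(reads)
        n_in = len(reads)
        reads = list(filtering.quality_filter(iter(reads),
                                              options.quality_filter))
        log.event("verbose", "quality_filter", "quality filtering done",
                  {"reads_in": n_in, "reads_kept": len(reads)})
        reads = iter(reads)
    # aligners here take FASTA; conversion drops qualities
    reads = filtering.convert_to_fasta(reads)
    prepared = scratch / "reads.fasta"
    n = formats.write_reads(reads, prepared, "fasta")
    log.event("verbose", "preprocess", "prepared mapper input",
              {"reads_out": n})
    return str(prepared)


def _obtain_mapping(job: Job, options: PipelineOptions, scratch: Path,
                    log: JobLog) -> str:
    adapter = options.adapter()
    if adapter.name == "precomputed":
        mapping = options.mapping_path
        if not mapping or not os.path.exists(mapping):
            raise JobError("mapping", f"precomputed mapping file not found: "
                                      f"{mapping!r}")
        log.event("info", "mapping", f"using precomputed mapping {mapping}")
        return mapping
    reads_path = _preprocess_reads(job, options, scratch, log)
    out = scratch / f"mapping.{adapter.parser}"
    cmd = adapter.command.format(reads=reads_path,
                                 reference=job.reference_path, output=out)
    if options.mapper_args:
        cmd += " " + options.mapper_args
    log.event("info", "mapping", f"running mapper {adapter.name}: {cmd}")
    proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
    if proc.returncode != 0:
        raise JobError("mapping", f"{adapter.name} exited "
                                  f"{proc.returncode}: {proc.stderr[-500:]}")
    return str(out)


def run_job(job: Job, options: Optional[PipelineOptions] = None,
            mirror_log: bool = False) -> str:
    """Execute the full per-worker workflow for one job.

    Returns the results file path (== ``job.output_path``). On any stage
    failure the partially written output is removed and :class:`JobError`
    is raised naming the stage; the per-job log (``<output>.log``) records
    what happened either way.
    """
    if options is None:
        options = job.options
    if not isinstance(options, PipelineOptions):
        raise ConfigurationError(f"job {job.job_id!r} has no pipeline options")
    output_path = Path(job.output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    log = JobLog(output_path.with_name(output_path.name + ".log"),
                 options.log_level, mirror_log)
    log.event("info", "job", f"start job {job.job_id}",
              {"reads": job.reads_path, "reference": job.reference_path,
               "annotations": job.annotations_path})
    own_scratch = options.scratch_dir is None
    scratch = Path(options.scratch_dir or tempfile.mkdtemp(prefix="tentacle-"))
    scratch.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        for stage, path in (("reads", job.reads_path),
                            ("reference", job.reference_path),
                            ("annotations", job.annotations_path)):
            if not os.path.exists(path):
                raise FileNotFoundError(f"{stage} file not found: {path}")

        stage = "annotations"
        annotations = formats.read_annotations(job.annotations_path)
        log.event("verbose", stage, "annotations loaded",
                  {"regions": len(annotations)})

        # Pre-processing feeds the mapper; with a precomputed mapping there
        # is no consumer, so the read stream is only touched when a quality
        # filter must validate the sample anyway.
        stage = "preprocess"
        adapter = options.adapter()
        if adapter.name == "precomputed" and options.quality_filter is not None:
            n_kept = 0
            for _ in filtering.quality_filter(
                    formats.stream_reads(job.reads_path),
                    options.quality_filter):
                n_kept += 1
            log.event("verbose", "quality_filter", "quality filtering done",
                      {"reads_kept": n_kept})

        stage = "mapping"
        mapping_path = _obtain_mapping(job, options, scratch, log)

        stage = "quantify"
        if options.compute_counts or options.compute_coverage:
            dialect = (options.mapping_format
                       if adapter.name == "precomputed" else adapter.parser)
            parse = (formats.parse_blast8 if dialect == "blast8"
                     else formats.parse_sam)
            hits = filtering.filter_hits(parse(mapping_path), options.criteria)
            log.event("verbose", stage, "hits retained after criteria",
                      {"hits": len(hits),
                       "best_hit_only": options.criteria.best_hit_only})
            ref_lengths = reference_lengths(job.reference_path)
            cov = (quantify.build_coverage(hits, ref_lengths)
                   if options.compute_coverage else None)
            counts = (quantify.count_reads(hits, annotations, options.overlap)
                      if options.compute_counts else None)
            results = quantify.region_statistics(cov, annotations, counts)
            stage = "write_results"
            tmp = output_path.with_name(output_path.name + ".part")
            formats.write_results(results, tmp)
            os.replace(tmp, output_path)  # atomic: no partial results file
            log.event("info", stage, f"results written to {output_path}",
                      {"regions": len(results)})
        else:
            log.event("info", stage, "counts and coverage disabled; "
                                     "results step skipped")

        if options.keep_mapping_output and adapter.name != "precomputed":
            kept = output_path.with_name(output_path.name + ".mapping.tsv")
            shutil.copyfile(mapping_path, kept)
            log.event("info", "mapping", f"mapping output retained at {kept}")
        log.event("info", "job", f"job {job.job_id} finished")
        return str(output_path)
    except JobError as exc:
        log.event("info", exc.stage, f"job {job.job_id} FAILED: {exc.cause}")
        _cleanup_partial(output_path)
        raise
    except Exception as exc:
        log.event("info", stage, f"job {job.job_id} FAILED: {exc}")
        _cleanup_partial(output_path)
        raise JobError(stage, str(exc)) from exc
    finally:
        log.flush()
        if own_scratch:
            # retained mapping output was already copied next to the results
            shutil.rmtree(scratch, ignore_errors=True)


def _cleanup_partial(output_path: Path) -> None:
    for p in (output_path, output_path.with_name(output_path.name + ".part")):
        if p.exists():
            p.unlink()


# ---------------------------------------------------------------------------
# Jobs files and the local launcher
# ---------------------------------------------------------------------------

def read_jobs_file(path: str,
                   options: Optional[PipelineOptions] = None) -> list[Job]:
    """Parse the jobs TSV: reads, reference, annotations, output[, mapping].

    The optional fifth column names a precomputed mapping file for that job;
    it overrides ``options.mapping_path``. Lines starting with '#' are
    ignored; job ids are j0001, j0002, ... in file order.
    """
    if options is None:
        options = PipelineOptions()
    jobs = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 5):
                raise formats.FormatError(
                    f"expected 4 or 5 columns, got {len(fields)}",
                    path=path, line=lineno)
            opts = options
            if len(fields) == 5 and fields[4]:
                opts = replace(options, mapping_path=fields[4])
            jobs.append(Job(f"j{len(jobs) + 1:04d}", fields[0], fields[1],
                            fields[2], fields[3], opts))
    return jobs


def _worker_entry(endpoint: tuple[str, int], worker_id: str) -> None:
    """Entry point of a spawned local worker process."""
    dmw.worker_loop(endpoint, run_job, worker_id=worker_id)


def run_local(jobs: list[Job] | str, workers: int = 1,
              options: Optional[PipelineOptions] = None,
              retry_limit: int = 3,
              executor: Optional[Callable[[Job], object]] = None
              ) -> RunSummary:
    """Run jobs on this machine: a master thread plus *workers* processes.

    With the deterministic precomputed adapter the results are identical to
    executing each job serially, whatever the worker count. *jobs* may be a
    jobs-file path or a prepared list; *executor* (default :func:`run_job`)
    is overridable for in-process testing, in which case workers run as
    threads instead of processes.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if isinstance(jobs, str):
        jobs = read_jobs_file(jobs, options)
    endpoint = dmw.free_endpoint()
    summary: dict[str, RunSummary] = {}

    def _serve():
        summary["run"] = dmw.master_serve(jobs, endpoint,
                                          retry_limit=retry_limit)

    master = Thread(target=_serve, daemon=True)
    master.start()
    procs: list = []
    ctx = multiprocessing.get_context()
    for i in range(workers):
        wid = f"local-{i}"
        if executor is None:
            proc = ctx.Process(target=_worker_entry, args=(endpoint, wid),
                               daemon=True)
        else:
            proc = Thread(target=dmw.worker_loop,
                          args=(endpoint, executor),
                          kwargs={"worker_id": wid}, daemon=True)
        proc.start()
        procs.append(proc)
    master.join()
    for proc in procs:
        proc.join(timeout=30)
    return summary["run"]
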