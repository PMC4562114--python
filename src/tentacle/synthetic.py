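"""Synthetic data generation and the coverage-accuracy validation study.

Everything the pipeline consumes can be generated here: random contigs with
whole-contig annotations, and read sets produced by uniformly fragmenting
selected contigs at a chosen fold-coverage ("spiking"), together with the
ground-truth mapping those reads imply. Because the true origin of every
read is known, quantification accuracy can be measured exactly: a contig of
length L spiked at coverage C with reads of length r receives round(C*L/r)
reads, so its per-base depth should estimate C.

The validation study runs spiked samples through the full pipeline (with the
precomputed-mapping adapter) and reports, per coverage level, the mean
relative deviation of the estimated median coverage from the theoretical
level, averaged over the spiked contigs.
"""

from __future__ import annotations

import logging
import math
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import formats, pipeline
from .dmw import Job
from .formats import Annotation
from .pipeline import PipelineOptions

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True, slots=True)
class SpikeDesign:
    """Parameters of one spiking experiment.

    ``coverage_level`` is the target fold-coverage C. Defaults mirror a
    typical short-read metagenome validation: 45 bp reads, contigs eligible
    from 2500 nt, 10 % of eligible contigs spiked.
    """

    coverage_level: float
    read_length: int = 45
    contig_min_len: int = 2500
    select_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.coverage_level <= 0:
            raise ValueError("coverage_level must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 < self.select_fraction <= 1:
            raise ValueError("select_fraction must be in (0, 1]")


@dataclass(slots=True)
class SpikedContig:
    """Ground truth for one spiked contig."""

    contig_id: str
    length: int
    n_reads: int
    coverage_level: float


@dataclass
class SpikeResult:
    """Paths and ground truth produced by :func:`spike_reads`."""

    fastq_path: str
    mapping_path: str
    truth_path: str
    spiked: list[SpikedContig] = field(default_factory=list)


def generate_contigs(n: int, length_range: tuple[int, int], seed: int,
                     fasta_path: str, annotations_path: str
                     ) -> list[tuple[str, int]]:
    """Write *n* uniform-random A/C/G/T contigs plus whole-contig annotations.

    Lengths are uniform integers in *length_range* (inclusive). Each contig
    gets one annotation spanning it entirely, labelled ``<id>_gene``.
    Reproducible from *seed*. Returns (contig id, length) pairs.
    """
    if n < 1 or length_range[0] < 1 or length_range[0] > length_range[1]:
        raise ValueError("need n >= 1 and a valid length range")
    rng = np.random.default_rng(seed)
    contigs = []
    annotations = []
    with open(fasta_path, "w") as fasta:
        for i in range(n):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            cid = f"contig{i + 1:05d}"
            seq = _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")
            fasta.write(f">{cid}\n{seq}\n")
            contigs.append((cid, length))
            annotations.append(Annotation(cid, 0, length, "+", f"{cid}_gene"))
    formats.write_annotations(annotations, annotations_path)
    return contigs


def spike_reads(contigs_fasta: str, design: SpikeDesign, fastq_path: str,
                mapping_path: str, truth_path: str,
                selected_ids: Optional[Sequence[str]] = None) -> SpikeResult:
    """Fragment selected contigs into error-free reads with known origins.

    From the contigs at least ``contig_min_len`` long, a ``select_fraction``
    subset is drawn (or *selected_ids* used verbatim); each selected contig
    of length L yields round(C*L/read_length) reads whose starts are uniform
    in [0, L - read_length], fully inside the contig. Reads carry constant
    Q40 qualities. The ground-truth mapping is written in the 12-column
    blast8 dialect at 100 % identity with the true coordinates, and the
    truth table records each contig's theoretical coverage.

    Eligible contigs shorter than ``read_length`` are excluded and logged.
    """
    rng = np.random.default_rng(design.seed)
    rl = design.read_length
    contigs = {rec.id: rec.sequence
               for rec in formats.stream_reads(contigs_fasta)}
    eligible = [cid for cid, seq in contigs.items()
                if len(seq) >= design.contig_min_len]
    short = [cid for cid in eligible if len(contigs[cid]) < rl]
    if short:
        logger.warning("spike_reads: excluded %d contig(s) shorter than the "
                       "read length", len(short))
        eligible = [cid for cid in eligible if cid not in set(short)]
    if selected_ids is None:
        k = max(1, round(design.select_fraction * len(eligible)))
        selected = [str(c) for c in rng.choice(eligible, size=k, replace=False)]
    else:
        selected = list(selected_ids)
    result = SpikeResult(fastq_path, mapping_path, truth_path)
    C = design.coverage_level
    qual = "I" * rl  # Phred+33 for Q40
    with open(fastq_path, "w") as fastq, open(mapping_path, "w") as mapping, \
            open(truth_path, "w") as truth:
        truth.write("#contig_id\tlength\tn_reads\tcoverage_level\n")
        for cid in selected:
            seq = contigs[cid]
            L = len(seq)
            n_reads = round(C * L / rl)
            starts = rng.integers(0, L - rl + 1, size=n_reads)
            fq_chunk = []
            map_chunk = []
            for i, s in enumerate(starts):
                rid = f"{cid}_read{i + 1}"
                fq_chunk.append(f"@{rid}\n{seq[s:s + rl]}\n+\n{qual}\n")
                # blast8: 1-based inclusive subject coordinates
                map_chunk.append(
                    f"{rid}\t{cid}\t100.00\t{rl}\t0\t0\t1\t{rl}\t"
                    f"{s + 1}\t{s + rl}\t1e-30\t{2 * rl:.1f}\n")
            fastq.write("".join(fq_chunk))
            mapping.write("".join(map_chunk))
            truth.write(f"{cid}\t{L}\t{n_reads}\t{C:g}\n")
            result.spiked.append(SpikedContig(cid, L, n_reads, C))
    return result


def read_truth(path: str) -> list[SpikedContig]:
    """Parse a truth table written by :func:`spike_reads`."""
    out = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cid, length, n_reads, cov = line.rstrip("\n").split("\t")
            out.append(SpikedContig(cid, int(length), int(n_reads), float(cov)))
    return out


@dataclass(slots=True)
class LevelResult:
    """Accuracy of median-coverage estimation at one spiking level."""

    coverage_level: float
    mean_deviation_pct: float
    se_deviation_pct: float
    n_contigs: int
    deviations_pct: list[float]


def validation_study(levels: Sequence[float],
                     seed: int = 0,
                     replicates: int = 3,
                     n_contigs: int = 100,
                     length_range: tuple[int, int] = (2500, 10000),
                     design: Optional[SpikeDesign] = None,
                     workdir: Optional[str] = None,
                     options: Optional[PipelineOptions] = None
                     ) -> dict[float, LevelResult]:
    """Measure median-coverage accuracy across spiking levels.

    For each replicate a fresh set of contigs is generated and a fixed 10 %
    of the eligible ones selected; each level fragments those same contigs
    at fold-coverage C and the spiked sample is quantified through the full
    pipeline (precomputed-mapping adapter). The per-level figure of merit is
    the mean over spiked contigs (all replicates pooled) of
    |estimated_median - C| / C * 100, with its standard error over contigs.
    """
    if design is None:
        design = SpikeDesign(coverage_level=1.0)
    if options is None:
        options = PipelineOptions(mapper="precomputed")
    own_dir = workdir is None
    root = Path(workdir or tempfile.mkdtemp(prefix="tentacle-study-"))
    root.mkdir(parents=True, exist_ok=True)
    devs: dict[float, list[float]] = {lvl: [] for lvl in levels}
    try:
        for rep in range(replicates):
            rep_dir = root / f"rep{rep + 1}"
            rep_dir.mkdir(exist_ok=True)
            rep_seed = int(np.random.SeedSequence([seed, rep])
                           .generate_state(1)[0] % 2**31)
            contigs_fa = str(rep_dir / "contigs.fasta")
            anns = str(rep_dir / "annotations.tsv")
            generate_contigs(n_contigs, length_range, rep_seed,
                             contigs_fa, anns)
            selected: Optional[list[str]] = None
            for li, level in enumerate(levels):
                lvl_seed = int(np.random.SeedSequence([seed, rep, li])
                               .generate_state(1)[0] % 2**31)
                d = replace(design, coverage_level=float(level),
                            seed=rep_seed if selected is None else lvl_seed)
                spike = spike_reads(
                    contigs_fa, d,
                    str(rep_dir / f"reads_{li}.fastq"),
                    str(rep_dir / f"mapping_{li}.blast8"),
                    str(rep_dir / f"truth_{li}.tsv"),
                    selected_ids=selected)
                if selected is None:  # same contigs at every level
                    selected = [s.contig_id for s in spike.spiked]
                out = str(rep_dir / f"results_{li}.tsv")
                job = Job(f"rep{rep}-lvl{li}", spike.fastq_path, contigs_fa,
                          anns, out,
                          replace(options, mapping_path=spike.mapping_path))
                pipeline.run_job(job)
                medians = {r.annotation.ref_id: r.median_cov
                           for r in formats.read_results(out)}
                for sc in spike.spiked:
                    dev = abs(medians[sc.contig_id] - level) / level * 100.0
                    devs[level].append(dev)
    finally:
        if own_dir:
            import shutil
            shutil.rmtree(root, ignore_errors=True)
    out: dict[float, LevelResult] = {}
    for level in levels:
        arr = np.asarray(devs[level], dtype=float)
        out[level] = LevelResult(
            coverage_level=float(level),
            mean_deviation_pct=float(arr.mean()),
            se_deviation_pct=float(arr.std(ddof=1) / math.sqrt(arr.size))
            if arr.size > 1 else 0.0,
            n_contigs=int(arr.size),
            deviations_pct=[float(x) for x in arr],
        )
    return out
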