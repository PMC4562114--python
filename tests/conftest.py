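import numpy as np
import pytest

from tentacle import filtering, quantify, synthetic
from tentacle.dmw import Job
from tentacle.formats import Annotation, Hit
from tentacle.pipeline import PipelineOptions


@pytest.fixture(scope="session")
def small_sample(tmp_path_factory):
    """A small spiked sample: contigs, annotations, reads, ground-truth mapping."""
    root = tmp_path_factory.mktemp("sample")
    fasta = str(root / "contigs.fasta")
    annotations = str(root / "annotations.tsv")
    synthetic.generate_contigs(20, (2500, 5000), seed=11, fasta_path=fasta,
                               annotations_path=annotations)
    design = synthetic.SpikeDesign(coverage_level=10.0, seed=12,
                                   select_fraction=0.5)
    spike = synthetic.spike_reads(fasta, design, str(root / "reads.fastq"),
                                  str(root / "mapping.blast8"),
                                  str(root / "truth.tsv"))
    return {"root": root, "fasta": fasta, "annotations": annotations,
            "spike": spike, "design": design}


@pytest.fixture
def sample_job(small_sample, tmp_path):
    spike = small_sample["spike"]
    options = PipelineOptions(mapping_path=spike.mapping_path)
    return Job("sample", spike.fastq_path, small_sample["fasta"],
               small_sample["annotations"], str(tmp_path / "results.tsv"),
               options)


def random_hits(rng, n_hits, ref_lengths, max_len=60, n_queries=None):
    """Random valid hits over the given references, in file order."""
    refs = list(ref_lengths)
    hits = []
    for order in range(n_hits):
        ref = refs[rng.integers(len(refs))]
        length = ref_lengths[ref]
        span = int(rng.integers(1, min(max_len, length) + 1))
        start = int(rng.integers(0, length - span + 1))
        qid = (f"q{rng.integers(n_queries)}" if n_queries
               else f"q{order}")
        hits.append(Hit(qid, ref, start, start + span,
                        float(rng.uniform(50, 100)), span, order))
    return hits
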