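"""Shared fixtures: simulated datasets and end-to-end pipeline runs.

The heavier fixtures are session-scoped so the full 50-cell simulations
(and the pipeline runs over them) are computed once and shared by the
module tests and the acceptance suite.
"""

from __future__ import annotations

import pysam
import pytest

from nanosc import SimParams, get_profile, run_pipeline, run_simulation
from nanosc.simulate import make_toy_reference

CHEM = get_profile("10x-3p-v3")


@pytest.fixture(scope="session")
def toy_reference():
    return make_toy_reference(n_genes=4, isoforms_per_gene=2, seed=3)


@pytest.fixture(scope="session")
def sim_clean(tmp_path_factory):
    """50 cells x 40 reads, zero error rates, with all artifacts on disk."""
    out = tmp_path_factory.mktemp("sim_clean")
    params = SimParams(n_cells=50, reads_per_cell=40, seed=11)
    return params, run_simulation(params, out), out


@pytest.fixture(scope="session")
def sim_noisy(tmp_path_factory):
    """Same design at 2% substitution rate."""
    out = tmp_path_factory.mktemp("sim_noisy")
    params = SimParams(n_cells=50, reads_per_cell=40, sub_rate=0.02, seed=7)
    return params, run_simulation(params, out), out


@pytest.fixture(scope="session")
def run_clean(sim_clean, tmp_path_factory):
    _, sim, sim_dir = sim_clean
    out = tmp_path_factory.mktemp("run_clean")
    result = run_pipeline(
        sim_dir / "reads.fastq",
        sim_dir / "genome.sam",
        sim_dir / "annotation.gtf",
        out,
        CHEM,
        expected_cells=50,
    )
    return sim, result


@pytest.fixture(scope="session")
def run_noisy(sim_noisy, tmp_path_factory):
    _, sim, sim_dir = sim_noisy
    out = tmp_path_factory.mktemp("run_noisy")
    result = run_pipeline(
        sim_dir / "reads.fastq",
        sim_dir / "genome.sam",
        sim_dir / "annotation.gtf",
        out,
        CHEM,
    )
    return sim, result


def make_sam(path, records, contigs):
    """Write a small SAM file from (name, flag, contig, pos, mapq, cigar, seq, tags)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": name, "LN": length} for name, length in contigs],
        }
    )
    tid = {name: i for i, (name, _) in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, flag, contig, pos, mapq, cigar, seq, tags in records:
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            rec.flag = flag
            if contig is not None:
                rec.reference_id = tid[contig]
                rec.reference_start = pos
                rec.cigarstring = cigar
            rec.mapping_quality = mapq
            if seq:
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            for tag, value in tags.items():
                rec.set_tag(tag, value, value_type="Z")
            out.write(rec)
    return path
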