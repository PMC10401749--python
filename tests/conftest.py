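"""Shared fixtures: small synthetic genomes and read sets, generated in-process."""

from __future__ import annotations

import numpy as np
import pytest

from mpcall.align_io import AlignedRead
from mpcall.simdata import (PlatformErrorProfile, SimConfig,
                            make_diploid_genome, simulate_reads)


@pytest.fixture(scope="session")
def small_genome():
    """20 kb, 2 contigs, moderately dense variants."""
    cfg = SimConfig(genome_length=20_000, n_contigs=2, snp_rate=0.002,
                    indel_rate=0.0005, seed=11)
    return make_diploid_genome(cfg)


@pytest.fixture(scope="session")
def clean_short_profile():
    return PlatformErrorProfile(label="illumina", read_length_mean=151)


@pytest.fixture(scope="session")
def clean_long_profile():
    return PlatformErrorProfile(label="hifi", read_length_mean=3000)


@pytest.fixture(scope="session")
def clean_reads_30x(small_genome, clean_short_profile):
    """Zero-error short reads at 30x plus the simulator ledger."""
    return simulate_reads(small_genome, clean_short_profile, 30, seed=7)


@pytest.fixture(scope="session")
def clean_long_reads_30x(small_genome, clean_long_profile):
    return simulate_reads(small_genome, clean_long_profile, 30, seed=8)


def make_read(read_id: str, contig: str, start: int, seq: str,
              cigar=None, mapq: int = 60, baseq: int = 35, strand: str = "+",
              hp=None, platform: str = "test") -> AlignedRead:
    """Hand-rolled alignment record for toy cases."""
    if cigar is None:
        cigar = [("M", len(seq))]
    return AlignedRead(read_id=read_id, contig=contig, start=start,
                       cigar=cigar, sequence=seq,
                       baseq=[baseq] * len(seq), mapq=mapq, strand=strand,
                       hp=hp, platform=platform)
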