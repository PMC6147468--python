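import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from rohvar.config import SimConfig
from rohvar.simdata import (
    make_toy_transcriptome,
    simulate_exome_variants,
    simulate_genotype_array,
    simulate_pedigree,
)
from rohvar.splice import TranscriptModel


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def pedigree(sim_config):
    return simulate_pedigree(sim_config)


@pytest.fixture(scope="session")
def transcriptome(sim_config):
    return make_toy_transcriptome(sim_config)


@pytest.fixture(scope="session")
def genome(transcriptome):
    return transcriptome[0]


@pytest.fixture(scope="session")
def transcripts(transcriptome):
    return transcriptome[1]


@pytest.fixture(scope="session")
def designated(transcripts):
    from rohvar.simdata import DESIGNATED_TRANSCRIPT

    return next(t for t in transcripts if t.id == DESIGNATED_TRANSCRIPT)


@pytest.fixture(scope="session")
def genotype_array(pedigree, sim_config):
    return simulate_genotype_array(pedigree, sim_config)


@pytest.fixture(scope="session")
def exome_variants(pedigree, transcripts, sim_config, genome):
    return simulate_exome_variants(pedigree, transcripts, sim_config, genome)


def make_tiny_transcript(strand: str = "+") -> TranscriptModel:
    """Hand-built 3-exon gene with a fully known 30-nt CDS.

    CDS  = ATG AAA CCC GGG | TTT GAC GAT | AAT AAG TGA   (protein MKPGFDDNK)
    exon1 holds 12 coding nt, exon2 9, exon3 9; introns are 10 nt GT..AG.
    """
    e1, e2, e3 = "ATGAAACCCGGG", "TTTGACGAT", "AATAAGTGA"
    i1, i2 = "GTCCAACTAG", "GTTGGCACAG"
    seq = e1 + e2 + e3
    if strand == "+":
        start = 100
        exons = (
            (start, start + 12),
            (start + 12 + 10, start + 12 + 10 + 9),
            (start + 31 + 10, start + 31 + 10 + 9),
        )
    else:
        # genomic layout mirrored: transcript order has descending coordinates
        start = 100
        g_len = 12 + 10 + 9 + 10 + 9
        exons = (
            (start + g_len - 12, start + g_len),
            (start + 9 + 10, start + 9 + 10 + 9),
            (start, start + 9),
        )
    return TranscriptModel(
        id=f"tiny{strand}",
        chrom="9",
        strand=strand,
        exons=exons,
        cds_start=0,
        cds_end=30,
        seq=seq,
    )
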