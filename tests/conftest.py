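"""Shared fixtures: a small simulated experiment and a hand-built toy gene."""

import numpy as np
import pytest

import malines as ml
from malines.reference import GeneModel, ReferenceBundle, encode_seq


@pytest.fixture(scope="session")
def small_config():
    """A small but complete MA experiment: 8 lines, 2 x 400 kb, inflated
    rates so every event class is populated."""
    return ml.SimulationConfig(
        seed=42, n_chromosomes=2, chromosome_length=400_000,
        n_lines=8, generations_per_line=(507, 465, 479, 460, 508, 503, 427, 504),
        snm_rate=4e-8, indel_rate=8e-9,
        loh_rate_per_het_site=6e-5,
        tract_length_dist=("lognormal", {"mean_log": np.log(15_000.0),
                                         "sigma_log": 0.5,
                                         "min": 4000, "max": 60_000}),
        deletion_fraction=0.3)


@pytest.fixture(scope="session")
def experiment(small_config):
    return ml.simulate_experiment(small_config, with_population=True)


@pytest.fixture(scope="session")
def analyzed(experiment):
    return ml.analyze_experiment(experiment)


def make_toy_bundle():
    """One 120-bp chromosome with a single plus-strand gene.

    CDS (31..60): ATG CAA CTT GGG TGC TCA GAT CCC TGG TAA
    amino acids:   M   Q   L   G   C   S   D   P   W   *
    """
    cds_seq = "ATGCAACTTGGGTGCTCAGATCCCTGGTAA"
    seq = "A" * 30 + cds_seq + "A" * 60
    genes = [GeneModel(gene_id="g1", chrom="t1", strand="+", cds=[(31, 60)])]
    return ReferenceBundle(sequences={"t1": encode_seq(seq)}, genes=genes)


@pytest.fixture()
def toy_bundle():
    return make_toy_bundle()
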