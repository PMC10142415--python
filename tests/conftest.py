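"""Shared fixtures: the reference design and small simulated experiments."""

from __future__ import annotations

from dataclasses import replace

import pytest

import nuhash as nh


@pytest.fixture(scope="session")
def design() -> nh.HashDesign:
    return nh.reference_design()


@pytest.fixture(scope="session")
def two_sample_design(design) -> nh.HashDesign:
    """2-plex barnyard subset (one human, one mouse sample)."""
    return nh.HashDesign(
        barcodes=design.barcodes[:2],
        umi1_len=design.umi1_len, umi2_len=design.umi2_len,
        anchor5=design.anchor5, anchor3=design.anchor3,
    )


@pytest.fixture(scope="session")
def clean_sim(design, tmp_path_factory):
    """Noise-free 2-plex run: no doublets, no ambient, no sequencing error."""
    config = replace(
        nh.barnyard_config(200, 2, seed=1),
        doublet_rate=0.0, ambient_fraction=0.0, base_error_rate=0.0,
        cross_species_noise=0.0,
    )
    out = tmp_path_factory.mktemp("clean_sim")
    return nh.simulate_experiment(config, design, out)


@pytest.fixture(scope="session")
def clean_matrix(clean_sim, design) -> nh.HashCountMatrix:
    return nh.count_hashes(clean_sim.fastq_r1, clean_sim.fastq_r2,
                           clean_sim.fastq_index, clean_sim.whitelist, design)


@pytest.fixture(scope="session")
def barnyard_sim(design, tmp_path_factory):
    """The default realistic preset at 500 nuclei per sample, seed 1."""
    config = nh.barnyard_config(500, 2, seed=1)
    out = tmp_path_factory.mktemp("barnyard_sim")
    return nh.simulate_experiment(config, design, out)


@pytest.fixture(scope="session")
def barnyard_matrix(barnyard_sim, design) -> nh.HashCountMatrix:
    return nh.count_hashes(barnyard_sim.fastq_r1, barnyard_sim.fastq_r2,
                           barnyard_sim.fastq_index,
                           barnyard_sim.whitelist, design)
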