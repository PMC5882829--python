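"""Shared fixtures: a toy polyploid simulation reused across test modules."""

from __future__ import annotations

import pytest

from polytile import simulate
from polytile.markers import design_markers


@pytest.fixture(scope="session")
def toy_params() -> simulate.SimulationParams:
    return simulate.SimulationParams(
        n_genes=12,
        region_length_bp=70_000,
        ploidy=2,
        n_tandem_dup_genes=2,
        transcript_detect_count=12,
        gene_loss_rate=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def toy_sim(toy_params):
    reference = simulate.simulate_reference_region(toy_params)
    homeologs, truths = simulate.derive_homeologs(reference, toy_params)
    transcripts = simulate.simulate_transcriptome(reference, truths, toy_params)
    library = simulate.simulate_bac_library(
        homeologs, 40, insert_mean_bp=16_000, insert_sd_bp=2_500, layout=(2, 5, 5), seed=1
    )
    return {
        "params": toy_params,
        "reference": reference,
        "homeologs": homeologs,
        "truths": truths,
        "transcripts": transcripts,
        "library": library,
    }


@pytest.fixture(scope="session")
def toy_markers(toy_sim):
    return design_markers(toy_sim["reference"].genes, toy_sim["transcripts"])
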