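"""Shared fixtures: a small synthetic cross and its pipeline result.

The small cross keeps every structural feature of the default study
conditions (planted element with TIRs/TSD, RIPed paralogs, decoy
insertions, three time-point libraries) at reduced scale so unit tests run
quickly; full-scale conditions are exercised in the acceptance tests.
"""

import numpy as np
import pytest

from masirna import (
    CrossConfig,
    ElementSpec,
    SrnaProfile,
    run_pipeline,
    simulate_cross,
)


def small_config(**overrides) -> CrossConfig:
    defaults = dict(
        chrom_length=30_000,
        mito_length=3_000,
        element=ElementSpec(body_length=800, tir_length=20, tsd_length=3),
        decoy_lengths=(600, 1200),
        srna=SrnaProfile(
            background_counts={"rRNA": 3000, "tRNA": 1500, "snoRNA": 600,
                               "milRNA": 600, "disiRNA": 600, "mito": 600,
                               "other": 1000},
            masirna_counts={"PP": 60, "2dPF": 60, "4dPF": 2000},
        ),
    )
    defaults.update(overrides)
    return CrossConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_cross(small_config(), seed=20240)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    b = small_bundle
    return run_pipeline(b.occupied, b.annotations, b.srna, b.wgs_reads,
                        carrier_wgs_records=b.carrier_wgs_reads,
                        empty_genome=b.empty)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
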