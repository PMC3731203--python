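import numpy as np
import pytest

import ribocodon as rc
from ribocodon.reference import OrfModel


def make_orf(orf_id: str, coding: str, up: str = "C" * 60, down: str = "C" * 60) -> OrfModel:
    orf = OrfModel(orf_id, coding, up, down)
    orf.validate(strict=False)
    return orf


@pytest.fixture(scope="session")
def small_orfs():
    return rc.build_synthetic_reference(6, (60, 110), seed=7)


@pytest.fixture(scope="session")
def uniform_length_truth(small_orfs):
    """Truth with equal mass on all 7 footprint lengths (calibration tests)."""
    return rc.SimulationTruth(
        gene_flux=rc.uniform_flux(small_orfs),
        length_distribution={L: 1 / 7 for L in range(25, 32)},
        seed=11,
    )


@pytest.fixture(scope="session")
def null_library(small_orfs, uniform_length_truth):
    """A deep null library with its calibration and pooled track."""
    reads = rc.simulate_footprints(small_orfs, uniform_length_truth, 200_000, seed=11)
    sized = rc.reads_to_sized_counts(reads)
    calib = rc.calibrate_psite(sized, small_orfs)
    track = rc.pool_and_frameshift(sized, small_orfs, calib)
    return {"reads": reads, "sized": sized, "calibration": calib, "track": track}
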