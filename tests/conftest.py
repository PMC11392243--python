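"""Shared fixtures.

The expensive artefacts — the end-to-end study run and a trained phantom
segmenter — are session-scoped so the acceptance tests and the module tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from echoflow.phantom import PhantomConfig, generate_cohort, generate_sequence
from echoflow.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def study_result(tmp_path_factory):
    """Full pipeline on the 40-subject phantom study cohort.

    Study conditions: 20 RWMA + 20 normal subjects, hypokinesia factor 0.3,
    two cardiac cycles of 25 frames at 64x64 (the desk-scale phantom size),
    28 disjoint fine-tune subjects for the segmenter and the backbones.
    """
    cfg = PipelineConfig(
        workdir=tmp_path_factory.mktemp("study"),
        n_rwma=20, n_normal=20,
        phantom=PhantomConfig(image_size=64, frames_per_cycle=25, n_cycles=2,
                              hypokinesia_factor=0.3),
        verbosity=30,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """10 labelled subjects at 64x64, one cycle — for cheap module tests."""
    tmpl = PhantomConfig(image_size=64, frames_per_cycle=25, n_cycles=1,
                         hypokinesia_factor=0.3)
    return generate_cohort(5, 5, tmpl, seed=7)


@pytest.fixture(scope="session")
def noiseless_sequence():
    """One noiseless phantom with graded, well-separated segment amplitudes."""
    factors = {0: 1.0, 1: 0.4, 2: 0.8, 3: 0.3, 4: 0.9, 5: 0.5, 6: 0.7, 7: 0.6}
    cfg = PhantomConfig(image_size=128, frames_per_cycle=25, n_cycles=1,
                        hypokinetic_segments=factors, speckle_sigma=0.0, seed=3)
    return generate_sequence(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
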