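"""Shared fixtures.

The full study-scale pipeline run (24 subjects, 30 parcels, 3
conditions) takes a few minutes, so it is executed once per session
and shared by every test that inspects end-to-end behavior.
"""

from __future__ import annotations

import numpy as np
import pytest

from chronnect import (
    PipelineConfig,
    SyntheticConfig,
    run_pipeline,
)
from chronnect.registry import load_hub_registry, packaged_table_paths


@pytest.fixture(scope="session")
def hub_registry():
    return load_hub_registry(packaged_table_paths())


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full synthetic pipeline run at the study-scale design.

    Trial count is scaled up (96 per condition) to keep per-node graph
    metrics at a signal-to-noise ratio comparable to the
    full-resolution (278-parcel) setting, compensating the reduced
    30-parcel network; see docs/methods.md.
    """
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(
        synthetic=SyntheticConfig(n_trials_per_condition=96, seed=20260930),
        output_dir=str(out),
    )
    manifest = run_pipeline(cfg)
    return cfg, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
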