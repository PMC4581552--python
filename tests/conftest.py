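"""Shared fixtures: packaged synthetic arrays/cochleae and one full batch
run reused by the acceptance checks."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cisim.batch import RunConfig, run_batch
from cisim.cochlea import synthesize_cochlea
from cisim.electrode import (
    CurlingProfile,
    ElectrodeConfig,
    profile_from_config,
    synthesize_curling_profile,
)
from cisim.fixtures import make_fixtures

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def moderate_profile():
    return synthesize_curling_profile("moderate")


@pytest.fixture(scope="session")
def flat_profile():
    return synthesize_curling_profile("flat")


@pytest.fixture(scope="session")
def pronounced_profile():
    return synthesize_curling_profile("pronounced")


@pytest.fixture(scope="session")
def cm_cochlea():
    return synthesize_cochlea(size="CM")


@pytest.fixture(scope="session")
def straight_profile():
    """Ideal straight start configuration (zero bow), short recording."""
    cfg = ElectrodeConfig(start_sagitta=0.0, s_max=1.0, step=0.2)
    return profile_from_config(cfg, label="straight")


def reduce_profile(profile: CurlingProfile, n_steps: int, stride: int = 1) -> CurlingProfile:
    """Sub-sampled copy with the first ``n_steps`` states at the stride."""
    states = profile.states[::stride][:n_steps]
    return CurlingProfile(
        states=states,
        s_max=float(states[-1].stylet_extraction_s),
        label=profile.label + f"-reduced{n_steps}",
        config=profile.config,
        meta=dict(profile.meta),
    )


@pytest.fixture(scope="session")
def batch_result(tmp_path_factory):
    """One full batch over the packaged fixtures: 4 arrays x 3 cochleae x
    3 strategies.  Built once per session; several acceptance checks read
    different aspects of it."""
    root = tmp_path_factory.mktemp("batch")
    fdir = root / "fixtures"
    make_fixtures(seed=0, outdir=fdir)
    cfg = RunConfig(
        fixture_dir=str(fdir),
        output_dir=str(root / "results"),
        seed=0,
        write_traces=False,
        log_level="WARNING",
    )
    return run_batch(cfg)


def batch_histograms(batch):
    """{(array, cochlea, strategy): (5,) grade histogram} from a batch."""
    out = {}
    for rec in batch.records:
        h = np.array(
            [rec["grade_0"], rec["grade_I"], rec["grade_II"], rec["grade_III"], rec["grade_IV"]]
        )
        out[(rec["array"], rec["cochlea"], rec["strategy"])] = h
    return out
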