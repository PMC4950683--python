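import numpy as np
import pytest

import restex as rx

#: master seed for all synthetic study conditions exercised by the suite
STUDY_SEED = 0


@pytest.fixture(scope="session")
def rft():
    return rx.rft_design()


@pytest.fixture(scope="session")
def edt():
    return rx.edt_design()


@pytest.fixture(scope="session")
def truth8():
    """Default 8-subject study conditions."""
    return rx.default_ground_truth(8, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def edt_task_runs(truth8, edt):
    """One task run + confounds per subject under the EDT paradigm."""
    return {
        sub: rx.generate_subject(edt, truth8, sub, "task", run_label="EDT")
        for sub in truth8.subjects
    }


@pytest.fixture(scope="session")
def experiment():
    """The full 8-subject EDT experiment (GSR on), shared across tests."""
    config = rx.ExperimentConfig(
        n_subjects=8, designs=("EDT",), gsr="on", seed=STUDY_SEED
    )
    return rx.run_experiment(config)


@pytest.fixture()
def tiny_run():
    """A small deterministic 4-D run for plumbing tests."""
    rng = np.random.default_rng(7)
    data = rng.standard_normal((4, 4, 3, 40))
    mask = np.ones((4, 4, 3), dtype=bool)
    return rx.BoldRun(data=data, tr=1.4, mask=mask)


def make_confounds(n, seed=5):
    rng = np.random.default_rng(seed)
    return rx.ConfoundSet(
        motion=rng.standard_normal((n, 6)),
        white_matter=rng.standard_normal(n),
        csf=rng.standard_normal(n),
        global_signal=rng.standard_normal(n),
    )


@pytest.fixture()
def tiny_confounds(tiny_run):
    return make_confounds(tiny_run.n_volumes)
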