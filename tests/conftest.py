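import numpy as np
import pytest

from hybridbci.config import PipelineConfig
from hybridbci.synthetic import SimConfig, generate_session


def small_sim_config(**overrides) -> SimConfig:
    """Short session that still fits the standard epoch windows."""
    base = dict(n_trials_per_class=3, rest_s=8.0, task_s=4.0, post_s=18.0,
                fs_eeg=500.0, fs_fnirs=7.81, seed=7)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_session():
    return generate_session(small_sim_config())


@pytest.fixture(scope="session")
def default_session():
    """One full-size session (50 trials) shared across structural tests."""
    return generate_session(SimConfig(seed=3))


@pytest.fixture(scope="session")
def default_run(default_session):
    """Preprocessed epochs + selection for the shared default session."""
    from hybridbci import preprocess as pre
    from hybridbci import select as sel

    cfg = PipelineConfig()
    eeg_epochs = pre.preprocess_eeg(default_session)
    series, hb_epochs = pre.preprocess_fnirs(default_session)
    selection, glm = sel.select_from_hbo(
        series.hbo, default_session.events, default_session.fs_fnirs,
        default_session.montage, alpha=cfg.select.alpha)
    return {"session": default_session, "cfg": cfg, "eeg_epochs": eeg_epochs,
            "hb_series": series, "hb_epochs": hb_epochs,
            "selection": selection, "glm": glm}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
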