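import numpy as np
import pandas as pd
import pytest

from metacog.synthetic_cohort import ObserverParams, run_staircase_session


def make_observer(meta_noise: float = 0.0, conf_bias: float = 0.0,
                  sens_memory: float = 2.7, sens_perception: float = 2.3,
                  subject_id: str = "s0", **kwargs) -> ObserverParams:
    defaults = dict(
        subject_id=subject_id, age=30, age_group=2,
        sens_memory=sens_memory, sens_perception=sens_perception,
        meta_noise_memory=meta_noise, meta_noise_perception=meta_noise,
        conf_bias_memory=conf_bias, conf_bias_perception=conf_bias,
        conf_gain=1.5, spe_mean_memory=5.0, spe_mean_perception=5.0)
    defaults.update(kwargs)
    return ObserverParams(**defaults)


def session_frame(obs: ObserverParams, domain: str, n_trials: int,
                  seed) -> pd.DataFrame:
    """Trial table (CSV schema) for one staircased session."""
    recs = run_staircase_session(obs, domain, n_trials, seed)
    df = pd.DataFrame([r.__dict__ for r in recs])
    df["rt_decision_s"] = df.pop("rt_decision")
    df["rt_confidence_s"] = df.pop("rt_confidence")
    df["age"] = obs.age
    df["age_group"] = obs.age_group
    return df


@pytest.fixture(scope="session")
def ideal_session():
    """10,000 staircased trials of a metacognitively ideal observer."""
    return session_frame(make_observer(meta_noise=0.0), "memory", 10000, 7)


@pytest.fixture(scope="session")
def ideal_counts(ideal_session):
    from metacog.preprocess import preprocess_trials
    _, counts, _ = preprocess_trials(ideal_session)
    return counts[0]
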