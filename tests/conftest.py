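import pytest

import fnirsblock as fb


@pytest.fixture(scope="session")
def montage():
    return fb.build_paper_montage()


@pytest.fixture(scope="session")
def quiet_cfg():
    """Noiseless, systemic-free configuration (identity checks)."""
    return fb.SimulationConfig(
        seed=7,
        mayer_amp=0.0,
        cardiac_amp=0.0,
        drift_scale=0.0,
        noise_sigma=0.0,
        od_noise_sigma=0.0,
        subject_gain_sd=0.0,
        trials_per_condition=5,
    )


@pytest.fixture(scope="session")
def quiet_session(quiet_cfg, montage):
    return fb.generate_session(quiet_cfg, 0, montage)


@pytest.fixture(scope="session")
def default_session(montage):
    """One subject under the full default noise model (fewer trials for speed)."""
    cfg = fb.SimulationConfig(seed=3, trials_per_condition=8)
    return fb.generate_session(cfg, 0, montage)


@pytest.fixture(scope="session")
def hb_session(default_session):
    """Default session converted to μM."""
    rec, gt = default_session
    return fb.beer_lambert(fb.to_optical_density(rec)), gt


def roi_estimate_table(betas_by_subject):
    """Helper: tidy estimate table from {subject: {(roi, cond, chroma): est}}."""
    import pandas as pd

    rows = [
        (subj, roi, cond, chroma, est)
        for subj, cells in betas_by_subject.items()
        for (roi, cond, chroma), est in cells.items()
    ]
    return pd.DataFrame(
        rows, columns=["subject", "roi", "condition", "chroma", "estimate"]
    )
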