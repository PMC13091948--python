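import numpy as np
import pandas as pd
import pytest

import tinntraj as tj


@pytest.fixture(scope="session")
def small_study():
    """A small two-class study with ground truth, smoothed and model-ready."""
    cfg = tj.SimConfig(
        n_subjects=60,
        n_days=84,
        class_proportions=(0.5, 0.5),
        class_anchor_curves=(((0, 20.0), (83, 25.0)), ((0, 70.0), (83, 60.0))),
        sigma_b=5.0,
        sigma_eps=5.0,
        missing_raw_fraction=0.2,
        seed=42,
    )
    panel, truth = tj.simulate_panel(cfg)
    smoothed = tj.smooth_panel(panel, cfg.n_days, items=[tj.PRIMARY_ITEM])
    data = tj.build_model_data(smoothed, tj.PRIMARY_ITEM)
    return cfg, panel, truth, smoothed, data


@pytest.fixture(scope="session")
def default_recovery():
    """Default study conditions (147 subjects, 84 days, 22.5% MCAR) fitted at G=4."""
    cfg = tj.default_study_config(seed=7)
    panel, truth = tj.simulate_panel(cfg)
    filtered, _ = tj.compliance_filter(panel, tj.PRIMARY_ITEM, 0.5, cfg.n_days)
    smoothed = tj.smooth_panel(filtered, cfg.n_days, items=[tj.PRIMARY_ITEM])
    data = tj.build_model_data(smoothed, tj.PRIMARY_ITEM)
    spec = tj.LCGMMSpec(4, data.basis, data.time_scale)
    fit = tj.grid_search_fit(data, spec, n_starts=30, burn_iters=30, seed=7)
    return cfg, panel, truth, data, fit


def panel_from_records(records):
    """Build an EMAPanel from (subject, day, item, value) tuples."""
    return tj.EMAPanel(
        pd.DataFrame(records, columns=["subject_id", "day", "item", "value"])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
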