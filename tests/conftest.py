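import pytest

import surveyfuse as sf


@pytest.fixture(scope="session")
def likert_population_50k():
    """Default-calibrated Likert population at n=50,000 (shared across
    calibration tests; truth computation skipped for speed)."""
    cfg = sf.PopulationConfig(n_population=50_000, seed=12345, compute_truth=False)
    frame, truth = sf.generate_population(cfg)
    return frame, truth


def make_gaussian_surveys(n_per_file, seed, **cfg_kwargs):
    """Well-specified continuous two-survey instance with known truth."""
    cfg = sf.PopulationConfig(
        n_population=2 * n_per_file, measurement="gaussian", seed=seed, **cfg_kwargs
    )
    pop, truth = sf.generate_population(cfg)
    A, B = sf.split_surveys(pop, sf.SplitSpec(frac_A=0.5, seed=seed + 1))
    return A, B, truth


@pytest.fixture()
def gaussian_surveys():
    return make_gaussian_surveys(1000, seed=42)


def null_anchor_config_kwargs():
    """Generator settings with no exposure-outcome or demographic signal:
    every pair is a true null given any covariate set."""
    return dict(
        target_anchors={(e, o): 0.0 for e in sf.EXPOSURES for o in sf.OUTCOMES},
        exposure_loading=0.0,
        outcome_loading=0.0,
    )
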