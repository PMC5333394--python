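import logging

import numpy as np
import pytest

from gllrasch.data import AnalysisConfig, apply_scoring, complete_case_filter, packaged_scales
from gllrasch.pipeline import run_full_analysis
from gllrasch.simulate import SyntheticConfig, generate_cohort, generate_study_cohort

logging.getLogger("gllrasch").setLevel(logging.ERROR)


def coded_cohort(cfg: SyntheticConfig):
    """Generate a cohort and return (coded complete-case scores, truth)."""
    raw, _, truth = generate_cohort(cfg)
    rm = complete_case_filter(apply_scoring(raw, cfg.scale))
    return rm.values_int(), truth


@pytest.fixture(scope="session")
def rasch_cohort_1000():
    """Locally independent 5-item, 5-category cohort with known thresholds."""
    cfg = SyntheticConfig(n=1000, seed=42)
    scores, truth = coded_cohort(cfg)
    return cfg, scores, truth


@pytest.fixture(scope="session")
def study_bundle():
    """One full pipeline run on the packaged 99-person study-shaped cohort."""
    scales = packaged_scales()
    responses, covariates, _ = generate_study_cohort(scales, seed=3)
    config = AnalysisConfig(seed=1, n_bootstrap=200, mc_persons=2000)
    return run_full_analysis(responses, covariates, scales, config)
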