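import numpy as np
import pandas as pd
import pytest

from serogx.cleaning import clean_serology
from serogx.compare import build_analysis_dataset
from serogx.mixture import decide_all
from serogx.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size cohort at the study conditions (2587 subjects), cleaned."""
    cfg = CohortConfig.default(seed=11)
    subjects, assays, truth = generate_cohort(cfg, return_truth=True)
    cleaned = clean_serology(subjects, assays)
    return cfg, subjects, assays, truth, cleaned


@pytest.fixture(scope="session")
def study_dataset(study_cohort):
    _, _, _, _, cleaned = study_cohort
    decisions = decide_all(cleaned.residuals)
    return build_analysis_dataset(cleaned.subjects, cleaned.residuals,
                                  decisions), decisions


def make_null_dataset(seed, group_size=40, n_analytes_correlated=False):
    """Small all-null cohort as an AnalysisDataset (continuous features)."""
    cfg = CohortConfig.null(seed=seed, group_size=group_size)
    subjects, assays = generate_cohort(cfg)
    cleaned = clean_serology(subjects, assays, exclude_flagged_plates=False)
    decisions = decide_all(cleaned.residuals)
    return build_analysis_dataset(cleaned.subjects, cleaned.residuals,
                                  decisions)
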