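"""Shared fixtures: the study-replicating synthetic dataset and helpers."""

import pytest

from ribotriage.pipeline import run_pipeline
from ribotriage.simulate import gen_structure_db, study_plan


@pytest.fixture(scope="session")
def study_dataset():
    """(structures, ground truth, compound→motif table) of the full plan."""
    plans, bound = study_plan()
    structures, truth = gen_structure_db(plans, seed=20230524)
    return structures, truth, bound


@pytest.fixture(scope="session")
def study_report(study_dataset):
    structures, _, bound = study_dataset
    return run_pipeline(structures, bound=bound)
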