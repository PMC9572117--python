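import pytest

from swaydetect import evaluation, pipeline, rig


@pytest.fixture(scope="session")
def small_dataset():
    """Two geometry cases, six patterns per class — fast unit-test rig."""
    cases = rig.default_cases(rig.RigConfig(seed=11))
    return rig.generate_dataset(
        {1: cases[1], 4: cases[4]}, {c: 6 for c in rig.CLASSES}, seed=11
    )


@pytest.fixture(scope="session")
def study_dataset():
    """Full six-case design, 25 patterns per class per case (600 total)."""
    cases = rig.default_cases(rig.RigConfig(seed=5))
    return rig.generate_dataset(cases, {c: 25 for c in rig.CLASSES}, seed=5)


@pytest.fixture(scope="session")
def study_tables(study_dataset):
    """(time table, DWT table, labels, train idx, test idx) with 60/40 split."""
    time_df, dwt_df, y = pipeline.feature_tables(study_dataset)
    tr, te = evaluation.split_indices(len(y), train_fraction=0.6, seed=5)
    return time_df, dwt_df, y, tr, te
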