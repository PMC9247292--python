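import numpy as np
import pytest

from hrdbench import (
    default_study_config,
    label_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def study_cohort():
    """One deterministic study-sized synthetic cohort (828 tumors)."""
    return simulate_cohort(default_study_config(), seed=20240917)


@pytest.fixture(scope="session")
def study_evidence(study_cohort):
    return label_cohort(
        [s.sample_id for s in study_cohort.samples], study_cohort.alterations
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def cohort_tsv(tmp_path):
    path = tmp_path / "cohort.tsv"
    path.write_text(
        "sample_id\tcancer_type\tchord_score\thrdetect_score\n"
        "S1\tBreast\t0.1\t0.2\n"
        "S2\tovary\t0.5\t0.55\n"
        "S3\tpancreas\t0.99\t0.97\n"
    )
    return path


@pytest.fixture()
def alterations_tsv(tmp_path):
    path = tmp_path / "alterations.tsv"
    path.write_text(
        "sample_id\tgene\thit_class\n"
        "S3\tBRCA1\tgermline_pv\n"
        "S3\tBRCA1\tloh\n"
        "S2\tRAD51C\tPromoter_Methylation\n"
        "S2\tRAD51C\tloh\n"
    )
    return path
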