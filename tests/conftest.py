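import pytest

from founderhap.fixtures import (
    literature_cohort_counts,
    study_cohort,
    study_genotypes,
    study_map,
)


@pytest.fixture(scope="session")
def gmap():
    return study_map()


@pytest.fixture(scope="session")
def genotypes():
    return study_genotypes()


@pytest.fixture(scope="session")
def cohort():
    return study_cohort()


@pytest.fixture(scope="session")
def literature():
    return literature_cohort_counts()


@pytest.fixture()
def fixture_dir(tmp_path, gmap, genotypes, cohort, literature):
    """Study fixtures written out as the three text dialects plus counts JSON."""
    import json

    from founderhap.io import write_cohort, write_genotypes, write_map

    write_map(gmap, tmp_path / "markers.map")
    write_genotypes(genotypes, tmp_path / "genotypes.ped")
    write_cohort(cohort, tmp_path / "cohort.tsv")
    (tmp_path / "literature.json").write_text(json.dumps(literature))
    return tmp_path
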