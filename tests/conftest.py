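import numpy as np
import pandas as pd
import pytest

from pancankit.cohort import Cohort
from pancankit.simulate import reference_fixture
from pancankit.ingest import save_cohort


@pytest.fixture(scope="session")
def fixture():
    """The cached reference cohort and its truth record (read-only)."""
    return reference_fixture()


@pytest.fixture(scope="session")
def cohort(fixture):
    return fixture[0]


@pytest.fixture(scope="session")
def truth(fixture):
    return fixture[1]


@pytest.fixture(scope="session")
def bundle_dir(cohort, tmp_path_factory):
    """The reference cohort serialized once for CLI tests."""
    path = tmp_path_factory.mktemp("bundle") / "cohort"
    save_cohort(cohort, path, seed=0)
    return path


@pytest.fixture
def tiny_cohort():
    """Hand-built COAD cohort: 5 tumor, 3 normal, 3 aligned pairs."""
    rng = np.random.default_rng(11)
    tumors = [f"SYNT-CD-{i:04d}-01A" for i in range(5)]
    normals = [f"SYNT-CD-{i:04d}-11A" for i in range(3)]
    samples = tumors + normals
    genes = ["KLF7", "KLF4", "TP53", "MYC"]
    expr = pd.DataFrame(rng.uniform(0.5, 8, (8, 4)), index=samples,
                        columns=genes)
    ann = pd.DataFrame(
        {"patient_id": ["-".join(s.split("-")[:3]) for s in samples],
         "group": ["tumor"] * 5 + ["normal"] * 3,
         "cancer_type": "COAD"}, index=pd.Index(samples, name="sample_id"))
    clinical = pd.DataFrame(
        {"age": [55, 70, 61, 48, 80],
         "os_time": [100.0, 400.0, 250.0, 90.0, 600.0],
         "os_event": [1, 0, 1, 1, 0]},
        index=pd.Index([f"SYNT-CD-{i:04d}" for i in range(5)],
                       name="patient_id"))
    tmb = pd.Series(rng.uniform(1, 20, 5), index=tumors, name="TMB")
    return Cohort(expression=expr, annotations=ann, clinical=clinical,
                  metrics={"TMB": tmb})
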