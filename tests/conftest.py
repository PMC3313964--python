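import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodegap.io_metadata import LocusAlignment, SampleRecord

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture()
def two_species_alignment():
    """Two clearly separated species, 3 samples each, 300 columns."""
    rng = np.random.default_rng(42)
    base = rng.choice(list("ACGT"), 300)
    other = base.copy()
    for k in rng.choice(300, 40, replace=False):
        other[k] = "ACGT"["ACGT".index(other[k]) - 1]
    rows = {}
    for i in range(3):
        a = base.copy()
        b = other.copy()
        # one private substitution each so rows are distinct
        a[i] = "ACGT"["ACGT".index(a[i]) - 2]
        b[299 - i] = "ACGT"["ACGT".index(b[299 - i]) - 2]
        rows[f"alpha_{i}"] = "".join(a)
        rows[f"beta_{i}"] = "".join(b)
    aln = LocusAlignment("demo", rows)
    records = [
        SampleRecord(sid, sid.split("_")[0], "sectionA" if sid.startswith("alpha") else "sectionB")
        for sid in rows
    ]
    return aln, records
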